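"""Power versus interaction effect size, at reduced scale.

Sweeps the rare-variant interaction magnitude c over three values
(with the common-variant effect at 2c) using 100 replicates and 500
permutations per point, and prints the empirical power of each test
at alpha = 0.05.  Power should rise with c, and the variable-weight
test should lead when both rare and common effects are present; the
full 5-point sweep runs in the acceptance checks.
"""

from towse import SimulationConfig, run_power_experiment

cfg = SimulationConfig(replicates=100, permutations=500, seed=9)
df = run_power_experiment(cfg, c_grid=(0.02, 0.06, 0.10))
print(df.pivot(index="c", columns="test", values="power"))
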