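import numpy as np
import pytest

from towse.simulate import (HaplotypePool, SimulationConfig,
                            build_haplotype_pool, draw_genotypes,
                            run_power_experiment, run_type1_experiment,
                            simulate_trait)


class TestHaplotypePool:
    def test_default_pool_matches_requested_spectrum(self, rng):
        pool = build_haplotype_pool(rng=rng)
        mafs = pool.implied_mafs()
        assert pool.haplotypes.shape == (64, 10)
        assert pool.frequencies.sum() == pytest.approx(1.0)
        assert ((mafs[:8] >= 0.001) & (mafs[:8] < 0.01)).all()
        assert ((mafs[8:] >= 0.05) & (mafs[8:] <= 0.5)).all()

    def test_haplotype_structure_shares_backbones(self, rng):
        # common variants ride on shared backbone haplotypes, not singletons
        pool = build_haplotype_pool(rng=rng)
        carriers = pool.haplotypes[:, 8:].sum(axis=0)
        assert (carriers >= 1).all()

    def test_infeasible_spectrum_rejected(self, rng):
        # two haplotypes cannot realise a MAF below 0.01
        with pytest.raises(ValueError):
            build_haplotype_pool(m_rare=1, m_common=0, n_haplotypes=2, rng=rng)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            HaplotypePool(haplotypes=np.zeros((2, 1)), frequencies=np.array([0.6, 0.6]),
                          m_rare=1, m_common=0)

    def test_empirical_mafs_match_implied(self, rng):
        pool = build_haplotype_pool(rng=rng)
        n = 100_000
        geno = draw_genotypes(pool, n, rng)
        implied = pool.implied_mafs()
        emp = geno.counts.mean(axis=0) / 2.0
        se = np.sqrt(implied * (1 - implied) / (2 * n))
        # 4 SE per variant keeps the family-wise failure odds across the
        # 10 simultaneous checks at the per-check 3-SE level
        assert (np.abs(emp - implied) <= 4 * se + 1e-12).all()


class TestDrawGenotypes:
    def test_single_zero_haplotype(self, rng):
        pool = HaplotypePool(haplotypes=np.zeros((1, 3)), frequencies=np.array([1.0]),
                             m_rare=3, m_common=0)
        geno = draw_genotypes(pool, 10, rng)
        np.testing.assert_array_equal(geno.counts, 0)

    def test_single_carrier_haplotype_gives_dosage_two(self, rng):
        pool = HaplotypePool(haplotypes=np.ones((1, 2)), frequencies=np.array([1.0]),
                             m_rare=0, m_common=2)
        geno = draw_genotypes(pool, 7, rng)
        np.testing.assert_array_equal(geno.counts, 2)

    def test_two_haplotype_binomial_mean(self, rng):
        q = 0.3
        pool = HaplotypePool(haplotypes=np.array([[0], [1]]),
                             frequencies=np.array([1 - q, q]),
                             m_rare=0, m_common=1)
        n = 100_000
        geno = draw_genotypes(pool, n, rng)
        se = np.sqrt(2 * q * (1 - q) / n)
        assert abs(geno.counts.mean() - 2 * q) <= 3 * se


class _SkeletonRng:
    """Stub generator: first normal call returns ones, later calls zeros."""

    def __init__(self):
        self.normal_calls = 0

    def normal(self, size=None):
        self.normal_calls += 1
        return np.ones(size) if self.normal_calls == 1 else np.zeros(size)

    def binomial(self, n, p, size=None):
        return np.zeros(size, dtype=int)

    def choice(self, options, size=None, replace=True, p=None):
        return np.asarray(options)[np.zeros(size, dtype=int)]


class TestSimulateTrait:
    def test_deterministic_skeleton(self, rng):
        # Z1 = 1, Z2 = 0, all coefficients and noise zero -> Y = 0.5
        pool = build_haplotype_pool(rng=rng)
        geno = draw_genotypes(pool, 5, rng)
        cfg = SimulationConfig(n=5, alpha1=0.0, main_effect=False, c=0.0)
        pheno = simulate_trait(geno, cfg, _SkeletonRng())
        np.testing.assert_allclose(pheno.y, 0.5)

    def test_null_variance_composition(self, rng):
        # Var(Y) = 0.25 Var(Z1) + 0.25 Var(Z2) + alpha1^2 Var(E) + Var(eps)
        #        = 0.25 + 0.0625 + alpha1^2 + 1 under the null without main effects
        pool = build_haplotype_pool(rng=rng)
        n = 100_000
        geno = draw_genotypes(pool, n, rng)
        cfg = SimulationConfig(n=n, main_effect=False, c=0.0)
        pheno = simulate_trait(geno, cfg, rng)
        target = 1.3125 + cfg.alpha1 ** 2
        mc_se = np.sqrt(2.0 / (n - 1)) * target
        assert abs(pheno.y.var(ddof=1) - target) <= 3 * mc_se

    def test_fixed_seed_reproduces_trait(self, rng):
        pool = build_haplotype_pool(rng=rng)
        geno = draw_genotypes(pool, 50, rng)
        cfg = SimulationConfig(n=50, c=0.05)
        y1 = simulate_trait(geno, cfg, np.random.default_rng(4)).y
        y2 = simulate_trait(geno, cfg, np.random.default_rng(4)).y
        np.testing.assert_array_equal(y1, y2)

    def test_too_many_causal_rare_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            SimulationConfig(n_causal_rare=9)

    def test_interaction_signs_half_positive_rounding_up(self, rng):
        from towse.simulate import _interaction_coefficients
        cfg = SimulationConfig(c=0.1, n_causal_rare=5)
        beta, beta_c = _interaction_coefficients(cfg, rng)
        nz = beta[beta != 0]
        assert nz.size == 5
        assert (nz > 0).sum() == 3 and (nz < 0).sum() == 2
        np.testing.assert_allclose(np.abs(nz), 0.1)
        assert beta_c == pytest.approx(0.2)  # positive, twice the rare magnitude

    def test_binary_environment_mode(self, rng):
        pool = build_haplotype_pool(rng=rng)
        geno = draw_genotypes(pool, 100, rng)
        cfg = SimulationConfig(n=100, env_kind="binary")
        pheno = simulate_trait(geno, cfg, rng)
        assert set(np.unique(pheno.env)) <= {0.0, 1.0}


class TestExperiments:
    def test_degenerate_alpha_level_rejects_everything(self):
        cfg = SimulationConfig(n=300, replicates=20, permutations=100, seed=12)
        df = run_type1_experiment(cfg, alphas=(1.0,))
        assert (df["rate"] == 1.0).all()

    def test_reduced_null_run_is_calibrated(self):
        # 200 replicates, B=500: empirical rate within the exact binomial
        # 99% interval around the nominal level
        from scipy.stats import binom

        cfg = SimulationConfig(replicates=200, permutations=500, seed=2024)
        df = run_type1_experiment(cfg, alphas=(0.05,))
        reps = 200
        lo = binom.ppf(0.005, reps, 0.05) / reps
        hi = binom.ppf(0.995, reps, 0.05) / reps
        for _, row in df.iterrows():
            assert lo <= row["rate"] <= hi, row["test"]

    def test_experiment_bit_reproducible(self):
        cfg = SimulationConfig(n=200, replicates=5, permutations=100, seed=31)
        df1 = run_type1_experiment(cfg, alphas=(0.05,))
        df2 = run_type1_experiment(cfg, alphas=(0.05,))
        assert df1.equals(df2)

    def test_power_rows_and_range(self):
        cfg = SimulationConfig(n=300, replicates=10, permutations=100, seed=8)
        df = run_power_experiment(cfg, c_grid=(0.0, 0.1))
        assert len(df) == 4  # two tests x two c values
        assert df["power"].between(0, 1).all()
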