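"""Haplotype-pool genotype simulator and Type I error / power experiments.

The study design emulated here is a single 10-variant gene with 8 rare
(MAF < 0.01) and 2 common variants.  Genotypes arise by drawing two
haplotypes per individual from a fixed pool according to its haplotype
frequencies; the pool is synthetic (a few common backbone haplotypes
plus a tail of low-frequency ones, with variant alleles placed on
haplotype subsets so that columns carry weak haplotype correlation
rather than being independent).

The quantitative trait follows

    Y = 0.5 Z1 + 0.5 Z2 + alpha1 E + G' alpha2 + E G' beta
        + E G_c beta_c + eps

with Z1 ~ N(0,1), Z2 ~ Bernoulli(0.5), E ~ N(0,1) (alpha1 = 0.015),
eps ~ N(0,1).  Under the "with main effect" scenario every entry of
alpha2 has magnitude 0.3 with a random sign; otherwise alpha2 = 0.
Interaction effects: a chosen number of rare variants get |beta_j| = c
(half positive, rounding up), and one designated common variant gets
beta_c = 2c, positive.  Setting c = 0 gives the null used for Type I
error.

Experiments redraw genotypes, covariates and noise for every replicate
from a single reproducible random stream; the haplotype pool itself is
built once per experiment, mirroring a fixed empirical pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, SampleTable
from .permutation import derive_rng, joint_test
from .residualize import build_interaction_matrix, residualize
from .vw import DEFAULT_LAMBDA_GRID

__all__ = [
    "HaplotypePool",
    "SimulationConfig",
    "build_haplotype_pool",
    "draw_genotypes",
    "simulate_trait",
    "run_type1_experiment",
    "run_power_experiment",
]


@dataclass
class HaplotypePool:
    """Fixed pool of 0/1 haplotypes with frequencies summing to one."""

    haplotypes: np.ndarray  # H x M of 0/1 alleles
    frequencies: np.ndarray  # length H, nonnegative, sums to 1
    m_rare: int
    m_common: int

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.min() < 0 or abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be nonnegative and sum to 1")
        if self.haplotypes.shape[0] != self.frequencies.size:
            raise ValueError("one frequency per haplotype required")

    @property
    def m(self) -> int:
        return self.haplotypes.shape[1]

    def implied_mafs(self) -> np.ndarray:
        """Population allele frequency of each variant under random pairing."""
        return self.frequencies @ self.haplotypes


@dataclass
class SimulationConfig:
    """All trait-model and experiment parameters with the study defaults."""

    n: int = 2000
    m_rare: int = 8
    m_common: int = 2
    maf_threshold: float = 0.01
    rare_maf_range: tuple[float, float] = (0.001, 0.01)
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    n_haplotypes: int = 64
    alpha1: float = 0.015
    main_effect: bool = True
    alpha2_magnitude: float = 0.3
    n_causal_rare: int = 4
    c: float = 0.0
    beta_common_factor: float = 2.0
    env_kind: str = "continuous"  # "continuous" N(0,1) | "binary" Bernoulli(0.5)
    replicates: int = 1000
    permutations: int = 10_000
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("interaction magnitude c must be nonnegative")
        if self.n_causal_rare > self.m_rare:
            raise ValueError("number of nonzero rare interaction effects exceeds "
                             f"the rare variant count ({self.n_causal_rare} > {self.m_rare})")
        if self.env_kind not in ("continuous", "binary"):
            raise ValueError("env_kind must be 'continuous' or 'binary'")


def build_haplotype_pool(m_rare: int = 8, m_common: int = 2,
                         rare_maf_range: tuple[float, float] = (0.001, 0.01),
                         common_maf_range: tuple[float, float] = (0.05, 0.5),
                         n_haplotypes: int = 64,
                         rng: np.random.Generator | int | None = None) -> HaplotypePool:
    """Construct a synthetic haplotype pool matching a rare/common MAF spectrum.

    A small group of common backbone haplotypes carries ~70% of the
    frequency mass; the remaining mass spreads over a tail of rare
    haplotypes.  Each variant's minor allele is placed greedily on a
    random haplotype subset until its implied frequency lands in the
    requested range; shared haplotypes between variants induce weak LD.
    Raises if the requested spectrum is infeasible for the pool shape.
    """
    if m_rare + m_common < 1:
        raise ValueError("need at least one variant")
    if n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    rng = np.random.default_rng(rng) if rng is None or isinstance(rng, (int, np.integer)) else rng
    last_err: Exception | None = None
    for _ in range(20):
        try:
            pool = _attempt_pool(m_rare, m_common, rare_maf_range, common_maf_range,
                                 n_haplotypes, rng)
        except ValueError as e:
            last_err = e
            continue
        # guard against exact allele-placement collinearity, which would make
        # the genotype main-effect adjustment rank deficient in every sample
        design = np.column_stack([np.ones(n_haplotypes), pool.haplotypes])
        if (n_haplotypes <= pool.m
                or np.linalg.matrix_rank(design) == pool.m + 1):
            return pool
    raise last_err or ValueError("could not build a non-degenerate haplotype pool")


def _attempt_pool(m_rare: int, m_common: int, rare_maf_range, common_maf_range,
                  n_haplotypes: int, rng: np.random.Generator) -> HaplotypePool:
    n_common_hap = min(max(2, n_haplotypes // 10), n_haplotypes - 1)
    n_rare_hap = n_haplotypes - n_common_hap
    w_common = rng.uniform(1.0, 2.0, n_common_hap)
    w_rare = rng.uniform(0.5, 1.5, n_rare_hap)
    freqs = np.concatenate([0.72 * w_common / w_common.sum(),
                            0.28 * w_rare / w_rare.sum()])
    hap = np.zeros((n_haplotypes, m_rare + m_common), dtype=np.int8)
    rare_idx = np.arange(n_common_hap, n_haplotypes)
    common_idx = np.arange(n_common_hap)

    def place(col: int, lo: float, hi: float, order_pool: np.ndarray) -> None:
        for _ in range(200):
            target = rng.uniform(lo, hi)
            order = rng.permutation(order_pool)
            cum, chosen = 0.0, []
            for h in order:
                if cum >= target:
                    break
                if cum + freqs[h] < hi:
                    chosen.append(h)
                    cum += freqs[h]
            if lo <= cum < hi and chosen:
                hap[chosen, col] = 1
                return
        raise ValueError(
            f"cannot place a variant with MAF in [{lo}, {hi}) on this haplotype pool; "
            "increase the number of haplotypes or relax the MAF range")

    for j in range(m_rare):
        place(j, *_checked_range(rare_maf_range), rare_idx)
    for j in range(m_rare, m_rare + m_common):
        lo, hi = _checked_range(common_maf_range)
        place(j, lo, hi, np.concatenate([common_idx, rare_idx]))
    return HaplotypePool(haplotypes=hap, frequencies=freqs,
                         m_rare=m_rare, m_common=m_common)


def _checked_range(r: tuple[float, float]) -> tuple[float, float]:
    lo, hi = r
    if not (0.0 <= lo < hi <= 0.5):
        raise ValueError(f"MAF range must satisfy 0 <= lo < hi <= 0.5, got {r}")
    return lo, hi


def draw_genotypes(pool: HaplotypePool, n: int,
                   rng: np.random.Generator | int | None = None) -> GenotypeMatrix:
    """Sample n diploid genotypes: two independent haplotype draws per individual."""
    rng = np.random.default_rng(rng) if rng is None or isinstance(rng, (int, np.integer)) else rng
    idx = rng.choice(pool.frequencies.size, size=(n, 2), p=pool.frequencies)
    counts = pool.haplotypes[idx[:, 0]] + pool.haplotypes[idx[:, 1]]
    ids = [f"rare_{j + 1}" for j in range(pool.m_rare)] + \
          [f"common_{j + 1}" for j in range(pool.m_common)]
    return GenotypeMatrix(samples=[f"s{i + 1:05d}" for i in range(n)],
                          variant_ids=ids, counts=counts.astype(float))


def _interaction_coefficients(cfg: SimulationConfig, rng: np.random.Generator):
    """Rare-variant interaction vector beta and the common-variant beta_c."""
    beta = np.zeros(cfg.m_rare)
    if cfg.c > 0 and cfg.n_causal_rare > 0:
        causal = rng.choice(cfg.m_rare, size=cfg.n_causal_rare, replace=False)
        k = cfg.n_causal_rare
        signs = np.concatenate([np.ones((k + 1) // 2), -np.ones(k // 2)])
        rng.shuffle(signs)
        beta[causal] = cfg.c * signs
    beta_c = cfg.beta_common_factor * cfg.c if cfg.m_common > 0 else 0.0
    return beta, beta_c


def simulate_trait(geno: GenotypeMatrix, cfg: SimulationConfig,
                   rng: np.random.Generator | int | None = None) -> SampleTable:
    """Generate covariates, environment and trait for one replicate."""
    rng = np.random.default_rng(rng) if rng is None or isinstance(rng, (int, np.integer)) else rng
    n = geno.n
    if geno.m != cfg.m_rare + cfg.m_common:
        raise ValueError("genotype layout does not match the configuration")
    G = geno.counts
    z1 = rng.normal(size=n)
    z2 = rng.binomial(1, 0.5, size=n).astype(float)
    if cfg.env_kind == "continuous":
        env = rng.normal(size=n)
    else:
        env = rng.binomial(1, 0.5, size=n).astype(float)
    eps = rng.normal(size=n)

    if cfg.main_effect:
        alpha2 = cfg.alpha2_magnitude * rng.choice([-1.0, 1.0], size=geno.m)
    else:
        alpha2 = np.zeros(geno.m)
    beta, beta_c = _interaction_coefficients(cfg, rng)

    y = 0.5 * z1 + 0.5 * z2 + cfg.alpha1 * env + G @ alpha2 \
        + env * (G[:, :cfg.m_rare] @ beta) + eps
    if cfg.m_common > 0:
        y = y + env * G[:, cfg.m_rare] * beta_c  # first common variant is the causal one
    return SampleTable(samples=list(geno.samples), y=y, env=env,
                       covariates=np.column_stack([z1, z2]),
                       trait_kind="continuous", covariate_names=["Z1", "Z2"])


def _replicate_pvalues(pool: HaplotypePool, cfg: SimulationConfig,
                       rng: np.random.Generator) -> tuple[float, float]:
    """One replicate: fresh data, residualize, shared-permutation p-values."""
    geno = draw_genotypes(pool, cfg.n, rng)
    pheno = simulate_trait(geno, cfg, rng)
    EG = build_interaction_matrix(geno.counts, pheno.env)
    resid = residualize(pheno.y, EG, Z=pheno.covariates, G=geno.counts, E=pheno.env)
    mafs = geno.mafs()
    perm_seed = int(rng.integers(2**31 - 1))
    tow_res, vw_res = joint_test(resid, mafs, B=cfg.permutations, seed=perm_seed,
                                 maf_threshold=cfg.maf_threshold,
                                 lambda_grid=cfg.lambda_grid)
    return tow_res.p_value, vw_res.p_value


def _binom_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    from scipy.stats import binomtest

    ci = binomtest(k, n).proportion_ci(confidence_level=conf, method="exact")
    return float(ci.low), float(ci.high)


def _experiment_pool(cfg: SimulationConfig) -> HaplotypePool:
    """One fixed gene per experiment: the pool stream depends only on the seed."""
    return build_haplotype_pool(cfg.m_rare, cfg.m_common, cfg.rare_maf_range,
                                cfg.common_maf_range, cfg.n_haplotypes,
                                derive_rng(cfg.seed, "pool"))


def _run_replicates(cfg: SimulationConfig, rng: np.random.Generator,
                    pool: HaplotypePool | None = None) -> pd.DataFrame:
    pool = pool if pool is not None else _experiment_pool(cfg)
    rows = []
    for _ in range(cfg.replicates):
        p_tow, p_vw = _replicate_pvalues(pool, cfg, rng)
        rows.append((p_tow, p_vw))
    return pd.DataFrame(rows, columns=["TOW-SE", "VW-TOW-SE"])


def run_type1_experiment(cfg: SimulationConfig,
                         alphas: tuple[float, ...] = (0.05, 0.01, 0.001)) -> pd.DataFrame:
    """Empirical Type I error of both tests under the null (all interactions zero).

    Forces c = 0 and reports, per test and nominal level, the rejection
    fraction with an exact binomial 95% interval.
    """
    cfg = SimulationConfig(**{**asdict(cfg), "c": 0.0})
    rng = derive_rng(cfg.seed, "type1")
    pvals = _run_replicates(cfg, rng)
    rows = []
    scenario = "with_main_effect" if cfg.main_effect else "no_main_effect"
    for test in pvals.columns:
        for a in alphas:
            k = int((pvals[test] <= a).sum())
            lo, hi = _binom_ci(k, cfg.replicates)
            rows.append({"scenario": scenario, "test": test, "alpha": a,
                         "rate": k / cfg.replicates, "ci_low": lo, "ci_high": hi,
                         "replicates": cfg.replicates, "permutations": cfg.permutations,
                         "seed": cfg.seed})
    return pd.DataFrame(rows)


def run_power_experiment(cfg: SimulationConfig,
                         c_grid: tuple[float, ...] = (0.02, 0.04, 0.06, 0.08, 0.10),
                         alpha: float = 0.05) -> pd.DataFrame:
    """Empirical power of both tests along a grid of interaction magnitudes c."""
    rows = []
    scenario = "with_main_effect" if cfg.main_effect else "no_main_effect"
    pool = _experiment_pool(cfg)  # same gene at every effect size
    for c in c_grid:
        cfg_c = SimulationConfig(**{**asdict(cfg), "c": float(c)})
        rng = derive_rng(cfg.seed, f"power_c{c}")
        pvals = _run_replicates(cfg_c, rng, pool)
        for test in pvals.columns:
            k = int((pvals[test] <= alpha).sum())
            lo, hi = _binom_ci(k, cfg.replicates)
            rows.append({"scenario": scenario, "test": test, "c": float(c),
                         "alpha": alpha, "power": k / cfg.replicates,
                         "ci_low": lo, "ci_high": hi,
                         "replicates": cfg.replicates,
                         "permutations": cfg.permutations, "seed": cfg.seed})
    return pd.DataFrame(rows)
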