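"""Shared permutation null, p-values and the high-level test runners.

Significance of both statistics is evaluated by permuting the residual
trait against the fixed residual interaction matrix.  Because trait and
interaction columns are already orthogonalised to the intercept,
covariates, genotype main effects and environment, reshuffling the
residual trait breaks exactly the interaction association and nothing
else.

One permutation stream serves everything: the full-set statistic T, the
stratum statistics T_r and T_c, and every lambda mixture.  This is both
cheap (one centred cross-product matrix per permutation gives all
per-variant contributions) and required: the VW min-p correction needs
paired permuted statistics.

Monte-Carlo p-values use the add-one convention p = (1 + #{T_b >=
T_obs}) / (1 + B), which cannot be zero and is valid for any B.  The
exhaustive mode enumerates all n! orderings (identity included) and
counts plainly, which is exact for tiny n.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .residualize import ResidualizedData
from .tow import _moments
from .vw import DEFAULT_LAMBDA_GRID, VwStatistic, partition_variants, vw_min_p

__all__ = [
    "PermutationPlan",
    "TestResult",
    "make_plan",
    "permute_residuals",
    "pvalue_tow",
    "pvalue_vw",
    "tow_se_test",
    "vw_tow_se_test",
    "joint_test",
    "derive_rng",
]

_EXHAUSTIVE_MAX_N = 8


def derive_rng(seed: int | None, label: str = "") -> np.random.Generator:
    """Deterministic per-SNP-set stream: (seed, crc32(label)) -> Generator.

    Multi-set runs are order independent because each set's stream
    depends only on the master seed and its own name.
    """
    if label:
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(label.encode()),))
    else:
        ss = np.random.SeedSequence(entropy=seed)
    return np.random.default_rng(ss)


@dataclass
class PermutationPlan:
    """Number of permutations, seed, and exhaustive-enumeration flag."""

    B: int = 10_000
    seed: int | None = None
    exhaustive: bool = False
    label: str = ""

    def rng(self) -> np.random.Generator:
        return derive_rng(self.seed, self.label)


def make_plan(n: int, B: int = 10_000, seed: int | None = None,
              exhaustive: bool = False, label: str = "") -> PermutationPlan:
    if exhaustive:
        if n > _EXHAUSTIVE_MAX_N:
            raise ValueError(f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_MAX_N}")
        B = math.factorial(n)
    elif B < 1:
        raise ValueError("need at least one permutation")
    return PermutationPlan(B=B, seed=seed, exhaustive=exhaustive, label=label)


def _permuted_traits(yc: np.ndarray, plan: PermutationPlan) -> np.ndarray:
    """B x n matrix of reshuffled centred residual traits."""
    n = yc.shape[0]
    if plan.exhaustive:
        return np.array([yc[list(p)] for p in itertools.permutations(range(n))])
    rng = plan.rng()
    tiled = np.tile(yc, (plan.B, 1))
    return rng.permuted(tiled, axis=1)


def _stratum_sums(Cp: np.ndarray, V: np.ndarray, retained: np.ndarray,
                  idx: np.ndarray) -> np.ndarray | None:
    cols = idx[retained[idx]]
    if cols.size == 0:
        return None
    return (Cp[..., cols] ** 2 / V[cols]).sum(axis=-1)


def permute_residuals(resid: ResidualizedData, plan: PermutationPlan,
                      strata: dict[str, np.ndarray] | None = None):
    """Observed and permuted TOW-SE statistics, overall and per stratum.

    Returns ``(obs, perm)`` dicts keyed by stratum name (always includes
    ``"all"``); a stratum with no retained column maps to None.  The
    residual trait is reordered against the fixed X_res and the
    closed-form statistic recomputed for every permutation.
    """
    C, V, retained = _moments(resid.y_res, resid.X_res)
    if not retained.any():
        raise ValueError("all interaction columns have zero variance: no testable interaction")
    yc = resid.y_res - resid.y_res.mean()
    Xc = resid.X_res - resid.X_res.mean(axis=0)
    Yp = _permuted_traits(yc, plan)
    Cp = Yp @ Xc  # (B, M)
    strata = dict(strata or {})
    strata["all"] = np.arange(resid.m)
    obs = {k: _stratum_sums(C, V, retained, np.asarray(idx, dtype=int))
           for k, idx in strata.items()}
    perm = {k: _stratum_sums(Cp, V, retained, np.asarray(idx, dtype=int))
            for k, idx in strata.items()}
    return obs, perm


def pvalue_tow(T_obs: float, perm_T: np.ndarray, exhaustive: bool = False) -> float:
    """One-sided permutation p-value of a non-negative statistic.

    Ties count as at least as extreme (conservative).  Add-one in
    Monte-Carlo mode; plain rank in exhaustive mode where the identity
    ordering is part of the enumeration.
    """
    perm_T = np.asarray(perm_T, dtype=float)
    B = perm_T.size
    if B < 1:
        raise ValueError("need at least one permutation")
    # tiny relative slack so a mathematical tie (e.g. the identity ordering
    # recomputed through a different BLAS path) always counts as >=
    tol = 1e-12 * max(abs(T_obs), 1.0)
    ge = int((perm_T >= T_obs - tol).sum())
    return ge / B if exhaustive else (1 + ge) / (1 + B)


def _perm_rank_p(perm_l: np.ndarray) -> np.ndarray:
    """Per-permutation, per-lambda p: fraction of permuted values >= own value."""
    from scipy.stats import rankdata

    B = perm_l.shape[0]
    # rank with method='min' is 1 + #{strictly less}; #{>=} = B - rank + 1
    ranks = rankdata(perm_l, method="min", axis=0)
    return (B - ranks + 1) / B


def pvalue_vw(T_r_obs: float | None, T_c_obs: float | None,
              perm_Tr: np.ndarray | None, perm_Tc: np.ndarray | None,
              lambda_grid=DEFAULT_LAMBDA_GRID,
              exhaustive: bool = False) -> tuple[float, VwStatistic]:
    """Corrected VW-TOW-SE p-value via the single-layer min-p permutation scheme.

    Every permutation gets its own min over lambda of its rank-based
    p_lambda within the permuted set; the corrected p-value is the
    add-one rank of the observed min-p among those per-permutation
    minima.  With the conventions used here the corrected p is never
    smaller than the raw min-p, and a degenerate stratum reduces it
    exactly to the single-stratum TOW-SE p-value.
    """
    vw = vw_min_p(T_r_obs, T_c_obs, perm_Tr, perm_Tc, lambda_grid, exhaustive=exhaustive)
    grid = vw.lambda_grid
    perms = perm_Tr if perm_Tr is not None else perm_Tc
    B = len(perms)

    def std(perm):
        if perm is None:
            return np.zeros(B)
        perm = np.asarray(perm, dtype=float)
        sd = perm.std(ddof=1)
        if sd == 0.0:
            return np.zeros(B)
        return (perm - perm.mean()) / sd

    zr = std(perm_Tr)
    zc = std(perm_Tc)
    perm_l = np.outer(zr, grid) + np.outer(zc, 1.0 - grid)
    min_p_b = _perm_rank_p(perm_l).min(axis=1)
    le = int((min_p_b <= vw.value).sum())
    p = le / B if exhaustive else (1 + le) / (1 + B)
    return p, vw


@dataclass
class TestResult:
    """Outcome of one SNP-set test."""

    set_name: str
    kind: str  # "TOW-SE" | "VW-TOW-SE"
    statistic: float
    B: int
    p_value: float
    n: int
    M: int
    M_rare: int | None = None
    M_common: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value outside (0, 1]")


def tow_se_test(resid: ResidualizedData, B: int = 10_000,
                seed: int | None = None, exhaustive: bool = False,
                set_name: str = "") -> TestResult:
    """Permutation TOW-SE test of a residualized SNP set."""
    plan = make_plan(resid.n, B=B, seed=seed, exhaustive=exhaustive, label=set_name)
    obs, perm = permute_residuals(resid, plan)
    p = pvalue_tow(obs["all"], perm["all"], exhaustive=plan.exhaustive)
    dropped = int(resid.m - _retained_count(resid))
    return TestResult(set_name=set_name, kind="TOW-SE", statistic=float(obs["all"]),
                      B=plan.B, p_value=p, n=resid.n, M=resid.m,
                      diagnostics={"dropped_variants": dropped})


def _retained_count(resid: ResidualizedData) -> int:
    _, _, retained = _moments(resid.y_res, resid.X_res)
    return int(retained.sum())


def vw_tow_se_test(resid: ResidualizedData, mafs: np.ndarray, B: int = 10_000,
                   seed: int | None = None, maf_threshold: float = 0.01,
                   lambda_grid=DEFAULT_LAMBDA_GRID, exhaustive: bool = False,
                   set_name: str = "") -> TestResult:
    """Permutation VW-TOW-SE test with a rare/common split at ``maf_threshold``."""
    _, res = joint_test(resid, mafs, B=B, seed=seed, maf_threshold=maf_threshold,
                        lambda_grid=lambda_grid, exhaustive=exhaustive, set_name=set_name)
    return res


def joint_test(resid: ResidualizedData, mafs: np.ndarray, B: int = 10_000,
               seed: int | None = None, maf_threshold: float = 0.01,
               lambda_grid=DEFAULT_LAMBDA_GRID, exhaustive: bool = False,
               set_name: str = "") -> tuple[TestResult, TestResult]:
    """TOW-SE and VW-TOW-SE on one shared permutation stream.

    The full-set statistic decomposes over variants, so the same
    permuted cross-products feed T, T_r and T_c at once.
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size != resid.m:
        raise ValueError("one MAF per interaction column is required")
    part = partition_variants(mafs, maf_threshold)
    plan = make_plan(resid.n, B=B, seed=seed, exhaustive=exhaustive, label=set_name)
    obs, perm = permute_residuals(resid, plan, {"rare": part.rare, "common": part.common})

    p_tow = pvalue_tow(obs["all"], perm["all"], exhaustive=plan.exhaustive)
    p_vw, vw = pvalue_vw(obs["rare"], obs["common"], perm["rare"], perm["common"],
                         lambda_grid, exhaustive=plan.exhaustive)
    dropped = int(resid.m - _retained_count(resid))
    common_diag = {"dropped_variants": dropped,
                   "degenerate_strata": vw.degenerate_strata}
    tow_res = TestResult(set_name=set_name, kind="TOW-SE", statistic=float(obs["all"]),
                         B=plan.B, p_value=p_tow, n=resid.n, M=resid.m,
                         M_rare=int(part.rare.size), M_common=int(part.common.size),
                         diagnostics=dict(common_diag))
    vw_res = TestResult(set_name=set_name, kind="VW-TOW-SE", statistic=float(vw.value),
                        B=plan.B, p_value=p_vw, n=resid.n, M=resid.m,
                        M_rare=int(part.rare.size), M_common=int(part.common.size),
                        diagnostics={**common_diag, "raw_min_p": float(vw.value),
                                     "p_lambda": vw.p_lambda.tolist()})
    return tow_res, vw_res
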