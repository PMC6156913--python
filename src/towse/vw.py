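"""Variable-weight combination of rare- and common-variant statistics (VW-TOW-SE).

The optimal weighting behind TOW-SE targets rare variants; with common
variants in the set it can lose power.  VW-TOW-SE splits the set at a
MAF threshold (default 0.01, strict `<` for rare), computes the TOW-SE
statistic separately on each stratum, standardises each by its
permutation mean and standard deviation, and mixes them as

    T_lambda = lambda * Z_r + (1 - lambda) * Z_c,   lambda in [0, 1].

Each mixture gets a permutation p-value p_lambda; the VW statistic is
min over lambda of p_lambda, evaluated on a fixed grid (the continuous
minimum is piecewise constant at permutation resolution).  The min-p is
itself corrected by permutation in :mod:`towse.permutation`.

Both strata must be standardised against the SAME permutations, so the
inputs here are the paired observed + permuted statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["VariantPartition", "VwStatistic", "partition_variants", "t_lambda",
           "vw_min_p", "DEFAULT_LAMBDA_GRID"]

DEFAULT_LAMBDA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 1))


@dataclass
class VariantPartition:
    """Disjoint, exhaustive split of variant indices at a MAF threshold."""

    rare: np.ndarray
    common: np.ndarray
    threshold: float = 0.01


def partition_variants(mafs: np.ndarray, threshold: float = 0.01) -> VariantPartition:
    """Rare means MAF strictly below the threshold; a boundary MAF is common."""
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size and (mafs.min() < 0 or mafs.max() > 0.5):
        raise ValueError("MAFs must lie in [0, 0.5]")
    idx = np.arange(mafs.size)
    rare = mafs < threshold
    return VariantPartition(rare=idx[rare], common=idx[~rare], threshold=threshold)


def t_lambda(t_r_std: float, t_c_std: float, lam: float) -> float:
    """Convex combination lambda * Z_r + (1 - lambda) * Z_c."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return lam * t_r_std + (1.0 - lam) * t_c_std


@dataclass
class VwStatistic:
    """Min-p statistic over the lambda grid, with the stratum diagnostics."""

    lambda_grid: np.ndarray
    T_r: float
    T_c: float
    sd_Tr: float
    sd_Tc: float
    p_lambda: np.ndarray
    value: float  # min over the grid of p_lambda
    degenerate_strata: list[str] = field(default_factory=list)


def _standardize(obs: float | None, perm: np.ndarray | None, label: str,
                 degenerate: list[str]):
    """Permutation-moment standardisation of one stratum; degenerate -> zeros."""
    if obs is None or perm is None:
        degenerate.append(label)
        return 0.0, 0.0, None
    perm = np.asarray(perm, dtype=float)
    sd = float(perm.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        warnings.warn(f"{label} stratum has zero permutation variance; "
                      "its standardized statistic is set to 0", stacklevel=3)
        degenerate.append(label)
        return 0.0, 0.0, np.zeros_like(perm)
    mu = float(perm.mean())
    return (obs - mu) / sd, sd, (perm - mu) / sd


def vw_min_p(T_r_obs: float | None, T_c_obs: float | None,
             perm_Tr: np.ndarray | None, perm_Tc: np.ndarray | None,
             lambda_grid=DEFAULT_LAMBDA_GRID,
             exhaustive: bool = False) -> VwStatistic:
    """Minimum over lambda of the permutation p-value of T_lambda.

    ``perm_Tr`` / ``perm_Tc`` must come from the same permutations
    (paired).  A stratum that is absent (None) or has zero permutation
    variance is degenerate: its standardized statistic is 0, so the
    minimum reduces to the usable endpoint.  Monte-Carlo p-values use
    the add-one convention; in exhaustive mode the permuted set already
    contains the identity and plain rank counting is exact.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0 or grid.min() < 0 or grid.max() > 1:
        raise ValueError("lambda grid must be non-empty within [0, 1]")
    perms = perm_Tr if perm_Tr is not None else perm_Tc
    if perms is None or len(perms) < 2:
        raise ValueError("need at least 2 permutations to standardize strata")
    B = len(perms)
    if perm_Tr is not None and perm_Tc is not None and len(perm_Tc) != B:
        raise ValueError("paired permuted statistics must have equal length")

    degenerate: list[str] = []
    zr_obs, sd_r, zr_perm = _standardize(T_r_obs, perm_Tr, "rare", degenerate)
    zc_obs, sd_c, zc_perm = _standardize(T_c_obs, perm_Tc, "common", degenerate)
    if zr_perm is None:
        zr_perm = np.zeros(B)
    if zc_perm is None:
        zc_perm = np.zeros(B)

    obs_l = grid * zr_obs + (1.0 - grid) * zc_obs                  # (L,)
    perm_l = np.outer(zr_perm, grid) + np.outer(zc_perm, 1.0 - grid)  # (B, L)
    # tiny relative slack so float-level ties count as >=
    tol = 1e-12 * np.maximum(np.abs(obs_l), 1.0)
    ge = (perm_l >= obs_l - tol).sum(axis=0)
    p_lam = ge / B if exhaustive else (1.0 + ge) / (1.0 + B)
    return VwStatistic(lambda_grid=grid,
                       T_r=np.nan if T_r_obs is None else float(T_r_obs),
                       T_c=np.nan if T_c_obs is None else float(T_c_obs),
                       sd_Tr=sd_r, sd_Tc=sd_c,
                       p_lambda=p_lam, value=float(p_lam.min()),
                       degenerate_strata=degenerate)
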