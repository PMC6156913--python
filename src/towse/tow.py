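"""Optimally weighted interaction score statistic (TOW-SE).

For residual trait y~ and residual interaction columns x~_m, the score
statistic of the weighted combination sum_m w_m x~_m is maximised by the
weights

    w_m = C_m / V_m,   C_m = sum_i (y~_i - mean) (x~_im - mean_m),
                       V_m = sum_i (x~_im - mean_m)^2,

under (approximate) independence of the columns — rare-variant
interaction columns are nearly orthogonal, which is the regime the
weights are designed for.  At those weights the statistic collapses to

    T = sum_m C_m^2 / V_m,

a single pass over columns that needs no explicit weighted combination;
each variant contributes C_m^2 / V_m >= 0.  Significance is assessed by
permutation only (the score-normalisation prefactor is permutation
invariant and omitted).

Interaction columns with zero variance — e.g. a variant carried only by
samples with E = 0 — carry no interaction information; they are dropped
from the statistic (weight undefined) and flagged, not errored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .residualize import ResidualizedData

__all__ = ["TowStatistic", "optimal_weights", "tow_statistic", "score_statistic"]

_VAR_RTOL = 1e-12


@dataclass
class TowStatistic:
    """TOW-SE statistic with its per-variant decomposition."""

    value: float
    weights: np.ndarray          # w_m = C_m / V_m; NaN for dropped columns
    per_variant_contrib: np.ndarray  # C_m^2 / V_m; 0 for dropped columns
    retained: np.ndarray         # bool mask of columns with positive variance


def _moments(y_res: np.ndarray, X_res: np.ndarray):
    yc = y_res - y_res.mean()
    Xc = X_res - X_res.mean(axis=0)
    V = np.einsum("ij,ij->j", Xc, Xc)
    scale = max(float(np.abs(Xc).max(initial=0.0)) ** 2, 1.0)
    retained = V > _VAR_RTOL * scale * X_res.shape[0]
    C = yc @ Xc
    return C, V, retained


def optimal_weights(resid: ResidualizedData) -> np.ndarray:
    """Per-variant optimal weights C_m / V_m (NaN where the column is degenerate)."""
    C, V, retained = _moments(resid.y_res, resid.X_res)
    if not retained.any():
        raise ValueError("all interaction columns have zero variance: no testable interaction")
    w = np.full(V.shape, np.nan)
    w[retained] = C[retained] / V[retained]
    return w


def tow_statistic(resid: ResidualizedData) -> TowStatistic:
    """TOW-SE statistic T = sum_m C_m^2 / V_m over retained columns."""
    C, V, retained = _moments(resid.y_res, resid.X_res)
    if not retained.any():
        raise ValueError("all interaction columns have zero variance: no testable interaction")
    contrib = np.zeros(V.shape)
    contrib[retained] = C[retained] ** 2 / V[retained]
    w = np.full(V.shape, np.nan)
    w[retained] = C[retained] / V[retained]
    return TowStatistic(value=float(contrib.sum()), weights=w,
                        per_variant_contrib=contrib, retained=retained)


def score_statistic(y_res: np.ndarray, X_res: np.ndarray, weights: np.ndarray) -> float:
    """Normalised score statistic S(w) of an arbitrary weighted combination.

    S(w) = n * cov_term^2 / (ss_y * ss_x) with x_i = sum_m w_m x~_im.
    Used as the independent check that the closed-form optimum really is
    the maximiser; not on the statistic's own computation path.
    """
    y_res = np.asarray(y_res, dtype=float)
    x = np.asarray(X_res, dtype=float) @ np.asarray(weights, dtype=float)
    yc = y_res - y_res.mean()
    xc = x - x.mean()
    ss_y = float(yc @ yc)
    ss_x = float(xc @ xc)
    if ss_x == 0.0 or ss_y == 0.0:
        return 0.0
    return len(y_res) * float(yc @ xc) ** 2 / (ss_y * ss_x)
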