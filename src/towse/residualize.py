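"""Covariate adjustment of trait and SNP x environment interaction terms.

The interaction score test operates on residuals: both the trait y and
every interaction column E*g_m are adjusted for an intercept, the
confounders Z, the per-variant genotype main effects G and the
environment E.  After this projection the only structure left to detect
is interaction signal, and permuting the residual trait against the
fixed residual interaction matrix is a valid null.

For a continuous trait the adjustment is ordinary least squares.  For a
binary trait the trait residual is the response residual y - p_hat from
the null logistic model (no interaction terms); the interaction columns
are still adjusted by least squares, which keeps the permutation scheme
identical across trait kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "ResidualizedData",
    "build_interaction_matrix",
    "prune_degenerate",
    "residualize",
]

RANK_RTOL = 1e-8  # relative tolerance for rank / degeneracy checks


@dataclass
class ModelSpec:
    """Adjustment-model description: link plus named nuisance design columns."""

    link: str  # "identity" | "logit"
    design_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.link not in ("identity", "logit"):
            raise ValueError("link must be 'identity' or 'logit'")


@dataclass
class ResidualizedData:
    """Residual trait and residual interaction matrix, ready for the score test.

    With an intercept in the adjustment design, ``y_res`` and every
    column of ``X_res`` have mean zero (exactly for least squares, and
    via the intercept score equation for the logistic response
    residuals).
    """

    y_res: np.ndarray
    X_res: np.ndarray
    model: ModelSpec | None = None
    pruned: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.y_res.shape[0]

    @property
    def m(self) -> int:
        return self.X_res.shape[1]


def build_interaction_matrix(counts: np.ndarray, env: np.ndarray) -> np.ndarray:
    """Elementwise interaction matrix: entry (i, m) = E_i * g_im."""
    counts = np.asarray(counts, dtype=float)
    env = np.asarray(env, dtype=float)
    if counts.ndim != 2 or env.ndim != 1 or counts.shape[0] != env.shape[0]:
        raise ValueError(
            f"dimension mismatch: genotypes {counts.shape}, environment {env.shape}")
    return env[:, None] * counts


def prune_degenerate(columns: np.ndarray, names: list[str] | None = None
                     ) -> tuple[np.ndarray, list[str]]:
    """Drop constant columns and exact duplicates from a design block.

    Returns the retained column indices and a report naming removals.
    Removing everything is legal (the intercept is added separately).
    """
    columns = np.asarray(columns, dtype=float)
    if columns.ndim == 1:
        columns = columns[:, None]
    k = columns.shape[1]
    names = names if names is not None else [f"col{j}" for j in range(k)]
    keep: list[int] = []
    report: list[str] = []
    for j in range(k):
        col = columns[:, j]
        scale = max(np.abs(col).max(initial=0.0), 1.0)
        if np.ptp(col) <= RANK_RTOL * scale:
            report.append(f"{names[j]}: constant")
            continue
        dup = next((i for i in keep if np.array_equal(columns[:, i], col)), None)
        if dup is not None:
            report.append(f"{names[j]}: duplicate of {names[dup]}")
            continue
        keep.append(j)
    return np.array(keep, dtype=int), report


def _design(Z, G, E, n, prune=True):
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for block, prefix in ((Z, "Z"), (G, "G"), (E, "E")):
        if block is None:
            continue
        block = np.asarray(block, dtype=float)
        if block.ndim == 1:
            block = block[:, None]
        if block.shape[0] != n:
            raise ValueError(f"{prefix} block has {block.shape[0]} rows, expected {n}")
        blocks.append(block)
        names += [f"{prefix}{j + 1}" for j in range(block.shape[1])]
    D = np.hstack(blocks)
    if not prune:
        return D, names, []
    keep, report = prune_degenerate(D[:, 1:], names[1:])
    D = np.hstack([D[:, :1], D[:, 1:][:, keep]])
    names = ["intercept"] + [names[1:][i] for i in keep]
    return D, names, report


def _check_rank(D: np.ndarray, names: list[str]) -> None:
    # pivoted QR exposes which columns are (numerically) collinear
    from scipy.linalg import qr

    _, r, piv = qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = RANK_RTOL * max(diag.max(initial=0.0), 1.0) * max(D.shape)
    bad = piv[diag < tol].tolist() if (diag < tol).any() else []
    if len(diag) < D.shape[1]:
        bad += piv[len(diag):].tolist()
    if bad:
        raise np.linalg.LinAlgError(
            "adjustment design is rank deficient after pruning; collinear columns: "
            + ", ".join(names[j] for j in sorted(bad)))


def residualize(y: np.ndarray,
                EG: np.ndarray,
                Z: np.ndarray | None = None,
                G: np.ndarray | None = None,
                E: np.ndarray | None = None,
                link: str = "identity") -> ResidualizedData:
    """Adjust trait and interaction columns for (1, Z, G, E).

    ``y_res`` is the least-squares residual of y on the adjustment design
    (identity link) or the response residual y - p_hat from the null
    logistic fit (logit link).  Each column of ``X_res`` is the
    least-squares residual of the corresponding interaction column on the
    same design.  Constant and duplicate adjustment columns are pruned
    before fitting; interaction columns are never pruned here (degenerate
    ones are handled by the statistic).
    """
    y = np.asarray(y, dtype=float)
    EG = np.atleast_2d(np.asarray(EG, dtype=float))
    n = y.shape[0]
    if EG.shape[0] != n:
        EG = EG.T
    if EG.shape[0] != n:
        raise ValueError("interaction matrix row count does not match trait length")
    D, names, report = _design(Z, G, E, n)
    _check_rank(D, names)

    # hat-matrix application via one economy QR of the pruned design
    Q, _ = np.linalg.qr(D)
    X_res = EG - Q @ (Q.T @ EG)

    if link == "identity":
        y_res = y - Q @ (Q.T @ y)
    elif link == "logit":
        import statsmodels.api as sm

        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("logit link requires a {0,1} trait")
        fit = sm.GLM(y, D, family=sm.families.Binomial()).fit(maxiter=100)
        if not fit.converged:
            raise RuntimeError("null logistic fit did not converge")
        y_res = y - fit.fittedvalues
    else:
        raise ValueError("link must be 'identity' or 'logit'")
    return ResidualizedData(y_res=y_res, X_res=X_res,
                            model=ModelSpec(link=link, design_names=names),
                            pruned=report)
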