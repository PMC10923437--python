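"""Least-squares primitives shared by the ratio and LIML estimators.

Everything here is ordinary least squares with an intercept always included.
:func:`focal_ols` fits one focal predictor with optional adjustment columns;
:func:`marginal_fits` does the same for a whole matrix of focal columns at
once by residualizing response and focal columns against the common
adjustment block (Frisch-Waugh-Lovell), which is what makes per-instrument
IVW regressions cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import Dataset, ValidationError

__all__ = ["RegressionFit", "focal_ols", "marginal_fits", "instrument_f"]

# Relative threshold below which a residualized focal column is treated as
# collinear with the adjustment block.
_RANK_TOL = 1e-10


@dataclass(frozen=True)
class RegressionFit:
    """Focal-coefficient summary of one OLS fit.

    ``f_stat`` is the squared t-ratio of the focal coefficient; in the simple
    no-adjustment case it equals (n-2) * R^2 / (1 - R^2).  A noiseless fit
    (zero residual variance) reports ``f_stat = inf``.
    """

    coef: float
    var: float          # sampling variance of the focal coefficient
    resid_var: float    # residual variance (RSS / df)
    df: int             # n - number of fitted columns
    f_stat: float


def _adjustment_block(n: int, adjustments: Optional[np.ndarray]) -> np.ndarray:
    one = np.ones((n, 1))
    if adjustments is None:
        return one
    A = np.asarray(adjustments, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if A.shape[0] != n:
        raise ValidationError(
            f"adjustments have {A.shape[0]} rows, expected {n}"
        )
    return np.hstack([one, A])


def _residualize(Z: np.ndarray, *arrays: np.ndarray):
    """Project each array onto the orthogonal complement of span(Z)."""
    Q, R = np.linalg.qr(Z)
    diag = np.abs(np.diag(R))
    if diag.min() <= _RANK_TOL * max(diag.max(), 1.0):
        raise ValidationError("adjustment block is rank deficient (collinear columns)")
    return [a - Q @ (Q.T @ a) for a in arrays]


def marginal_fits(
    response: np.ndarray,
    focal: np.ndarray,
    adjustments: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, int, np.ndarray]:
    """Per-column OLS of ``response`` on [1, adjustments, focal[:, j]].

    Returns ``(coefs, variances, resid_vars, df, f_stats)`` as vectors over
    the focal columns.  Each column is fitted *marginally* (one at a time)
    alongside the shared adjustment block.
    """
    y = np.asarray(response, dtype=float)
    F = np.asarray(focal, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    n = y.shape[0]
    if F.shape[0] != n:
        raise ValidationError(f"focal has {F.shape[0]} rows, expected {n}")
    Z = _adjustment_block(n, adjustments)
    yr, Fr = _residualize(Z, y, F)
    sxx = np.einsum("ij,ij->j", Fr, Fr)
    scale = float(np.einsum("ij,ij->j", np.asarray(F, float), F).max())
    if np.any(sxx <= _RANK_TOL * max(scale, 1.0)):
        bad = np.where(sxx <= _RANK_TOL * max(scale, 1.0))[0]
        raise ValidationError(
            f"focal columns {bad.tolist()} are collinear with the adjustment block"
        )
    sxy = Fr.T @ y
    coefs = sxy / sxx
    df = n - Z.shape[1] - 1
    if df <= 0:
        raise ValidationError(f"non-positive degrees of freedom ({df})")
    rss = np.maximum(yr @ yr - coefs**2 * sxx, 0.0)
    resid_vars = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        variances = resid_vars / sxx
        f_stats = np.where(variances > 0, coefs**2 / variances, np.inf)
    return coefs, variances, resid_vars, df, f_stats


def focal_ols(
    response: np.ndarray,
    focal: np.ndarray,
    adjustments: Optional[np.ndarray] = None,
) -> RegressionFit:
    """OLS of ``response`` on [1, adjustments, focal]; report the focal term.

    Raises :class:`~bimr.core.ValidationError` on length mismatch or a
    rank-deficient design.
    """
    focal = np.asarray(focal, dtype=float)
    if focal.ndim != 1:
        raise ValidationError("focal must be a single column; use marginal_fits for many")
    coefs, variances, resid_vars, df, f_stats = marginal_fits(
        response, focal[:, None], adjustments
    )
    return RegressionFit(
        coef=float(coefs[0]),
        var=float(variances[0]),
        resid_var=float(resid_vars[0]),
        df=df,
        f_stat=float(f_stats[0]),
    )


def instrument_f(
    data: Dataset,
    trait: int,
    instrument: int,
    adjustments: Optional[np.ndarray] = None,
) -> float:
    """First-stage strength of one instrument: F-statistic of the instrument
    in a regression of its own trait on that instrument (plus adjustments).

    Because the simple-regression F is symmetric in which variable is the
    response, this matches the convention of regressing the instrument on the
    trait.  A value below 10 conventionally flags a weak instrument.
    """
    if trait == 1:
        y, X = data.y1, data.X1
    elif trait == 2:
        y, X = data.y2, data.X2
    else:
        raise ValidationError(f"trait must be 1 or 2, got {trait}")
    if not (0 <= instrument < X.shape[1]):
        raise ValidationError(
            f"instrument index {instrument} out of range for trait {trait} "
            f"({X.shape[1]} instruments)"
        )
    fit = focal_ols(y, X[:, instrument], adjustments)
    return fit.f_stat


def mean_instrument_f(
    data: Dataset, trait: int, adjustments: Optional[np.ndarray] = None
) -> float:
    """Mean first-stage F over a trait's full instrument set (marginal fits)."""
    y, X = (data.y1, data.X1) if trait == 1 else (data.y2, data.X2)
    _, _, _, _, f_stats = marginal_fits(y, X, adjustments)
    return float(np.mean(f_stats))
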