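"""Ratio-family causal-effect estimators.

The single-instrument ratio estimate of the effect of an exposure trait on an
outcome trait is (outcome-on-instrument coefficient) / (exposure-on-instrument
coefficient); multiple instruments are combined by inverse-variance weighting
(IVW) with weights from the numerator coefficient's variance.

Two bidirectional variants are provided:

* ``naive_bidirectional_ratio`` applies the marginal per-instrument IVW ratio
  independently in each direction, ignoring the feedback loop — the standard
  comparator.
* ``biratio`` additionally adjusts every per-instrument regression for the
  *opposite* direction's full instrument set, which cancels the common
  feedback factor 1/(1 - gamma12*gamma21) from numerator and denominator and
  removes the loop-induced bias.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from .core import BiMRError, CausalEstimate, Dataset, ValidationError
from .regress import marginal_fits

__all__ = [
    "NearZeroDenominatorError",
    "ratio_single",
    "ivw_combine",
    "naive_bidirectional_ratio",
    "biratio",
]

# A denominator coefficient this close to zero signals an irrelevant
# instrument; erroring beats a silently sign-flipped, exploding ratio.
DENOMINATOR_TOL = 1e-8


class NearZeroDenominatorError(BiMRError):
    """Exposure-on-instrument coefficient is numerically zero."""


def _direction_arrays(data: Dataset, direction: str):
    """(exposure, outcome, own instruments, opposite instruments)."""
    if direction == "1->2":
        return data.y1, data.y2, data.X1, data.X2
    if direction == "2->1":
        return data.y2, data.y1, data.X2, data.X1
    raise ValidationError(f"unknown direction {direction!r}")


def _stack_adjustments(*blocks: Optional[np.ndarray]) -> Optional[np.ndarray]:
    cols = []
    for b in blocks:
        if b is None:
            continue
        b = np.asarray(b, dtype=float)
        cols.append(b[:, None] if b.ndim == 1 else b)
    if not cols:
        return None
    return np.hstack(cols)


def _direction_triples(
    data: Dataset,
    direction: str,
    adjust_cross: bool,
    covariates: Optional[np.ndarray],
) -> List[Tuple[float, float, float]]:
    """Per-instrument (numerator coef, denominator coef, numerator variance)."""
    exposure, outcome, own, opposite = _direction_arrays(data, direction)
    adj = _stack_adjustments(covariates, opposite if adjust_cross else None)
    num_coefs, num_vars, _, _, _ = marginal_fits(outcome, own, adj)
    den_coefs, den_vars, _, _, _ = marginal_fits(exposure, own, adj)
    # exact (noiseless) fits have zero sampling variance; floor it so the
    # IVW weights stay finite in the noiseless limit
    num_vars = np.maximum(num_vars, 1e-30)
    small = np.abs(den_coefs) < DENOMINATOR_TOL
    if np.any(small):
        raise NearZeroDenominatorError(
            f"direction {direction}: instruments {np.where(small)[0].tolist()} have "
            f"near-zero exposure coefficients (|coef| < {DENOMINATOR_TOL:g})"
        )
    return list(zip(num_coefs.tolist(), den_coefs.tolist(), num_vars.tolist()))


def ivw_combine(
    triples: List[Tuple[float, float, float]],
    direction: str = "1->2",
    method: str = "ratio",
) -> CausalEstimate:
    """Inverse-variance-weighted combination of per-instrument regressions.

    With per-instrument numerator coefficient ``num_i``, denominator
    coefficient ``den_i`` and numerator variance ``v_i``::

        estimate = sum(num_i * den_i / v_i) / sum(den_i**2 / v_i)
        se       = sqrt(1 / sum(den_i**2 / v_i))

    A single triple reduces exactly to the ratio estimate ``num/den`` with the
    first-order delta-method SE ``sqrt(v)/|den|``.  Wald 95% CI and two-sided
    normal p-value.
    """
    if len(triples) == 0:
        raise ValidationError("ivw_combine requires at least one instrument triple")
    num = np.array([t[0] for t in triples], dtype=float)
    den = np.array([t[1] for t in triples], dtype=float)
    var = np.array([t[2] for t in triples], dtype=float)
    if np.any(var <= 0):
        raise ValidationError("numerator variances must be positive")
    w_den = float(np.sum(den**2 / var))
    estimate = float(np.sum(num * den / var)) / w_den
    se = float(np.sqrt(1.0 / w_den))
    z = stats.norm.ppf(0.975)
    p = float(max(2.0 * stats.norm.sf(abs(estimate) / se), np.nextafter(0, 1)))
    return CausalEstimate(
        direction=direction,
        method=method,
        estimate=estimate,
        se=se,
        ci_low=estimate - z * se,
        ci_high=estimate + z * se,
        p_value=p,
        per_instrument=list(triples),
    )


def ratio_single(
    data: Dataset,
    direction: str,
    instrument: int,
    adjust_cross: bool = False,
    covariates: Optional[np.ndarray] = None,
) -> CausalEstimate:
    """Single-instrument ratio estimate for one direction.

    With ``adjust_cross`` both regressions additionally adjust for the full
    opposite-direction instrument set (the bidirectional variant).
    """
    _, _, own, _ = _direction_arrays(data, direction)
    if not (0 <= instrument < own.shape[1]):
        raise ValidationError(
            f"instrument index {instrument} out of range ({own.shape[1]} instruments)"
        )
    sub = Dataset(
        y1=data.y1, y2=data.y2,
        X1=data.X1[:, [instrument]] if direction == "1->2" else data.X1,
        X2=data.X2[:, [instrument]] if direction == "2->1" else data.X2,
        covariates=data.covariates, confounder=data.confounder,
    )
    triples = _direction_triples(sub, direction, adjust_cross, covariates)
    method = "biratio" if adjust_cross else "ratio"
    return ivw_combine(triples, direction=direction, method=method)


def naive_bidirectional_ratio(
    data: Dataset, covariates: Optional[np.ndarray] = None
) -> Tuple[CausalEstimate, CausalEstimate]:
    """IVW ratio applied independently in each direction (feedback ignored)."""
    est12 = ivw_combine(
        _direction_triples(data, "1->2", False, covariates), "1->2", "ratio"
    )
    est21 = ivw_combine(
        _direction_triples(data, "2->1", False, covariates), "2->1", "ratio"
    )
    return est12, est21


def biratio(
    data: Dataset, covariates: Optional[np.ndarray] = None
) -> Tuple[CausalEstimate, CausalEstimate]:
    """Feedback-aware IVW ratio: each per-instrument regression adjusts for the
    complete opposite-direction instrument set (and covariates)."""
    est12 = ivw_combine(
        _direction_triples(data, "1->2", True, covariates), "1->2", "biratio"
    )
    est21 = ivw_combine(
        _direction_triples(data, "2->1", True, covariates), "2->1", "biratio"
    )
    return est12, est21
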