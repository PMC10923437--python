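"""Domain types and reduced-form algebra for bidirectional Mendelian randomization.

Two continuous phenotypes ``y1`` and ``y2`` may each causally affect the other
(effects ``gamma12``: trait 1 -> trait 2, and ``gamma21``: trait 2 -> trait 1).
Each trait has its own set of genetic instruments (SNP dosages), and an
unmeasured confounder ``C`` loads on both traits.  The structural system

    y1 = beta01 + X1 @ beta11 + beta_c_y1 * C + gamma21 * y2 + eps1
    y2 = beta02 + X2 @ beta22 + beta_c_y2 * C + gamma12 * y1 + eps2

defines a feedback loop.  When ``|gamma12 * gamma21| < 1`` the loop converges
and each phenotype has a closed-form reduced form in instruments, confounder,
and composite errors only; :func:`reduced_form` computes those coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BiMRError",
    "ConvergenceError",
    "ValidationError",
    "BMRParameters",
    "ReducedFormCoefficients",
    "Dataset",
    "CausalEstimate",
    "ReplicateSummary",
    "reduced_form",
    "validate_dataset",
]


class BiMRError(Exception):
    """Base class for all errors raised by this package."""


class ConvergenceError(BiMRError):
    """The feedback loop does not converge (|gamma12 * gamma21| >= 1)."""


class ValidationError(BiMRError):
    """Invalid parameters or data (shape mismatch, missing values, ...)."""


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be a 1-d vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class BMRParameters:
    """Structural coefficients of the bidirectional model plus simulation settings.

    ``beta11``/``beta22`` are per-instrument effect vectors (lengths k1, k2);
    a scalar is broadcast to a length-1 vector.  Defaults mirror the standard
    simulation conditions: confounder ~ Normal(1, 1) with effect 0.3 on both
    traits, intercepts 1, unit structural error SDs, MAF 0.3, n = 1000.
    """

    gamma12: float
    gamma21: float
    beta11: np.ndarray
    beta22: np.ndarray
    beta01: float = 1.0
    beta02: float = 1.0
    beta_c_y1: float = 0.3
    beta_c_y2: float = 0.3
    confounder_mean: float = 1.0
    confounder_sd: float = 1.0
    maf: float = 0.3
    n: int = 1000
    error_sd1: float = 1.0
    error_sd2: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "beta11", _as_vector(self.beta11, "beta11"))
        object.__setattr__(self, "beta22", _as_vector(self.beta22, "beta22"))
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.n < 10:
            raise ValidationError(f"n must be >= 10, got {self.n}")
        if self.beta11.size < 1 or self.beta22.size < 1:
            raise ValidationError("each trait needs at least one instrument")
        for name in ("confounder_sd", "error_sd1", "error_sd2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def k1(self) -> int:
        return self.beta11.size

    @property
    def k2(self) -> int:
        return self.beta22.size

    @property
    def feedback_product(self) -> float:
        """gamma12 * gamma21; the loop converges iff its magnitude is < 1."""
        return self.gamma12 * self.gamma21


@dataclass(frozen=True)
class ReducedFormCoefficients:
    """Composite coefficients of the converged feedback loop.

    With d = 1 - gamma12*gamma21:

    * ``alpha11 = beta11 / d`` — own instruments in the trait-1 equation,
    * ``gamma23 = gamma21 * beta22 / d`` — trait-2 instruments leaking into
      trait 1 through the loop (and symmetrically ``alpha22``, ``gamma13``),
    * composite errors ``delta1 = (eps1 + gamma21*eps2)/d`` and
      ``delta2 = (eps2 + gamma12*eps1)/d`` whose SDs and correlation are
      stored in closed form.
    """

    alpha01: float
    alpha02: float
    alpha_c_y1: float
    alpha_c_y2: float
    alpha11: np.ndarray
    alpha22: np.ndarray
    gamma23: np.ndarray
    gamma13: np.ndarray
    delta1_sd: float
    delta2_sd: float
    delta_corr: float


def reduced_form(params: BMRParameters) -> ReducedFormCoefficients:
    """Solve the 2x2 structural system for its converged reduced form.

    Raises
    ------
    ConvergenceError
        If ``|gamma12 * gamma21| >= 1`` (non-convergent feedback loop).
    """
    prod = params.feedback_product
    if abs(prod) >= 1.0:
        raise ConvergenceError(
            f"|gamma12*gamma21| = {abs(prod):.6g} >= 1: feedback loop does not converge"
        )
    d = 1.0 - prod
    g12, g21 = params.gamma12, params.gamma21
    s1, s2 = params.error_sd1, params.error_sd2
    var1 = (s1**2 + g21**2 * s2**2) / d**2
    var2 = (s2**2 + g12**2 * s1**2) / d**2
    cov12 = (g12 * s1**2 + g21 * s2**2) / d**2
    return ReducedFormCoefficients(
        alpha01=(params.beta01 + g21 * params.beta02) / d,
        alpha02=(params.beta02 + g12 * params.beta01) / d,
        alpha_c_y1=(params.beta_c_y1 + g21 * params.beta_c_y2) / d,
        alpha_c_y2=(params.beta_c_y2 + g12 * params.beta_c_y1) / d,
        alpha11=params.beta11 / d,
        alpha22=params.beta22 / d,
        gamma23=g21 * params.beta22 / d,
        gamma13=g12 * params.beta11 / d,
        delta1_sd=float(np.sqrt(var1)),
        delta2_sd=float(np.sqrt(var2)),
        delta_corr=float(cov12 / np.sqrt(var1 * var2)),
    )


@dataclass
class Dataset:
    """One cohort: two phenotypes, two instrument dosage matrices, optional extras.

    ``X1`` holds the instruments for trait 1 (n x k1), ``X2`` for trait 2.
    ``covariates`` are observed covariates handed to estimators on request;
    ``confounder`` is the simulated unmeasured confounder, retained for
    diagnostics only and not used by estimators unless explicitly passed.
    """

    y1: np.ndarray
    y2: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    covariates: Optional[np.ndarray] = None
    confounder: Optional[np.ndarray] = None
    instrument_ids_1: Optional[Sequence[str]] = None
    instrument_ids_2: Optional[Sequence[str]] = None
    sample_ids: Optional[Sequence[str]] = None

    @property
    def n(self) -> int:
        return self.y1.shape[0]

    def swapped(self) -> "Dataset":
        """The same cohort with the trait-1/trait-2 roles exchanged."""
        return Dataset(
            y1=self.y2, y2=self.y1, X1=self.X2, X2=self.X1,
            covariates=self.covariates, confounder=self.confounder,
            instrument_ids_1=self.instrument_ids_2,
            instrument_ids_2=self.instrument_ids_1,
            sample_ids=self.sample_ids,
        )


def validate_dataset(data: Dataset) -> Dataset:
    """Enforce Dataset invariants: aligned row counts, no missing values,
    dosages within [0, 2].

    Returns the dataset (arrays coerced to float64) or raises
    :class:`ValidationError` naming the offending component/rows.
    """
    y1 = _as_vector(data.y1, "y1")
    y2 = _as_vector(data.y2, "y2")
    X1 = np.atleast_2d(np.asarray(data.X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(data.X2, dtype=float))
    n = y1.shape[0]
    for name, arr in (("y2", y2), ("X1", X1), ("X2", X2)):
        if arr.shape[0] != n:
            raise ValidationError(
                f"dimension mismatch: {name} has {arr.shape[0]} rows, expected {n}"
            )
    cov = data.covariates
    if cov is not None:
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        if cov.shape[0] != n:
            raise ValidationError(
                f"dimension mismatch: covariates has {cov.shape[0]} rows, expected {n}"
            )
    conf = data.confounder
    if conf is not None:
        conf = _as_vector(conf, "confounder")
        if conf.shape[0] != n:
            raise ValidationError(
                f"dimension mismatch: confounder has {conf.shape[0]} rows, expected {n}"
            )
    for name, arr in (("y1", y1), ("y2", y2), ("X1", X1), ("X2", X2)):
        bad = np.where(~np.isfinite(arr))[0] if arr.ndim == 1 else np.where(
            ~np.all(np.isfinite(arr), axis=1)
        )[0]
        if bad.size:
            raise ValidationError(
                f"missing/non-finite values in {name} at rows {bad[:10].tolist()}"
            )
    if cov is not None and not np.all(np.isfinite(cov)):
        bad = np.where(~np.all(np.isfinite(cov), axis=1))[0]
        raise ValidationError(
            f"missing/non-finite values in covariates at rows {bad[:10].tolist()}"
        )
    for name, X in (("X1", X1), ("X2", X2)):
        if X.size and (X.min() < 0.0 or X.max() > 2.0):
            raise ValidationError(f"{name} dosages must lie in [0, 2]")
    return Dataset(
        y1=y1, y2=y2, X1=X1, X2=X2, covariates=cov, confounder=conf,
        instrument_ids_1=data.instrument_ids_1,
        instrument_ids_2=data.instrument_ids_2,
        sample_ids=data.sample_ids,
    )


@dataclass(frozen=True)
class CausalEstimate:
    """One directed causal-effect estimate with Wald inference and diagnostics.

    ``direction`` is ``"1->2"`` (effect of trait 1 on trait 2, gamma12) or
    ``"2->1"``.  ``k_hat`` is the k-class eigenvalue (LIML family only);
    ``per_instrument`` holds (numerator coef, denominator coef, numerator
    variance) triples (ratio family only).
    """

    direction: str
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    k_hat: Optional[float] = None
    per_instrument: Optional[list] = None

    def __post_init__(self):
        if self.direction not in ("1->2", "2->1"):
            raise ValidationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class ReplicateSummary:
    """One benchmark cell: accuracy of one method/direction across replicates.

    ``rmab`` is the relative median absolute bias (MAB / |truth|) and is
    ``None`` exactly when the true effect is 0.
    """

    scenario: str
    method: str
    direction: str
    true_value: float
    median_estimate: float
    mab: float
    rmab: Optional[float]
    mean_f: float
    n_reps: int
    n_failed: int = 0
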