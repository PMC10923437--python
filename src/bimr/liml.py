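"""k-class / LIML machinery for one-sample MR, naive and bidirectional.

For one direction (say trait 1 -> trait 2) the structural equation treats the
exposure phenotype as an endogenous regressor.  With

* ``W``  — full instrument design (intercept, covariates, included exogenous
  instruments, excluded instruments),
* ``C*`` — restricted design (W minus the excluded instruments),
* ``M_A = I - A (A'A)^{-1} A'`` the annihilator of a design A,

the LIML eigenvalue is the smallest eigenvalue of the 2x2 pencil
``(Y' M_{C*} Y, Y' M_W Y)`` with ``Y = [exposure, outcome]``, and the k-class
solve is ``beta = (X'(I - k M_W) X)^{-1} X'(I - k M_W) y_out`` with structural
design ``X = [intercept, covariates, included instruments, exposure]``.

The naive estimator excludes the opposite trait's instruments entirely; the
bidirectional variant (BiLIML) carries them as *included* exogenous columns,
which is what accounts for the feedback loop.  Annihilators are applied via
thin-QR orthogonal decompositions, never as explicit n x n matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import linalg, stats

from .core import BiMRError, CausalEstimate, Dataset, ValidationError

__all__ = [
    "SingularityError",
    "DegenerateProblemError",
    "KClassProblem",
    "build_kclass_problem",
    "kappa_hat",
    "kclass_solve",
    "naive_liml",
    "biliml",
]


class SingularityError(BiMRError):
    """A required cross-product matrix is singular / not positive definite."""


class DegenerateProblemError(BiMRError):
    """No excluded instruments: the k-class problem is unidentified."""


def _qr_basis(A: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise SingularityError("design matrix is rank deficient")
    return Q


@dataclass
class KClassProblem:
    """One direction's k-class estimation problem.

    ``q_w`` and ``q_c`` are orthonormal bases of span(W) and span(C*); the
    annihilators are applied as ``v - Q (Q' v)``.  Because span(C*) is nested
    in span(W), the LIML eigenvalue is always >= 1.
    """

    y_out: np.ndarray       # outcome phenotype
    exposure: np.ndarray    # endogenous regressor (exposure phenotype)
    X: np.ndarray           # structural design [1, covariates, included, exposure]
    q_w: np.ndarray
    q_c: np.ndarray
    direction: str = "1->2"
    method: str = "liml"
    k_hat: Optional[float] = field(default=None)

    def annihilate_w(self, v: np.ndarray) -> np.ndarray:
        return v - self.q_w @ (self.q_w.T @ v)

    def annihilate_c(self, v: np.ndarray) -> np.ndarray:
        return v - self.q_c @ (self.q_c.T @ v)


def build_kclass_problem(
    outcome: np.ndarray,
    exposure: np.ndarray,
    excluded: np.ndarray,
    included: Optional[np.ndarray] = None,
    covariates: Optional[np.ndarray] = None,
    direction: str = "1->2",
    method: str = "liml",
    q_w: Optional[np.ndarray] = None,
) -> KClassProblem:
    """Assemble designs for one direction.

    ``excluded`` are the exposure's own instruments (excluded from the
    structural equation); ``included`` are exogenous instrument columns kept
    in the structural equation (the opposite set, for the bidirectional
    variant).  ``q_w`` may be supplied to reuse a precomputed basis of
    span(W) — the projection depends only on the column span.
    """
    outcome = np.asarray(outcome, dtype=float)
    n = outcome.shape[0]
    excluded = np.asarray(excluded, dtype=float)
    if excluded.ndim == 1:
        excluded = excluded[:, None]
    if excluded.shape[1] == 0:
        raise DegenerateProblemError(
            "no excluded instruments: causal effect is unidentified"
        )
    one = np.ones((n, 1))
    blocks = [one]
    for b in (covariates, included):
        if b is not None:
            b = np.asarray(b, dtype=float)
            blocks.append(b[:, None] if b.ndim == 1 else b)
    C_star = np.hstack(blocks)
    W = np.hstack([C_star, excluded])
    X = np.hstack([C_star, np.asarray(exposure, dtype=float)[:, None]])
    return KClassProblem(
        y_out=outcome,
        exposure=np.asarray(exposure, dtype=float),
        X=X,
        q_w=_qr_basis(W) if q_w is None else q_w,
        q_c=_qr_basis(C_star),
        direction=direction,
        method=method,
    )


def kappa_hat(problem: KClassProblem) -> float:
    """Smallest eigenvalue of the pencil (Y' M_{C*} Y, Y' M_W Y).

    Equals the minimum over gamma of the variance ratio
    ``(y - gamma x)' M_{C*} (y - gamma x) / (y - gamma x)' M_W (y - gamma x)``
    and is >= 1 because span(C*) is nested in span(W).  When W = C* (no
    excluded instruments would add information) it is exactly 1.
    """
    Y = np.column_stack([problem.exposure, problem.y_out])
    Mw_Y = problem.annihilate_w(Y)
    Mc_Y = problem.annihilate_c(Y)
    B = Y.T @ Mw_Y
    A = Y.T @ Mc_Y
    try:
        k = float(linalg.eigh(A, B, eigvals_only=True)[0])
    except linalg.LinAlgError as exc:  # B not positive definite
        raise SingularityError(f"Y' M_W Y is not positive definite: {exc}") from exc
    # clip tiny negative excursions below 1 from floating point
    k = max(k, 1.0)
    problem.k_hat = k
    return k


def kclass_solve(problem: KClassProblem, k: Optional[float] = None) -> CausalEstimate:
    """Closed-form k-class solve; k defaults to the LIML eigenvalue.

    ``k = 1`` gives two-stage least squares.  The coefficient on the
    endogenous exposure column is reported with SE from the k-class
    asymptotic covariance ``sigma^2 (X'(I - k M_W) X)^{-1}`` (sigma^2 from
    structural residuals, df = n - structural columns) and a t-based 95% CI.
    """
    if k is None:
        k = problem.k_hat if problem.k_hat is not None else kappa_hat(problem)
    X, y = problem.X, problem.y_out
    n, p = X.shape
    QwX = problem.q_w.T @ X
    Qwy = problem.q_w.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    # X'(I - k M_W) X = X'X - k (X'X - (Qw'X)'(Qw'X))
    A = XtX - k * (XtX - QwX.T @ QwX)
    b = Xty - k * (Xty - QwX.T @ Qwy)
    try:
        beta = linalg.solve(A, b, assume_a="sym")
        Ainv = linalg.inv(A)
    except linalg.LinAlgError as exc:
        raise SingularityError(f"k-class normal matrix is singular: {exc}") from exc
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        raise ValidationError(f"non-positive degrees of freedom ({df})")
    sigma2 = float(resid @ resid) / df
    var = sigma2 * Ainv[-1, -1]
    if var <= 0:
        raise SingularityError("non-positive k-class variance estimate")
    se = float(np.sqrt(var))
    estimate = float(beta[-1])
    if se == 0.0:  # noiseless data: exact recovery
        p_value, ci_low, ci_high = np.nextafter(0, 1), estimate, estimate
    else:
        tq = stats.t.ppf(0.975, df)
        ci_low, ci_high = estimate - tq * se, estimate + tq * se
        p_value = float(
            max(2.0 * stats.t.sf(abs(estimate) / se, df), np.nextafter(0, 1))
        )
    return CausalEstimate(
        direction=problem.direction,
        method=problem.method,
        estimate=estimate,
        se=se if se > 0 else np.nextafter(0, 1),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        k_hat=float(k),
    )


def _direction_arrays(data: Dataset, direction: str):
    if direction == "1->2":
        return data.y1, data.y2, data.X1, data.X2
    if direction == "2->1":
        return data.y2, data.y1, data.X2, data.X1
    raise ValidationError(f"unknown direction {direction!r}")


def naive_liml(
    data: Dataset, covariates: Optional[np.ndarray] = None
) -> Tuple[CausalEstimate, CausalEstimate]:
    """LIML applied per direction under the unidirectional model: the
    exposure's own instruments are excluded and the opposite set is omitted
    entirely (the standard comparator)."""
    out = []
    for direction in ("1->2", "2->1"):
        exposure, outcome, own, _ = _direction_arrays(data, direction)
        prob = build_kclass_problem(
            outcome, exposure, own, included=None, covariates=covariates,
            direction=direction, method="liml",
        )
        out.append(kclass_solve(prob))
    return tuple(out)


def biliml(
    data: Dataset, covariates: Optional[np.ndarray] = None
) -> Tuple[CausalEstimate, CausalEstimate]:
    """Feedback-aware LIML: the opposite direction's instruments enter the
    structural equation as included exogenous columns.

    Both directions share the same full-instrument span
    [1, covariates, X1, X2], so its orthonormal basis is computed once.
    """
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    one = np.ones((data.n, 1))
    blocks = [one] + ([cov] if cov is not None else []) + [data.X1, data.X2]
    q_w = _qr_basis(np.hstack(blocks))
    out = []
    for direction in ("1->2", "2->1"):
        exposure, outcome, own, opposite = _direction_arrays(data, direction)
        prob = build_kclass_problem(
            outcome, exposure, own, included=opposite, covariates=covariates,
            direction=direction, method="biliml", q_w=q_w,
        )
        out.append(kclass_solve(prob))
    return tuple(out)
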