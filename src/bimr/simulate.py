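"""Cohort simulation under the unidirectional and bidirectional MR models.

Genotype dosages are Binomial(2, maf) (Hardy-Weinberg proportions), the
confounder is Normal(confounder_mean, confounder_sd), and structural errors
are Normal(0, error_sd).  Bidirectional cohorts are generated directly from
the converged reduced form; :func:`fixed_point_oracle` iterates the raw
structural equations instead and serves as an independent cross-check.

Noise draw order is fixed (X1, X2, confounder, eps1, eps2), so a bidirectional
simulation with ``gamma21 = 0`` reproduces the unidirectional one bit-for-bit
at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .core import (
    BMRParameters,
    ConvergenceError,
    Dataset,
    ValidationError,
    reduced_form,
)

__all__ = [
    "ScenarioConfig",
    "simulate_genotypes",
    "simulate_umr",
    "simulate_bmr",
    "fixed_point_oracle",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: generative model kind + parameters + replication.

    ``kind`` is ``"umr"`` (no trait2 -> trait1 effect; trait-1 equation has no
    y2 term) or ``"bmr"`` (full feedback loop).  Replicate ``r`` of a
    benchmark uses seed ``seed + r``.
    """

    kind: str
    params: BMRParameters
    n_reps: int = 1000
    seed: int = 0
    strength: Optional[str] = None  # optional "strong"/"weak" label
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("umr", "bmr"):
            raise ValidationError(f"scenario kind must be 'umr' or 'bmr', got {self.kind!r}")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if self.kind == "umr" and self.params.gamma21 != 0.0:
            raise ValidationError("umr scenario requires gamma21 = 0")


def _rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(
    n: int, k: int, maf: float, seed: Union[int, np.random.Generator, None] = None
) -> np.ndarray:
    """n x k matrix of independent SNP dosages, each Binomial(2, maf).

    Under Hardy-Weinberg proportions the genotype frequencies are
    ((1-maf)^2, 2*maf*(1-maf), maf^2) for dosages (0, 1, 2).
    """
    if not (0.0 < maf <= 0.5):
        raise ValidationError(f"maf must be in (0, 0.5], got {maf}")
    if n < 1 or k < 1:
        raise ValidationError(f"n and k must be >= 1, got n={n}, k={k}")
    rng = _rng(seed)
    return rng.binomial(2, maf, size=(n, k)).astype(float)


def _draw_noise(params: BMRParameters, rng: np.random.Generator):
    """Shared draw pathway: genotypes, confounder, structural errors."""
    X1 = simulate_genotypes(params.n, params.k1, params.maf, rng)
    X2 = simulate_genotypes(params.n, params.k2, params.maf, rng)
    C = rng.normal(params.confounder_mean, params.confounder_sd, params.n)
    eps1 = rng.normal(0.0, params.error_sd1, params.n)
    eps2 = rng.normal(0.0, params.error_sd2, params.n)
    return X1, X2, C, eps1, eps2


def simulate_umr(config: ScenarioConfig, seed: Union[int, None] = None) -> Dataset:
    """Unidirectional cohort: trait 1 from its instruments only, trait 2 from
    its instruments plus ``gamma12 * y1``.  ``gamma21`` must be 0."""
    if config.kind != "umr":
        raise ValidationError("simulate_umr requires a config with kind='umr'")
    p = config.params
    rng = _rng(config.seed if seed is None else seed)
    X1, X2, C, eps1, eps2 = _draw_noise(p, rng)
    y1 = p.beta01 + X1 @ p.beta11 + p.beta_c_y1 * C + eps1
    y2 = p.beta02 + X2 @ p.beta22 + p.beta_c_y2 * C + p.gamma12 * y1 + eps2
    return Dataset(y1=y1, y2=y2, X1=X1, X2=X2, confounder=C)


def simulate_bmr(config: ScenarioConfig, seed: Union[int, None] = None) -> Dataset:
    """Bidirectional cohort drawn from the converged reduced form.

    Raises :class:`ConvergenceError` when ``|gamma12*gamma21| >= 1``.
    """
    if config.kind != "bmr":
        raise ValidationError("simulate_bmr requires a config with kind='bmr'")
    p = config.params
    rf = reduced_form(p)  # raises ConvergenceError if the loop diverges
    rng = _rng(config.seed if seed is None else seed)
    X1, X2, C, eps1, eps2 = _draw_noise(p, rng)
    d = 1.0 - p.feedback_product
    delta1 = (eps1 + p.gamma21 * eps2) / d
    delta2 = (eps2 + p.gamma12 * eps1) / d
    y1 = rf.alpha01 + rf.alpha_c_y1 * C + X1 @ rf.alpha11 + X2 @ rf.gamma23 + delta1
    y2 = rf.alpha02 + rf.alpha_c_y2 * C + X1 @ rf.gamma13 + X2 @ rf.alpha22 + delta2
    return Dataset(y1=y1, y2=y2, X1=X1, X2=X2, confounder=C)


def fixed_point_oracle(
    params: BMRParameters,
    eps1: np.ndarray,
    eps2: np.ndarray,
    C: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Iterate the raw structural equations to their fixed point.

    Alternating (Gauss-Seidel) updates from zero initialization: each pass
    recomputes y1 from the current y2, then y2 from the new y1.  The error
    contracts by |gamma12*gamma21| per pass, so the limit equals the
    closed-form reduced-form phenotypes; non-convergence within ``max_iter``
    raises :class:`ConvergenceError`.
    """
    base1 = params.beta01 + X1 @ params.beta11 + params.beta_c_y1 * C + eps1
    base2 = params.beta02 + X2 @ params.beta22 + params.beta_c_y2 * C + eps2
    y1 = np.zeros_like(base1)
    y2 = np.zeros_like(base2)
    for _ in range(max_iter):
        y1_new = base1 + params.gamma21 * y2
        y2_new = base2 + params.gamma12 * y1_new
        delta = max(
            np.max(np.abs(y1_new - y1), initial=0.0),
            np.max(np.abs(y2_new - y2), initial=0.0),
        )
        y1, y2 = y1_new, y2_new
        if delta < tol:
            return y1, y2
    raise ConvergenceError(
        f"fixed-point iteration did not converge in {max_iter} iterations "
        f"(|gamma12*gamma21| = {abs(params.feedback_product):.6g})"
    )
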