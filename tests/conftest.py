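import numpy as np
import pytest

from bimr import BMRParameters, Dataset, ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240308)


def make_params(gamma12, gamma21, k=1, beta=1.0, **kw):
    return BMRParameters(
        gamma12=gamma12,
        gamma21=gamma21,
        beta11=np.full(k, beta),
        beta22=np.full(k, beta),
        **kw,
    )


def noiseless_bmr_dataset(rng, n, k, beta, gamma12, gamma21, maf=0.3):
    """Exact reduced-form phenotypes with zero structural error and no
    confounder effect: both bidirectional estimators recover the truth
    exactly on such data."""
    X1 = rng.binomial(2, maf, size=(n, k)).astype(float)
    X2 = rng.binomial(2, maf, size=(n, k)).astype(float)
    d = 1.0 - gamma12 * gamma21
    b = np.full(k, beta)
    y1 = (1.0 + gamma21 * 1.0) / d + X1 @ (b / d) + X2 @ (gamma21 * b / d)
    y2 = (1.0 + gamma12 * 1.0) / d + X1 @ (gamma12 * b / d) + X2 @ (b / d)
    return Dataset(y1=y1, y2=y2, X1=X1, X2=X2)


def noisy_bmr_dataset(rng, n, k, beta, gamma12, gamma21, noise_sd=1.0, conf=True):
    X1 = rng.binomial(2, 0.3, size=(n, k)).astype(float)
    X2 = rng.binomial(2, 0.3, size=(n, k)).astype(float)
    C = rng.normal(1, 1, n) if conf else np.zeros(n)
    e1 = rng.normal(0, noise_sd, n)
    e2 = rng.normal(0, noise_sd, n)
    d = 1.0 - gamma12 * gamma21
    b = np.full(k, beta)
    bc = 0.3 if conf else 0.0
    y1 = (
        (1.0 + gamma21) / d + (bc + gamma21 * bc) / d * C
        + X1 @ (b / d) + X2 @ (gamma21 * b / d) + (e1 + gamma21 * e2) / d
    )
    y2 = (
        (1.0 + gamma12) / d + (bc + gamma12 * bc) / d * C
        + X1 @ (gamma12 * b / d) + X2 @ (b / d) + (e2 + gamma12 * e1) / d
    )
    return Dataset(y1=y1, y2=y2, X1=X1, X2=X2, confounder=C)


@pytest.fixture
def small_bmr_dataset(rng):
    return noisy_bmr_dataset(rng, 400, 3, 1.0, -1.9, 0.5)


def scenario(kind, gamma12, gamma21, k, beta, n_reps, seed, n=1000):
    return ScenarioConfig(
        kind=kind,
        params=make_params(gamma12, gamma21, k=k, beta=beta, n=n),
        n_reps=n_reps,
        seed=seed,
    )
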