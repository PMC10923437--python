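import numpy as np
import pytest

from bimr import (
    ConvergenceError,
    ValidationError,
    fixed_point_oracle,
    reduced_form,
    simulate_bmr,
    simulate_genotypes,
    simulate_umr,
)
from bimr.regress import focal_ols
from conftest import make_params, scenario


class TestGenotypes:
    def test_hardy_weinberg_proportions(self):
        X = simulate_genotypes(40_000, 3, maf=0.3, seed=1)
        freqs = [np.mean(X == d) for d in (0, 1, 2)]
        np.testing.assert_allclose(freqs, [0.49, 0.42, 0.09], atol=0.01)
        assert X.mean() == pytest.approx(0.6, abs=0.01)

    def test_seed_determinism(self):
        a = simulate_genotypes(4, 2, maf=0.5, seed=42)
        b = simulate_genotypes(4, 2, maf=0.5, seed=42)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n,k,maf", [(10, 0, 0.3), (0, 2, 0.3), (10, 2, 0.0)])
    def test_invalid_arguments(self, n, k, maf):
        with pytest.raises(ValidationError):
            simulate_genotypes(n, k, maf)


class TestFixedPointOracle:
    """The module's central correctness property: the closed-form reduced-form
    simulation and the iterated structural equations agree on shared noise."""

    @pytest.mark.parametrize(
        "g12,g21", [(-1.9, -0.5), (-1.9, 0.5), (0.9, 0.9), (1.9, 0.0), (0.0, 0.0)]
    )
    def test_closed_form_equals_fixed_point(self, rng, g12, g21):
        params = make_params(g12, g21, k=3, beta=0.7, n=300)
        cfg = scenario("bmr", g12, g21, k=3, beta=0.7, n_reps=1, seed=5, n=300)
        data = simulate_bmr(cfg)
        # replay the exact noise draws of the simulator
        replay = np.random.default_rng(5)
        X1 = replay.binomial(2, 0.3, (300, 3)).astype(float)
        X2 = replay.binomial(2, 0.3, (300, 3)).astype(float)
        C = replay.normal(1, 1, 300)
        e1 = replay.normal(0, 1, 300)
        e2 = replay.normal(0, 1, 300)
        y1, y2 = fixed_point_oracle(params, e1, e2, C, X1, X2, tol=1e-12)
        np.testing.assert_allclose(y1, data.y1, atol=1e-8)
        np.testing.assert_allclose(y2, data.y2, atol=1e-8)

    def test_no_feedback_converges_immediately(self, rng):
        params = make_params(1.9, 0.0, n=50)
        n = 50
        args = (rng.normal(size=n), rng.normal(size=n), rng.normal(size=n),
                rng.binomial(2, 0.3, (n, 1)).astype(float),
                rng.binomial(2, 0.3, (n, 1)).astype(float))
        y1, y2 = fixed_point_oracle(params, *args, max_iter=2)
        assert np.all(np.isfinite(y1)) and np.all(np.isfinite(y2))

    def test_divergent_loop_raises(self, rng):
        params = make_params(1.05, 1.05, n=50)
        n = 50
        args = (rng.normal(size=n), rng.normal(size=n), rng.normal(size=n),
                rng.binomial(2, 0.3, (n, 1)).astype(float),
                rng.binomial(2, 0.3, (n, 1)).astype(float))
        with pytest.raises(ConvergenceError):
            fixed_point_oracle(params, *args, max_iter=200)


class TestSimulators:
    def test_bmr_without_feedback_matches_umr_bitwise(self):
        cfg_b = scenario("bmr", 1.9, 0.0, k=2, beta=1.0, n_reps=1, seed=9, n=500)
        cfg_u = scenario("umr", 1.9, 0.0, k=2, beta=1.0, n_reps=1, seed=9, n=500)
        db, du = simulate_bmr(cfg_b), simulate_umr(cfg_u)
        np.testing.assert_array_equal(db.X1, du.X1)
        np.testing.assert_allclose(db.y1, du.y1, rtol=1e-12)
        np.testing.assert_allclose(db.y2, du.y2, rtol=1e-12)

    def test_umr_noiseless_limit_is_exact_linear(self, rng):
        # with no confounder effect and vanishing error, y2 - g12*y1 is an
        # exact linear function of the trait-2 instruments
        params = make_params(
            1.9, 0.0, k=1, beta=1.0, n=100,
            beta_c_y1=0.0, beta_c_y2=0.0, error_sd1=1e-12, error_sd2=1e-12,
        )
        cfg = scenario("umr", 1.9, 0.0, k=1, beta=1.0, n_reps=1, seed=3, n=100)
        cfg = type(cfg)(kind="umr", params=params, n_reps=1, seed=3)
        d = simulate_umr(cfg)
        resid = d.y2 - 1.9 * d.y1 - 1.0 - d.X2[:, 0]
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_umr_first_stage_recovers_instrument_effect(self):
        cfg = scenario("umr", 1.9, 0.0, k=1, beta=1.0, n_reps=1, seed=11, n=20_000)
        d = simulate_umr(cfg)
        fit = focal_ols(d.y1, d.X1[:, 0])
        assert fit.coef == pytest.approx(1.0, abs=0.03)

    def test_umr_observational_slope_is_confounded(self):
        # OLS of y2 on y1 converges to g12 + bc2*cov(y1,C)/var(y1), not g12
        cfg = scenario("umr", 1.9, 0.0, k=1, beta=1.0, n_reps=1, seed=13, n=40_000)
        d = simulate_umr(cfg)
        fit = focal_ols(d.y2, d.y1)
        expected = 1.9 + 0.3 * (0.3 * 1.0) / (0.42 + 0.09 + 1.0)
        assert fit.coef == pytest.approx(expected, abs=0.02)
        assert fit.coef > 1.93

    def test_strong_feedback_inflates_first_stage_slope(self):
        # 1 - g12*g21 = 0.05, so the observed slope of y1 on x1 is ~20
        cfg = scenario("bmr", -1.9, -0.5, k=1, beta=1.0, n_reps=1, seed=17, n=20_000)
        d = simulate_bmr(cfg)
        fit = focal_ols(d.y1, d.X1[:, 0])
        assert fit.coef == pytest.approx(20.0, rel=0.05)

    def test_empirical_variance_matches_reduced_form(self):
        params = make_params(-1.9, 0.5, k=4, beta=1.0, n=40_000)
        cfg = type(scenario("bmr", -1.9, 0.5, k=4, beta=1.0, n_reps=1, seed=19))(
            kind="bmr", params=params, n_reps=1, seed=19
        )
        d = simulate_bmr(cfg)
        rf = reduced_form(params)
        gvar = 2 * 0.3 * 0.7
        expected = (
            gvar * (rf.alpha11**2).sum()
            + gvar * (rf.gamma23**2).sum()
            + rf.alpha_c_y1**2
            + rf.delta1_sd**2
        )
        assert d.y1.var() == pytest.approx(expected, rel=0.05)

    def test_umr_config_rejects_feedback(self):
        with pytest.raises(ValidationError):
            scenario("umr", 1.9, 0.5, k=1, beta=1.0, n_reps=1, seed=0)
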