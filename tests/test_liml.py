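import numpy as np
import pytest
from scipy import optimize

from bimr import (
    DegenerateProblemError,
    KClassProblem,
    biliml,
    build_kclass_problem,
    kappa_hat,
    kclass_solve,
    naive_liml,
    ratio_single,
)
from conftest import noiseless_bmr_dataset, noisy_bmr_dataset


def _random_problem(seed, n=80, k_exc=3, k_inc=2):
    rng = np.random.default_rng(seed)
    exc = rng.normal(size=(n, k_exc))
    inc = rng.normal(size=(n, k_inc)) if k_inc else None
    exposure = exc @ rng.normal(size=k_exc) + rng.normal(size=n)
    outcome = 0.7 * exposure + rng.normal(size=n)
    if inc is not None:
        outcome = outcome + inc @ rng.normal(size=k_inc)
    return build_kclass_problem(outcome, exposure, exc, included=inc)


class TestKappaHat:
    def test_equal_designs_give_kappa_one(self, rng):
        # no excluded instruments add information: both annihilators match
        n = 60
        C = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        Q, _ = np.linalg.qr(C)
        prob = KClassProblem(
            y_out=rng.normal(size=n),
            exposure=rng.normal(size=n),
            X=np.column_stack([C, rng.normal(size=n)]),
            q_w=Q,
            q_c=Q,
        )
        assert kappa_hat(prob) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_kappa_at_least_one(self, seed):
        assert kappa_hat(_random_problem(seed)) >= 1.0

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_kappa_minimizes_variance_ratio(self, seed):
        """kappa equals min over gamma of the ratio of restricted to full
        annihilated sums of squares of (y - gamma * x)."""
        prob = _random_problem(seed)

        def objective(gamma):
            r = prob.y_out - gamma * prob.exposure
            num = r @ prob.annihilate_c(r)
            den = r @ prob.annihilate_w(r)
            return num / den

        grid = np.linspace(-10, 10, 4001)
        vals = [objective(g) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            objective, bounds=(g0 - 0.2, g0 + 0.2), method="bounded",
            options={"xatol": 1e-12},
        )
        assert kappa_hat(prob) == pytest.approx(res.fun, abs=1e-6)

    def test_annihilators_idempotent_and_nested(self):
        prob = _random_problem(99)
        v = np.random.default_rng(7).normal(size=prob.y_out.shape[0])
        mw = prob.annihilate_w(v)
        mc = prob.annihilate_c(v)
        np.testing.assert_allclose(prob.annihilate_w(mw), mw, atol=1e-10)
        np.testing.assert_allclose(prob.annihilate_c(mc), mc, atol=1e-10)
        # span(C*) nested in span(W): annihilating more leaves less variance
        assert v @ mw <= v @ mc + 1e-10

    def test_annihilator_matches_explicit_projection_matrix(self):
        prob = _random_problem(3, n=40)
        n = 40
        W = np.linalg.qr(prob.q_w)[0]  # any basis of span(W)
        Mw = np.eye(n) - W @ W.T
        v = np.random.default_rng(1).normal(size=n)
        np.testing.assert_allclose(prob.annihilate_w(v), Mw @ v, atol=1e-10)


class TestKClassSolve:
    def test_just_identified_equals_ratio(self, rng):
        d = noisy_bmr_dataset(rng, 500, 1, 1.0, -1.9, -0.5)
        liml12, liml21 = naive_liml(d)
        ratio12 = ratio_single(d, "1->2", 0)
        ratio21 = ratio_single(d, "2->1", 0)
        assert liml12.estimate == pytest.approx(ratio12.estimate, rel=1e-10)
        assert liml21.estimate == pytest.approx(ratio21.estimate, rel=1e-10)
        assert liml12.k_hat == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [20, 21, 22])
    def test_k_one_equals_bruteforce_2sls(self, seed):
        prob = _random_problem(seed)
        est = kclass_solve(prob, k=1.0)
        # explicit projection-matrix 2SLS oracle
        n = prob.y_out.shape[0]
        Pw = prob.q_w @ prob.q_w.T
        X = prob.X
        beta = np.linalg.solve(X.T @ Pw @ X, X.T @ Pw @ prob.y_out)
        assert est.estimate == pytest.approx(beta[-1], rel=1e-10)
        assert est.k_hat == 1.0

    def test_noiseless_exact_recovery_with_k_one(self, rng):
        d = noiseless_bmr_dataset(rng, 200, 2, 1.0, -1.9, 0.5)
        prob = build_kclass_problem(d.y2, d.y1, d.X1, included=d.X2)
        est = kclass_solve(prob, k=1.0)
        assert est.estimate == pytest.approx(-1.9, abs=1e-9)

    def test_near_noiseless_biliml_recovery(self, rng):
        d = noisy_bmr_dataset(rng, 400, 2, 1.0, -1.9, 0.5, noise_sd=1e-6, conf=False)
        est12, est21 = biliml(d)
        assert est12.estimate == pytest.approx(-1.9, abs=1e-4)
        assert est21.estimate == pytest.approx(0.5, abs=1e-4)

    def test_degenerate_direction_rejected(self, rng):
        with pytest.raises(DegenerateProblemError):
            build_kclass_problem(
                rng.normal(size=30), rng.normal(size=30), np.empty((30, 0))
            )

    def test_swap_symmetry(self, rng):
        d = noisy_bmr_dataset(rng, 300, 3, 1.0, -1.2, 0.4)
        for estimator in (naive_liml, biliml):
            a12, a21 = estimator(d)
            b12, b21 = estimator(d.swapped())
            assert a12.estimate == pytest.approx(b21.estimate, rel=1e-9)
            assert a21.estimate == pytest.approx(b12.estimate, rel=1e-9)
            assert a12.k_hat == pytest.approx(b21.k_hat, rel=1e-9)

    def test_confidence_interval_brackets_estimate(self, rng):
        d = noisy_bmr_dataset(rng, 300, 3, 1.0, -1.2, 0.4)
        est12, est21 = biliml(d)
        for est in (est12, est21):
            assert est.ci_low <= est.estimate <= est.ci_high
            assert est.se > 0
            assert 0 < est.p_value <= 1
            assert est.k_hat >= 1.0
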