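import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings, strategies as st

from coxshoot import (QuadraticSurrogate, SolverConfig, adaptive_l12_fit,
                      adaptive_lasso_fit, fit, l1_shoot_update,
                      l12_shoot_update, lambda_grid, lasso_fit, linearize,
                      partial_residual_gradient, reweighted_l1_pass, l12_pass,
                      select_lambda, true_beta, SimulationConfig,
                      generate_dataset, selection_metrics)
from coxshoot.penalized_solvers import _SweepWorkspace, _weights
from tests.conftest import make_exp_cox_data


def grid_minimize(hjj, S0, t, lo=-20.0, hi=20.0, step=1e-4):
    """Brute-force 1-D minimizer of hjj*b^2 + S0*b + t*|b| (independent oracle)."""
    b = np.arange(lo, hi + step, step)
    f = hjj * b ** 2 + S0 * b + t * np.abs(b)
    return b[np.argmin(f)]


def reference_sweep(H, b, beta, thresh):
    """Pure-python cyclic shooting sweep on an explicit quadratic (oracle)."""
    beta = np.array(beta, dtype=float)
    for j in range(beta.shape[0]):
        h = H[j, j]
        if h <= 0:
            beta[j] = 0.0
            continue
        S0 = 2.0 * (H[j] @ beta - h * beta[j] - b[j])
        t = thresh[j]
        if S0 > t:
            beta[j] = (t - S0) / (2 * h)
        elif S0 < -t:
            beta[j] = (-t - S0) / (2 * h)
        else:
            beta[j] = 0.0
    return beta


def random_surrogate(seed, p=5):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((2 * p, p))
    H = A.T @ A / (2 * p)
    b = rng.standard_normal(p)
    return QuadraticSurrogate.from_normal_equations(H, b), H, b


class TestScalarUpdates:
    def test_l12_update_matches_printed_branches(self):
        # S0 beyond the threshold: (lam*w - 2*S0) / (4*hjj)
        assert l12_shoot_update(10.0, 1.0, 1.0, 4.0) == pytest.approx(-4.0)
        # inside the threshold band the update is exactly zero
        assert l12_shoot_update(1.9, 1.0, 1.0, 4.0) == 0.0

    def test_l1_update_matches_printed_branches(self):
        assert l1_shoot_update(10.0, 1.0, 1.0, 4.0) == pytest.approx(-3.0)
        assert l1_shoot_update(3.9, 1.0, 1.0, 4.0) == 0.0

    def test_zero_lambda_is_quadratic_vertex(self):
        assert l1_shoot_update(3.0, 1.0, 2.0, 0.0) == pytest.approx(-0.75)
        assert l12_shoot_update(3.0, 1.0, 2.0, 0.0) == pytest.approx(-0.75)

    @given(S0=st.floats(-8, 8), lam=st.floats(0, 5), w=st.floats(0.1, 2),
           hjj=st.floats(0.5, 3))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_sign_symmetry(self, S0, lam, w, hjj):
        assert l1_shoot_update(-S0, w, hjj, lam) == pytest.approx(
            -l1_shoot_update(S0, w, hjj, lam))
        assert l12_shoot_update(-S0, w, hjj, lam) == pytest.approx(
            -l12_shoot_update(S0, w, hjj, lam))

    @pytest.mark.parametrize("seed", range(4))
    def test_updates_match_grid_minimizer(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            S0 = rng.uniform(-10, 10)
            lam = rng.uniform(0, 5)
            w = rng.uniform(0.1, 2)
            hjj = rng.uniform(0.5, 3)
            npt.assert_allclose(l1_shoot_update(S0, w, hjj, lam),
                                grid_minimize(hjj, S0, lam * w), atol=2e-4)
            npt.assert_allclose(l12_shoot_update(S0, w, hjj, lam),
                                grid_minimize(hjj, S0, 0.5 * lam * w), atol=2e-4)

    def test_degenerate_coordinate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            l1_shoot_update(1.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            l12_shoot_update(1.0, 1.0, -1.0, 1.0)

    def test_threshold_nesting(self):
        # a coordinate zeroed by the L1 rule at penalty lam*w/2 is zeroed
        # by the L1/2 rule at lam*w
        rng = np.random.default_rng(9)
        for _ in range(200):
            S0, lam, w, h = (rng.uniform(-5, 5), rng.uniform(0, 4),
                             rng.uniform(0.1, 2), rng.uniform(0.5, 2))
            if l1_shoot_update(S0, w / 2.0, h, lam) == 0.0:
                assert l12_shoot_update(S0, w, h, lam) == 0.0


class TestPartialResidualGradient:
    def test_orthogonal_null_case(self):
        sur = QuadraticSurrogate.from_normal_equations(np.eye(3), np.zeros(3))
        for j in range(3):
            assert partial_residual_gradient(sur, [1.0, -2.0, 0.5], j) \
                == pytest.approx(0.0, abs=1e-12)

    def test_two_dim_hand_example(self):
        sur = QuadraticSurrogate.from_normal_equations(
            np.array([[1.0, 0.5], [0.5, 1.0]]), np.array([1.0, 0.0]))
        assert partial_residual_gradient(sur, [0.0, 1.0], 0) \
            == pytest.approx(-1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_numeric_rss_derivative_at_zero(self, seed):
        sur, H, b = random_surrogate(seed)
        rng = np.random.default_rng(seed + 50)
        beta = rng.standard_normal(5)
        for j in range(5):
            bj = beta.copy()
            eps = 1e-7
            bj[j] = eps
            up = sur.rss(bj)
            bj[j] = -eps
            down = sur.rss(bj)
            npt.assert_allclose(partial_residual_gradient(sur, beta, j),
                                (up - down) / (2 * eps), atol=1e-6)


class TestSweeps:
    @pytest.mark.parametrize("seed", range(3))
    def test_kernel_matches_pure_python_reference(self, seed):
        sur, H, b = random_surrogate(seed)
        rng = np.random.default_rng(seed + 10)
        beta = rng.standard_normal(5)
        thresh = rng.uniform(0.0, 2.0, 5)
        ws = _SweepWorkspace(sur, beta)
        ws.cycle(thresh)
        npt.assert_allclose(ws.beta, reference_sweep(H, b, beta, thresh),
                            atol=1e-9)

    def test_l12_pass_equals_l1_sweep_at_half_penalty(self):
        sur, H, b = random_surrogate(4)
        beta_t = np.array([1.0, -0.5, 0.0, 2.0, -0.1])
        config = SolverConfig()
        lam = 1.3
        got = l12_pass(sur, beta_t, lam, config)
        w = _weights(beta_t, config.epsilon, config.l12_weight_exponent)
        expected = reference_sweep(H, b, beta_t, 0.5 * lam * w)
        npt.assert_allclose(got, expected, atol=1e-9)

    def test_zero_lambda_converges_to_surrogate_minimizer(self):
        sur, H, b = random_surrogate(2, p=3)
        config = SolverConfig(tol_inner=1e-10, max_inner=2000)
        beta, _, conv = reweighted_l1_pass(sur, np.zeros(3), np.zeros(3), 0.0,
                                           config, unit_weights=True)
        assert conv
        npt.assert_allclose(beta, np.linalg.solve(H, b), atol=1e-6)

    def test_large_lambda_keeps_zero_vector(self):
        sur, H, b = random_surrogate(3)
        lam = 10 * float(np.max(np.abs(2 * b)))
        beta, _, _ = reweighted_l1_pass(sur, np.zeros(5), np.zeros(5), lam,
                                        SolverConfig(), unit_weights=True)
        assert np.all(beta == 0.0)

    def test_sweeps_monotonically_decrease_fixed_weight_objective(self):
        sur, H, b = random_surrogate(6)
        rng = np.random.default_rng(123)
        beta = rng.standard_normal(5) * 2
        w = rng.uniform(0.5, 2.0, 5)
        lam = 0.8

        def obj(v):
            return sur.rss(v) + lam * np.sum(w * np.abs(v))

        ws = _SweepWorkspace(sur, beta)
        prev = obj(ws.beta)
        for _ in range(10):
            ws.cycle(lam * w)
            cur = obj(ws.beta)
            assert cur <= prev + 1e-10
            prev = cur


class TestFits:
    def test_zero_lambda_matches_unpenalized_cox(self, midsize_data):
        from lifelines import CoxPHFitter
        cph = CoxPHFitter()
        cph.fit(midsize_data.to_frame(), "time", "status")
        ref = cph.params_.to_numpy()
        for method in ("lasso", "adaptive_lasso", "adaptive_l12"):
            res = fit(midsize_data, method, 0.0)
            assert res.converged
            npt.assert_allclose(res.beta, ref, atol=1e-4)

    def test_huge_lambda_gives_null_model(self, midsize_data):
        lam_max = lambda_grid(midsize_data, n_lambda=2, ratio=0.5)[0]
        for method in ("lasso", "adaptive_lasso", "adaptive_l12"):
            res = fit(midsize_data, method, 10 * lam_max)
            assert np.all(res.beta == 0.0), method

    def test_zeros_are_bit_exact(self):
        data = make_exp_cox_data(31, 60, [0.9, 0.0, 0.0, -0.7, 0.0])
        lam_max = lambda_grid(data, n_lambda=2, ratio=0.5)[0]
        res = lasso_fit(data, 0.5 * lam_max)
        zeroed = res.beta[res.beta == 0.0]
        assert zeroed.size > 0
        assert all(v == 0.0 and np.copysign(1, v) == 1.0 for v in zeroed)

    def test_determinism_bit_identical(self, midsize_data):
        a = adaptive_l12_fit(midsize_data, 2.0)
        b = adaptive_l12_fit(midsize_data, 2.0)
        assert np.array_equal(a.beta, b.beta)
        assert a.objective_trace == b.objective_trace

    def test_unit_weight_adaptive_lasso_equals_lasso(self, midsize_data):
        config = SolverConfig(l1_weight_exponent=0.0)  # forces omega = 1
        a = adaptive_lasso_fit(midsize_data, 1.5, config)
        l = lasso_fit(midsize_data, 1.5, config)
        npt.assert_allclose(a.beta, l.beta, atol=1e-10)

    def test_converged_flag_implies_small_last_step(self, midsize_data):
        res = lasso_fit(midsize_data, 1.0)
        assert res.converged
        assert res.n_outer <= SolverConfig().max_outer

    def test_unknown_method_raises(self, midsize_data):
        with pytest.raises(ValueError, match="unknown method"):
            fit(midsize_data, "scad", 1.0)


@pytest.fixture(scope="module")
def recovery_data():
    beta = np.zeros(20)
    beta[[0, 1, 2]] = [0.9, -0.8, 0.7]
    rng = np.random.default_rng(2024)
    X = rng.standard_normal((200, 20))
    T = -np.log(rng.uniform(size=200)) / np.exp(X @ beta)
    C = rng.exponential(2.0, 200)
    from coxshoot import SurvivalDataset
    data = SurvivalDataset(np.maximum(np.minimum(T, C), 1e-12),
                           (T <= C).astype(int), X)
    return data, beta


class TestRecovery:

    def test_strong_effects_recovered_with_signs(self, recovery_data):
        data, beta_true = recovery_data
        cv = select_lambda(data, "adaptive_l12", K=5, seed=3, n_lambda=15,
                           ratio=0.05)
        res = adaptive_l12_fit(data, cv.lam_best)
        for j in range(3):
            assert res.beta[j] != 0.0
            assert np.sign(res.beta[j]) == np.sign(beta_true[j])

    def test_adaptive_lasso_no_denser_than_lasso(self, recovery_data):
        data, _ = recovery_data
        lam = lambda_grid(data, n_lambda=10, ratio=0.05)[5]
        n_alasso = int(np.sum(adaptive_lasso_fit(data, lam).beta != 0.0))
        n_lasso = int(np.sum(lasso_fit(data, lam).beta != 0.0))
        assert n_alasso <= n_lasso
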