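import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from stprev.basis import build_basis
from stprev.data import PanelCounts
from stprev.graph import RegionGraph
from stprev.models import (
    BYMParams,
    PriorConfig,
    SCMParams,
    binom_loglik,
    bym_linear_predictor,
    invlogit,
    log_icar,
    log_joint_bym,
    log_joint_scm,
    log_mcar,
    logit,
    scm_linear_predictor,
    variance_share,
)

from conftest import random_connected_graph


def random_scm_params(rng, N, K, T, scale=0.5):
    p = SCMParams.zeros(N, K, T)
    p.alpha = scale * rng.standard_normal(2)
    p.b0 = scale * rng.standard_normal(N)
    p.b_shared_spline = scale * rng.standard_normal((N, K))
    p.a_gender = scale * rng.standard_normal((2, K))
    p.b_gender = scale * rng.standard_normal((2, N))
    p.beta_gender_spline = scale * rng.standard_normal((2, N, K))
    p.beta_it = scale * rng.standard_normal((N, T))
    p.log_delta = 0.3 * rng.standard_normal(T)
    p.tau_beta = float(rng.gamma(3, 1))
    p.tau_b = float(rng.gamma(3, 1))
    A = rng.standard_normal((K, K))
    p.Gamma_b = A @ A.T + K * np.eye(K)
    return p


def random_panel(rng, graph, waves, n_sexes):
    shape = (n_sexes, graph.n_regions, len(waves))
    n = rng.integers(50, 400, size=shape)
    O = rng.binomial(n, rng.uniform(0.1, 0.5, size=shape))
    return PanelCounts(graph, waves, O, n)


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------


class TestBYMPredictor:
    def test_all_zero_params_give_half(self, basis9):
        p = BYMParams.zeros(7, basis9.K)
        prev = invlogit(bym_linear_predictor(p, basis9))
        np.testing.assert_allclose(prev, 0.5)

    def test_intercept_anchors_baseline_prevalence(self, basis9):
        p = BYMParams.zeros(7, basis9.K)
        p.alpha0 = float(logit(0.117))
        prev = invlogit(bym_linear_predictor(p, basis9))
        np.testing.assert_allclose(prev, 0.117, rtol=1e-12)

    def test_single_cell_matches_scalar_hand_evaluation(self, basis9):
        rng = np.random.default_rng(0)
        p = BYMParams.zeros(7, basis9.K)
        p.alpha0 = rng.standard_normal()
        p.a = rng.standard_normal(basis9.K)
        p.u0 = rng.standard_normal(7)
        p.s0 = rng.standard_normal(7)
        p.b_spline = rng.standard_normal((7, basis9.K))
        eta = bym_linear_predictor(p, basis9)
        i, t = 3, 5
        expected = (
            p.alpha0
            + sum(p.a[k] * basis9.B[t, k] for k in range(basis9.K))
            + p.u0[i]
            + p.s0[i]
            + sum(p.b_spline[i, k] * basis9.B[t, k] for k in range(basis9.K))
        )
        assert eta[i, t] == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_names_axis(self, basis9):
        p = BYMParams.zeros(7, basis9.K)
        p.a = np.zeros(basis9.K + 1)
        with pytest.raises(ValueError, match="spline axis"):
            bym_linear_predictor(p, basis9)


class TestSCMPredictor:
    def test_all_zero_params_give_half(self, basis9):
        p = SCMParams.zeros(7, basis9.K, 9)
        prev = invlogit(scm_linear_predictor(p, basis9))
        np.testing.assert_allclose(prev, 0.5)

    def test_shared_only_with_unit_weight_is_sex_symmetric(self, basis9):
        rng = np.random.default_rng(1)
        p = SCMParams.zeros(7, basis9.K, 9)
        p.b0 = rng.standard_normal(7)
        p.b_shared_spline = rng.standard_normal((7, basis9.K))
        eta = scm_linear_predictor(p, basis9)
        np.testing.assert_allclose(eta[0], eta[1], atol=1e-12)

    def test_constant_log_weight_scales_shared_term_by_exp_2c(self, basis9):
        rng = np.random.default_rng(2)
        c = 0.4
        p = SCMParams.zeros(7, basis9.K, 9)
        p.b0 = rng.standard_normal(7) + 2.0  # keep the shared term nonzero
        p.log_delta = np.full(9, c)
        eta = scm_linear_predictor(p, basis9)
        np.testing.assert_allclose(eta[0] / eta[1], np.exp(2 * c), rtol=1e-10)


class TestVarianceShare:
    def test_no_sex_specific_terms_gives_one(self, basis9):
        rng = np.random.default_rng(3)
        p = SCMParams.zeros(7, basis9.K, 9)
        p.b0 = rng.standard_normal(7)
        p.b_shared_spline = rng.standard_normal((7, basis9.K))
        np.testing.assert_allclose(variance_share(p, basis9), 1.0, atol=1e-12)

    def test_zero_shared_terms_give_zero(self, basis9):
        rng = np.random.default_rng(4)
        p = SCMParams.zeros(7, basis9.K, 9)
        p.b_gender = rng.standard_normal((2, 7))
        p.beta_it = rng.standard_normal((7, 9))
        np.testing.assert_allclose(variance_share(p, basis9), 0.0, atol=1e-12)

    def test_matches_two_pass_variance_oracle(self, basis9):
        rng = np.random.default_rng(5)
        p = random_scm_params(rng, 7, basis9.K, 9)
        got = variance_share(p, basis9)
        eta = scm_linear_predictor(p, basis9)
        shared = p.b0[:, None] + p.b_shared_spline @ basis9.B.T
        w = np.stack([np.exp(p.log_delta), np.exp(-p.log_delta)])
        for j in range(2):
            for t in range(9):
                num = np.var(shared[:, t] * w[j, t], ddof=1)
                den = np.var(eta[j, :, t], ddof=1)
                assert got[j, t] == pytest.approx(num / den, rel=1e-10)

    def test_single_region_rejected(self, basis9):
        p = SCMParams.zeros(1, basis9.K, 9)
        with pytest.raises(ValueError, match="at least 2 regions"):
            variance_share(p, basis9)


# ---------------------------------------------------------------------------
# CAR kernels
# ---------------------------------------------------------------------------


class TestIcar:
    def test_path_graph_hand_value(self, path3):
        # edges (1,2),(2,3): sum of squared differences = 1 + 1 = 2 -> -1
        assert log_icar([-1.0, 0.0, 1.0], 1.0, path3) == pytest.approx(-1.0, abs=1e-12)

    def test_zero_vector_is_kernel_maximum(self, path3):
        assert log_icar(np.zeros(3), 1.0, path3) == pytest.approx(0.0, abs=1e-15)

    def test_matches_laplacian_quadratic_form(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            g = random_connected_graph(rng, int(rng.integers(2, 11)))
            x = rng.standard_normal(g.n_regions)
            tau = float(rng.gamma(2, 1))
            L = np.diag(g.D) - g.W
            expected = -0.5 * tau * (x @ L @ x) + 0.5 * (g.n_regions - 1) * np.log(tau)
            assert log_icar(x, tau, g) == pytest.approx(expected, abs=1e-10)

    def test_isolated_region_rejected(self):
        W = np.zeros((3, 3), dtype=int)
        W[0, 1] = W[1, 0] = 1
        g = RegionGraph(("a", "b", "c"), W)
        with pytest.raises(ValueError, match="isolated"):
            log_icar(np.zeros(3), 1.0, g)


class TestMcar:
    def test_identity_gamma_decomposes_into_icar_columns(self, study7):
        rng = np.random.default_rng(7)
        b = rng.standard_normal((7, 3))
        got = log_mcar(b, np.eye(3), study7)
        expected = sum(log_icar(b[:, k], 1.0, study7) for k in range(3))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_matrix_gives_zero_kernel(self, study7):
        assert log_mcar(np.zeros((7, 2)), np.eye(2), study7) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_matches_dense_kronecker_quadratic_form(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            g = random_connected_graph(rng, 4)
            K = 2
            A = rng.standard_normal((K, K))
            Gamma = A @ A.T + K * np.eye(K)
            b = rng.standard_normal((4, K))
            L = np.diag(g.D) - g.W
            omega = np.kron(L, Gamma)  # region-major vec ordering
            vec = b.reshape(-1)
            expected = -0.5 * vec @ omega @ vec + 0.5 * (4 - 1) * np.linalg.slogdet(
                Gamma
            )[1]
            assert log_mcar(b, Gamma, g) == pytest.approx(expected, abs=1e-10)

    def test_non_spd_gamma_rejected(self, study7):
        with pytest.raises(ValueError, match="positive definite"):
            log_mcar(np.zeros((7, 2)), np.array([[1.0, 2.0], [2.0, 1.0]]), study7)


# ---------------------------------------------------------------------------
# joint densities
# ---------------------------------------------------------------------------


def test_binomial_loglik_closed_form_single_cell():
    # O=3, n=10 at p=0.5: log C(10,3) + 10 log 0.5
    val = binom_loglik(np.array(0.0), np.array(3.0), np.array(10.0))
    assert val == pytest.approx(np.log(comb(10, 3)) + 10 * np.log(0.5), rel=1e-12)


def test_log_joint_bym_finite_for_finite_params(study7, waves, basis9):
    rng = np.random.default_rng(9)
    data = random_panel(rng, study7, waves, 1)
    p = BYMParams.zeros(7, basis9.K)
    p.alpha0 = -1.0
    p.a = rng.standard_normal(basis9.K)
    p.u0 = rng.standard_normal(7)
    p.s0 = rng.standard_normal(7)
    p.b_spline = rng.standard_normal((7, basis9.K))
    assert np.isfinite(log_joint_bym(p, data, basis9))


def test_log_joint_scm_matches_term_by_term_oracle(study7, waves, basis9):
    rng = np.random.default_rng(10)
    data = random_panel(rng, study7, waves, 2)
    p = random_scm_params(rng, 7, basis9.K, 9)
    prior = PriorConfig()

    # independent recomputation of every named contribution
    eta = scm_linear_predictor(p, basis9)
    prob = invlogit(eta)
    ll = stats.binom.logpmf(data.O, data.n, prob).sum()
    L = np.diag(study7.D) - study7.W
    K = basis9.K
    var = prior.fixed_effect_var

    def normal_kernel(x, v):
        x = np.asarray(x)
        return -(x**2).sum() / (2 * v) - 0.5 * x.size * np.log(v)

    expected = ll
    expected += normal_kernel(np.r_[p.alpha, p.a_gender.ravel()], var)
    expected += normal_kernel(p.b0, var) + normal_kernel(p.b_gender, var)
    expected += (
        -0.5 * np.trace(p.b_shared_spline.T @ L @ p.b_shared_spline @ p.Gamma_b)
        + 0.5 * 6 * np.linalg.slogdet(p.Gamma_b)[1]
    )
    qf_g = sum(
        p.beta_gender_spline[j, :, k] @ L @ p.beta_gender_spline[j, :, k]
        for j in range(2)
        for k in range(K)
    )
    expected += -0.5 * p.tau_b * qf_g + 0.5 * 2 * K * 6 * np.log(p.tau_b)
    qf_b = np.trace(p.beta_it.T @ L @ p.beta_it)
    expected += -0.5 * p.tau_beta * qf_b + 0.5 * 9 * 6 * np.log(p.tau_beta)
    expected += normal_kernel(p.log_delta, prior.log_delta_var)
    for tau in (p.tau_beta, p.tau_b):
        expected += (5 - 1) * np.log(tau) - 5e-4 * tau
    expected += 0.5 * (K - K - 1) * np.linalg.slogdet(p.Gamma_b)[1] - 0.5 * np.trace(
        p.Gamma_b
    )

    assert log_joint_scm(p, data, basis9, prior) == pytest.approx(expected, rel=1e-10)


def test_weaker_delta_penalty_raises_joint(study7, waves, basis9):
    rng = np.random.default_rng(11)
    data = random_panel(rng, study7, waves, 2)
    p = random_scm_params(rng, 7, basis9.K, 9)
    p.log_delta = np.full(9, 0.5)
    from dataclasses import replace

    loose = replace(PriorConfig(), log_delta_var=2 * 0.169)
    assert log_joint_scm(p, data, basis9, loose) > log_joint_scm(
        p, data, basis9, PriorConfig()
    )


class TestSymmetries:
    def test_gender_relabel_with_inverted_weights_is_invariant(
        self, study7, waves, basis9
    ):
        rng = np.random.default_rng(12)
        for trial in range(5):
            data = random_panel(rng, study7, waves, 2)
            p = random_scm_params(rng, 7, basis9.K, 9)
            base = log_joint_scm(p, data, basis9)

            swapped_data = PanelCounts(study7, waves, data.O[::-1], data.n[::-1])
            q = p.copy()
            q.alpha = p.alpha[::-1].copy()
            q.a_gender = p.a_gender[::-1].copy()
            q.b_gender = p.b_gender[::-1].copy()
            q.beta_gender_spline = p.beta_gender_spline[::-1].copy()
            q.log_delta = -p.log_delta
            assert log_joint_scm(q, swapped_data, basis9) == pytest.approx(
                base, abs=1e-10, rel=1e-12
            )

    def test_region_permutation_invariance(self, waves):
        rng = np.random.default_rng(13)
        g = random_connected_graph(rng, 6)
        basis = build_basis(waves, (0.0,))
        data = random_panel(rng, g, waves, 2)
        p = random_scm_params(rng, 6, basis.K, 9)
        base = log_joint_scm(p, data, basis)

        perm = rng.permutation(6)
        gp = RegionGraph(
            tuple(g.region_ids[i] for i in perm), g.W[np.ix_(perm, perm)]
        )
        dp = PanelCounts(gp, waves, data.O[:, perm], data.n[:, perm])
        q = p.copy()
        q.b0 = p.b0[perm]
        q.b_shared_spline = p.b_shared_spline[perm]
        q.b_gender = p.b_gender[:, perm]
        q.beta_gender_spline = p.beta_gender_spline[:, perm]
        q.beta_it = p.beta_it[perm]
        assert log_joint_scm(q, dp, basis) == pytest.approx(base, rel=1e-12)


class TestDeltaPrior:
    def test_delta_squared_interval_closed_form(self):
        # log delta ~ N(0, 0.169): delta^2 in [1/5, 5] iff |log delta| <= log(5)/2
        sd = np.sqrt(0.169)
        prob = stats.norm.cdf(np.log(5) / 2, scale=sd) - stats.norm.cdf(
            -np.log(5) / 2, scale=sd
        )
        assert round(prob, 2) == 0.95

    def test_delta_squared_interval_monte_carlo(self):
        rng = np.random.default_rng(14)
        ld = rng.normal(0.0, np.sqrt(0.169), size=1_000_000)
        frac = np.mean((np.exp(2 * ld) >= 0.2) & (np.exp(2 * ld) <= 5.0))
        sd = np.sqrt(0.169)
        exact = stats.norm.cdf(np.log(5) / 2, scale=sd) - stats.norm.cdf(
            -np.log(5) / 2, scale=sd
        )
        assert frac == pytest.approx(exact, abs=3 * 0.0007)  # 3 binomial SEs
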