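import numpy as np
import pytest

from stprev.basis import build_basis
from stprev.data import PanelCounts
from stprev.graph import RegionGraph
from stprev.inference import (
    FitResult,
    MCMCConfig,
    compute_dic,
    run_mcmc,
    sensitivity_harness,
)
from stprev.models import BYMParams, ModelSpec, PriorConfig, invlogit
from stprev.simulate import bym_preset, chns_like_preset, simulate_bym, simulate_scm

TINY = MCMCConfig(n_chains=2, n_iter=400, burn_in=200, thin=3, seed=7)


@pytest.fixture(scope="module")
def small_bym_fit():
    truth = bym_preset(seed=1)
    panel, record = simulate_bym(truth)
    fit = run_mcmc(ModelSpec(kind="bym"), panel, truth.basis(), None, TINY)
    return truth, panel, record, fit


def two_region_intercept_panel():
    """Two regions, two waves, all cells sharing one prevalence: the model
    with every non-intercept block disabled reduces to a single binomial."""
    W = np.array([[0, 1], [1, 0]])
    g = RegionGraph(("a", "b"), W)
    waves = (2000, 2004)
    O = np.array([[[8, 7], [8, 7]]])  # 30 cases
    n = np.array([[[25, 25], [25, 25]]])  # of 100 trials
    return g, waves, PanelCounts(g, waves, O, n)


INTERCEPT_ONLY = ModelSpec(
    kind="bym",
    include_spatial=False,
    include_random_spline=False,
    include_fixed_spline=False,
)


class TestBookkeeping:
    def test_kept_draw_count_follows_ceiling_rule(self, small_bym_fit):
        *_, fit = small_bym_fit
        expected = int(np.ceil((TINY.n_iter - TINY.burn_in) / TINY.thin))
        assert fit.n_kept == expected
        assert fit.deviance.shape == (2, expected)
        for arr in fit.draws.values():
            assert arr.shape[:2] == (2, expected)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="burn_in"):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError, match="thin"):
            MCMCConfig(thin=0)
        with pytest.raises(ValueError, match="init"):
            MCMCConfig(init="warmstart")

    def test_sum_to_zero_constraints_on_every_kept_draw(self, small_bym_fit):
        *_, fit = small_bym_fit
        s0 = fit.draws["s0"]
        np.testing.assert_allclose(s0.sum(axis=2), 0.0, atol=1e-10)
        b = fit.draws["b_spline"]
        np.testing.assert_allclose(b.sum(axis=2), 0.0, atol=1e-10)


class TestDeterminism:
    def test_identical_seed_gives_identical_fit(self):
        truth = bym_preset(seed=2)
        panel, _ = simulate_bym(truth)
        f1 = run_mcmc(ModelSpec(kind="bym"), panel, truth.basis(), None, TINY)
        f2 = run_mcmc(ModelSpec(kind="bym"), panel, truth.basis(), None, TINY)
        np.testing.assert_array_equal(f1.deviance, f2.deviance)
        for k in f1.draws:
            np.testing.assert_array_equal(f1.draws[k], f2.draws[k])

    def test_different_seeds_differ(self):
        truth = bym_preset(seed=2)
        panel, _ = simulate_bym(truth)
        f1 = run_mcmc(ModelSpec(kind="bym"), panel, truth.basis(), None, TINY)
        from dataclasses import replace

        f2 = run_mcmc(
            ModelSpec(kind="bym"), panel, truth.basis(), None, replace(TINY, seed=8)
        )
        assert not np.array_equal(f1.deviance, f2.deviance)


class TestPosteriorCorrectness:
    def test_intercept_only_matches_quadrature(self):
        g, waves, panel = two_region_intercept_panel()
        basis = build_basis(waves)
        config = MCMCConfig(n_chains=2, n_iter=6000, burn_in=1000, thin=1, seed=3)
        fit = run_mcmc(INTERCEPT_ONLY, panel, basis, None, config)
        draws_p = invlogit(fit.stacked("alpha0"))

        # quadrature oracle: posterior of alpha0 under N(0, 1e4) prior and
        # Binomial(30 of 100) likelihood
        grid = np.linspace(-4, 3, 20_001)
        logpost = (
            -(grid**2) / (2e4) + 30 * grid - 100 * np.logaddexp(0, grid)
        )
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        mean_p = float((invlogit(grid) * w).sum())

        # Monte-Carlo SE from the chains' effective sample size
        from stprev.diagnostics import autocorrelation

        acfs = np.mean(
            [autocorrelation(c, 50) for c in fit.draws["alpha0"]], axis=0
        )
        ess = draws_p.size / max(1.0, 1 + 2 * acfs[1:].sum())
        mcse = draws_p.std() / np.sqrt(ess)
        assert abs(draws_p.mean() - mean_p) < 3 * mcse + 1e-4

    def test_bym_recovers_intercept_from_prior_predictive_data(self):
        from dataclasses import replace as rep

        truth = rep(bym_preset(seed=11), draw_hyper_from_prior=True)
        panel, record = simulate_bym(truth)
        fit = run_mcmc(
            ModelSpec(kind="bym"), panel, truth.basis(), None,
            MCMCConfig.desk_scale(seed=12),
        )
        a0 = fit.stacked("alpha0")
        lo, hi = np.quantile(a0, [0.025, 0.975])
        assert lo <= record["params"].alpha0 <= hi


class TestDic:
    def test_parameter_free_model_has_zero_pd(self):
        truth = bym_preset(seed=4)
        panel, record = simulate_bym(truth)
        basis = truth.basis()
        spec = ModelSpec(kind="bym", fixed_params=record["params"])
        fit = run_mcmc(spec, panel, basis, None, TINY)
        dbar, pd_, dic = fit.dic
        assert pd_ == pytest.approx(0.0, abs=1e-8)
        assert dic == pytest.approx(dbar, abs=1e-8)

    def test_dic_identity_holds(self, small_bym_fit):
        *_, fit = small_bym_fit
        dbar, pd_, dic = fit.dic
        assert dic == pytest.approx(dbar + pd_, rel=1e-12)

    def test_intercept_only_pd_is_about_one(self):
        g, waves, panel = two_region_intercept_panel()
        basis = build_basis(waves)
        config = MCMCConfig(n_chains=2, n_iter=6000, burn_in=1000, thin=1, seed=5)
        fit = run_mcmc(INTERCEPT_ONLY, panel, basis, None, config)
        _, pd_, _ = fit.dic
        assert pd_ == pytest.approx(1.0, abs=0.4)

    def test_extra_parameter_block_does_not_reduce_pd(self):
        truth = bym_preset(seed=6)
        panel, _ = simulate_bym(truth)
        basis = truth.basis()
        small = ModelSpec(
            kind="bym", include_spatial=False, include_random_spline=False
        )
        big = ModelSpec(kind="bym", include_random_spline=False)
        cfg = MCMCConfig(n_chains=2, n_iter=2000, burn_in=1000, thin=2, seed=6)
        pd_small = run_mcmc(small, panel, basis, None, cfg).dic[1]
        pd_big = run_mcmc(big, panel, basis, None, cfg).dic[1]
        assert pd_big >= pd_small - 0.5

    def test_empty_trace_rejected(self, small_bym_fit):
        truth, panel, _, fit = small_bym_fit
        broken = FitResult(
            model_spec=fit.model_spec,
            draws=fit.draws,
            deviance=np.empty((2, 0)),
            mcmc_config=fit.mcmc_config,
        )
        with pytest.raises(ValueError, match="empty deviance"):
            compute_dic(broken, fit.model_spec, panel, truth.basis())


@pytest.fixture(scope="module")
def harness_table():
    from dataclasses import replace

    # well-identified conditions: large totals, a strong persistent spatial
    # signal and a negligible true interaction, so the b/beta split is pinned
    # by the data rather than by the precision prior under scrutiny
    base = chns_like_preset(seed=2)
    base.params.tau_beta = 1.0e4
    base.params.tau_b = 1.0e4
    truth = replace(
        base,
        totals_range=(3000, 6000),
        random_effect_sds={"b0": 0.15, "b_gender": 0.3},
    )
    panel, _ = simulate_scm(truth)
    return sensitivity_harness(
        ModelSpec(kind="scm"), panel, truth.basis(), MCMCConfig.desk_scale(seed=3)
    )


class TestSensitivityHarness:
    def test_three_variants_all_complete_with_finite_dic(self, harness_table):
        assert sorted(harness_table.prior_variant.unique()) == [1, 2, 3]
        assert (harness_table.status == "ok").all()
        assert np.isfinite(harness_table.dic).all()
        assert np.isfinite(harness_table[["mean", "ci_lo", "ci_hi"]]).all().all()

    def test_posterior_means_robust_across_priors(self, harness_table):
        for q in ("exp_b_male", "exp_b_female", "exp_S_male", "exp_S_female"):
            m = harness_table[harness_table.quantity == q]["mean"].to_numpy()
            spread = (m.max() - m.min()) / abs(m.mean())
            assert spread < 0.10, f"{q}: {m}"

    def test_unknown_variant_rejected(self):
        truth = chns_like_preset(seed=2)
        panel, _ = simulate_scm(truth)
        with pytest.raises(ValueError, match="unknown prior variant"):
            sensitivity_harness(
                ModelSpec(kind="scm"), panel, truth.basis(), TINY, variants=(4,)
            )


def test_nonfinite_initialization_is_reported():
    g, waves, panel = two_region_intercept_panel()
    basis = build_basis(waves)
    bad = BYMParams.zeros(2, basis.K)
    bad.alpha0 = np.inf
    from stprev.sampler import BYMSampler

    with np.errstate(invalid="ignore"), pytest.raises(RuntimeError, match="initialization"):
        BYMSampler(
            panel, basis, PriorConfig(), ModelSpec(kind="bym"),
            np.random.default_rng(0), bad,
        )


def test_fit_serialization_round_trip(tmp_path, small_bym_fit):
    *_, fit = small_bym_fit
    fit.save(tmp_path / "fit")
    import json

    summary = json.loads((tmp_path / "fit" / "summary.json").read_text())
    assert summary["schema"] == "stprev-fit-v1"
    assert summary["n_kept"] == fit.n_kept
    import pandas as pd

    alpha = pd.read_csv(tmp_path / "fit" / "alpha0.csv")
    np.testing.assert_allclose(
        alpha["c0"].to_numpy().reshape(2, -1), fit.draws["alpha0"], rtol=1e-10
    )
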