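import numpy as np
import pandas as pd
import pytest

from stprev.inference import MCMCConfig, run_mcmc
from stprev.models import ModelSpec
from stprev.report import (
    compare_models,
    covariate_report,
    delta_eta_report,
    read_table,
    summarize_risk,
    write_table,
)
from stprev.simulate import bym_preset, chns_like_preset, simulate_bym, simulate_scm

CFG = MCMCConfig(n_chains=2, n_iter=1200, burn_in=600, thin=2, seed=1)


@pytest.fixture(scope="module")
def bym_fit():
    truth = bym_preset(seed=1)
    panel, _ = simulate_bym(truth)
    fit = run_mcmc(ModelSpec(kind="bym", tag="bym-full"), panel, truth.basis(), None, CFG)
    return truth, panel, fit


@pytest.fixture(scope="module")
def scm_fit():
    truth = chns_like_preset(seed=1)
    panel, _ = simulate_scm(truth)
    fit = run_mcmc(ModelSpec(kind="scm", tag="scm-full"), panel, truth.basis(), None, CFG)
    return truth, panel, fit


class TestSummarizeRisk:
    def test_row_count_is_regions_by_waves(self, bym_fit):
        truth, panel, fit = bym_fit
        risk = summarize_risk(fit, fit.model_spec, panel, truth.basis(), force=True)
        assert len(risk) == 7 * 9

    def test_scm_doubles_rows_for_sexes(self, scm_fit):
        truth, panel, fit = scm_fit
        risk = summarize_risk(fit, fit.model_spec, panel, truth.basis(), force=True)
        assert len(risk) == 2 * 7 * 9
        assert set(risk.sex) == {"m", "f"}

    def test_summaries_match_independent_quantiles(self, bym_fit):
        truth, panel, fit = bym_fit
        basis = truth.basis()
        risk = summarize_risk(fit, fit.model_spec, panel, basis, force=True)
        from stprev.models import invlogit
        from stprev.report import _eta_draws

        eta = _eta_draws(fit, panel, basis)
        p = invlogit(eta[:, 0, 2, 3])
        row = risk[(risk.region == fit.region_ids[2]) & (risk.year == fit.waves[3])]
        assert row.p_mean.iloc[0] == pytest.approx(p.mean(), rel=1e-12)
        assert row.p_lo.iloc[0] == pytest.approx(np.percentile(p, 2.5), rel=1e-9)
        assert row.p_hi.iloc[0] == pytest.approx(np.percentile(p, 97.5), rel=1e-9)

    def test_degenerate_posterior_collapses_summaries(self, bym_fit):
        truth, panel, fit = bym_fit
        import copy

        frozen = copy.copy(fit)
        frozen.draws = {
            k: np.broadcast_to(v[:1, :1], v.shape).copy() for k, v in fit.draws.items()
        }
        risk = summarize_risk(frozen, fit.model_spec, panel, truth.basis(), force=True)
        np.testing.assert_allclose(risk.p_mean, risk.p_median, rtol=1e-12)
        np.testing.assert_allclose(risk.p_mean, risk.p_lo, rtol=1e-12)
        np.testing.assert_allclose(risk.p_mean, risk.p_hi, rtol=1e-12)

    def test_prevalence_summaries_in_unit_interval(self, scm_fit):
        truth, panel, fit = scm_fit
        risk = summarize_risk(fit, fit.model_spec, panel, truth.basis(), force=True)
        for col in ("p_lo", "p_median", "p_hi", "p_mean"):
            assert ((risk[col] > 0) & (risk[col] < 1)).all()
        assert (risk.p_lo <= risk.p_median).all()
        assert (risk.p_median <= risk.p_hi).all()


class TestDeltaEtaReport:
    def test_bym_fit_rejected(self, bym_fit):
        truth, _, fit = bym_fit
        with pytest.raises(ValueError, match="delta undefined for BYM"):
            delta_eta_report(fit, truth.basis())

    def test_table_shape_and_bounds(self, scm_fit):
        truth, panel, fit = scm_fit
        tab = delta_eta_report(fit, truth.basis(), panel.X)
        assert (tab[tab.quantity == "delta"].shape[0]) == 9
        assert (tab[(tab.quantity == "eta_share") & (tab.sex == "m")].shape[0]) == 9
        eta_rows = tab[tab.quantity == "eta_share"]
        assert (eta_rows["median"] >= 0).all()
        assert (tab.lo <= tab.hi).all()

    def test_unit_delta_truth_recovered(self, scm_fit):
        # preset truth has log delta = 0 for every wave
        truth, panel, fit = scm_fit
        tab = delta_eta_report(fit, truth.basis(), panel.X)
        d = tab[tab.quantity == "delta"]
        covered = ((d.lo <= 1.0) & (1.0 <= d.hi)).sum()
        assert covered >= 8


class TestCovariateReport:
    def test_covariate_free_fit_rejected(self, bym_fit):
        _, panel, fit = bym_fit
        with pytest.raises(ValueError, match="no covariate block"):
            covariate_report(fit, panel)

    def test_zero_coefficient_maps_to_unit_odds_ratio(self, bym_fit):
        truth, panel, fit = bym_fit
        import copy

        with_cov = copy.copy(fit)
        with_cov.model_spec = ModelSpec(kind="bym", covariate_mode="constant")
        with_cov.draws = dict(fit.draws)
        with_cov.draws["beta_cov"] = np.zeros((fit.n_chains, fit.n_kept, 4))
        panel_cov, _ = simulate_bym(
            bym_preset(seed=1, with_covariates=True)
        )
        tab = covariate_report(with_cov, panel_cov)
        assert np.allclose(tab.or_mean, 1.0)
        assert len(tab) == 4

    def test_known_positive_effect_detected(self):
        # strong overweight effect baked into the truth; the posterior OR
        # should exclude 1 in nearly every replicate
        from dataclasses import replace

        from stprev.simulate import CovariateConfig

        hits = 0
        for seed in range(5):
            truth = bym_preset(seed=30 + seed, with_covariates=True)
            truth.params.beta_cov = np.array([0.0, 3.0, 0.0, 0.0])
            truth = replace(truth, covariates=CovariateConfig(cell_sd=0.05))
            panel, _ = simulate_bym(truth)
            fit = run_mcmc(
                ModelSpec(kind="bym", covariate_mode="constant"),
                panel, truth.basis(), None, CFG,
            )
            tab = covariate_report(fit, panel)
            row = tab[tab.covariate == "overweight"].iloc[0]
            hits += (row.or_lo > 1.0) and (row.or_mean > 1.0)
        assert hits >= 4

    def test_time_varying_mode_emits_one_row_per_wave(self):
        truth = bym_preset(seed=40, with_covariates=True)
        truth.params.beta_cov = np.zeros((4, truth.basis().K))
        panel, _ = simulate_bym(truth)
        fit = run_mcmc(
            ModelSpec(kind="bym", covariate_mode="time_varying"),
            panel, truth.basis(), None, CFG,
        )
        tab = covariate_report(fit, panel, truth.basis())
        assert len(tab) == 4 * 9


class TestCompareModels:
    def test_sorted_by_dic(self, bym_fit):
        truth, panel, fit = bym_fit
        import copy

        better = copy.copy(fit)
        better.model_spec = ModelSpec(kind="bym", tag="better")
        better.dic = (fit.dic[0] - 10, fit.dic[1], fit.dic[2] - 10)
        tab = compare_models([fit, better])
        assert tab.model.tolist()[0] == "better"
        assert tab.DIC.is_monotonic_increasing

    def test_single_fit_allowed(self, bym_fit):
        *_, fit = bym_fit
        assert len(compare_models([fit])) == 1

    def test_different_data_rejected(self, bym_fit):
        *_, fit = bym_fit
        import copy

        other = copy.copy(fit)
        other.data_fingerprint = "deadbeef"
        with pytest.raises(ValueError, match="not on the same data"):
            compare_models([fit, other])


def test_csv_round_trip_at_twelve_significant_digits(tmp_path, scm_fit):
    truth, panel, fit = scm_fit
    tab = delta_eta_report(fit, truth.basis(), panel.X)
    f = tmp_path / "tab.csv"
    write_table(tab, f)
    back = read_table(f)
    assert list(back.columns) == list(tab.columns)
    for col in ("median", "lo", "hi"):
        np.testing.assert_allclose(back[col], tab[col], rtol=1e-11)
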