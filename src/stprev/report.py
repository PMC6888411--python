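"""Posterior post-processing: risk surfaces, shared-weight series, variance
shares, covariate odds ratios, and DIC model comparison tables.

All tables are pandas DataFrames whose CSV exports round-trip exactly at 12
significant digits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import SplineBasis
from .data import PanelCounts
from .diagnostics import gelman_rubin
from .inference import FitResult
from .models import (
    BYMParams,
    ModelSpec,
    SCMParams,
    bym_linear_predictor,
    invlogit,
    scm_linear_predictor,
    variance_share,
)

__all__ = [
    "summarize_risk",
    "delta_eta_report",
    "covariate_report",
    "compare_models",
    "write_table",
    "read_table",
]

FLOAT_FMT = "%.12g"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _eta_draws(fit: FitResult, data: PanelCounts, basis: SplineBasis) -> np.ndarray:
    """Linear-predictor draws: (pooled draws, n_sexes, N, T)."""
    d = fit.draws
    n_draws = fit.n_chains * fit.n_kept
    if fit.model_spec.kind == "bym":
        out = np.empty((n_draws, 1, len(fit.region_ids), len(fit.waves)))
        for idx in range(n_draws):
            p = BYMParams(
                alpha0=float(fit.stacked("alpha0")[idx]),
                a=fit.stacked("a")[idx],
                u0=fit.stacked("u0")[idx],
                s0=fit.stacked("s0")[idx],
                b_spline=fit.stacked("b_spline")[idx],
                tau_u=1.0,
                tau_s=1.0,
                Gamma=np.eye(basis.K),
                beta_cov=None if "beta_cov" not in d else fit.stacked("beta_cov")[idx],
            )
            out[idx, 0] = bym_linear_predictor(p, basis, data.X)
        return out
    out = np.empty((n_draws, 2, len(fit.region_ids), len(fit.waves)))
    for idx in range(n_draws):
        p = SCMParams(
            alpha=fit.stacked("alpha")[idx],
            b0=fit.stacked("b0")[idx],
            b_shared_spline=fit.stacked("b_shared_spline")[idx],
            a_gender=fit.stacked("a_gender")[idx],
            b_gender=fit.stacked("b_gender")[idx],
            beta_gender_spline=fit.stacked("beta_gender_spline")[idx],
            beta_it=fit.stacked("beta_it")[idx],
            log_delta=fit.stacked("log_delta")[idx],
            tau_beta=1.0,
            tau_b=1.0,
            Gamma_b=np.eye(basis.K),
            beta_cov=None if "beta_cov" not in d else fit.stacked("beta_cov")[idx],
        )
        out[idx] = scm_linear_predictor(p, basis, data.X)
    return out


def convergence_gate(fit: FitResult, data: PanelCounts, basis: SplineBasis,
                     threshold: float = 1.1) -> tuple[bool, list[tuple[str, float]]]:
    """R-hat check on the reported quantities (prevalence cells + deviance).

    The intercept and the vague iid spatial blocks are deliberately
    near-unidentified in these models (only their sum enters the
    likelihood), so the gate monitors the identified surfaces the reports
    are built from rather than raw blocks.
    """
    eta = _eta_draws(fit, data, basis)
    n_sex = eta.shape[1]
    eta_c = eta.reshape(fit.n_chains, fit.n_kept, -1)
    worst: list[tuple[str, float]] = []
    names_sex = ("all",) if n_sex == 1 else ("m", "f")
    flat_names = [
        f"p[{s},{r},{w}]"
        for s in names_sex
        for r in fit.region_ids
        for w in fit.waves
    ]
    for i, name in enumerate(flat_names):
        r = gelman_rubin(eta_c[:, :, i])
        if r >= threshold:
            worst.append((name, r))
    r_dev = gelman_rubin(fit.deviance)
    if r_dev >= threshold:
        worst.append(("deviance", r_dev))
    worst.sort(key=lambda kv: -kv[1])
    return (len(worst) == 0), worst


def summarize_risk(
    fit: FitResult,
    model_spec: ModelSpec,
    data: PanelCounts,
    basis: SplineBasis,
    force: bool = False,
    rhat_threshold: float = 1.1,
) -> pd.DataFrame:
    """Posterior summaries of prevalence and of the relative-scale effect.

    One row per region x wave (x sex): mean, median and central 95%
    interval of the prevalence p and of exp(eta - alpha) (the relative
    risk-style scale on which area effects are usually mapped).  Unless
    ``force`` is set, an unconverged fit (R-hat over the threshold on the
    reported surfaces) raises, listing the worst offenders.
    """
    ok, worst = convergence_gate(fit, data, basis, rhat_threshold)
    if not ok and not force:
        top = ", ".join(f"{n}: {v:.3f}" for n, v in worst[:5])
        raise RuntimeError(
            f"fit not converged (R-hat >= {rhat_threshold}); worst: {top}; "
            "pass force=True to summarise anyway"
        )
    eta = _eta_draws(fit, data, basis)
    prev = invlogit(eta)
    if fit.model_spec.kind == "bym":
        alpha = fit.stacked("alpha0").reshape(-1, 1, 1, 1)
    else:
        alpha = fit.stacked("alpha").reshape(-1, 2, 1, 1)
    rel = np.exp(eta - alpha)

    names_sex = ("all",) if eta.shape[1] == 1 else ("m", "f")
    rows = []
    for s, sex in enumerate(names_sex):
        for i, region in enumerate(fit.region_ids):
            for t, wave in enumerate(fit.waves):
                pd_, rd = prev[:, s, i, t], rel[:, s, i, t]
                rows.append(
                    {
                        "model": model_spec.label(),
                        "sex": sex,
                        "region": region,
                        "year": wave,
                        "p_mean": pd_.mean(),
                        "p_median": np.median(pd_),
                        "p_lo": np.quantile(pd_, 0.025),
                        "p_hi": np.quantile(pd_, 0.975),
                        "rel_mean": rd.mean(),
                        "rel_median": np.median(rd),
                        "rel_lo": np.quantile(rd, 0.025),
                        "rel_hi": np.quantile(rd, 0.975),
                    }
                )
    return pd.DataFrame(rows)


def delta_eta_report(fit: FitResult, basis: SplineBasis,
                     X: np.ndarray | None = None) -> pd.DataFrame:
    """Per-wave summaries of the shared weight delta_t and variance shares.

    delta_t rows report the posterior median and central 95% interval of
    exp(log delta_t); eta rows the same for the share of predictor
    variance carried by the weighted shared component, per sex.  Shares
    above 1 (possible only through anticorrelation of shared and
    sex-specific terms) are counted in ``flagged_gt1``.
    """
    if fit.model_spec.kind != "scm":
        raise ValueError("delta undefined for BYM fits; need a shared-component fit")
    ld = fit.stacked("log_delta")  # (draws, T)
    n_draws = ld.shape[0]
    T = ld.shape[1]
    shares = np.empty((n_draws, 2, T))
    for idx in range(n_draws):
        p = SCMParams(
            alpha=fit.stacked("alpha")[idx],
            b0=fit.stacked("b0")[idx],
            b_shared_spline=fit.stacked("b_shared_spline")[idx],
            a_gender=fit.stacked("a_gender")[idx],
            b_gender=fit.stacked("b_gender")[idx],
            beta_gender_spline=fit.stacked("beta_gender_spline")[idx],
            beta_it=fit.stacked("beta_it")[idx],
            log_delta=ld[idx],
            tau_beta=1.0,
            tau_b=1.0,
            Gamma_b=np.eye(basis.K),
            beta_cov=None if "beta_cov" not in fit.draws else fit.stacked("beta_cov")[idx],
        )
        shares[idx] = variance_share(p, basis, X)
    delta = np.exp(ld)
    rows = []
    for t, wave in enumerate(fit.waves):
        rows.append(
            {
                "quantity": "delta",
                "sex": "both",
                "year": wave,
                "median": np.median(delta[:, t]),
                "lo": np.quantile(delta[:, t], 0.025),
                "hi": np.quantile(delta[:, t], 0.975),
                "flagged_gt1": 0,
            }
        )
    for j, sex in enumerate(("m", "f")):
        for t, wave in enumerate(fit.waves):
            sh = shares[:, j, t]
            rows.append(
                {
                    "quantity": "eta_share",
                    "sex": sex,
                    "year": wave,
                    "median": np.median(sh),
                    "lo": np.quantile(sh, 0.025),
                    "hi": np.quantile(sh, 0.975),
                    "flagged_gt1": int((sh > 1).sum()),
                }
            )
    return pd.DataFrame(rows)


def covariate_report(fit: FitResult, data: PanelCounts,
                     basis: SplineBasis | None = None) -> pd.DataFrame:
    """Odds-ratio-scale posterior summaries per covariate.

    Constant-effect fits give one row per covariate (per sex for the
    shared-component model); time-varying fits expand the spline
    coefficients to one row per covariate and wave.  A coefficient frozen
    at 0 maps to an odds ratio of exactly 1.
    """
    if "beta_cov" not in fit.draws:
        raise ValueError("fit has no covariate block; refit with covariates enabled")
    bc = fit.stacked("beta_cov")  # bym: (draws, C[, K]); scm: (draws, 2, C[, K])
    names = data.covariate_names
    scm = fit.model_spec.kind == "scm"
    sexes = ("m", "f") if scm else ("all",)
    time_varying = fit.model_spec.covariate_mode == "time_varying"
    rows = []
    for s, sex in enumerate(sexes):
        coef = bc[:, s] if scm else bc
        for c, name in enumerate(names):
            if not time_varying:
                draws = np.exp(coef[:, c])
                rows.append(
                    {
                        "covariate": name,
                        "sex": sex,
                        "year": "all",
                        "or_mean": draws.mean(),
                        "or_lo": np.quantile(draws, 0.025),
                        "or_hi": np.quantile(draws, 0.975),
                    }
                )
            else:
                if basis is None:
                    raise ValueError("time-varying covariate report needs the basis")
                eff = coef[:, c, :] @ basis.B.T  # (draws, T)
                for t, wave in enumerate(fit.waves):
                    draws = np.exp(eff[:, t])
                    rows.append(
                        {
                            "covariate": name,
                            "sex": sex,
                            "year": wave,
                            "or_mean": draws.mean(),
                            "or_lo": np.quantile(draws, 0.025),
                            "or_hi": np.quantile(draws, 0.975),
                        }
                    )
    return pd.DataFrame(rows)


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits of the same data by DIC (ascending)."""
    if not fits:
        raise ValueError("need at least one fit")
    fps = {f.data_fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError(
            f"fits are not on the same data (fingerprints {sorted(fps)}); "
            "DIC comparison is only meaningful on identical data"
        )
    rows = []
    for f in fits:
        dbar, pd_, dic = f.dic
        rows.append(
            {"model": f.model_spec.label(), "Dbar": dbar, "pD": pd_, "DIC": dic}
        )
    return pd.DataFrame(rows).sort_values("DIC", ignore_index=True)
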