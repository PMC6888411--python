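"""Synthetic prevalence panels with known latent truth.

The real survey microdata behind the motivating study are access-restricted,
so every stage of this package is exercised on panels generated from the
models themselves: fixed temporal trends plus spatial/spline random effects
drawn from their priors (or frozen at supplied values), binomial sampling
of cases, and optional regional covariates with linear drifts.

``chns_like_preset`` mimics the published survey's structure: the seven
study provinces with their contiguity pattern, the nine 1991-2015 waves,
per-cell totals of a few hundred to ~1,500, and a pooled prevalence rising
from roughly 0.11 to 0.35 with males above females.  Its latent parameter
values are synthetic inventions tuned only to those pooled anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .basis import SplineBasis, build_basis
from .data import COVARIATE_NAMES, PanelCounts
from .graph import RegionGraph, study7_graph
from .models import BYMParams, SCMParams, invlogit, logit, variance_share

__all__ = [
    "TruthConfig",
    "CovariateConfig",
    "simulate_bym",
    "simulate_scm",
    "chns_like_preset",
    "sample_icar",
    "sample_mcar",
    "sample_wishart",
    "STUDY_WAVES",
]

STUDY_WAVES = (1991, 1993, 1997, 2000, 2004, 2006, 2009, 2011, 2015)


# -- random-effect samplers (also used for prior-draw initialisation) --------


def _icar_modes(graph: RegionGraph) -> tuple[np.ndarray, np.ndarray]:
    lam, V = np.linalg.eigh(graph.laplacian.astype(float))
    keep = lam > 1e-9
    return lam[keep], V[:, keep]


def sample_icar(rng: np.random.Generator, graph: RegionGraph, tau: float) -> np.ndarray:
    """Draw from the intrinsic CAR on the sum-to-zero subspace."""
    lam, V = _icar_modes(graph)
    z = rng.standard_normal(lam.size)
    return V @ (z / np.sqrt(tau * lam))


def sample_mcar(
    rng: np.random.Generator, graph: RegionGraph, Gamma: np.ndarray
) -> np.ndarray:
    """Draw an (N, K) matrix from the intrinsic MCAR with precision (D-W) (x) Gamma."""
    lam, V = _icar_modes(graph)
    K = Gamma.shape[0]
    cov_chol = np.linalg.cholesky(np.linalg.inv(Gamma))
    Z = rng.standard_normal((lam.size, K))
    return V @ (Z / np.sqrt(lam)[:, None]) @ cov_chol.T


def sample_wishart(rng: np.random.Generator, V: np.ndarray, df: int) -> np.ndarray:
    from scipy import stats

    return np.atleast_2d(stats.wishart.rvs(df=df, scale=V, random_state=rng))


# -- configuration -----------------------------------------------------------


@dataclass(frozen=True)
class CovariateConfig:
    """Linear-drift generator for the four regional covariates.

    Each covariate c in region i follows baseline_i(c) + drift(c) * u(t)
    with u scaled to [0, 1] over the study period, plus a little regional
    scatter; values are clipped to [0.01, 0.99].
    """

    baselines: dict[str, float] = field(
        default_factory=lambda: {
            "age60plus": 0.12,
            "overweight": 0.20,
            "ever_smoker": 0.30,
            "drinker": 0.25,
        }
    )
    drifts: dict[str, float] = field(
        default_factory=lambda: {
            "age60plus": 0.10,
            "overweight": 0.18,
            "ever_smoker": -0.05,
            "drinker": 0.03,
        }
    )
    regional_sd: float = 0.03
    cell_sd: float = 0.01  # wave-to-wave sampling wiggle within a region


@dataclass(frozen=True)
class TruthConfig:
    """Ground truth for one synthetic panel.

    ``params`` supplies the fixed-effect blocks and the precisions; when
    ``draw_random_effects`` is set, the spatial/spline/interaction blocks
    are redrawn from their priors at those precisions (seed-deterministic),
    otherwise the blocks in ``params`` are used verbatim.
    """

    kind: Literal["bym", "scm"]
    params: BYMParams | SCMParams
    graph: RegionGraph = field(default_factory=study7_graph)
    waves: tuple[int, ...] = STUDY_WAVES
    center_year: int = 2004
    interior_knots: tuple[float, ...] = (0.0,)
    totals_range: tuple[int, int] = (200, 1500)
    totals: np.ndarray | None = None  # explicit (n_sexes, N, T) totals
    draw_random_effects: bool = False
    draw_hyper_from_prior: bool = False  # precisions from their own priors
    random_effect_sds: dict[str, float] = field(default_factory=dict)
    covariates: CovariateConfig | None = None
    seed: int = 0

    def basis(self) -> SplineBasis:
        return build_basis(self.waves, self.interior_knots, self.center_year)

    def validate(self) -> None:
        if self.totals is not None and np.any(np.asarray(self.totals) < 1):
            raise ValueError("totals must be >= 1")
        lo, hi = self.totals_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid totals_range")


def _gen_totals(truth: TruthConfig, rng, n_sexes: int) -> np.ndarray:
    N, T = truth.graph.n_regions, len(truth.waves)
    if truth.totals is not None:
        return np.asarray(truth.totals, dtype=np.int64)
    lo, hi = truth.totals_range
    return rng.integers(lo, hi + 1, size=(n_sexes, N, T))


def _gen_covariates(truth: TruthConfig, rng) -> np.ndarray | None:
    cfg = truth.covariates
    if cfg is None:
        return None
    N, T = truth.graph.n_regions, len(truth.waves)
    u = (np.asarray(truth.waves) - truth.waves[0]) / (truth.waves[-1] - truth.waves[0])
    X = np.empty((N, T, len(COVARIATE_NAMES)))
    for c, name in enumerate(COVARIATE_NAMES):
        base = cfg.baselines[name] + cfg.regional_sd * rng.standard_normal(N)
        X[:, :, c] = (
            base[:, None]
            + cfg.drifts[name] * u[None, :]
            + cfg.cell_sd * rng.standard_normal((N, T))
        )
    return np.clip(X, 0.01, 0.99)


def _sd(truth: TruthConfig, key: str, default: float) -> float:
    return truth.random_effect_sds.get(key, default)


# -- generators --------------------------------------------------------------


def simulate_bym(truth: TruthConfig) -> tuple[PanelCounts, dict]:
    """Generate a single-outcome panel from the BYM structure.

    Returns the panel and a latent-truth record holding the realised
    parameters and the true prevalence surface.
    """
    truth.validate()
    if truth.kind != "bym":
        raise ValueError("truth.kind must be 'bym'")
    rng = np.random.default_rng(truth.seed)
    basis = truth.basis()
    graph = truth.graph
    p = truth.params.copy()
    if truth.draw_hyper_from_prior:
        from .models import PriorConfig

        pr = PriorConfig()
        p.tau_u = float(rng.gamma(pr.tau_gamma_shape, 1.0 / pr.tau_gamma_rate))
        p.tau_s = float(rng.gamma(pr.tau_gamma_shape, 1.0 / pr.tau_gamma_rate))
        p.Gamma = sample_wishart(rng, *pr.wishart(basis.K))
    if truth.draw_random_effects:
        p.u0 = rng.standard_normal(graph.n_regions) / np.sqrt(p.tau_u)
        p.s0 = sample_icar(rng, graph, p.tau_s)
        p.b_spline = sample_mcar(rng, graph, p.Gamma)
    X = _gen_covariates(truth, rng)
    from .models import bym_linear_predictor

    eta = bym_linear_predictor(p, basis, X)
    prob = invlogit(eta)
    n = _gen_totals(truth, rng, 1)
    O = rng.binomial(n[0], prob)[None, :, :]
    panel = PanelCounts(
        graph, truth.waves, O, n,
        X=X, covariate_names=COVARIATE_NAMES if X is not None else (),
    )
    record = {"params": p, "prevalence": prob, "eta": eta, "basis": basis}
    return panel, record


def simulate_scm(truth: TruthConfig) -> tuple[PanelCounts, dict]:
    """Generate a two-sex panel from the shared-component structure.

    The latent record additionally carries the true weights delta_t and the
    true variance shares eta_j(t) computed from the latent surfaces.
    """
    truth.validate()
    if truth.kind != "scm":
        raise ValueError("truth.kind must be 'scm'")
    rng = np.random.default_rng(truth.seed)
    basis = truth.basis()
    graph = truth.graph
    N, T = graph.n_regions, len(truth.waves)
    p = truth.params.copy()
    if truth.draw_hyper_from_prior:
        from .models import PriorConfig

        pr = PriorConfig()
        p.tau_beta = float(rng.gamma(pr.tau_gamma_shape, 1.0 / pr.tau_gamma_rate))
        p.tau_b = float(rng.gamma(pr.tau_gamma_shape, 1.0 / pr.tau_gamma_rate))
        p.Gamma_b = sample_wishart(rng, *pr.wishart(basis.K))
    if truth.draw_random_effects:
        p.b0 = _sd(truth, "b0", 0.15) * rng.standard_normal(N)
        p.b_gender = _sd(truth, "b_gender", 0.10) * rng.standard_normal((2, N))
        p.b_shared_spline = sample_mcar(rng, graph, p.Gamma_b)
        for j in range(2):
            for k in range(basis.K):
                p.beta_gender_spline[j, :, k] = sample_icar(rng, graph, p.tau_b)
        for t in range(T):
            p.beta_it[:, t] = sample_icar(rng, graph, p.tau_beta)
    X = _gen_covariates(truth, rng)
    from .models import scm_linear_predictor

    eta = scm_linear_predictor(p, basis, X)
    prob = invlogit(eta)
    n = _gen_totals(truth, rng, 2)
    O = rng.binomial(n, prob)
    panel = PanelCounts(
        graph, truth.waves, O, n,
        X=X, covariate_names=COVARIATE_NAMES if X is not None else (),
    )
    record = {
        "params": p,
        "prevalence": prob,
        "eta": eta,
        "basis": basis,
        "delta": p.delta.copy(),
        "variance_share": variance_share(p, basis, X),
    }
    return panel, record


# -- the survey-like preset --------------------------------------------------


def _anchor_trend(p0: float, p1: float, t_values: np.ndarray) -> np.ndarray:
    """Logit-scale trend through the printed prevalence anchors.

    Linear interpolation on the logit scale between the first and last
    waves, with mild convexity so the rise steepens in the later waves (as
    the survey's descriptive trend does).
    """
    u = (t_values - t_values[0]) / (t_values[-1] - t_values[0])
    curve = u + 0.35 * u * (u - 1.0)  # still 0 at u=0 and 1 at u=1
    return logit(p0) + (logit(p1) - logit(p0)) * curve


def chns_like_preset(
    seed: int = 0, with_covariates: bool = False, interior_knots: tuple[float, ...] = (0.0,)
) -> TruthConfig:
    """Synthetic truth emulating the study panel's shape and pooled trend.

    Male prevalence rises roughly 0.13 -> 0.38 and female 0.11 -> 0.31
    over 1991-2015, on the seven-province contiguity graph with totals of a
    few hundred to ~1,500 per region-wave cell.  Latent spatial and
    interaction effects are drawn from their priors at moderate scales
    (spatial sd ~ 0.15, interaction sd ~ 0.1); shared weights are delta_t = 1.
    """
    graph = study7_graph()
    basis = build_basis(STUDY_WAVES, interior_knots, 2004)
    K, T, N = basis.K, basis.n_waves, graph.n_regions
    anchors = [(0.128, 0.381), (0.108, 0.315)]  # (1991, 2015) by sex
    params = SCMParams.zeros(N, K, T)
    design = np.column_stack([np.ones(T), basis.B])
    for j, (p0, p1) in enumerate(anchors):
        target = _anchor_trend(p0, p1, basis.t_values)
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        params.alpha[j] = coef[0]
        params.a_gender[j] = coef[1:]
    params.tau_beta = 100.0  # interaction sd 0.1
    params.tau_b = 400.0  # sex-specific spline sd 0.05
    params.Gamma_b = np.eye(K) * 100.0  # shared spline sd ~ 0.1
    return TruthConfig(
        kind="scm",
        params=params,
        graph=graph,
        waves=STUDY_WAVES,
        interior_knots=tuple(interior_knots),
        totals_range=(200, 1500),
        draw_random_effects=True,
        random_effect_sds={"b0": 0.15, "b_gender": 0.10},
        covariates=CovariateConfig() if with_covariates else None,
        seed=seed,
    )


def bym_preset(seed: int = 0, sex: int = 0, **kw) -> TruthConfig:
    """Single-outcome analogue of :func:`chns_like_preset` (one sex's trend)."""
    scm = chns_like_preset(seed=seed, **kw)
    basis = scm.basis()
    params = BYMParams.zeros(scm.graph.n_regions, basis.K)
    params.alpha0 = float(scm.params.alpha[sex])
    params.a = scm.params.a_gender[sex].copy()
    params.tau_u = 1.0 / 0.1**2
    params.tau_s = 1.0 / 0.15**2
    params.Gamma = np.eye(basis.K) * 100.0
    return replace(scm, kind="bym", params=params)
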