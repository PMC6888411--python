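"""Spatio-temporal areal prevalence models: BYM and shared-component.

Both models are binomial-logit models on a region x wave grid.

*BYM (single outcome).*  With convolution random effects and B-spline
temporal trends::

    O_it ~ Binomial(n_it, p_it)
    logit(p_it) = alpha0 + S0(t) + b_i0 + RS_i(t)          b_i0 = u_i0 + s_i0
    S0(t)  = sum_k a_k B_k(t)        (fixed global trend)
    RS_i(t) = sum_k b_ik B_k(t)      (random local trends)

``u`` is i.i.d. Gaussian (precision tau_u), ``s`` intrinsic CAR (precision
tau_s), and the rows of the random spline coefficient matrix ``b`` carry an
intrinsic multivariate CAR with precision ``(D - W) (x) Gamma``.

*Shared-component (two outcomes, j = 1 male, j = 2 female).*  A shared
spatial/spatio-temporal surface is split between the sexes by time-varying
weights ``delta_t`` and ``1/delta_t`` (log weights sum to zero by
construction), on top of sex-specific temporal, spatial and spatio-temporal
terms and a space-time interaction ``beta_it``::

    logit(p_1it) = alpha_1 + (b0_i + RS0_i(t)) * delta_t + S_1(t) + b_1i + RS_1i(t) + beta_it
    logit(p_2it) = alpha_2 + (b0_i + RS0_i(t)) / delta_t + S_2(t) + b_2i + RS_2i(t) + beta_it

The variance share ``eta_j(t)`` is the variance across regions of the
weighted shared term divided by the variance of the full predictor
(intercept excluded, which is constant over regions).

Optional regional covariates (proportions) enter the predictor linearly;
in ``time_varying`` mode each covariate coefficient is expanded in the
fixed spline basis so its effect can drift over the study period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.special import gammaln

from .basis import SplineBasis
from .data import PanelCounts
from .graph import RegionGraph

__all__ = [
    "ModelSpec",
    "PriorConfig",
    "BYMParams",
    "SCMParams",
    "bym_linear_predictor",
    "scm_linear_predictor",
    "variance_share",
    "log_icar",
    "log_mcar",
    "log_joint_bym",
    "log_joint_scm",
    "binom_loglik",
    "invlogit",
    "logit",
]

CovariateMode = Literal["constant", "time_varying"]
SensitivityVariant = Literal["gamma_prec", "unif_sd", "halfnormal_var"]


def invlogit(x: np.ndarray) -> np.ndarray:
    """Numerically safe inverse logit."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Which model to build and which optional blocks it carries.

    ``include_spatial``/``include_random_spline`` exist to express
    deliberately under-specified comparison models; the full model keeps
    both on.  ``fixed_params`` freezes every parameter at the given values
    (no free parameters; used for degenerate DIC checks).
    """

    kind: Literal["bym", "scm"]
    covariate_mode: CovariateMode | None = None
    include_spatial: bool = True
    include_random_spline: bool = True
    include_interaction: bool = True  # SCM beta_it
    include_fixed_spline: bool = True  # intercept-only when False
    tag: str = ""
    fixed_params: "BYMParams | SCMParams | None" = None

    def label(self) -> str:
        return self.tag or self.kind


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of every prior in the two models.

    Defaults: N(0, 1e4) (variance) on fixed effects and on the iid spatial
    blocks of the shared-component model; gamma(5, 5e-4) shape-rate on
    precisions; Wishart(identity scale, df = K) on the spline-coefficient
    precision; N(0, 0.169) (variance) on log delta_t, which puts delta^2 in
    [1/5, 5] with 95% prior probability.  ``sensitivity_variant`` switches
    the prior of the structured-interaction precision (tau_s for BYM,
    tau_beta for the shared-component model) between the three variants of
    the sensitivity analysis.
    """

    fixed_effect_var: float = 1.0e4
    tau_gamma_shape: float = 5.0
    tau_gamma_rate: float = 5.0e-4
    log_delta_var: float = 0.169
    wishart_R: np.ndarray | None = None  # K x K; identity when None
    wishart_df: int | None = None  # defaults to K
    sensitivity_variant: SensitivityVariant = "gamma_prec"
    unif_sd_upper: float = 1.0
    halfnormal_var_scale: float = 10.0  # sd of the half-normal on sigma^2

    def __post_init__(self) -> None:
        for name in (
            "fixed_effect_var",
            "tau_gamma_shape",
            "tau_gamma_rate",
            "log_delta_var",
            "unif_sd_upper",
            "halfnormal_var_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sensitivity_variant not in (
            "gamma_prec",
            "unif_sd",
            "halfnormal_var",
        ):
            raise ValueError(
                f"unknown sensitivity_variant {self.sensitivity_variant!r}"
            )

    def wishart(self, K: int) -> tuple[np.ndarray, int]:
        R = np.eye(K) if self.wishart_R is None else np.asarray(self.wishart_R, float)
        if R.shape != (K, K):
            raise ValueError(f"wishart_R must be {K}x{K}")
        df = K if self.wishart_df is None else int(self.wishart_df)
        if df < K:
            raise ValueError("wishart_df must be >= K")
        return R, df

    def structured_tau_logprior(self, tau: float) -> float:
        """Log prior density of the structured-interaction precision.

        Expressed on the tau scale with the exact change of variables from
        the variant's native parameterisation (sigma or sigma^2).
        """
        if tau <= 0:
            return -np.inf
        if self.sensitivity_variant == "gamma_prec":
            a, r = self.tau_gamma_shape, self.tau_gamma_rate
            return (a - 1.0) * np.log(tau) - r * tau
        if self.sensitivity_variant == "unif_sd":
            # sigma = tau^{-1/2} ~ U(0, upper)  =>  tau > upper^{-2}
            if tau < self.unif_sd_upper ** -2:
                return -np.inf
            return -1.5 * np.log(tau)  # |d sigma / d tau| up to constants
        # halfnormal_var: sigma^2 ~ N(0, scale^2) truncated to (0, inf)
        v = 1.0 / tau
        return -(v * v) / (2.0 * self.halfnormal_var_scale ** 2) - 2.0 * np.log(tau)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


def _zeros(*shape: int) -> np.ndarray:
    return np.zeros(shape, dtype=float)


@dataclass
class BYMParams:
    """Parameter state of the spatio-temporal BYM model (single outcome)."""

    alpha0: float
    a: np.ndarray  # (K,) fixed spline coefficients
    u0: np.ndarray  # (N,) unstructured spatial effects
    s0: np.ndarray  # (N,) ICAR spatial effects
    b_spline: np.ndarray  # (N, K) random spline coefficients (MCAR rows)
    tau_u: float
    tau_s: float
    Gamma: np.ndarray  # (K, K) SPD precision of the MCAR
    beta_cov: np.ndarray | None = None  # (C,) or (C, K) in time-varying mode

    @classmethod
    def zeros(
        cls, N: int, K: int, n_cov: int = 0, covariate_mode: CovariateMode | None = None
    ) -> "BYMParams":
        beta = None
        if n_cov:
            beta = _zeros(n_cov) if covariate_mode != "time_varying" else _zeros(n_cov, K)
        return cls(
            alpha0=0.0,
            a=_zeros(K),
            u0=_zeros(N),
            s0=_zeros(N),
            b_spline=_zeros(N, K),
            tau_u=1.0,
            tau_s=1.0,
            Gamma=np.eye(K),
            beta_cov=beta,
        )

    def copy(self) -> "BYMParams":
        return replace(
            self,
            a=self.a.copy(),
            u0=self.u0.copy(),
            s0=self.s0.copy(),
            b_spline=self.b_spline.copy(),
            Gamma=self.Gamma.copy(),
            beta_cov=None if self.beta_cov is None else self.beta_cov.copy(),
        )


@dataclass
class SCMParams:
    """Parameter state of the spatio-temporal shared-component model."""

    alpha: np.ndarray  # (2,) sex intercepts
    b0: np.ndarray  # (N,) shared spatial effects (iid normal prior)
    b_shared_spline: np.ndarray  # (N, K) shared random spline coeffs (MCAR)
    a_gender: np.ndarray  # (2, K) fixed spline coefficients per sex
    b_gender: np.ndarray  # (2, N) sex-specific spatial effects (iid normal)
    beta_gender_spline: np.ndarray  # (2, N, K) sex-specific random spline (CAR/col)
    beta_it: np.ndarray  # (N, T) space-time interaction (CAR per wave)
    log_delta: np.ndarray  # (T,) log shared-component weights
    tau_beta: float
    tau_b: float
    Gamma_b: np.ndarray  # (K, K)
    beta_cov: np.ndarray | None = None  # (2, C) or (2, C, K)

    @classmethod
    def zeros(
        cls,
        N: int,
        K: int,
        T: int,
        n_cov: int = 0,
        covariate_mode: CovariateMode | None = None,
    ) -> "SCMParams":
        beta = None
        if n_cov:
            beta = (
                _zeros(2, n_cov)
                if covariate_mode != "time_varying"
                else _zeros(2, n_cov, K)
            )
        return cls(
            alpha=_zeros(2),
            b0=_zeros(N),
            b_shared_spline=_zeros(N, K),
            a_gender=_zeros(2, K),
            b_gender=_zeros(2, N),
            beta_gender_spline=_zeros(2, N, K),
            beta_it=_zeros(N, T),
            log_delta=_zeros(T),
            tau_beta=1.0,
            tau_b=1.0,
            Gamma_b=np.eye(K),
            beta_cov=beta,
        )

    def copy(self) -> "SCMParams":
        return replace(
            self,
            alpha=self.alpha.copy(),
            b0=self.b0.copy(),
            b_shared_spline=self.b_shared_spline.copy(),
            a_gender=self.a_gender.copy(),
            b_gender=self.b_gender.copy(),
            beta_gender_spline=self.beta_gender_spline.copy(),
            beta_it=self.beta_it.copy(),
            log_delta=self.log_delta.copy(),
            Gamma_b=self.Gamma_b.copy(),
            beta_cov=None if self.beta_cov is None else self.beta_cov.copy(),
        )

    @property
    def delta(self) -> np.ndarray:
        return np.exp(self.log_delta)

    def shared_surface(self, basis: SplineBasis) -> np.ndarray:
        """Unweighted shared term ``b0_i + RS0_i(t)`` as an (N, T) array."""
        return self.b0[:, None] + self.b_shared_spline @ basis.B.T


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------


def _covariate_term(
    beta_cov: np.ndarray, X: np.ndarray, basis: SplineBasis
) -> np.ndarray:
    """(N, T) covariate contribution for one outcome.

    ``beta_cov`` is (C,) for constant effects or (C, K) for time-varying
    effects b_c(t) = sum_k beta_ck B_k(t).
    """
    if beta_cov.ndim == 1:
        return np.einsum("itc,c->it", X, beta_cov)
    coef_t = basis.B @ beta_cov.T  # (T, C)
    return np.einsum("itc,tc->it", X, coef_t)


def bym_linear_predictor(
    params: BYMParams, basis: SplineBasis, X: np.ndarray | None = None
) -> np.ndarray:
    """(N, T) matrix of logit prevalences under the BYM model."""
    K = basis.K
    if params.a.shape != (K,):
        raise ValueError(f"a has shape {params.a.shape}, expected ({K},) [spline axis]")
    N = params.u0.shape[0]
    if params.s0.shape != (N,):
        raise ValueError(f"s0 has shape {params.s0.shape}, expected ({N},) [region axis]")
    if params.b_spline.shape != (N, K):
        raise ValueError(
            f"b_spline has shape {params.b_spline.shape}, expected ({N}, {K}) "
            "[region x spline axes]"
        )
    eta = (
        params.alpha0
        + (basis.B @ params.a)[None, :]
        + (params.u0 + params.s0)[:, None]
        + params.b_spline @ basis.B.T
    )
    if params.beta_cov is not None:
        if X is None:
            raise ValueError("beta_cov set but no covariate array X supplied")
        if X.shape[:2] != (N, basis.n_waves):
            raise ValueError(
                f"X has shape {X.shape}, expected ({N}, {basis.n_waves}, C) "
                "[region x wave axes]"
            )
        eta = eta + _covariate_term(params.beta_cov, X, basis)
    return eta


def scm_linear_predictor(
    params: SCMParams, basis: SplineBasis, X: np.ndarray | None = None
) -> np.ndarray:
    """(2, N, T) matrix of logit prevalences under the shared-component model."""
    N, T = params.beta_it.shape
    if T != basis.n_waves:
        raise ValueError(f"beta_it has {T} waves, basis has {basis.n_waves} [wave axis]")
    if params.log_delta.shape != (T,):
        raise ValueError(
            f"log_delta has shape {params.log_delta.shape}, expected ({T},) [wave axis]"
        )
    if params.b_shared_spline.shape != (N, basis.K):
        raise ValueError(
            f"b_shared_spline has shape {params.b_shared_spline.shape}, "
            f"expected ({N}, {basis.K}) [region x spline axes]"
        )
    shared = params.shared_surface(basis)  # (N, T)
    delta = params.delta
    weights = np.stack([delta, 1.0 / delta])  # (2, T)
    eta = np.empty((2, N, T))
    for j in range(2):
        eta[j] = (
            params.alpha[j]
            + shared * weights[j][None, :]
            + (basis.B @ params.a_gender[j])[None, :]
            + params.b_gender[j][:, None]
            + params.beta_gender_spline[j] @ basis.B.T
            + params.beta_it
        )
        if params.beta_cov is not None:
            if X is None:
                raise ValueError("beta_cov set but no covariate array X supplied")
            eta[j] += _covariate_term(params.beta_cov[j], X, basis)
    return eta


def variance_share(
    params: SCMParams, basis: SplineBasis, X: np.ndarray | None = None
) -> np.ndarray:
    """(2, T) proportion of predictor variance carried by the shared term.

    For each sex j and wave t: variance across regions of the weighted
    shared component divided by the variance across regions of the full
    linear predictor (the intercept drops out of both).  Values can exceed
    1 only through anticorrelation between shared and sex-specific terms.
    """
    N = params.b0.shape[0]
    if N < 2:
        raise ValueError("variance share needs at least 2 regions")
    shared = params.shared_surface(basis)
    delta = params.delta
    weights = np.stack([delta, 1.0 / delta])
    eta = scm_linear_predictor(params, basis, X)
    out = np.empty((2, basis.n_waves))
    for j in range(2):
        num = np.var(shared * weights[j][None, :], axis=0, ddof=1)
        den = np.var(eta[j], axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[j] = np.where(den > 0, num / den, np.nan)
    return out


# ---------------------------------------------------------------------------
# likelihood and prior kernels
# ---------------------------------------------------------------------------


def binom_logcoef(O: np.ndarray, n: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(O + 1.0) - gammaln(n - O + 1.0)


def binom_loglik(
    eta: np.ndarray, O: np.ndarray, n: np.ndarray, logcoef: np.ndarray | None = None
) -> np.ndarray:
    """Element-wise binomial log likelihood at logit-scale ``eta``.

    Uses O*eta - n*log(1+e^eta) which is exact and stable for any finite
    eta; includes the binomial coefficient so deviances are on the
    conventional (BUGS) scale.
    """
    if logcoef is None:
        logcoef = binom_logcoef(O, n)
    return logcoef + O * eta - n * np.logaddexp(0.0, eta)


def log_icar(x: np.ndarray, tau: float, graph: RegionGraph) -> float:
    """Intrinsic CAR log kernel on the sum-to-zero subspace.

    ``-(tau/2) * sum_{i~j} (x_i - x_j)^2 + (N-1)/2 * log tau`` up to a
    constant; the quadratic form equals ``x^T (D - W) x``.
    """
    graph.validate_for_car()
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n_regions,):
        raise ValueError(f"x must have length {graph.n_regions}")
    if tau <= 0:
        return -np.inf
    qf = float(x @ graph.laplacian @ x)
    return -0.5 * tau * qf + 0.5 * (graph.n_regions - 1) * np.log(tau)


def log_mcar(b: np.ndarray, Gamma: np.ndarray, graph: RegionGraph) -> float:
    """Intrinsic multivariate CAR log kernel for an (N, K) coefficient matrix.

    The precision of ``vec(b)`` (region-major) is ``(D - W) (x) Gamma``, so
    the kernel is ``-1/2 trace(b^T (D - W) b Gamma) + (N-1)/2 log det Gamma``
    on the per-column sum-to-zero subspace.
    """
    graph.validate_for_car()
    b = np.asarray(b, dtype=float)
    if b.ndim != 2 or b.shape[0] != graph.n_regions:
        raise ValueError(f"b must be (N={graph.n_regions}, K), got {b.shape}")
    Gamma = np.asarray(Gamma, dtype=float)
    K = b.shape[1]
    if Gamma.shape != (K, K) or not np.allclose(Gamma, Gamma.T):
        raise ValueError("Gamma must be symmetric K x K")
    sign, logdet = np.linalg.slogdet(Gamma)
    if sign <= 0 or np.any(np.linalg.eigvalsh(Gamma) <= 0):
        raise ValueError("Gamma must be symmetric positive definite")
    qf = float(np.trace(b.T @ graph.laplacian @ b @ Gamma))
    return -0.5 * qf + 0.5 * (graph.n_regions - 1) * logdet


def _log_gamma_prior(tau: float, shape: float, rate: float) -> float:
    if tau <= 0:
        return -np.inf
    return (shape - 1.0) * np.log(tau) - rate * tau


def _log_normal_kernel(x: np.ndarray, var: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(-(x * x).sum() / (2.0 * var) - 0.5 * x.size * np.log(var))


def _log_wishart_kernel(Gamma: np.ndarray, V: np.ndarray, df: int) -> float:
    K = Gamma.shape[0]
    sign, logdet = np.linalg.slogdet(Gamma)
    if sign <= 0:
        return -np.inf
    return 0.5 * (df - K - 1) * logdet - 0.5 * float(np.trace(np.linalg.solve(V, Gamma)))


def log_joint_bym(
    params: BYMParams,
    data: PanelCounts,
    basis: SplineBasis,
    prior: PriorConfig | None = None,
) -> float:
    """Unnormalised log posterior of the BYM model (single-outcome panel)."""
    prior = prior or PriorConfig()
    if data.n_sexes != 1:
        raise ValueError("BYM expects a single-outcome panel (sex='all')")
    eta = bym_linear_predictor(params, basis, data.X)
    ll = float(binom_loglik(eta, data.O[0], data.n[0]).sum())

    K = basis.K
    R, df = prior.wishart(K)
    lp = 0.0
    lp += _log_normal_kernel(np.r_[params.alpha0, params.a], prior.fixed_effect_var)
    lp += _log_normal_kernel(params.u0, 1.0 / params.tau_u) if params.tau_u > 0 else -np.inf
    lp += log_icar(params.s0, params.tau_s, data.graph)
    lp += log_mcar(params.b_spline, params.Gamma, data.graph)
    lp += _log_gamma_prior(params.tau_u, prior.tau_gamma_shape, prior.tau_gamma_rate)
    lp += prior.structured_tau_logprior(params.tau_s)
    lp += _log_wishart_kernel(params.Gamma, R, df)
    if params.beta_cov is not None:
        lp += _log_normal_kernel(params.beta_cov, prior.fixed_effect_var)
    return ll + lp


def log_joint_scm(
    params: SCMParams,
    data: PanelCounts,
    basis: SplineBasis,
    prior: PriorConfig | None = None,
) -> float:
    """Unnormalised log posterior of the shared-component model."""
    prior = prior or PriorConfig()
    if data.n_sexes != 2:
        raise ValueError("shared-component model needs a two-sex panel")
    eta = scm_linear_predictor(params, basis, data.X)
    ll = float(binom_loglik(eta, data.O, data.n).sum())

    graph = data.graph
    N, T = params.beta_it.shape
    K = basis.K
    R, df = prior.wishart(K)
    L = graph.laplacian

    lp = 0.0
    lp += _log_normal_kernel(
        np.concatenate([params.alpha, params.a_gender.ravel()]), prior.fixed_effect_var
    )
    lp += _log_normal_kernel(params.b0, prior.fixed_effect_var)
    lp += _log_normal_kernel(params.b_gender, prior.fixed_effect_var)
    lp += log_mcar(params.b_shared_spline, params.Gamma_b, graph)
    # sex-specific random splines: independent ICAR per sex and column
    if params.tau_b <= 0:
        return -np.inf
    qf_b = float(
        sum(
            params.beta_gender_spline[j, :, k] @ L @ params.beta_gender_spline[j, :, k]
            for j in range(2)
            for k in range(K)
        )
    )
    lp += -0.5 * params.tau_b * qf_b + 0.5 * 2 * K * (N - 1) * np.log(params.tau_b)
    # space-time interaction: ICAR over regions, independent across waves
    if params.tau_beta <= 0:
        return -np.inf
    qf_beta = float(np.trace(params.beta_it.T @ L @ params.beta_it))
    lp += -0.5 * params.tau_beta * qf_beta + 0.5 * T * (N - 1) * np.log(params.tau_beta)
    lp += _log_normal_kernel(params.log_delta, prior.log_delta_var)
    lp += prior.structured_tau_logprior(params.tau_beta)
    lp += _log_gamma_prior(params.tau_b, prior.tau_gamma_shape, prior.tau_gamma_rate)
    lp += _log_wishart_kernel(params.Gamma_b, R, df)
    if params.beta_cov is not None:
        lp += _log_normal_kernel(params.beta_cov, prior.fixed_effect_var)
    return ll + lp
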