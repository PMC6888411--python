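"""Adaptive Metropolis-within-Gibbs samplers for the two areal models.

Design notes
------------
The posterior is explored with single-site random-walk Metropolis updates
for every latent effect, vectorised through graph colouring: regions are
partitioned into independent sets, so all sites of one colour can be
proposed and accepted in parallel (their Markov-blanket neighbours are all
outside the class).  Precisions with gamma priors and the Wishart-prior
spline precision matrix have conjugate full conditionals and are drawn by
Gibbs; sensitivity variants on the structured precision (uniform on the sd,
half-normal on the variance) use Metropolis on log tau with the exact
transformed prior density.

Proposal scales adapt per site during burn-in only (Robbins-Monro towards
0.44 acceptance for scalar sites, 0.24 for row blocks) and are frozen
afterwards, so the kept chain is a genuine Markov chain.

Intrinsic CAR / MCAR blocks are recentred after every sweep.  Where the
linear predictor admits an exact absorber the level is moved there
(BYM: s0 level into alpha0, spline-column means into the fixed spline
coefficients; same for the sex-specific spline columns of the shared-
component model); the shared spline columns and the space-time interaction
of the shared-component model have no exact absorber because the shared
term is scaled by delta_t, and are plainly recentred (the classic
GeoBUGS-style treatment of intrinsic blocks).  Additional exact
directional Gibbs moves redistribute the level between the intercepts and
the iid spatial blocks, which removes the slow near-flat posterior
direction those vague priors create.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .basis import SplineBasis
from .data import PanelCounts
from .models import (
    BYMParams,
    ModelSpec,
    PriorConfig,
    SCMParams,
    binom_logcoef,
    bym_linear_predictor,
    scm_linear_predictor,
)

_TARGET_SCALAR = 0.44
_TARGET_BLOCK = 0.24


class _Adaptive:
    """Per-site log proposal scales with decaying Robbins-Monro adaptation."""

    def __init__(self, n: int, init_scale: float, target: float):
        self.ls = np.full(n, np.log(init_scale))
        self.target = target
        self.count = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.ls)

    def update(self, acc) -> None:
        self.count += 1
        gain = min(0.5, 2.0 / self.count**0.6)
        self.ls += gain * (np.asarray(acc, dtype=float) - self.target)
        np.clip(self.ls, -12.0, 4.0, out=self.ls)


def _gibbs_gamma(rng, shape: float, rate: float) -> float:
    return float(rng.gamma(shape, 1.0 / rate))


def _mh_log_tau(rng, tau, qf, rank_half, prior: PriorConfig, step=0.3):
    """One Metropolis step on log tau for a non-conjugate structured prior.

    Target in tau: prior(tau) * tau^{rank_half} * exp(-tau*qf/2); proposal
    is a random walk on log tau (Jacobian included).
    """

    def logpost(ltau: float) -> float:
        t = np.exp(ltau)
        return (
            prior.structured_tau_logprior(t)
            + rank_half * ltau
            - 0.5 * t * qf
            + ltau  # Jacobian of the log transform
        )

    lt = np.log(tau)
    lt_new = lt + step * rng.standard_normal()
    if np.log(rng.uniform()) < logpost(lt_new) - logpost(lt):
        return float(np.exp(lt_new))
    return tau


class _SamplerBase:
    def __init__(self, data: PanelCounts, basis: SplineBasis, prior: PriorConfig,
                 spec: ModelSpec, rng: np.random.Generator):
        data.graph.validate_for_car()
        self.data = data
        self.basis = basis
        self.prior = prior
        self.spec = spec
        self.rng = rng
        self.graph = data.graph
        self.N = data.n_regions
        self.T = data.n_waves
        self.K = basis.K
        self.B = basis.B  # (T, K)
        self.W = self.graph.W.astype(float)
        self.Dg = self.graph.D.astype(float)
        self.colors = self.graph.coloring()
        self.logcoef = binom_logcoef(data.O, data.n)
        self.Of = data.O.astype(float)
        self.nf = data.n.astype(float)
        self.adapting = True

    def _ll_cells(self, eta: np.ndarray) -> np.ndarray:
        """Binomial log-lik per cell, without the constant coefficient."""
        return self.Of * eta - self.nf * np.logaddexp(0.0, eta)

    def deviance(self, eta: np.ndarray) -> float:
        return float(-2.0 * (self.logcoef + self._ll_cells(eta)).sum())


# ---------------------------------------------------------------------------
# BYM
# ---------------------------------------------------------------------------


class BYMSampler(_SamplerBase):
    """Sampler for the single-outcome spatio-temporal BYM model."""

    def __init__(self, data, basis, prior, spec, rng, init: BYMParams):
        super().__init__(data, basis, prior, spec, rng)
        if data.n_sexes != 1:
            raise ValueError("BYM sampler needs a single-outcome panel")
        self.p = init.copy()
        n_cov_coef = 0 if self.p.beta_cov is None else self.p.beta_cov.size
        self.ad_fixed = _Adaptive(1 + self.K + n_cov_coef, 0.05, _TARGET_SCALAR)
        self.ad_u = _Adaptive(self.N, 0.1, _TARGET_SCALAR)
        self.ad_s = _Adaptive(self.N, 0.1, _TARGET_SCALAR)
        self.ad_b = _Adaptive(self.N, 0.1, _TARGET_BLOCK)
        self.eta = self._eta()
        if not np.isfinite(self._ll_cells(self.eta)).all():
            raise RuntimeError("non-finite likelihood at initialization (linear predictor)")

    def _eta(self) -> np.ndarray:
        return bym_linear_predictor(self.p, self.basis, self.data.X)[None, :, :]

    def _ll_total(self, eta) -> float:
        return float(self._ll_cells(eta).sum())

    # -- updates -------------------------------------------------------------
    def _update_fixed(self) -> None:
        """Scalar MH on alpha0, each a_k, and each covariate coefficient."""
        p, rng = self.p, self.rng
        scales = self.ad_fixed.scale
        acc = np.zeros(scales.size)
        ll_cur = self._ll_total(self.eta)
        var = self.prior.fixed_effect_var
        idx = 0

        def try_scalar(get, set_, deriv):
            nonlocal ll_cur, idx
            x = get()
            d = scales[idx] * rng.standard_normal()
            eta_new = self.eta + d * deriv
            ll_new = self._ll_total(eta_new)
            dprior = -((x + d) ** 2 - x**2) / (2.0 * var)
            if np.log(rng.uniform()) < ll_new - ll_cur + dprior:
                set_(x + d)
                self.eta = eta_new
                ll_cur = ll_new
                acc[idx] = 1.0
            idx += 1

        try_scalar(lambda: p.alpha0, lambda v: setattr(p, "alpha0", v), 1.0)
        for k in range(self.K if self.spec.include_fixed_spline else 0):
            deriv = self.B[:, k][None, None, :]
            try_scalar(
                lambda k=k: p.a[k],
                lambda v, k=k: p.a.__setitem__(k, v),
                deriv,
            )
        if p.beta_cov is not None:
            X = self.data.X
            flat = p.beta_cov.reshape(-1)
            for c in range(flat.size):
                if p.beta_cov.ndim == 1:
                    deriv = X[:, :, c][None, :, :]
                else:
                    ci, ki = divmod(c, self.K)
                    deriv = (X[:, :, ci] * self.B[:, ki][None, :])[None, :, :]
                try_scalar(
                    lambda c=c: flat[c],
                    lambda v, c=c: flat.__setitem__(c, v),
                    deriv,
                )
        if self.adapting:
            self.ad_fixed.update(acc)

    def _row_ll(self, eta) -> np.ndarray:
        return self._ll_cells(eta).sum(axis=(0, 2))

    def _update_u(self) -> None:
        if not self.spec.include_spatial:
            return
        p, rng = self.p, self.rng
        d = self.ad_u.scale * rng.standard_normal(self.N)
        eta_new = self.eta + d[None, :, None]
        dll = self._ll_cells(eta_new).sum(axis=(0, 2)) - self._row_ll(self.eta)
        dprior = -0.5 * p.tau_u * ((p.u0 + d) ** 2 - p.u0**2)
        accept = np.log(rng.uniform(size=self.N)) < dll + dprior
        p.u0[accept] += d[accept]
        self.eta[:, accept, :] = eta_new[:, accept, :]
        if self.adapting:
            self.ad_u.update(accept)

    def _update_s(self) -> None:
        if not self.spec.include_spatial:
            return
        p, rng = self.p, self.rng
        for cls in self.colors:
            d = self.ad_s.scale[cls] * rng.standard_normal(cls.size)
            eta_new = self.eta[:, cls, :] + d[None, :, None]
            dll = self._ll_cells_rows(eta_new, cls) - self._ll_cells_rows(
                self.eta[:, cls, :], cls
            )
            Ws = self.W[cls] @ p.s0
            s_old = p.s0[cls]
            s_new = s_old + d
            dprior = -0.5 * p.tau_s * (
                self.Dg[cls] * (s_new**2 - s_old**2) - 2.0 * d * Ws
            )
            accept = np.log(rng.uniform(size=cls.size)) < dll + dprior
            sel = cls[accept]
            p.s0[sel] += d[accept]
            self.eta[:, sel, :] = eta_new[:, accept, :]
            if self.adapting:
                self.ad_s.ls[cls] += min(0.5, 2.0 / (self.ad_s.count + 1) ** 0.6) * (
                    accept - self.ad_s.target
                )
        if self.adapting:
            self.ad_s.count += 1
            np.clip(self.ad_s.ls, -12.0, 4.0, out=self.ad_s.ls)

    def _ll_cells_rows(self, eta_rows, cls) -> np.ndarray:
        return (
            self.Of[:, cls, :] * eta_rows
            - self.nf[:, cls, :] * np.logaddexp(0.0, eta_rows)
        ).sum(axis=(0, 2))

    def _update_b(self) -> None:
        if not self.spec.include_random_spline:
            return
        p, rng = self.p, self.rng
        G = p.Gamma
        for cls in self.colors:
            m = cls.size
            d = self.ad_b.scale[cls][:, None] * rng.standard_normal((m, self.K))
            eta_new = self.eta[:, cls, :] + (d @ self.B.T)[None, :, :]
            dll = self._ll_cells_rows(eta_new, cls) - self._ll_cells_rows(
                self.eta[:, cls, :], cls
            )
            b_old = p.b_spline[cls]
            b_new = b_old + d
            Wb = self.W[cls] @ p.b_spline  # (m, K) neighbour sums
            quad = lambda M: np.einsum("ik,kl,il->i", M, G, M)
            dprior = -0.5 * (
                self.Dg[cls] * (quad(b_new) - quad(b_old))
                - 2.0 * np.einsum("ik,kl,il->i", d, G, Wb)
            )
            accept = np.log(rng.uniform(size=m)) < dll + dprior
            sel = cls[accept]
            p.b_spline[sel] += d[accept]
            self.eta[:, sel, :] = eta_new[:, accept, :]
            if self.adapting:
                self.ad_b.ls[cls] += min(0.5, 2.0 / (self.ad_b.count + 1) ** 0.6) * (
                    accept - self.ad_b.target
                )
        if self.adapting:
            self.ad_b.count += 1
            np.clip(self.ad_b.ls, -12.0, 4.0, out=self.ad_b.ls)

    def _update_precisions(self) -> None:
        p, rng, prior = self.p, self.rng, self.prior
        L = self.graph.laplacian
        if self.spec.include_spatial:
            p.tau_u = _gibbs_gamma(
                rng,
                prior.tau_gamma_shape + 0.5 * self.N,
                prior.tau_gamma_rate + 0.5 * float(p.u0 @ p.u0),
            )
            qf_s = float(p.s0 @ L @ p.s0)
            if prior.sensitivity_variant == "gamma_prec":
                p.tau_s = _gibbs_gamma(
                    rng,
                    prior.tau_gamma_shape + 0.5 * (self.N - 1),
                    prior.tau_gamma_rate + 0.5 * qf_s,
                )
            else:
                p.tau_s = _mh_log_tau(rng, p.tau_s, qf_s, 0.5 * (self.N - 1), prior)
        if self.spec.include_random_spline:
            R, df = prior.wishart(self.K)
            S = p.b_spline.T @ L @ p.b_spline
            scale = np.linalg.inv(np.linalg.inv(R) + S)
            scale = 0.5 * (scale + scale.T)
            p.Gamma = stats.wishart.rvs(df=df + self.N - 1, scale=scale, random_state=rng)
            p.Gamma = np.atleast_2d(p.Gamma)

    def _level_moves(self) -> None:
        """Exact directional Gibbs between alpha0 and the iid spatial block."""
        if not self.spec.include_spatial:
            return
        p, rng = self.p, self.rng
        var_a = self.prior.fixed_effect_var
        # conditional of the shift e along (alpha0 + e, u0 - e): Gaussian with
        # precision 1/V + N*tau_u (likelihood is constant along the line)
        prec = 1.0 / var_a + self.N * p.tau_u
        mean = (p.tau_u * p.u0.sum() - p.alpha0 / var_a) / prec
        e = mean + rng.standard_normal() / np.sqrt(prec)
        p.alpha0 += e
        p.u0 -= e

    def _recenter(self) -> None:
        p = self.p
        if self.spec.include_spatial:
            m = p.s0.mean()
            p.s0 -= m
            p.alpha0 += m
        if self.spec.include_random_spline:
            mb = p.b_spline.mean(axis=0)
            p.b_spline -= mb[None, :]
            if self.spec.include_fixed_spline:
                p.a += mb
        self.eta = self._eta()

    def sweep(self) -> None:
        self._update_fixed()
        self._update_u()
        self._update_s()
        self._update_b()
        self._level_moves()
        self._recenter()
        self._update_precisions()

    def state_blocks(self) -> dict[str, np.ndarray]:
        p = self.p
        out = {
            "alpha0": np.array(p.alpha0),
            "a": p.a.copy(),
            "u0": p.u0.copy(),
            "s0": p.s0.copy(),
            "b_spline": p.b_spline.copy(),
            "tau_u": np.array(p.tau_u),
            "tau_s": np.array(p.tau_s),
            "Gamma": p.Gamma.copy(),
        }
        if p.beta_cov is not None:
            out["beta_cov"] = p.beta_cov.copy()
        return out

    def current_deviance(self) -> float:
        return self.deviance(self.eta)


# ---------------------------------------------------------------------------
# shared-component model
# ---------------------------------------------------------------------------


class SCMSampler(_SamplerBase):
    """Sampler for the two-outcome shared-component model."""

    def __init__(self, data, basis, prior, spec, rng, init: SCMParams):
        super().__init__(data, basis, prior, spec, rng)
        if data.n_sexes != 2:
            raise ValueError("shared-component sampler needs a two-sex panel")
        self.p = init.copy()
        n_cov_coef = 0 if self.p.beta_cov is None else self.p.beta_cov.size
        self.ad_fixed = _Adaptive(2 + 2 * self.K + n_cov_coef, 0.05, _TARGET_SCALAR)
        self.ad_b0 = _Adaptive(self.N, 0.1, _TARGET_SCALAR)
        self.ad_bsh = _Adaptive(self.N, 0.1, _TARGET_BLOCK)
        self.ad_bg = _Adaptive(2 * self.N, 0.1, _TARGET_SCALAR)
        self.ad_bgs = _Adaptive(2 * self.N, 0.1, _TARGET_BLOCK)
        self.ad_beta = _Adaptive(self.N * self.T, 0.1, _TARGET_SCALAR)
        self.ad_delta = _Adaptive(self.T, 0.1, _TARGET_SCALAR)
        self.ad_level = _Adaptive(1, 0.1, _TARGET_SCALAR)
        self.eta = scm_linear_predictor(self.p, basis, data.X)
        if not np.isfinite(self._ll_cells(self.eta)).all():
            raise RuntimeError("non-finite likelihood at initialization (linear predictor)")

    def _refresh_eta(self) -> None:
        self.eta = scm_linear_predictor(self.p, self.basis, self.data.X)

    def _ll_total(self, eta) -> float:
        return float(self._ll_cells(eta).sum())

    def _weights(self) -> np.ndarray:
        delta = np.exp(self.p.log_delta)
        return np.stack([delta, 1.0 / delta])  # (2, T)

    # -- fixed effects --------------------------------------------------------
    def _update_fixed(self) -> None:
        p, rng = self.p, self.rng
        scales = self.ad_fixed.scale
        acc = np.zeros(scales.size)
        ll_cur = self._ll_total(self.eta)
        var = self.prior.fixed_effect_var
        idx = 0

        def try_scalar(get, set_, deriv):
            nonlocal ll_cur, idx
            x = get()
            d = scales[idx] * rng.standard_normal()
            eta_new = self.eta + d * deriv
            ll_new = self._ll_total(eta_new)
            dprior = -((x + d) ** 2 - x**2) / (2.0 * var)
            if np.log(rng.uniform()) < ll_new - ll_cur + dprior:
                set_(x + d)
                self.eta = eta_new
                ll_cur = ll_new
                acc[idx] = 1.0
            idx += 1

        for j in range(2):
            dj = np.zeros((2, 1, 1))
            dj[j] = 1.0
            try_scalar(
                lambda j=j: p.alpha[j],
                lambda v, j=j: p.alpha.__setitem__(j, v),
                dj,
            )
        for j in range(2 if self.spec.include_fixed_spline else 0):
            for k in range(self.K):
                deriv = np.zeros((2, 1, self.T))
                deriv[j, 0, :] = self.B[:, k]
                try_scalar(
                    lambda j=j, k=k: p.a_gender[j, k],
                    lambda v, j=j, k=k: p.a_gender.__setitem__((j, k), v),
                    deriv,
                )
        if p.beta_cov is not None:
            X = self.data.X
            shape = p.beta_cov.shape
            flat = p.beta_cov.reshape(-1)
            per_sex = flat.size // 2
            for c in range(flat.size):
                j, rem = divmod(c, per_sex)
                deriv = np.zeros((2, self.N, self.T))
                if p.beta_cov.ndim == 2:
                    deriv[j] = X[:, :, rem]
                else:
                    ci, ki = divmod(rem, self.K)
                    deriv[j] = X[:, :, ci] * self.B[:, ki][None, :]
                try_scalar(
                    lambda c=c: flat[c],
                    lambda v, c=c: flat.__setitem__(c, v),
                    deriv,
                )
        if self.adapting:
            self.ad_fixed.update(acc)

    # -- shared spatial & spline ----------------------------------------------
    def _row_dll(self, eta_new_rows, cls) -> np.ndarray:
        old = self.eta[:, cls, :]
        o, nn = self.Of[:, cls, :], self.nf[:, cls, :]
        return (
            o * eta_new_rows - nn * np.logaddexp(0.0, eta_new_rows)
            - (o * old - nn * np.logaddexp(0.0, old))
        ).sum(axis=(0, 2))

    def _update_b0(self) -> None:
        p, rng = self.p, self.rng
        w = self._weights()  # (2, T)
        d = self.ad_b0.scale * rng.standard_normal(self.N)
        eta_new = self.eta + d[None, :, None] * w[:, None, :]
        dll = (
            self.Of * eta_new - self.nf * np.logaddexp(0.0, eta_new)
            - (self.Of * self.eta - self.nf * np.logaddexp(0.0, self.eta))
        ).sum(axis=(0, 2))
        var = self.prior.fixed_effect_var
        dprior = -((p.b0 + d) ** 2 - p.b0**2) / (2.0 * var)
        accept = np.log(rng.uniform(size=self.N)) < dll + dprior
        p.b0[accept] += d[accept]
        self.eta[:, accept, :] = eta_new[:, accept, :]
        if self.adapting:
            self.ad_b0.update(accept)

    def _update_b_shared(self) -> None:
        p, rng = self.p, self.rng
        w = self._weights()
        G = p.Gamma_b
        for cls in self.colors:
            m = cls.size
            d = self.ad_bsh.scale[cls][:, None] * rng.standard_normal((m, self.K))
            dsurf = d @ self.B.T  # (m, T)
            eta_new = self.eta[:, cls, :] + dsurf[None, :, :] * w[:, None, :]
            dll = self._row_dll(eta_new, cls)
            b_old = p.b_shared_spline[cls]
            b_new = b_old + d
            Wb = self.W[cls] @ p.b_shared_spline
            quad = lambda M: np.einsum("ik,kl,il->i", M, G, M)
            dprior = -0.5 * (
                self.Dg[cls] * (quad(b_new) - quad(b_old))
                - 2.0 * np.einsum("ik,kl,il->i", d, G, Wb)
            )
            accept = np.log(rng.uniform(size=m)) < dll + dprior
            sel = cls[accept]
            p.b_shared_spline[sel] += d[accept]
            self.eta[:, sel, :] = eta_new[:, accept, :]
            if self.adapting:
                self.ad_bsh.ls[cls] += min(0.5, 2.0 / (self.ad_bsh.count + 1) ** 0.6) * (
                    accept - self.ad_bsh.target
                )
        if self.adapting:
            self.ad_bsh.count += 1
            np.clip(self.ad_bsh.ls, -12.0, 4.0, out=self.ad_bsh.ls)

    # -- sex-specific blocks ---------------------------------------------------
    def _update_b_gender(self) -> None:
        p, rng = self.p, self.rng
        var = self.prior.fixed_effect_var
        for j in range(2):
            sl = slice(j * self.N, (j + 1) * self.N)
            d = self.ad_bg.scale[sl] * rng.standard_normal(self.N)
            eta_new = self.eta[j] + d[:, None]
            o, nn = self.Of[j], self.nf[j]
            dll = (
                o * eta_new - nn * np.logaddexp(0.0, eta_new)
                - (o * self.eta[j] - nn * np.logaddexp(0.0, self.eta[j]))
            ).sum(axis=1)
            dprior = -((p.b_gender[j] + d) ** 2 - p.b_gender[j] ** 2) / (2.0 * var)
            accept = np.log(rng.uniform(size=self.N)) < dll + dprior
            p.b_gender[j, accept] += d[accept]
            self.eta[j, accept, :] = eta_new[accept, :]
            if self.adapting:
                acc_full = np.zeros(self.N)
                acc_full[:] = accept
                self.ad_bg.ls[sl] += min(0.5, 2.0 / (self.ad_bg.count + 1) ** 0.6) * (
                    accept - self.ad_bg.target
                )
        if self.adapting:
            self.ad_bg.count += 1
            np.clip(self.ad_bg.ls, -12.0, 4.0, out=self.ad_bg.ls)

    def _update_beta_gender_spline(self) -> None:
        if not self.spec.include_random_spline:
            return
        p, rng = self.p, self.rng
        tau = p.tau_b
        for j in range(2):
            base = j * self.N
            for cls in self.colors:
                m = cls.size
                d = self.ad_bgs.scale[base + cls][:, None] * rng.standard_normal(
                    (m, self.K)
                )
                eta_new = self.eta[j, cls, :] + d @ self.B.T
                o, nn = self.Of[j, cls, :], self.nf[j, cls, :]
                old = self.eta[j, cls, :]
                dll = (
                    o * eta_new - nn * np.logaddexp(0.0, eta_new)
                    - (o * old - nn * np.logaddexp(0.0, old))
                ).sum(axis=1)
                b_old = p.beta_gender_spline[j][cls]
                b_new = b_old + d
                Wb = self.W[cls] @ p.beta_gender_spline[j]
                dprior = -0.5 * tau * (
                    self.Dg[cls] * ((b_new**2).sum(1) - (b_old**2).sum(1))
                    - 2.0 * (d * Wb).sum(1)
                )
                accept = np.log(rng.uniform(size=m)) < dll + dprior
                sel = cls[accept]
                p.beta_gender_spline[j][sel] += d[accept]
                self.eta[j, sel, :] = eta_new[accept, :]
                if self.adapting:
                    self.ad_bgs.ls[base + cls] += min(
                        0.5, 2.0 / (self.ad_bgs.count + 1) ** 0.6
                    ) * (accept - self.ad_bgs.target)
        if self.adapting:
            self.ad_bgs.count += 1
            np.clip(self.ad_bgs.ls, -12.0, 4.0, out=self.ad_bgs.ls)

    # -- interaction and weights ----------------------------------------------
    def _update_beta_it(self) -> None:
        if not self.spec.include_interaction:
            return
        p, rng = self.p, self.rng
        tau = p.tau_beta
        scales = self.ad_beta.scale.reshape(self.N, self.T)
        for cls in self.colors:
            m = cls.size
            d = scales[cls] * rng.standard_normal((m, self.T))
            eta_new = self.eta[:, cls, :] + d[None, :, :]
            o, nn = self.Of[:, cls, :], self.nf[:, cls, :]
            old = self.eta[:, cls, :]
            dll = (
                o * eta_new - nn * np.logaddexp(0.0, eta_new)
                - (o * old - nn * np.logaddexp(0.0, old))
            ).sum(axis=0)  # (m, T): summed over sexes only
            Wb = self.W[cls] @ p.beta_it  # (m, T)
            b_old = p.beta_it[cls]
            b_new = b_old + d
            dprior = -0.5 * tau * (
                self.Dg[cls][:, None] * (b_new**2 - b_old**2) - 2.0 * d * Wb
            )
            accept = np.log(rng.uniform(size=(m, self.T))) < dll + dprior
            p.beta_it[cls] = np.where(accept, b_new, b_old)
            self.eta[:, cls, :] = np.where(accept[None, :, :], eta_new, old)
            if self.adapting:
                gain = min(0.5, 2.0 / (self.ad_beta.count + 1) ** 0.6)
                ls = self.ad_beta.ls.reshape(self.N, self.T)
                ls[cls] += gain * (accept - self.ad_beta.target)
        if self.adapting:
            self.ad_beta.count += 1
            np.clip(self.ad_beta.ls, -12.0, 4.0, out=self.ad_beta.ls)

    def _update_log_delta(self) -> None:
        p, rng = self.p, self.rng
        shared = p.shared_surface(self.basis)  # (N, T)
        ld_old = p.log_delta
        d = self.ad_delta.scale * rng.standard_normal(self.T)
        ld_new = ld_old + d
        w1_old, w2_old = np.exp(ld_old), np.exp(-ld_old)
        w1_new, w2_new = np.exp(ld_new), np.exp(-ld_new)
        eta1 = self.eta[0] + shared * (w1_new - w1_old)[None, :]
        eta2 = self.eta[1] + shared * (w2_new - w2_old)[None, :]
        eta_new = np.stack([eta1, eta2])
        dll = (
            self.Of * eta_new - self.nf * np.logaddexp(0.0, eta_new)
            - (self.Of * self.eta - self.nf * np.logaddexp(0.0, self.eta))
        ).sum(axis=(0, 1))  # per wave
        dprior = -(ld_new**2 - ld_old**2) / (2.0 * self.prior.log_delta_var)
        accept = np.log(rng.uniform(size=self.T)) < dll + dprior
        p.log_delta[accept] = ld_new[accept]
        self.eta[:, :, accept] = eta_new[:, :, accept]
        if self.adapting:
            self.ad_delta.update(accept)

    # -- precisions -------------------------------------------------------------
    def _update_precisions(self) -> None:
        p, rng, prior = self.p, self.rng, self.prior
        L = self.graph.laplacian
        if self.spec.include_interaction:
            qf_beta = float(np.trace(p.beta_it.T @ L @ p.beta_it))
            rank_half = 0.5 * self.T * (self.N - 1)
            if prior.sensitivity_variant == "gamma_prec":
                p.tau_beta = _gibbs_gamma(
                    rng,
                    prior.tau_gamma_shape + rank_half,
                    prior.tau_gamma_rate + 0.5 * qf_beta,
                )
            else:
                p.tau_beta = _mh_log_tau(rng, p.tau_beta, qf_beta, rank_half, prior)
        if self.spec.include_random_spline:
            qf_b = float(
                sum(
                    np.trace(p.beta_gender_spline[j].T @ L @ p.beta_gender_spline[j])
                    for j in range(2)
                )
            )
            p.tau_b = _gibbs_gamma(
                rng,
                prior.tau_gamma_shape + 0.5 * 2 * self.K * (self.N - 1),
                prior.tau_gamma_rate + 0.5 * qf_b,
            )
            R, df = prior.wishart(self.K)
            S = p.b_shared_spline.T @ L @ p.b_shared_spline
            scale = np.linalg.inv(np.linalg.inv(R) + S)
            scale = 0.5 * (scale + scale.T)
            p.Gamma_b = np.atleast_2d(
                stats.wishart.rvs(df=df + self.N - 1, scale=scale, random_state=rng)
            )

    # -- identifiability moves ---------------------------------------------------
    def _level_moves(self) -> None:
        """Directional Gibbs between alpha_j and b_gender[j] (exact), and an
        MH level move between b0 and the two intercepts (near-flat when
        delta_t ~ 1)."""
        p, rng = self.p, self.rng
        var = self.prior.fixed_effect_var
        for j in range(2):
            prec = 1.0 / var + self.N / var
            mean = (p.b_gender[j].sum() / var - p.alpha[j] / var) / prec
            e = mean + rng.standard_normal() / np.sqrt(prec)
            p.alpha[j] += e
            p.b_gender[j] -= e
        # joint b0-level vs intercepts (Metropolis, exact accept/reject)
        w = self._weights()
        wbar = w.mean(axis=1)
        e = self.ad_level.scale[0] * rng.standard_normal()
        cand = p.copy()
        cand.b0 = p.b0 + e
        cand.alpha = p.alpha - e * wbar
        eta_new = scm_linear_predictor(cand, self.basis, self.data.X)
        dll = self._ll_total(eta_new) - self._ll_total(self.eta)
        dprior = (
            -((cand.b0**2).sum() - (p.b0**2).sum()) / (2.0 * var)
            - ((cand.alpha**2).sum() - (p.alpha**2).sum()) / (2.0 * var)
        )
        acc = np.log(rng.uniform()) < dll + dprior
        if acc:
            p.b0 = cand.b0
            p.alpha = cand.alpha
            self.eta = eta_new
        if self.adapting:
            self.ad_level.update(np.array([float(acc)]))

    def _recenter(self) -> None:
        p = self.p
        # sex-specific spline columns: exact absorber in the fixed splines
        if self.spec.include_random_spline:
            for j in range(2):
                mcol = p.beta_gender_spline[j].mean(axis=0)
                p.beta_gender_spline[j] -= mcol[None, :]
                if self.spec.include_fixed_spline:
                    p.a_gender[j] += mcol
            # shared spline columns: no exact absorber (weighted by delta_t)
            p.b_shared_spline -= p.b_shared_spline.mean(axis=0)[None, :]
        if self.spec.include_interaction:
            p.beta_it -= p.beta_it.mean(axis=0)[None, :]
        self._refresh_eta()

    def sweep(self) -> None:
        self._update_fixed()
        self._update_b0()
        self._update_b_shared()
        self._update_b_gender()
        self._update_beta_gender_spline()
        self._update_beta_it()
        self._update_log_delta()
        self._level_moves()
        self._recenter()
        self._update_precisions()

    def state_blocks(self) -> dict[str, np.ndarray]:
        p = self.p
        out = {
            "alpha": p.alpha.copy(),
            "b0": p.b0.copy(),
            "b_shared_spline": p.b_shared_spline.copy(),
            "a_gender": p.a_gender.copy(),
            "b_gender": p.b_gender.copy(),
            "beta_gender_spline": p.beta_gender_spline.copy(),
            "beta_it": p.beta_it.copy(),
            "log_delta": p.log_delta.copy(),
            "tau_beta": np.array(p.tau_beta),
            "tau_b": np.array(p.tau_b),
            "Gamma_b": p.Gamma_b.copy(),
        }
        if p.beta_cov is not None:
            out["beta_cov"] = p.beta_cov.copy()
        return out

    def current_deviance(self) -> float:
        return self.deviance(self.eta)
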