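"""Blocked Metropolis-within-Gibbs sampler for the occupancy-detection model.

The latent occupancy states are drawn from their exact full conditional.
Logit-scale parameters use vectorised random-walk Metropolis steps whose
proposal scales adapt during burn-in (Robbins-Monro towards a 0.44
acceptance rate); year effects under the random-walk prior are updated in
even/odd column sweeps so that each block's components are conditionally
independent.  Standard deviations are updated by univariate slice sampling
on the log scale.  Likelihood evaluations reduce to sufficient statistics,
so one full sweep costs O(n_visits + n_sites * n_years).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit, log_expit

_TARGET_ACCEPT = 0.44
_LOG_2PI = float(np.log(2.0 * np.pi))


def _norm_logpdf(x, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * (x / sd) ** 2


def _b0_logpdf(x, spec):
    kind = spec[0]
    if kind == "normal":
        return _norm_logpdf(np.asarray(x, dtype=float) - spec[1], spec[2])
    if kind == "logistic":
        z = (np.asarray(x, dtype=float) - spec[1]) / spec[2]
        return -z - 2.0 * np.logaddexp(0.0, -z) - np.log(spec[2])
    raise ValueError(f"unknown b0 prior {kind!r}")


def _sd_logpdf(x, spec):
    x = float(x)
    if x <= 0:
        return -np.inf
    kind = spec[0]
    if kind == "halfnormal":
        scale = spec[1]
        return (
            np.log(2.0) - 0.5 * _LOG_2PI - np.log(scale) - 0.5 * (x / scale) ** 2
        )
    if kind == "uniform":
        upper = spec[1]
        return -np.log(upper) if x < upper else -np.inf
    raise ValueError(f"unknown sd prior {kind!r}")


def _slice_sample(x0, logf, rng, w=1.0, max_steps=50):
    """Univariate stepping-out slice sampler (Neal 2003)."""
    y0 = logf(x0)
    if not np.isfinite(y0):
        raise RuntimeError("slice sampler started outside the support")
    y = y0 - rng.exponential()
    left = x0 - w * rng.random()
    right = left + w
    k = max_steps
    while k > 0 and logf(left) > y:
        left -= w
        k -= 1
    k = max_steps
    while k > 0 and logf(right) > y:
        right += w
        k -= 1
    for _ in range(200):
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


class ChainSampler:
    """One MCMC chain over the occupancy-detection posterior."""

    def __init__(self, data, priors, fixed=None, adapt=True):
        self.priors = priors
        self.adapt = adapt
        self.fixed = dict(fixed or {})

        self.R = data.n_regions
        self.T = data.n_years
        region = data.region
        self.ns = int(region.size)
        order = np.argsort(region, kind="stable")
        self.inv = np.empty_like(order)
        self.inv[order] = np.arange(order.size)
        self.region_sorted = region[order]
        # contiguous row blocks per region in the sorted site ordering
        self.bounds = np.searchsorted(self.region_sorted, np.arange(self.R + 1))
        self.region_counts = np.diff(self.bounds)
        self.active = self.region_counts > 0

        vsite = self.inv[data.vsite]
        self.vyear = data.vyear
        self.vdt = data.vdt
        self.vy = data.vy.astype(np.float64)
        self.n_visits = int(self.vy.size)
        self.sy = vsite * self.T + self.vyear
        self.n_sy = self.ns * self.T
        det = np.bincount(self.sy, weights=self.vy, minlength=self.n_sy)
        self.anydet = (det > 0).reshape(self.ns, self.T)
        self.tdt = self.vyear * 3 + self.vdt

        self.t_even = np.arange(0, self.T, 2)
        self.t_odd = np.arange(1, self.T, 2)

    # -- state initialisation ------------------------------------------------

    def _init_state(self, rng):
        R, T, ns = self.R, self.T, self.ns
        naive = np.full((R, T), 0.5)
        for r in range(R):
            block = self.anydet[self.bounds[r] : self.bounds[r + 1]]
            if block.shape[0]:
                naive[r] = block.mean(axis=0)
        with np.errstate(divide="ignore"):
            self.b = np.log(np.clip(naive, 0.05, 0.95))
        self.b -= np.log1p(-np.clip(naive, 0.05, 0.95))
        self.b[~self.active] = 0.0
        self.u = np.zeros(ns)
        rate = float(self.vy.mean()) if self.n_visits else 0.2
        rate = min(max(rate, 0.05), 0.95)
        a0 = math.log(rate / (1.0 - rate))
        self.a = np.full(T, a0)
        self.mu_a = a0
        self.sigma_a = 1.0
        self.beta1 = 0.0
        self.beta2 = 0.0
        self.sigma_u = 1.0
        self.sigma_rw = 0.3

        f = self.fixed
        if "b" in f:
            self.b = np.broadcast_to(np.asarray(f["b"], float), (R, T)).copy()
        if "u" in f:
            self.u = np.broadcast_to(np.asarray(f["u"], float), (ns,)).copy()
        if "a" in f:
            self.a = np.broadcast_to(np.asarray(f["a"], float), (T,)).copy()
        for name in ("beta1", "beta2", "sigma_u", "sigma_rw", "mu_a", "sigma_a"):
            if name in f:
                setattr(self, name, float(f[name]))

        psi0 = expit(self.b[self.region_sorted] + self.u[:, None])
        self.z = self.anydet | (rng.random((ns, T)) < psi0)
        self.zf = self.z.astype(np.float64)

        self.ls_b = np.full((R, T), math.log(0.3))
        self.ls_u = np.full(ns, math.log(0.5))
        self.ls_a = np.full(T, math.log(0.3))
        self.ls_a_mat = self.ls_a[None, :]
        self.ls_beta = np.full(2, math.log(0.3))

    @property
    def betavec(self):
        return np.array([0.0, self.beta1, self.beta2])

    @staticmethod
    def _gamma(it):
        return min(0.25, 2.0 * (it + 1.0) ** -0.6)

    def _region_rowsum(self, mat):
        out = np.zeros((self.R, mat.shape[1]))
        for r in range(self.R):
            lo, hi = self.bounds[r], self.bounds[r + 1]
            if hi > lo:
                out[r] = mat[lo:hi].sum(axis=0)
        return out

    # -- latent occupancy ----------------------------------------------------

    def _update_z(self, rng):
        eta = self.b[self.region_sorted] + self.u[:, None]
        if self.n_visits:
            lq = log_expit(-(self.a[self.vyear] + self.betavec[self.vdt]))
            log_l0 = np.bincount(self.sy, weights=lq, minlength=self.n_sy)
            log_l0 = log_l0.reshape(self.ns, self.T)
        else:
            log_l0 = 0.0
        # Pr(z=1 | no detection) has log-odds  logit(psi) + log Pr(miss | present)
        pz = expit(eta + log_l0)
        self.z = rng.random((self.ns, self.T)) < pz
        self.z |= self.anydet
        self.zf = self.z.astype(np.float64)

    def _update_detstats(self):
        if not self.n_visits:
            self.kd = np.zeros((self.T, 3))
            self.nd = np.zeros((self.T, 3))
            return
        occ = self.z.reshape(-1)[self.sy]
        idx = self.tdt[occ]
        self.kd = np.bincount(
            idx, weights=self.vy[occ], minlength=3 * self.T
        ).reshape(self.T, 3)
        self.nd = np.bincount(idx, minlength=3 * self.T).reshape(self.T, 3)
        self.nd = self.nd.astype(np.float64)

    # -- random-walk prior machinery ----------------------------------------

    def _rw_local_lp(self, mat, vals, tcols, sigma, b0spec):
        """Prior terms involving the entries of ``mat`` at columns ``tcols``
        when those entries take the values ``vals`` (neighbours from ``mat``)."""
        lp = np.zeros_like(vals)
        m0 = tcols == 0
        if m0.any():
            lp[:, m0] += _b0_logpdf(vals[:, m0], b0spec)
            if self.T > 1:
                lp[:, m0] += -0.5 * ((mat[:, [1]] - vals[:, m0]) / sigma) ** 2
        ml = tcols > 0
        if ml.any():
            lp[:, ml] += -0.5 * (
                (vals[:, ml] - mat[:, tcols[ml] - 1]) / sigma
            ) ** 2
        mr = (tcols > 0) & (tcols < self.T - 1)
        if mr.any():
            lp[:, mr] += -0.5 * (
                (mat[:, tcols[mr] + 1] - vals[:, mr]) / sigma
            ) ** 2
        return lp

    def _rw_parity_update(
        self, mat, ls, sigma, b0spec, ll_fn, rng, adapting, it, row_mask=None
    ):
        for tcols in (self.t_even, self.t_odd):
            if tcols.size == 0:
                continue
            cur = mat[:, tcols]
            prop = cur + np.exp(ls[:, tcols]) * rng.standard_normal(cur.shape)
            d = ll_fn(prop, tcols) - ll_fn(cur, tcols)
            d += self._rw_local_lp(mat, prop, tcols, sigma, b0spec)
            d -= self._rw_local_lp(mat, cur, tcols, sigma, b0spec)
            d = np.where(np.isfinite(d), d, -np.inf)
            acc = np.log(rng.random(d.shape)) < d
            if row_mask is not None:
                acc &= row_mask[:, None]
            cur = np.where(acc, prop, cur)
            mat[:, tcols] = cur
            if adapting:
                ls[:, tcols] = np.clip(
                    ls[:, tcols] + self._gamma(it) * (acc - _TARGET_ACCEPT),
                    -8.0,
                    4.0,
                )

    # -- state sub-model updates ---------------------------------------------

    def _state_ll_cols(self, bvals, tcols):
        eta = bvals[self.region_sorted] + self.u[:, None]
        ll = self.zf[:, tcols] * eta - np.logaddexp(0.0, eta)
        return self._region_rowsum(ll)

    def _update_b(self, rng, adapting, it):
        self._rw_parity_update(
            self.b,
            self.ls_b,
            self.sigma_rw,
            self.priors.b0,
            self._state_ll_cols,
            rng,
            adapting,
            it,
            row_mask=self.active,
        )

    def _update_u(self, rng, adapting, it):
        eta_c = self.b[self.region_sorted] + self.u[:, None]
        prop = self.u + np.exp(self.ls_u) * rng.standard_normal(self.ns)
        eta_p = eta_c + (prop - self.u)[:, None]
        d = (
            self.zf * (eta_p - eta_c)
            - np.logaddexp(0.0, eta_p)
            + np.logaddexp(0.0, eta_c)
        ).sum(axis=1)
        d += -0.5 * ((prop / self.sigma_u) ** 2 - (self.u / self.sigma_u) ** 2)
        acc = np.log(rng.random(self.ns)) < d
        self.u = np.where(acc, prop, self.u)
        if adapting:
            self.ls_u = np.clip(
                self.ls_u + self._gamma(it) * (acc - _TARGET_ACCEPT), -8.0, 4.0
            )

    def _update_sigma_u(self, rng):
        n = self.ns
        ssq = float(self.u @ self.u)
        spec = self.priors.sigma_u_prior

        def logf(logs):
            s = math.exp(logs)
            lp = _sd_logpdf(s, spec)
            if not np.isfinite(lp):
                return -math.inf
            return lp - n * logs - ssq / (2.0 * s * s) + logs

        self.sigma_u = math.exp(
            _slice_sample(math.log(self.sigma_u), logf, rng)
        )

    def _update_sigma_rw(self, rng):
        if self.T < 2:
            return
        diffs = np.diff(self.b[self.active], axis=1)
        n = diffs.size
        if n == 0:
            return
        ssq = float(np.sum(diffs**2))
        spec = self.priors.sigma_rw_prior

        def logf(logs):
            s = math.exp(logs)
            lp = _sd_logpdf(s, spec)
            if not np.isfinite(lp):
                return -math.inf
            return lp - n * logs - ssq / (2.0 * s * s) + logs

        self.sigma_rw = math.exp(
            _slice_sample(math.log(self.sigma_rw), logf, rng)
        )

    # -- observation sub-model updates ----------------------------------------

    def _det_ll_by_year(self, a):
        eta = a[:, None] + self.betavec[None, :]
        return (
            self.kd * log_expit(eta) + (self.nd - self.kd) * log_expit(-eta)
        ).sum(axis=1)

    def _det_ll_cols_a(self, avals, tcols):
        eta = avals[0][:, None] + self.betavec[None, :]
        ll = self.kd[tcols] * log_expit(eta) + (
            self.nd[tcols] - self.kd[tcols]
        ) * log_expit(-eta)
        return ll.sum(axis=1)[None, :]

    def _update_a(self, rng, adapting, it):
        pr = self.priors
        if pr.a_prior == "rw":
            self._rw_parity_update(
                self.a[None, :],
                self.ls_a_mat,
                self.sigma_a,
                ("normal", 0.0, pr.a_sd),
                self._det_ll_cols_a,
                rng,
                adapting,
                it,
            )
            if self.T > 1 and "sigma_a" not in self.fixed:
                self._update_sigma_a(np.diff(self.a), rng)
            return
        prop = self.a + np.exp(self.ls_a) * rng.standard_normal(self.T)
        d = self._det_ll_by_year(prop) - self._det_ll_by_year(self.a)
        if pr.a_prior == "normal":
            d += -0.5 * ((prop / pr.a_sd) ** 2 - (self.a / pr.a_sd) ** 2)
        else:  # hierarchical
            d += -0.5 * (
                ((prop - self.mu_a) / self.sigma_a) ** 2
                - ((self.a - self.mu_a) / self.sigma_a) ** 2
            )
        acc = np.log(rng.random(self.T)) < d
        self.a = np.where(acc, prop, self.a)
        if adapting:
            self.ls_a = np.clip(
                self.ls_a + self._gamma(it) * (acc - _TARGET_ACCEPT), -8.0, 4.0
            )
        if pr.a_prior == "hierarchical":
            if "mu_a" not in self.fixed:
                prec = self.T / self.sigma_a**2 + 1.0 / pr.a_sd**2
                mean = (self.a.sum() / self.sigma_a**2) / prec
                self.mu_a = mean + rng.standard_normal() / math.sqrt(prec)
            if "sigma_a" not in self.fixed:
                self._update_sigma_a(self.a - self.mu_a, rng)

    def _update_sigma_a(self, resid, rng):
        n = resid.size
        ssq = float(np.sum(resid**2))
        spec = self.priors.sigma_a_prior

        def logf(logs):
            s = math.exp(logs)
            lp = _sd_logpdf(s, spec)
            if not np.isfinite(lp):
                return -math.inf
            return lp - n * logs - ssq / (2.0 * s * s) + logs

        self.sigma_a = math.exp(
            _slice_sample(math.log(self.sigma_a), logf, rng)
        )

    def _update_betas(self, rng, adapting, it):
        for j, name in ((0, "beta1"), (1, "beta2")):
            if name in self.fixed:
                continue
            cur = getattr(self, name)
            prop = cur + math.exp(self.ls_beta[j]) * rng.standard_normal()
            bv_cur = self.betavec
            bv_prop = bv_cur.copy()
            bv_prop[j + 1] = prop
            eta_c = self.a[:, None] + bv_cur[None, :]
            eta_p = self.a[:, None] + bv_prop[None, :]
            ll_c = (
                self.kd * log_expit(eta_c)
                + (self.nd - self.kd) * log_expit(-eta_c)
            ).sum()
            ll_p = (
                self.kd * log_expit(eta_p)
                + (self.nd - self.kd) * log_expit(-eta_p)
            ).sum()
            d = ll_p - ll_c
            d += -0.5 * (
                (prop / self.priors.beta_sd) ** 2
                - (cur / self.priors.beta_sd) ** 2
            )
            if math.log(rng.random()) < d:
                setattr(self, name, prop)
                accepted = 1.0
            else:
                accepted = 0.0
            if adapting:
                self.ls_beta[j] = float(
                    np.clip(
                        self.ls_beta[j]
                        + self._gamma(it) * (accepted - _TARGET_ACCEPT),
                        -8.0,
                        4.0,
                    )
                )

    # -- main loop -------------------------------------------------------------

    def _occupancy(self):
        occ = np.full((self.R, self.T), np.nan)
        for r in range(self.R):
            lo, hi = self.bounds[r], self.bounds[r + 1]
            if hi > lo:
                occ[r] = self.zf[lo:hi].mean(axis=0)
        return occ

    def run(self, iterations, burnin, thin, rng):
        self._init_state(rng)
        f = self.fixed
        n_keep = (iterations - burnin) // thin
        track_a_hyper = self.priors.a_prior in ("hierarchical", "rw")
        out = {
            "b": np.empty((n_keep, self.R, self.T)),
            "u": np.empty((n_keep, self.ns)),
            "a": np.empty((n_keep, self.T)),
            "beta1": np.empty(n_keep),
            "beta2": np.empty(n_keep),
            "sigma_u": np.empty(n_keep),
            "sigma_rw": np.empty(n_keep),
            "occ": np.empty((n_keep, self.R, self.T)),
        }
        if track_a_hyper:
            out["mu_a"] = np.empty(n_keep)
            out["sigma_a"] = np.empty(n_keep)

        k = 0
        for it in range(iterations):
            adapting = self.adapt and it < burnin
            self._update_z(rng)
            self._update_detstats()
            if "a" not in f:
                self._update_a(rng, adapting, it)
            self._update_betas(rng, adapting, it)
            if "b" not in f:
                self._update_b(rng, adapting, it)
            if "u" not in f:
                self._update_u(rng, adapting, it)
                if "sigma_u" not in f:
                    self._update_sigma_u(rng)
            if "b" not in f and "sigma_rw" not in f:
                self._update_sigma_rw(rng)

            if it >= burnin and (it - burnin) % thin == thin - 1:
                out["b"][k] = self.b
                out["u"][k] = self.u[self.inv]
                out["a"][k] = self.a
                out["beta1"][k] = self.beta1
                out["beta2"][k] = self.beta2
                out["sigma_u"][k] = self.sigma_u
                out["sigma_rw"][k] = self.sigma_rw
                out["occ"][k] = self._occupancy()
                if track_a_hyper:
                    out["mu_a"][k] = self.mu_a
                    out["sigma_a"][k] = self.sigma_a
                k += 1
        assert k == n_keep
        return out
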