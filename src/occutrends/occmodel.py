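"""Hierarchical Bayesian occupancy-detection model with regional year effects.

The model separates the ecological state from the observation process.
The state sub-model says site *i* is occupied in year *t* with probability
psi_it,

    z_it ~ Bernoulli(psi_it),      logit(psi_it) = b_{t, region(i)} + u_i,

where each cropland region (high / low / none) has its own year-effect
trajectory b_t and u_i is a site random effect with standard deviation
sigma_u.  The observation sub-model says a species present at a visited
site-year is detected on visit *v* with probability p_itv,

    y_itv | z_it ~ Bernoulli(p_itv * z_it),
    logit(p_itv) = a_t + beta1 * [short list] + beta2 * [long list],

so detectability depends on a year effect a_t and on the list-length
category of the visit (single species, 2-3, or >= 4).  A random-walk prior
links consecutive year effects b_t so occupancy changes smoothly; the walk
runs independently per region and is anchored by a wide prior on b_0.

Fitting is by MCMC (see ``_sampler``); convergence is judged with the
split-chain Gelman-Rubin statistic on the first- and last-year regional
occupancy, the quantities the trend estimates rest on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_expit
from sklearn.base import BaseEstimator

from ._sampler import ChainSampler, _b0_logpdf, _norm_logpdf, _sd_logpdf
from .records import DATATYPES
from .stratify import REGIONS


# ---------------------------------------------------------------------------
# data container


@dataclass
class ModelData:
    """Arrays consumed by the occupancy-detection model for one species.

    ``region`` codes each site into ``region_names``; the per-visit arrays
    give the site index, year index, list-length category code
    (0=single, 1=short, 2=long) and the binary detection outcome.
    """

    region: np.ndarray
    vsite: np.ndarray
    vyear: np.ndarray
    vdt: np.ndarray
    vy: np.ndarray
    n_years: int
    region_names: tuple = REGIONS
    site_ids: list | None = None

    def __post_init__(self):
        self.region = np.asarray(self.region, dtype=np.int64)
        self.vsite = np.asarray(self.vsite, dtype=np.int64)
        self.vyear = np.asarray(self.vyear, dtype=np.int64)
        self.vdt = np.asarray(self.vdt, dtype=np.int64)
        self.vy = np.asarray(self.vy, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return int(self.region.size)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_visits(self) -> int:
        return int(self.vsite.size)

    def validate(self):
        if self.n_sites == 0:
            raise ValueError("no sites")
        if self.region.min(initial=0) < 0 or (
            self.region.max(initial=0) >= self.n_regions
        ):
            raise ValueError("region codes outside region_names")
        if self.n_visits:
            if self.vsite.min() < 0 or self.vsite.max() >= self.n_sites:
                raise ValueError("visit site index out of range")
            if self.vyear.min() < 0 or self.vyear.max() >= self.n_years:
                raise ValueError("visit year index out of range")
            if not np.isin(self.vdt, [0, 1, 2]).all():
                raise ValueError("datatype codes must be 0, 1 or 2")
            if not np.isin(self.vy, [0, 1]).all():
                raise ValueError("detections must be 0/1")
            visited = np.zeros(self.n_sites, dtype=bool)
            visited[self.vsite] = True
            if not visited.all():
                raise ValueError("every site must have at least one visit")
        return self

    @classmethod
    def from_visits(
        cls,
        history: pd.DataFrame,
        site_regions,
        n_years: int,
        region_names: tuple = REGIONS,
    ) -> "ModelData":
        """Build from a detection-history table and a site -> region mapping.

        ``history`` needs columns ``site, year_index, datatype, y``.
        """
        regions = dict(site_regions)
        sites = sorted(history["site"].unique())
        missing = [s for s in sites if s not in regions]
        if missing:
            raise ValueError(f"unclassified sites: {missing[:5]}")
        code = {name: k for k, name in enumerate(region_names)}
        bad = sorted({regions[s] for s in sites} - set(region_names))
        if bad:
            raise ValueError(f"unknown region labels: {bad}")
        site_index = {s: k for k, s in enumerate(sites)}
        dt_code = {name: k for k, name in enumerate(DATATYPES)}
        data = cls(
            region=np.array([code[regions[s]] for s in sites]),
            vsite=history["site"].map(site_index).to_numpy(),
            vyear=history["year_index"].to_numpy(),
            vdt=history["datatype"].map(dt_code).to_numpy(),
            vy=history["y"].to_numpy(),
            n_years=int(n_years),
            region_names=tuple(region_names),
            site_ids=sites,
        )
        return data.validate()


# ---------------------------------------------------------------------------
# priors


@dataclass
class PriorConfig:
    """Prior configuration.

    The defaults follow the uninformative-prior convention common in
    occupancy modelling of recording-scheme data: wide zero-mean normals on
    logit-scale location parameters, half-normal priors on standard
    deviations, and a hierarchical normal on the detection year effect a_t
    (``a_prior`` may instead be ``"normal"`` for independent fixed-variance
    effects or ``"rw"`` for a random walk on a_t).  ``b0`` anchors the
    state random walk; the ``("logistic", loc, scale)`` option makes the
    implied prior on first-year occupancy uniform, which is what conjugate
    closed-form checks need.
    """

    b0: tuple = ("normal", 0.0, 10.0)
    a_prior: str = "hierarchical"
    a_sd: float = 10.0
    beta_sd: float = 10.0
    sigma_u_prior: tuple = ("halfnormal", 2.5)
    sigma_rw_prior: tuple = ("halfnormal", 1.0)
    sigma_a_prior: tuple = ("halfnormal", 2.5)

    def __post_init__(self):
        if self.a_prior not in ("hierarchical", "normal", "rw"):
            raise ValueError("a_prior must be hierarchical, normal or rw")


# ---------------------------------------------------------------------------
# logit link helpers (the model equations, exposed directly)


def state_logit(params: dict, data: ModelData, i: int, t: int) -> float:
    """logit occupancy of site *i* in year *t*: b of the site's own region + u_i."""
    r = int(data.region[i])
    if not 0 <= r < data.n_regions:
        raise ValueError(f"site {i} has unknown region code {r}")
    return float(params["b"][r, t] + params["u"][i])


def obs_logit(params: dict, t: int, datatype: str) -> float:
    """logit detection probability in year *t* for a list-length category."""
    offsets = {
        "single": 0.0,
        "short": float(params["beta1"]),
        "long": float(params["beta2"]),
    }
    if datatype not in offsets:
        raise ValueError(f"unknown datatype {datatype!r}")
    return float(params["a"][t] + offsets[datatype])


# ---------------------------------------------------------------------------
# reference posterior kernel


def _params_finite(params) -> bool:
    for v in params.values():
        if not np.all(np.isfinite(np.asarray(v, dtype=float))):
            return False
    return True


def log_posterior_kernel(
    params: dict,
    data: ModelData,
    priors: PriorConfig | None = None,
    z: np.ndarray | None = None,
) -> float:
    """Log posterior density kernel (reference implementation).

    With ``z`` supplied the data-augmented kernel is returned; without it
    the latent occupancy states are marginalised exactly: each site-year
    contributes

        psi * prod_v p^y (1-p)^(1-y)  +  (1-psi) * [all y = 0].

    Used as the ground truth the sampler is checked against; not on the
    sampling hot path.
    """
    priors = priors or PriorConfig()
    if not _params_finite(params):
        return -np.inf

    b = np.asarray(params["b"], dtype=float)
    u = np.asarray(params["u"], dtype=float)
    a = np.asarray(params["a"], dtype=float)
    beta1 = float(params["beta1"])
    beta2 = float(params["beta2"])
    sigma_u = float(params["sigma_u"])
    sigma_rw = float(params["sigma_rw"])
    if sigma_u <= 0 or sigma_rw <= 0:
        return -np.inf

    T = data.n_years
    lp = 0.0
    # state priors: anchored random walk per region, site effects
    lp += float(np.sum(_b0_logpdf(b[:, 0], priors.b0)))
    if T > 1:
        lp += float(np.sum(_norm_logpdf(np.diff(b, axis=1), sigma_rw)))
    lp += float(np.sum(_norm_logpdf(u, sigma_u)))
    lp += _sd_logpdf(sigma_u, priors.sigma_u_prior)
    lp += _sd_logpdf(sigma_rw, priors.sigma_rw_prior)
    # observation priors
    if priors.a_prior == "normal":
        lp += float(np.sum(_norm_logpdf(a, priors.a_sd)))
    elif priors.a_prior == "hierarchical":
        mu_a = float(params["mu_a"])
        sigma_a = float(params["sigma_a"])
        if sigma_a <= 0:
            return -np.inf
        lp += float(np.sum(_norm_logpdf(a - mu_a, sigma_a)))
        lp += float(_norm_logpdf(mu_a, priors.a_sd))
        lp += _sd_logpdf(sigma_a, priors.sigma_a_prior)
    else:  # random walk on a_t
        sigma_a = float(params["sigma_a"])
        if sigma_a <= 0:
            return -np.inf
        lp += float(_norm_logpdf(a[0], priors.a_sd))
        if T > 1:
            lp += float(np.sum(_norm_logpdf(np.diff(a), sigma_a)))
        lp += _sd_logpdf(sigma_a, priors.sigma_a_prior)
    lp += float(_norm_logpdf(beta1, priors.beta_sd))
    lp += float(_norm_logpdf(beta2, priors.beta_sd))

    n_sy = data.n_sites * T
    eta = b[data.region] + u[:, None]
    lpsi = log_expit(eta).reshape(-1)
    l1mpsi = log_expit(-eta).reshape(-1)

    if data.n_visits:
        beta_vec = np.array([0.0, beta1, beta2])
        eta_p = a[data.vyear] + beta_vec[data.vdt]
        obs_ll = np.where(
            data.vy == 1, log_expit(eta_p), log_expit(-eta_p)
        )
        sy = data.vsite * T + data.vyear
        det1 = np.bincount(sy, weights=obs_ll, minlength=n_sy)
        anydet = np.bincount(sy, weights=data.vy, minlength=n_sy) > 0
    else:
        det1 = np.zeros(n_sy)
        anydet = np.zeros(n_sy, dtype=bool)

    if z is not None:
        zf = np.asarray(z, dtype=float).reshape(-1)
        if np.any(anydet & (zf == 0)):
            return -np.inf  # a detection forces presence: y <= z
        lp += float(np.sum(zf * (lpsi + det1) + (1.0 - zf) * l1mpsi))
    else:
        occupied = lpsi + det1
        lp += float(
            np.sum(
                np.where(anydet, occupied, np.logaddexp(occupied, l1mpsi))
            )
        )
    return lp


# ---------------------------------------------------------------------------
# convergence


def gelman_rubin(chains) -> float:
    """Split-chain Gelman-Rubin statistic for one scalar quantity.

    ``chains`` is an (m, n) array of m chains with n draws each.  Each chain
    is split in half, the between- and within-chain variances compared.
    Returns NaN when the within-chain variance is zero everywhere (the
    statistic is undefined for degenerate chains).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    half = x.shape[1] // 2
    xs = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    w = xs.var(axis=1, ddof=1).mean()
    if w == 0.0:
        return float("nan")
    b_over_n = xs.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b_over_n
    return float(np.sqrt(var_plus / w))


def convergence_filter(reports, threshold: float = 1.1):
    """Split species into retained and flagged by first/last-year Rhat.

    ``reports`` is an iterable of dicts with keys ``species``,
    ``rhat_first`` and ``rhat_last``.  A species is retained iff both
    values are present, finite and below ``threshold``; anything else
    (including a missing Rhat) is flagged, never silently retained.
    """
    retained, flagged = [], []
    for rep in reports:
        first = rep.get("rhat_first")
        last = rep.get("rhat_last")
        ok = (
            first is not None
            and last is not None
            and np.isfinite(first)
            and np.isfinite(last)
            and first < threshold
            and last < threshold
        )
        (retained if ok else flagged).append(rep["species"])
    return retained, flagged


def retained_draws(chains: int, iterations: int, burnin: int, thin: int) -> int:
    """Number of posterior draws kept: chains x floor((iterations - burnin)/thin)."""
    if min(chains, iterations, thin) < 1 or burnin < 0 or burnin >= iterations:
        raise ValueError("invalid MCMC configuration")
    return chains * ((iterations - burnin) // thin)


# ---------------------------------------------------------------------------
# estimator


class OccupancyModel(BaseEstimator):
    """Bayesian occupancy-detection model fitted by blocked Gibbs/Metropolis MCMC.

    Parameters mirror the usual MCMC configuration: ``chains`` independent
    chains of ``iterations`` sweeps, the first ``burnin`` discarded, every
    ``thin``-th kept.  ``priors`` is a :class:`PriorConfig`; ``fixed`` maps
    parameter-block names (e.g. ``"u"``, ``"a"``, ``"beta1"``) to values
    held constant, which is how degenerate test configurations (perfect
    detection, no site effects) are expressed.

    Fitted attributes
    -----------------
    draws_ : dict of parameter name -> array with leading draw axis,
        ordered by (chain, iteration).
    chain_id_ : chain index per draw.
    occupancy_ : (S, n_regions, n_years) finite-sample occupancy per draw,
        the fraction of modelled sites in each region whose latent state is
        occupied.
    rhat_ : dict of split Gelman-Rubin statistics for the first- and
        last-year regional occupancy.
    """

    def __init__(
        self,
        chains: int = 3,
        iterations: int = 32000,
        burnin: int = 30000,
        thin: int = 6,
        seed: int | None = None,
        priors: PriorConfig | None = None,
        fixed: dict | None = None,
        adapt: bool = True,
    ):
        self.chains = chains
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.seed = seed
        self.priors = priors
        self.fixed = fixed
        self.adapt = adapt

    def fit(self, X: ModelData, y=None):
        data = X.validate()
        n_keep = retained_draws(self.chains, self.iterations, self.burnin, self.thin)
        priors = self.priors or PriorConfig()
        ss = np.random.SeedSequence(0 if self.seed is None else int(self.seed))
        children = ss.spawn(self.chains)

        per_chain = []
        for c in range(self.chains):
            rng = np.random.default_rng(children[c])
            sampler = ChainSampler(data, priors, fixed=self.fixed, adapt=self.adapt)
            per_chain.append(
                sampler.run(self.iterations, self.burnin, self.thin, rng)
            )

        self.draws_ = {
            k: np.concatenate([d[k] for d in per_chain], axis=0)
            for k in per_chain[0]
        }
        s_chain = per_chain[0]["occ"].shape[0]
        self.chain_id_ = np.repeat(np.arange(self.chains), s_chain)
        self.occupancy_ = self.draws_["occ"]
        self.n_draws_ = self.occupancy_.shape[0]
        assert self.n_draws_ == n_keep

        self.rhat_ = {}
        T = data.n_years
        for r, name in enumerate(data.region_names):
            if not np.any(data.region == r):
                continue
            for label, t in (("first", 0), ("last", T - 1)):
                series = self.occupancy_[:, r, t].reshape(self.chains, s_chain)
                if self.chains >= 2 and s_chain >= 4:
                    value = gelman_rubin(series)
                else:
                    value = float("nan")  # undiagnosable with one chain
                self.rhat_[f"occ_{name}_{label}"] = value
        firsts = [v for k, v in self.rhat_.items() if k.endswith("_first")]
        lasts = [v for k, v in self.rhat_.items() if k.endswith("_last")]
        self.rhat_occ_first_ = _max_or_nan(firsts)
        self.rhat_occ_last_ = _max_or_nan(lasts)
        self.data_ = data
        return self

    def occupancy_summary(self) -> pd.DataFrame:
        """Posterior median and mean of regional occupancy per year."""
        from .indicators import hdi

        rows = []
        data = self.data_
        for r, name in enumerate(data.region_names):
            if not np.any(data.region == r):
                continue
            for t in range(data.n_years):
                draws = self.occupancy_[:, r, t]
                lo, hi = hdi(draws)
                rows.append(
                    {
                        "region": name,
                        "year_index": t,
                        "mean": float(draws.mean()),
                        "median": float(np.median(draws)),
                        "hdi_lower": lo,
                        "hdi_upper": hi,
                    }
                )
        return pd.DataFrame(rows)

    def draws_frame(self, parameters=("occ",)) -> pd.DataFrame:
        """Long-format ``chain, draw, parameter, value`` table of draws."""
        frames = []
        for name in parameters:
            arr = self.draws_[name]
            flat = arr.reshape(arr.shape[0], -1)
            idx = [
                "[" + ",".join(map(str, ix)) + "]" if arr.ndim > 1 else ""
                for ix in np.ndindex(*arr.shape[1:])
            ] or [""]
            for j, suffix in enumerate(idx):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": self.chain_id_,
                            "draw": np.arange(flat.shape[0]),
                            "parameter": name + suffix,
                            "value": flat[:, j] if flat.ndim > 1 else flat,
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def _max_or_nan(values):
    finite = [v for v in values if np.isfinite(v)]
    if not values:
        return float("nan")
    if len(finite) < len(values):
        return float("nan")
    return float(max(finite))


def sample_posterior(data: ModelData, mcmc: dict) -> OccupancyModel:
    """Fit :class:`OccupancyModel` from a plain MCMC config dict."""
    model = OccupancyModel(
        chains=mcmc.get("chains", 3),
        iterations=mcmc.get("iterations", 32000),
        burnin=mcmc.get("burnin", 30000),
        thin=mcmc.get("thin", 6),
        seed=mcmc.get("seed"),
        priors=mcmc.get("priors"),
        fixed=mcmc.get("fixed"),
    )
    return model.fit(data)
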