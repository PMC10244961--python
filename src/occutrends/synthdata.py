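"""Synthetic landscapes, occupancy dynamics and opportunistic recording data.

Generates datasets with known ground truth that emulate the structure of
citizen-science recording: a landscape of 1 km cells stratified by cropland
cover, latent Bernoulli occupancy per species/site/year whose logit-scale
year effects follow a prescribed geometric trend per region, recorder
visits of varying list length, and imperfect detection that depends on the
list-length category.  Detected species are written as presence-only
records — non-detections are never written, so the records module has to
infer them, exactly as with real recording-scheme data.

Every generated dataset is accompanied by a :class:`TruthLedger` holding
the generating parameters and latent states, from which all derived "true"
quantities (regional occupancy, growth rates, effect sizes) can be
recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import indicators
from .stratify import REGIONS

_LL_PROBS = (0.25, 0.35, 0.40)


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe a moderate recovery scenario: three regions of 60
    sites, 15 species over 20 years, initial occupancy 0.4 everywhere,
    declines of 5 and 2% per year in the high- and low-cropland regions and
    a flat trend outside cropland, and modest site and species
    heterogeneity.  Recording mirrors the large-group regime of real
    schemes, where any focal species is a small fraction of each list:
    per-visit detection probabilities are low (0.10 / 0.20 / 0.33 for
    single / short / long lists) and information accrues over roughly five
    visits per site-year, giving a per-site-year detection probability of
    about 0.7 at an occupied site.
    """

    n_sites: dict = field(
        default_factory=lambda: {"high": 60, "low": 60, "none": 60}
    )
    n_species: int = 15
    first_year: int = 2000
    last_year: int = 2019
    initial_occupancy: dict = field(
        default_factory=lambda: {"high": 0.4, "low": 0.4, "none": 0.4}
    )
    growth_pct: dict = field(
        default_factory=lambda: {"high": -5.0, "low": -2.0, "none": 0.0}
    )
    species_logit_sd: float = 0.25
    sigma_u: float = 0.3
    detection_base: float = 0.1
    beta1: float = 0.8
    beta2: float = 1.5
    visits_per_site_year: float = 5.0
    list_length_probs: tuple = _LL_PROBS
    n_background: int = 40
    taxon_group: str = "synthgroup"
    seed: int = None  # mandatory
    n_change_violations: int = 0
    n_incomparable_violations: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for a reproducible scenario")
        if self.last_year <= self.first_year:
            raise ValueError("study window must span at least two years")
        for r, p in self.initial_occupancy.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"initial occupancy for {r} outside (0,1)")
        for r, g in self.growth_pct.items():
            if g <= -100.0:
                raise ValueError(f"growth for {r} must exceed -100%/yr")
        if abs(sum(self.list_length_probs) - 1.0) > 1e-9:
            raise ValueError("list-length probabilities must sum to 1")

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    @property
    def regions(self) -> tuple:
        return tuple(r for r in REGIONS if self.n_sites.get(r, 0) > 0)


@dataclass
class TruthLedger:
    """Ground truth of a generated scenario; every derived quantity is
    recomputable from the latent states ``z``."""

    b: np.ndarray  # (n_regions, n_years) logit of target occupancy
    species_offset: np.ndarray  # (n_species,)
    u: np.ndarray  # (n_species, n_sites)
    z: np.ndarray  # (n_species, n_sites, n_years) bool
    region: np.ndarray  # (n_sites,) codes into region_names
    site_ids: list
    region_names: tuple
    years: np.ndarray
    species_ids: list

    def occupancy(self) -> np.ndarray:
        """Realised per-region occupancy: (n_species, n_regions, n_years)."""
        S, _, T = self.z.shape
        out = np.empty((S, len(self.region_names), T))
        for r in range(len(self.region_names)):
            sites = self.region == r
            out[:, r, :] = self.z[:, sites, :].mean(axis=1)
        return out

    def species_growth(self) -> np.ndarray:
        """Realised annual growth per species and region (% per year)."""
        occ = self.occupancy()
        n_sites_r = np.array(
            [(self.region == r).sum() for r in range(len(self.region_names))]
        )
        occ = indicators.floor_occupancy(occ, n_sites_r[None, :, None])
        y = len(self.years) - 1
        return indicators.growth_rate(occ[:, :, 0], occ[:, :, -1], y)

    def group_growth(self) -> np.ndarray:
        """Realised group-level growth per region (% per year)."""
        gr = self.species_growth()  # (S, R)
        return indicators.multi_species_growth(gr, axis=0)

    def effect_size(self, region_a: str = "high", region_b: str = "low") -> float:
        gg = self.group_growth()
        ia = self.region_names.index(region_a)
        ib = self.region_names.index(region_b)
        return float(gg[ia] - gg[ib])


def _site_ids(cfg: ScenarioConfig) -> tuple[list, np.ndarray]:
    ids, codes = [], []
    for r, name in enumerate(cfg.regions):
        for k in range(cfg.n_sites[name]):
            ids.append(f"{name}_{k:03d}")
            codes.append(r)
    return ids, np.asarray(codes, dtype=np.int64)


def gen_landscape(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Long-format cover table whose classification reproduces the scenario.

    Non-violating cells are constructed so the stratification filters keep
    them and the region classifier returns the requested label; the
    configured numbers of violating cells (cropland change > 10 points, or
    an incomparable class above 25%) are appended with ``viol_`` site ids so
    exclusion logic can be exercised without disturbing the region counts.
    """
    site_ids, codes = _site_ids(cfg)
    rows = []

    def add_cell(site, crop_early, crop_late, wetland=None):
        for epoch, crop in (("early", crop_early), ("late", crop_late)):
            wet = float(wetland) if wetland is not None else rng.uniform(0, 8)
            built = rng.uniform(0, 8)
            rest = 100.0 - crop - wet - built
            grass = rest * rng.uniform(0.3, 0.7)
            wood = rest - grass
            rows.extend(
                {
                    "site": site,
                    "epoch": epoch,
                    "class": cls,
                    "percent": pct,
                }
                for cls, pct in (
                    ("cropland", crop),
                    ("grassland", grass),
                    ("woodland", wood),
                    ("wetland", wet),
                    ("built_up", built),
                )
            )

    for site, code in zip(site_ids, codes):
        name = cfg.regions[code]
        if name == "none":
            late = 0.0
        elif name == "low":
            late = rng.uniform(2.0, 50.0)
        else:
            late = rng.uniform(50.5, 84.0)
        early = 0.0 if name == "none" else float(
            np.clip(late + rng.uniform(-8.0, 8.0), 0.1, 100.0)
        )
        add_cell(site, early, late)

    for k in range(cfg.n_change_violations):
        late = rng.uniform(25.0, 60.0)
        add_cell(f"viol_change_{k:03d}", late + 20.0, late)
    for k in range(cfg.n_incomparable_violations):
        late = rng.uniform(5.0, 40.0)
        add_cell(f"viol_incomp_{k:03d}", late, late, wetland=40.0)

    return pd.DataFrame(rows)


def gen_dynamics(cfg: ScenarioConfig, rng: np.random.Generator) -> TruthLedger:
    """Latent occupancy dynamics with the requested per-region trends.

    The shared region trajectories satisfy expit(b[r, t]) =
    psi0 * (1 + growth/100)**t; species get a logit-scale offset and each
    species x site pair an independent site effect, and the latent states
    are Bernoulli draws from the resulting probabilities.
    """
    site_ids, codes = _site_ids(cfg)
    T = cfg.n_years
    R = len(cfg.regions)
    t = np.arange(T)
    psi = np.empty((R, T))
    for r, name in enumerate(cfg.regions):
        traj = cfg.initial_occupancy[name] * (
            1.0 + cfg.growth_pct[name] / 100.0
        ) ** t
        if np.any((traj <= 0.0) | (traj >= 1.0)):
            raise ValueError(
                f"occupancy trajectory for region {name!r} leaves (0, 1)"
            )
        psi[r] = traj
    b = logit(psi)

    S = cfg.n_species
    offsets = rng.normal(0.0, cfg.species_logit_sd, size=S)
    u = rng.normal(0.0, cfg.sigma_u, size=(S, len(site_ids)))
    eta = (
        b[codes][None, :, :] + offsets[:, None, None] + u[:, :, None]
    )  # (S, n_sites, T)
    z = rng.random(eta.shape) < expit(eta)

    return TruthLedger(
        b=b,
        species_offset=offsets,
        u=u,
        z=z,
        region=codes,
        site_ids=site_ids,
        region_names=cfg.regions,
        years=np.arange(cfg.first_year, cfg.last_year + 1),
        species_ids=[f"sp{k:02d}" for k in range(S)],
    )


def gen_records(
    truth: TruthLedger,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    return_visits: bool = False,
):
    """Presence-only occurrence records from the latent states.

    Visit counts per site-year are Poisson; visit dates within a year are
    sampled without replacement so site/date pairs are unique; each visit
    carries a list-length category drawn from the configured distribution,
    which sets the per-species detection probability of the focal
    (modelled) species.  As in real scheme data, a visit only exists
    because records exist: recordings of a background pool of non-modelled
    group members pad every list up to its category, so the list-length
    covariate is effectively exogenous to any focal species and every
    visit yields at least one record (``n_background = 0`` disables the
    padding, leaving visits without detections unrecorded).  Only
    detections are written out.  With ``return_visits=True`` the full
    visit table is returned as well — useful for checking the generator,
    unavailable for real data.
    """
    n_sites = len(truth.site_ids)
    T = cfg.n_years
    counts = rng.poisson(cfg.visits_per_site_year, size=(n_sites, T))
    counts = np.minimum(counts, 200)

    vsite, vyear, vday = [], [], []
    for i in range(n_sites):
        for t in range(T):
            c = int(counts[i, t])
            if c == 0:
                continue
            days = rng.choice(365, size=min(c, 365), replace=False)
            vsite.extend([i] * len(days))
            vyear.extend([t] * len(days))
            vday.extend(days.tolist())
    vsite = np.asarray(vsite, dtype=np.int64)
    vyear = np.asarray(vyear, dtype=np.int64)
    vday = np.asarray(vday, dtype=np.int64)
    n_visits = vsite.size

    dt = rng.choice(3, size=n_visits, p=np.asarray(cfg.list_length_probs))
    base = logit(cfg.detection_base)
    p_by_dt = expit(base + np.array([0.0, cfg.beta1, cfg.beta2]))
    p_visit = p_by_dt[dt]

    z_at_visit = truth.z[:, vsite, vyear]  # (S, n_visits)
    detected = z_at_visit & (
        rng.random(z_at_visit.shape) < p_visit[None, :]
    )

    dates = (
        pd.to_datetime(
            {
                "year": truth.years[vyear],
                "month": np.ones(n_visits, dtype=int),
                "day": np.ones(n_visits, dtype=int),
            }
        )
        + pd.to_timedelta(vday, unit="D")
    ).dt.strftime("%Y-%m-%d")

    date_arr = dates.to_numpy()
    bg_species, bg_sites, bg_dates = [], [], []

    if cfg.n_background > 0 and n_visits:
        # the list-length category is an effort level: the recorded list
        # holds its target number of species (unbounded only for "long").
        # Detected focal species beyond the target go unrecorded — the
        # recorder stopped — and background group members pad shorter lists
        # up to the target, so the recorded list realises its category and
        # every visit leaves records.
        target = np.select(
            [dt == 0, dt == 1],
            [1, rng.integers(2, 4, size=n_visits)],
            default=rng.integers(4, 7, size=n_visits),
        )
        n_focal = detected.sum(axis=0)
        for v in np.nonzero((dt < 2) & (n_focal > target))[0]:
            hits = np.nonzero(detected[:, v])[0]
            drop = rng.choice(hits, size=hits.size - int(target[v]), replace=False)
            detected[drop, v] = False
        n_bg = np.clip(target - detected.sum(axis=0), 0, cfg.n_background)
        for v in np.nonzero(n_bg)[0]:
            picks = rng.choice(cfg.n_background, size=int(n_bg[v]), replace=False)
            for k in picks:
                bg_species.append(f"bg{k:02d}")
                bg_sites.append(truth.site_ids[vsite[v]])
                bg_dates.append(date_arr[v])

    sp_idx, visit_idx = np.nonzero(detected)
    species_col = [truth.species_ids[s] for s in sp_idx] + bg_species
    site_col = [truth.site_ids[i] for i in vsite[visit_idx]] + bg_sites
    date_col = list(date_arr[visit_idx]) + bg_dates

    records = pd.DataFrame(
        {
            "species": species_col,
            "group": cfg.taxon_group,
            "site": site_col,
            "date": date_col,
            "spatial_precision_m": 1000,
            "temporal_precision": "day",
        }
    )
    records = records.sort_values(
        ["site", "date", "species"], kind="stable"
    ).reset_index(drop=True)

    if return_visits:
        visits = pd.DataFrame(
            {
                "site": [truth.site_ids[i] for i in vsite],
                "year_index": vyear,
                "date": dates,
                "datatype_generated": dt,
                "p_detect": p_visit,
            }
        )
        return records, visits
    return records


@dataclass
class SyntheticDataset:
    records: pd.DataFrame
    cover: pd.DataFrame
    truth: TruthLedger
    config: ScenarioConfig


def generate_scenario(cfg: ScenarioConfig) -> SyntheticDataset:
    """Full scenario: landscape, dynamics and records, all from one seed."""
    root = np.random.SeedSequence(int(cfg.seed))
    rl, rd, rr = (np.random.default_rng(s) for s in root.spawn(3))
    cover = gen_landscape(cfg, rl)
    truth = gen_dynamics(cfg, rd)
    records = gen_records(truth, cfg, rr)
    return SyntheticDataset(records=records, cover=cover, truth=truth, config=cfg)


def write_scenario(ds: SyntheticDataset, outdir) -> None:
    """Write records, cover tables and the truth ledger as plain text."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.records.to_csv(out / "records.csv", index=False)
    ds.cover.to_csv(out / "cover.csv", index=False)

    truth = ds.truth
    occ = truth.occupancy()
    rows = []
    for s, sp in enumerate(truth.species_ids):
        for r, name in enumerate(truth.region_names):
            for t, year in enumerate(truth.years):
                rows.append(
                    {
                        "species": sp,
                        "region": name,
                        "year": int(year),
                        "true_occupancy": occ[s, r, t],
                    }
                )
    pd.DataFrame(rows).to_csv(out / "truth_occupancy.csv", index=False)
    gg = truth.group_growth()
    pd.DataFrame(
        {"region": list(truth.region_names), "true_group_growth": gg}
    ).to_csv(out / "truth_group_growth.csv", index=False)
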