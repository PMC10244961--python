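"""End-to-end orchestration: records -> stratification -> model fits -> indicators.

The stages run in the order the analysis dictates: standardise records,
build visits and detection histories, classify sites into cropland regions,
drop visits at excluded sites, filter species expected to give imprecise
estimates, fit the occupancy-detection model per species, assess
convergence, and derive multi-species indicators, growth rates and
between-region effect sizes with draw-wise uncertainty propagation.
Summaries are always computed from draw vectors, never from summarised
inputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import indicators as ind
from .occmodel import ModelData, OccupancyModel, PriorConfig, convergence_filter
from .records import detection_matrix, standardize_records
from .stratify import REGIONS, classify_sites, region_summary

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    first_year: int = 1990
    last_year: int = 2019
    seed: int = 0
    cleaning: dict = field(default_factory=dict)
    stratify: dict = field(default_factory=dict)
    mcmc: dict = field(
        default_factory=lambda: {
            "chains": 3,
            "iterations": 32000,
            "burnin": 30000,
            "thin": 6,
        }
    )
    rule_of_thumb: dict = field(default_factory=dict)
    species_subset: list | None = None
    apply_convergence_filter: bool = False
    rhat_threshold: float = 1.1
    hdi_mass: float = 0.95

    def __post_init__(self):
        if self.last_year < self.first_year:
            raise ValueError("last_year before first_year")
        mc = self.mcmc
        if mc.get("burnin", 0) >= mc.get("iterations", 1):
            raise ValueError("burnin must be smaller than iterations")

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        """Build from a config mapping, ignoring unrelated sections
        (e.g. a ``scenario`` block consumed by the synthetic generator)."""
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def resolved(self) -> dict:
        out = {
            "first_year": self.first_year,
            "last_year": self.last_year,
            "seed": self.seed,
            "cleaning": dict(self.cleaning),
            "stratify": dict(self.stratify),
            "mcmc": {k: v for k, v in self.mcmc.items() if k != "priors"},
            "rule_of_thumb": dict(self.rule_of_thumb),
            "species_subset": (
                None if self.species_subset is None else list(self.species_subset)
            ),
            "apply_convergence_filter": self.apply_convergence_filter,
            "rhat_threshold": self.rhat_threshold,
            "hdi_mass": self.hdi_mass,
        }
        priors = self.mcmc.get("priors")
        if priors is not None:
            if isinstance(priors, PriorConfig):
                out["mcmc"]["priors"] = vars(priors)
            else:
                out["mcmc"]["priors"] = dict(priors)
        return out

    def prior_config(self) -> PriorConfig | None:
        priors = self.mcmc.get("priors")
        if priors is None or isinstance(priors, PriorConfig):
            return priors
        kw = {
            k: tuple(v) if isinstance(v, list) else v for k, v in priors.items()
        }
        return PriorConfig(**kw)


def species_seed(master_seed: int, species: str) -> int:
    """Deterministic per-species seed below 2**31, independent of fit order."""
    h = zlib.crc32(species.encode("utf8"))
    return int((int(master_seed) * 1000003 + h) % (2**31 - 1))


def species_visit_join(visits: pd.DataFrame, classification: pd.DataFrame):
    """Attach region labels to visits; drop visits at excluded sites.

    Returns ``(kept_row_mask, site_region_map, n_dropped)``.  Sites absent
    from the classification table abort with the offending ids.
    """
    regions = classification.set_index("site")["region"].to_dict()
    sites = visits["site"]
    unknown = sorted(set(sites) - set(regions))
    if unknown:
        raise ValueError(f"unclassified sites in visits: {unknown[:10]}")
    region_of = sites.map(regions)
    keep = (region_of != "excluded").to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d visits at excluded sites", n_dropped)
    site_region = {
        s: r for s, r in regions.items() if r != "excluded"
    }
    return keep, site_region, n_dropped


@dataclass
class GroupResult:
    """Draw-level and summary results for one taxonomic group."""

    group: str
    region_names: tuple
    species: list
    occ_draws: np.ndarray  # (n_species, S, R, T), floored
    index_draws: np.ndarray  # (S, R, T)
    species_growth_draws: np.ndarray  # (n_species, S, R)
    group_growth_draws: np.ndarray  # (S, R)
    effect: ind.EffectSize | None
    convergence: list  # per-species dicts
    report: dict


def _fit_group(
    group: str,
    records: pd.DataFrame,
    classification: pd.DataFrame,
    cfg: RunConfig,
) -> GroupResult:
    visits, mat = detection_matrix(records, first_year=cfg.first_year)
    if len(visits) == 0:
        raise RuntimeError(f"group {group!r}: no visits after cleaning")
    keep, site_region, n_dropped = species_visit_join(visits, classification)
    visits = visits.loc[keep].reset_index(drop=True)
    mat = mat.loc[keep].reset_index(drop=True)
    if len(visits) == 0:
        raise RuntimeError(f"group {group!r}: all visits at excluded sites")

    kept_sites = set(visits["site"])
    recs_kept = records[records["site"].isin(kept_sites)]
    summaries = ind.species_summaries(recs_kept)
    retained = ind.rule_of_thumb_filter(summaries, **cfg.rule_of_thumb)
    species = sorted(retained.index[retained])
    if cfg.species_subset is not None:
        # all group records still build visits and inferred non-detections;
        # occupancy models are fitted for the requested species only
        species = [sp for sp in species if sp in set(cfg.species_subset)]
    n_cleaned = int(summaries.shape[0])

    present = {site_region[s] for s in kept_sites}
    region_names = tuple(r for r in REGIONS if r in present)
    T = cfg.n_years

    priors = cfg.prior_config()
    occ_list, convergence = [], []
    for sp in species:
        history = visits.assign(y=mat[sp].to_numpy().astype(int))
        data = ModelData.from_visits(
            history, site_region, n_years=T, region_names=region_names
        )
        model = OccupancyModel(
            chains=cfg.mcmc.get("chains", 3),
            iterations=cfg.mcmc.get("iterations", 32000),
            burnin=cfg.mcmc.get("burnin", 30000),
            thin=cfg.mcmc.get("thin", 6),
            seed=species_seed(cfg.seed, sp),
            priors=priors,
        ).fit(data)
        occ_list.append(model.occupancy_)
        convergence.append(
            {
                "species": sp,
                "rhat_first": model.rhat_occ_first_,
                "rhat_last": model.rhat_occ_last_,
            }
        )
        log.info(
            "fitted %s/%s: Rhat(first)=%.3f Rhat(last)=%.3f",
            group,
            sp,
            model.rhat_occ_first_,
            model.rhat_occ_last_,
        )

    converged, flagged = convergence_filter(convergence, cfg.rhat_threshold)
    modelled = species
    if cfg.apply_convergence_filter:
        idx = [i for i, sp in enumerate(species) if sp in set(converged)]
        if not idx:
            raise RuntimeError(f"group {group!r}: no species converged")
        modelled = [species[i] for i in idx]
        occ_list = [occ_list[i] for i in idx]

    occ = np.stack(occ_list)  # (n_species, S, R, T)
    n_sites_r = np.array(
        [sum(1 for s in kept_sites if site_region[s] == r) for r in region_names]
    )
    occ = ind.floor_occupancy(occ, n_sites_r[None, None, :, None])

    index_draws = ind.occupancy_index(occ, species_axis=0)  # (S, R, T)
    y_steps = T - 1
    sp_growth = ind.growth_rate(occ[:, :, :, 0], occ[:, :, :, -1], y_steps)
    group_growth = ind.multi_species_growth(sp_growth, axis=0)  # (S, R)

    effect = None
    if "high" in region_names and "low" in region_names:
        ih = region_names.index("high")
        il = region_names.index("low")
        effect = ind.effect_size(
            group_growth[:, ih], group_growth[:, il], mass=cfg.hdi_mass
        )

    report = {
        "n_species_cleaned": n_cleaned,
        "n_species_rule_of_thumb": len(species),
        "n_species_converged": len(converged),
        "n_species_modelled": len(modelled),
        "species_modelled": modelled,
        "species_flagged_nonconverged": flagged,
        "visits_dropped_excluded_sites": n_dropped,
        "n_visits": int(len(visits)),
        "growth": {
            r: ind.summarize(group_growth[:, k], mass=cfg.hdi_mass)
            for k, r in enumerate(region_names)
        },
    }
    if effect is not None:
        report["effect_size_high_low"] = {
            "median": effect.median,
            "hdi_lower": effect.hdi_lower,
            "hdi_upper": effect.hdi_upper,
            "prob_below_zero": effect.prob_below_zero,
        }

    return GroupResult(
        group=group,
        region_names=region_names,
        species=modelled,
        occ_draws=occ,
        index_draws=index_draws,
        species_growth_draws=sp_growth,
        group_growth_draws=group_growth,
        effect=effect,
        convergence=convergence,
        report=report,
    )


@dataclass
class RunResult:
    report: dict
    groups: dict  # group name -> GroupResult
    cleaned: pd.DataFrame
    classification: pd.DataFrame


def run(
    cfg: RunConfig,
    records: pd.DataFrame,
    cover: pd.DataFrame,
    output_dir=None,
) -> RunResult:
    """Execute the full pipeline on in-memory tables.

    With ``output_dir`` set, stage outputs (cleaned records, classification,
    per-species occupancy draws, indicator tables) and a machine-readable
    ``report.json`` are written there.
    """
    cleaned, clean_report = standardize_records(
        records,
        first_year=cfg.first_year,
        last_year=cfg.last_year,
        **cfg.cleaning,
    )
    classification = classify_sites(cover, **cfg.stratify)
    strat = region_summary(classification)

    groups = {}
    for group in sorted(cleaned["group"].unique()):
        recs = cleaned[cleaned["group"] == group]
        groups[group] = _fit_group(group, recs, classification, cfg)

    report = {
        "config": cfg.resolved(),
        "cleaning": clean_report,
        "stratification": {
            "counts": dict(zip(strat["region"], strat["count"].astype(int))),
            "shares_pct": dict(
                zip(strat["region"], strat["share_pct"].round(6))
            ),
            "n_excluded": int((classification["region"] == "excluded").sum()),
        },
        "groups": {g: r.report for g, r in groups.items()},
    }

    result = RunResult(
        report=report, groups=groups, cleaned=cleaned,
        classification=classification,
    )
    if output_dir is not None:
        _write_outputs(result, cfg, Path(output_dir))
    return result


def _write_outputs(result: RunResult, cfg: RunConfig, out: Path):
    (out / "cleaned").mkdir(parents=True, exist_ok=True)
    (out / "stratify").mkdir(exist_ok=True)
    (out / "indicators").mkdir(exist_ok=True)
    result.cleaned.to_csv(out / "cleaned" / "records.csv", index=False)
    result.classification.to_csv(
        out / "stratify" / "classification.csv", index=False
    )
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg.resolved(), fh)

    idx_rows, gr_rows, eff_rows, sum_rows = [], [], [], []
    for gname, g in result.groups.items():
        fits = out / "fits" / gname
        fits.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(g.convergence).to_csv(fits / "convergence.csv", index=False)
        S = g.index_draws.shape[0]
        for k, region in enumerate(g.region_names):
            for t in range(g.index_draws.shape[2]):
                idx_rows.append(
                    pd.DataFrame(
                        {
                            "group": gname,
                            "region": region,
                            "year": cfg.first_year + t,
                            "draw": np.arange(S),
                            "index_value": g.index_draws[:, k, t],
                        }
                    )
                )
            gr_rows.append(
                pd.DataFrame(
                    {
                        "group": gname,
                        "region": region,
                        "draw": np.arange(S),
                        "growth_rate": g.group_growth_draws[:, k],
                    }
                )
            )
            sum_rows.append(
                {
                    "group": gname,
                    "region": region,
                    "quantity": "growth_rate",
                    **ind.summarize(g.group_growth_draws[:, k], cfg.hdi_mass),
                }
            )
        if g.effect is not None:
            eff_rows.append(
                pd.DataFrame(
                    {
                        "group": gname,
                        "draw": np.arange(g.effect.draws.size),
                        "effect_size": g.effect.draws,
                    }
                )
            )
            sum_rows.append(
                {
                    "group": gname,
                    "region": "high-low",
                    "quantity": "effect_size",
                    "median": g.effect.median,
                    "hdi_lower": g.effect.hdi_lower,
                    "hdi_upper": g.effect.hdi_upper,
                }
            )
    pd.concat(idx_rows, ignore_index=True).to_csv(
        out / "indicators" / "index_draws.csv", index=False
    )
    pd.concat(gr_rows, ignore_index=True).to_csv(
        out / "indicators" / "growth_draws.csv", index=False
    )
    if eff_rows:
        pd.concat(eff_rows, ignore_index=True).to_csv(
            out / "indicators" / "effect_draws.csv", index=False
        )
    pd.DataFrame(sum_rows).to_csv(
        out / "indicators" / "summary.csv", index=False
    )
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
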