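"""Multi-species indicators, growth rates, effect sizes and credible intervals.

All derived quantities are computed draw-wise on the posterior samples and
only summarised (median, 95% highest-density interval) at the very end, so
the uncertainty of every species-level model propagates into the
group-level statements.

The annual growth rate between first-year occupancy ``s`` and last-year
occupancy ``f`` over ``y`` annual steps is

    growth = ((f / s)**(1 / y) - 1) * 100     [% per year],

the annualised multiplier that compounds ``s`` to ``f`` exactly.  Group
trends aggregate species either as the geometric mean of annual occupancy
(the occupancy indicator) or as the geometric mean of per-species annual
multipliers ``1 + growth/100``; the two routes agree algebraically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def geometric_mean(values, axis=None):
    """exp(mean(log(values))); all values must be strictly positive."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("geometric mean of an empty set")
    if np.any(v <= 0):
        raise ValueError(
            "geometric mean requires positive values; apply a zero floor first"
        )
    return np.exp(np.mean(np.log(v), axis=axis))


def growth_rate(s, f, y):
    """Annual percentage growth rate mapping occupancy ``s`` to ``f`` in ``y`` steps.

    ``s`` must be positive (zero initial occupancy leaves the rate
    undefined); ``f = 0`` yields -100.  Vectorised over ``s`` and ``f``.
    """
    s_arr = np.asarray(s, dtype=float)
    f_arr = np.asarray(f, dtype=float)
    if y < 1:
        raise ValueError("y must be >= 1")
    if np.any(s_arr <= 0):
        raise ValueError("growth rate undefined for non-positive initial occupancy")
    if np.any(f_arr < 0):
        raise ValueError("final occupancy must be non-negative")
    out = ((f_arr / s_arr) ** (1.0 / y) - 1.0) * 100.0
    if np.isscalar(s) and np.isscalar(f):
        return float(out)
    return out


def multi_species_growth(growth_draws, axis=0):
    """Group growth per draw: geometric mean of per-species annual multipliers.

    ``growth_draws`` has species along ``axis`` (default: rows are species,
    columns are posterior draws).  Species whose multiplier ``1 + gr/100``
    is non-positive in a draw (growth <= -100, i.e. collapse to zero) are
    excluded from that draw with a log entry.
    """
    gr = np.asarray(growth_draws, dtype=float)
    mult = 1.0 + gr / 100.0
    bad = mult <= 0
    if bad.any():
        log.warning(
            "excluding %d species-draw multipliers <= 0 from group growth",
            int(bad.sum()),
        )
        mult = np.where(bad, np.nan, mult)
    with np.errstate(invalid="ignore"):
        group = np.exp(np.nanmean(np.log(mult), axis=axis)) - 1.0
    return group * 100.0


@dataclass
class EffectSize:
    """Draw-wise difference of growth rates between two regions."""

    draws: np.ndarray
    median: float
    hdi_lower: float
    hdi_upper: float
    prob_below_zero: float


def effect_size(growth_high, growth_low, mass: float = 0.95) -> EffectSize:
    """Paired draw-wise difference high - low with its posterior summary.

    Negative values mean the decline is stronger in the high-cropland
    region.  ``prob_below_zero`` is the fraction of draws strictly below 0.
    """
    high = np.asarray(growth_high, dtype=float)
    low = np.asarray(growth_low, dtype=float)
    if high.shape != low.shape:
        raise ValueError("draw vectors must be paired (equal length)")
    draws = high - low
    lo, hi = hdi(draws, mass=mass)
    return EffectSize(
        draws=draws,
        median=float(np.median(draws)),
        hdi_lower=lo,
        hdi_upper=hi,
        prob_below_zero=float(np.mean(draws < 0.0)),
    )


def hdi(draws, mass: float = 0.95):
    """Shortest interval containing ``mass`` of the empirical draws."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 draws for a stable HDI")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize(draws, mass: float = 0.95) -> dict:
    """Median and HDI of a draw vector as a plain dict."""
    lo, hi = hdi(draws, mass=mass)
    return {
        "median": float(np.median(np.asarray(draws, dtype=float))),
        "hdi_lower": lo,
        "hdi_upper": hi,
    }


def floor_occupancy(occ, n_sites_region):
    """Floor zero occupancy draws at half the smallest observable value.

    With a finite number of sites a draw can put zero occupied sites in a
    region, where the geometric mean and the growth rate are undefined.
    Such draws are floored at 1 / (2 * n_sites) of the region, below any
    non-zero observable occupancy; the number of floored entries is logged.
    """
    occ = np.asarray(occ, dtype=float).copy()
    floor = 1.0 / (2.0 * np.asarray(n_sites_region, dtype=float))
    floored = occ <= 0
    if floored.any():
        log.info("flooring %d zero occupancy draws", int(floored.sum()))
        occ = np.maximum(occ, np.broadcast_to(floor, occ.shape))
    return occ


def occupancy_index(occ_draws, species_axis: int = 0):
    """Geometric-mean occupancy across species, per draw.

    ``occ_draws`` typically has shape (n_species, S, n_regions, n_years);
    zeros must have been floored beforehand (see :func:`floor_occupancy`).
    """
    return geometric_mean(occ_draws, axis=species_axis)


def species_summaries(cleaned: pd.DataFrame) -> pd.DataFrame:
    """Per-species recording summary feeding the rule-of-thumb filter."""
    date = pd.to_datetime(cleaned["date"])
    df = cleaned.assign(_year=date.dt.year)
    out = df.groupby("species").agg(
        n_records=("site", "size"),
        n_sites=("site", "nunique"),
        n_years=("_year", "nunique"),
    )
    return out.reset_index()


def rule_of_thumb_filter(
    summaries: pd.DataFrame,
    min_records: int = 10,
    min_sites: int = 5,
    min_years: int = 2,
) -> pd.Series:
    """Include/exclude species expected to give imprecise occupancy estimates.

    A species is retained iff its record count, number of distinct sites and
    number of years with records all meet the configured minima.  The
    default thresholds are this package's own choices for synthetic-scale
    data; calibrate them to the dataset at hand.
    """
    required = {"species", "n_records", "n_sites", "n_years"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing fields: {sorted(missing)}")
    keep = (
        (summaries["n_records"] >= min_records)
        & (summaries["n_sites"] >= min_sites)
        & (summaries["n_years"] >= min_years)
    )
    return pd.Series(keep.to_numpy(), index=summaries["species"], name="retained")
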