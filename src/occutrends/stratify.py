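"""Land-cover stratification of 1 km cells into cropland-cover regions.

Each 1 km cell carries fractional cover per land class for two epochs
(an early and a late land-cover map).  Cells whose cropland cover changed
by more than a threshold between the epochs, or which are dominated by
classes not comparable with cropland (wetland, built-up areas, "other"),
are excluded.  The remaining cells are classified by their late-epoch
cropland percentage into no- (0%), low- (>0-50%) and high-cropland (>50%)
regions.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

REGIONS = ("high", "low", "none")
CROPLAND = "cropland"
DEFAULT_INCOMPARABLE = ("wetland", "built_up", "other")


def aggregate_cover(labels: Iterable[str]) -> dict[str, float]:
    """Percentage cover per class from per-subcell labels.

    ``labels`` holds one land-class label per fine-resolution subcell of the
    cell (e.g. the 40 x 40 = 1600 subcells of a 1 km cell mapped at 25 m).
    """
    counts = pd.Series(list(labels)).value_counts()
    total = int(counts.sum())
    if total == 0:
        raise ValueError("cell has no subcells")
    return {cls: 100.0 * n / total for cls, n in counts.items()}


def classify_region(cropland_late: float) -> str:
    """Region label from late-epoch cropland percentage.

    0% -> "none"; (0, 50] -> "low"; (50, 100] -> "high".
    """
    x = float(cropland_late)
    if not 0.0 <= x <= 100.0:
        raise ValueError(f"cropland percentage {x} outside [0, 100]")
    if x == 0.0:
        return "none"
    if x <= 50.0:
        return "low"
    return "high"


def apply_exclusions(
    early: dict[str, float],
    late: dict[str, float],
    change_threshold: float = 10.0,
    incomparable_threshold: float = 25.0,
    incomparable_classes=DEFAULT_INCOMPARABLE,
    check_both_epochs: bool = False,
):
    """Stability and comparability filters for one cell.

    Returns ``(True, None)`` if the cell is kept, else ``(False, reason)``
    with ``reason`` one of ``"cover_change"`` (absolute cropland change in
    percentage points above ``change_threshold``) or ``"incomparable_class"``
    (any of ``incomparable_classes`` above ``incomparable_threshold``;
    evaluated on the late epoch, or on both if ``check_both_epochs``).
    """
    if early is None or late is None:
        raise ValueError("both epochs are required for exclusion filtering")
    crop_early = float(early.get(CROPLAND, 0.0))
    crop_late = float(late.get(CROPLAND, 0.0))
    if abs(crop_late - crop_early) > change_threshold:
        return False, "cover_change"
    epochs = (late, early) if check_both_epochs else (late,)
    for cover in epochs:
        if max(float(cover.get(c, 0.0)) for c in incomparable_classes) > (
            incomparable_threshold
        ):
            return False, "incomparable_class"
    return True, None


class RegionClassifier(BaseEstimator, TransformerMixin):
    """Classify 1 km cells into cropland-cover regions.

    Consumes a long-format cover table with columns
    ``site, epoch, class, percent`` (``epoch`` in {"early", "late"}) and
    produces one row per site with the cropland percentages, the region
    label and, for excluded cells, the exclusion reason.
    """

    def __init__(
        self,
        change_threshold: float = 10.0,
        incomparable_threshold: float = 25.0,
        incomparable_classes=DEFAULT_INCOMPARABLE,
        check_both_epochs: bool = False,
        percent_sum_tolerance: float = 0.5,
    ):
        self.change_threshold = change_threshold
        self.incomparable_threshold = incomparable_threshold
        self.incomparable_classes = incomparable_classes
        self.check_both_epochs = check_both_epochs
        self.percent_sum_tolerance = percent_sum_tolerance

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        required = {"site", "epoch", "class", "percent"}
        if not required.issubset(X.columns):
            raise ValueError(f"cover table needs columns {sorted(required)}")
        bad_epoch = set(X["epoch"]) - {"early", "late"}
        if bad_epoch:
            raise ValueError(f"unknown epoch labels: {sorted(bad_epoch)}")

        wide = X.pivot_table(
            index=["site", "epoch"], columns="class", values="percent",
            aggfunc="sum", fill_value=0.0,
        )
        sums = wide.sum(axis=1)
        off = (sums - 100.0).abs() > self.percent_sum_tolerance
        if off.any():
            sites = sorted({s for s, _ in sums.index[off]})
            raise ValueError(
                f"cover percentages do not sum to 100 for sites {sites[:5]}"
            )

        rows = []
        for site in wide.index.get_level_values("site").unique():
            cell = wide.loc[site]
            if "early" not in cell.index or "late" not in cell.index:
                raise ValueError(f"site {site!r} missing an epoch")
            early = cell.loc["early"].to_dict()
            late = cell.loc["late"].to_dict()
            keep, reason = apply_exclusions(
                early,
                late,
                change_threshold=self.change_threshold,
                incomparable_threshold=self.incomparable_threshold,
                incomparable_classes=self.incomparable_classes,
                check_both_epochs=self.check_both_epochs,
            )
            crop_late = float(late.get(CROPLAND, 0.0))
            rows.append(
                {
                    "site": site,
                    "cropland_early": float(early.get(CROPLAND, 0.0)),
                    "cropland_late": crop_late,
                    "region": classify_region(crop_late) if keep else "excluded",
                    "exclusion_reason": reason,
                }
            )
        return pd.DataFrame(rows)


def classify_sites(cover: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`RegionClassifier`."""
    return RegionClassifier(**kwargs).fit_transform(cover)


def region_summary(classifications) -> pd.DataFrame:
    """Counts and percentage shares per region over non-excluded cells.

    Accepts either the classification table produced by
    :class:`RegionClassifier` or a mapping ``region -> count``.
    """
    if isinstance(classifications, pd.DataFrame):
        counts = (
            classifications.loc[classifications["region"] != "excluded", "region"]
            .value_counts()
            .to_dict()
        )
    else:
        counts = {r: int(n) for r, n in dict(classifications).items()}
    counts = {r: int(counts.get(r, 0)) for r in REGIONS}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no non-excluded cells to summarise")
    return pd.DataFrame(
        {
            "region": list(REGIONS),
            "count": [counts[r] for r in REGIONS],
            "share_pct": [100.0 * counts[r] / total for r in REGIONS],
        }
    )
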