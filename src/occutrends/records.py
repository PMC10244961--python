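"""Cleaning of opportunistic occurrence records and visit-level detection histories.

Citizen-science recording schemes produce verified presence-only records:
a species was seen at a place on a day.  To make such data usable for
occupancy modelling they are standardised to a common spatial (1 km cell)
and temporal (calendar day) resolution and organised into *visits* — unique
combinations of site and date.  Non-detections of a focal species are then
inferred from visits on which other species of the same taxonomic group were
recorded (the target-group approach), and the number of species on each
visit (the list length) is kept as a proxy for recorder effort.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

RECORD_COLUMNS = (
    "species",
    "group",
    "site",
    "date",
    "spatial_precision_m",
    "temporal_precision",
)

#: List-length categories: lists of 1, 2-3, and >= 4 species.
DATATYPES = ("single", "short", "long")

#: Default pattern flagging names identified above species level
#: (e.g. "Bombus sp.", "Carabidae indet.").
ABOVE_SPECIES_PATTERN = r"(?:\bsp{1,2}\.?|\bindet\.?|\bagg\.)\s*$"


def datatype_of(list_length):
    """Map a list length to its effort category.

    Lists of a single species are the least informative about effort, lists
    of 2-3 species intermediate, and complete-looking lists of 4 or more
    species the most.  Accepts a scalar or an array; returns a string or an
    object array of strings.
    """
    arr = np.asarray(list_length)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("list_length must be a positive integer")
        arr = arr.astype(int)
    if np.any(arr < 1):
        raise ValueError("list_length must be >= 1")
    out = np.where(arr >= 4, "long", np.where(arr >= 2, "short", "single"))
    if np.isscalar(list_length) or arr.ndim == 0:
        return str(out.item() if out.ndim == 0 else out)
    return out.astype(object)


class RecordCleaner(BaseEstimator, TransformerMixin):
    """Standardise raw occurrence records to analysis resolution.

    Keeps only rows with spatial precision at or below ``max_spatial_precision_m``
    and day-resolution dates inside ``[first_year, last_year]``; relabels
    configured species aggregates; drops rows identified above species level
    and species on the exclusion list; collapses duplicate
    (species, group, site, date) rows.

    Parameters
    ----------
    first_year, last_year : int
        Closed study window in calendar years.
    max_spatial_precision_m : int, default 1000
        Coarsest admissible spatial precision (1 km cell).
    exclude_species : sequence of str
        Species dropped outright (e.g. a rapidly invading alien whose trend
        reflects invasion, not management).
    aggregate_map : mapping or None
        Maps recorded names onto species aggregates before any filtering,
        for taxa whose taxonomy changed over the study period.
    known_groups : sequence of str or None
        If given, any record whose group is not listed rejects the whole
        input with an informative error.
    above_species_pattern : str
        Regex identifying names recorded above species level.
    """

    def __init__(
        self,
        first_year: int = 1990,
        last_year: int = 2019,
        max_spatial_precision_m: int = 1000,
        exclude_species=(),
        aggregate_map=None,
        known_groups=None,
        above_species_pattern: str = ABOVE_SPECIES_PATTERN,
    ):
        self.first_year = first_year
        self.last_year = last_year
        self.max_spatial_precision_m = max_spatial_precision_m
        self.exclude_species = exclude_species
        self.aggregate_map = aggregate_map
        self.known_groups = known_groups
        self.above_species_pattern = above_species_pattern

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        df = X.copy()
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"records table missing columns: {missing}")

        report: dict[str, int] = {"input": len(df)}

        if self.known_groups is not None:
            unknown = sorted(set(df["group"]) - set(self.known_groups))
            if unknown:
                raise ValueError(f"unknown taxon group(s): {unknown}")

        if self.aggregate_map:
            df["species"] = df["species"].map(
                lambda s: self.aggregate_map.get(s, s)
            )

        parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
        bad_date = parsed.isna()
        report["unparseable_date"] = int(bad_date.sum())
        df = df.loc[~bad_date].assign(date=parsed[~bad_date].dt.normalize())

        non_daily = df["temporal_precision"] != "day"
        report["non_daily"] = int(non_daily.sum())
        df = df.loc[~non_daily]

        coarse = df["spatial_precision_m"] > self.max_spatial_precision_m
        report["coarse_spatial"] = int(coarse.sum())
        df = df.loc[~coarse]

        year = df["date"].dt.year
        outside = (year < self.first_year) | (year > self.last_year)
        report["outside_window"] = int(outside.sum())
        df = df.loc[~outside]

        above = df["species"].str.contains(
            self.above_species_pattern, regex=True, na=True
        )
        if self.aggregate_map:
            # configured aggregates are modelling units, not indeterminate ids
            above &= ~df["species"].isin(set(self.aggregate_map.values()))
        report["above_species_level"] = int(above.sum())
        df = df.loc[~above]

        excluded = df["species"].isin(set(self.exclude_species))
        report["excluded_species"] = int(excluded.sum())
        df = df.loc[~excluded]

        n_before = len(df)
        df = df.drop_duplicates(subset=["species", "group", "site", "date"])
        report["duplicates"] = n_before - len(df)
        report["output"] = len(df)

        self.report_ = report
        return df.reset_index(drop=True)


def standardize_records(raw: pd.DataFrame, **cfg):
    """Clean raw records; return ``(cleaned, report)``.

    Thin functional wrapper over :class:`RecordCleaner`; ``report`` counts
    the rows dropped by each rule.
    """
    cleaner = RecordCleaner(**cfg)
    cleaned = cleaner.fit_transform(raw)
    return cleaned, cleaner.report_


class VisitBuilder(BaseEstimator, TransformerMixin):
    """Group cleaned records of one taxonomic group into visits.

    A visit is a unique (site, date) combination; its list length is the
    number of distinct species recorded on it.
    """

    def __init__(self, first_year: int = 1990):
        self.first_year = first_year

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if len(X) == 0:
            return pd.DataFrame(
                columns=["site", "date", "year_index", "list_length", "datatype"]
            )
        date = pd.to_datetime(X["date"])
        grouped = (
            X.assign(date=date)
            .groupby(["site", "date"], sort=True)["species"]
            .nunique()
            .rename("list_length")
            .reset_index()
        )
        grouped["year_index"] = grouped["date"].dt.year - self.first_year
        grouped["datatype"] = datatype_of(grouped["list_length"].to_numpy())
        return grouped[["site", "date", "year_index", "list_length", "datatype"]]


def build_visits(cleaned: pd.DataFrame, first_year: int = 1990) -> pd.DataFrame:
    """One row per (site, date) with list length and effort category."""
    return VisitBuilder(first_year=first_year).fit_transform(cleaned)


def detection_matrix(
    cleaned: pd.DataFrame, first_year: int = 1990
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Visits plus a visits x species boolean detection matrix.

    The matrix row order matches the visit table; a ``True`` entry means the
    species was recorded on that visit, and — by the target-group logic — a
    ``False`` entry on a visit is an inferred non-detection.
    """
    visits = build_visits(cleaned, first_year=first_year)
    if len(visits) == 0:
        return visits, pd.DataFrame(index=visits.index)
    key = pd.MultiIndex.from_frame(visits[["site", "date"]])
    df = cleaned.assign(date=pd.to_datetime(cleaned["date"]))
    mat = (
        pd.crosstab([df["site"], df["date"]], df["species"]) > 0
    ).reindex(key, fill_value=False)
    mat.index = visits.index
    return visits, mat


def detection_history(
    cleaned: pd.DataFrame, focal_species: str, first_year: int = 1990
) -> pd.DataFrame:
    """Per-visit binary detection history for one focal species.

    y = 1 where the focal species was recorded on the visit, 0 otherwise.
    Every visit of the taxonomic group contributes one row, so non-detections
    are inferred from the activity of other recorders of the same group.
    """
    visits, mat = detection_matrix(cleaned, first_year=first_year)
    if focal_species not in mat.columns:
        import warnings

        warnings.warn(
            f"focal species {focal_species!r} absent from the group's records;"
            " detection history is all zeros",
            stacklevel=2,
        )
        y = np.zeros(len(visits), dtype=int)
    else:
        y = mat[focal_species].to_numpy().astype(int)
    return visits.assign(y=y)
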