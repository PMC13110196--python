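"""Long-format clinical measurement data: the :class:`Study` container, file
I/O and pre-analysis cleaning.

A study is a flat long-format table (one row per measurement) together with
the enrollment hierarchy region -> country -> site -> subject.  Measurements
are numeric; anything unparsable maps to the single canonical missing marker
(NaN).  Visit coordinates are 1-based protocol-schedule indices; series from
different subjects are compared only at identical indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: canonical column order of the in-memory record table
COLUMNS = [
    "subject_id",
    "site_id",
    "country_id",
    "region_id",
    "parameter",
    "visit_index",
    "scheduled",
    "screen_failure",
    "value",
]

#: columns that must be present in every input file (the rest have defaults)
MANDATORY_FIELDS = ["subject_id", "site_id", "parameter", "visit_index", "value"]


@dataclass
class Study:
    """A set of measurement records plus the site hierarchy.

    Parameters
    ----------
    records : pandas.DataFrame
        One row per measurement with the columns of :data:`COLUMNS`.
        ``value`` is float with NaN as the missing marker; ``scheduled`` and
        ``screen_failure`` are boolean flags used by :func:`clean_study`.
    """

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise ConfigurationError(f"study records missing columns: {missing}")
        self.records = self.records[COLUMNS].reset_index(drop=True)
        self._check_hierarchy()

    def _check_hierarchy(self) -> None:
        for child, parent in [
            ("subject_id", "site_id"),
            ("site_id", "country_id"),
            ("country_id", "region_id"),
        ]:
            n_parents = self.records.groupby(child, sort=False)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise DataError(
                    f"inconsistent hierarchy: {child} {bad.index[0]!r} maps to "
                    f"{bad.iloc[0]} distinct {parent} values"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def parameters(self) -> list[str]:
        return sorted(self.records["parameter"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.records["subject_id"].unique())

    @property
    def sites(self) -> list[str]:
        return sorted(self.records["site_id"].unique())

    def subject_sites(self) -> pd.Series:
        """Mapping subject_id -> site_id."""
        return (
            self.records.drop_duplicates("subject_id")
            .set_index("subject_id")["site_id"]
        )

    def site_hierarchy(self) -> pd.DataFrame:
        """One row per site with its country and region."""
        return (
            self.records.drop_duplicates("site_id")
            .set_index("site_id")[["country_id", "region_id"]]
            .sort_index()
        )

    def copy(self) -> "Study":
        return Study(self.records.copy())


def read_study(
    path,
    column_map: dict[str, str] | None = None,
    delimiter: str = ",",
) -> Study:
    """Read a delimited long-format measurement table into a :class:`Study`.

    ``column_map`` maps record fields (keys of :data:`COLUMNS`) to file column
    names; identity mapping by default.  Country/region columns are optional —
    absent levels collapse to a single synthetic country/region so the
    nested-model hierarchy is always well formed.  Non-numeric value cells
    (including "NA" and empty strings) become the missing marker.

    Raises
    ------
    ConfigurationError
        If a mandatory column is absent from the file.
    DataError
        If the same (subject, parameter, visit) key occurs twice.  Duplicates
        are an error rather than being averaged: silent aggregation could mask
        the anomalies being hunted.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")

    out = pd.DataFrame()
    for fld in COLUMNS:
        col = column_map.get(fld, fld)
        if col in df.columns:
            out[fld] = df[col]
        elif fld in MANDATORY_FIELDS:
            raise ConfigurationError(
                f"mandatory column {col!r} (field {fld!r}) not found in {path}"
            )
    if "country_id" not in out:
        out["country_id"] = "COUNTRY1"
    if "region_id" not in out:
        out["region_id"] = "REGION1"
    if "scheduled" not in out:
        out["scheduled"] = "True"
    if "screen_failure" not in out:
        out["screen_failure"] = "False"

    out["visit_index"] = pd.to_numeric(out["visit_index"], errors="raise").astype(int)
    out["value"] = pd.to_numeric(out["value"], errors="coerce")
    for flag in ("scheduled", "screen_failure"):
        out[flag] = (
            out[flag]
            .fillna("")
            .str.strip()
            .str.lower()
            .isin(["true", "1", "yes", "y", "t"])
        )

    dup = out.duplicated(["subject_id", "parameter", "visit_index"])
    if dup.any():
        key = out.loc[dup.idxmax(), ["subject_id", "parameter", "visit_index"]]
        raise DataError(
            "duplicate (subject, parameter, visit) row: "
            f"({key['subject_id']}, {key['parameter']}, {key['visit_index']})"
        )
    return Study(out)


def write_study(study: Study, path, delimiter: str = ",", header: str | None = None) -> None:
    """Write a study to a delimited file (canonical dialect: UTF-8, "." decimal).

    ``header`` lines, if given, are written as "#"-prefixed comments that
    :func:`read_study` skips on re-read.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        study.records.to_csv(fh, sep=delimiter, index=False)


def clean_study(study: Study) -> Study:
    """Drop unscheduled-visit records and all records of screen-failure subjects.

    Both removals mirror standard pre-analysis cleaning: unscheduled visits
    break the cross-subject visit alignment and screening failures never
    contribute analysable series.  Idempotent.
    """
    df = study.records
    failed = df.loc[df["screen_failure"], "subject_id"].unique()
    keep = df["scheduled"] & ~df["subject_id"].isin(failed)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("clean_study: dropped %d of %d records", n_dropped, len(df))
    return Study(df[keep].copy())


def reassign_sites(study: Study, seed: int) -> Study:
    """Randomly permute subjects across the existing sites.

    Each site keeps its original subject count and its country/region
    membership; only the subject -> site assignment is shuffled.  This removes
    any pre-existing site-level signal while preserving the site-size
    distribution.  Deterministic for a fixed seed.

    Raises
    ------
    DataError
        For a single-site study (a permutation would be meaningless).
    """
    df = study.records
    subject_site = study.subject_sites()
    sites = study.site_hierarchy()
    if len(sites) < 2:
        raise DataError("site reassignment requires at least 2 sites")

    rng = np.random.default_rng(seed)
    subjects = np.array(subject_site.index)
    # slots: each site repeated by its current subject count
    slots = np.repeat(
        subject_site.value_counts().sort_index().index.to_numpy(),
        subject_site.value_counts().sort_index().to_numpy(),
    )
    new_site = pd.Series(slots, index=rng.permutation(subjects))

    out = df.copy()
    out["site_id"] = out["subject_id"].map(new_site)
    out["country_id"] = out["site_id"].map(sites["country_id"])
    out["region_id"] = out["site_id"].map(sites["region_id"])
    return Study(out)
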