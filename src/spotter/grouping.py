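"""Equal-length time-series group discovery.

Subjects enroll at different times, so at any analysis cut-off their series
have different lengths.  Summary features are only comparable between series
covering the same visits, so subjects are organised into *time-series
groups*: a parameter, an ordered prefix of the visit schedule, and every
subject whose missing-value fraction over those visits is within the cap.

Automatic discovery starts from the longest observed schedule prefix and
walks down one visit at a time, accepting the first window that reaches the
minimum group size and, after that, any shorter window that increases the
eligible-subject count by at least the improvement ratio (default 20%,
inclusive).  Groups of length one are allowed: some measurements are taken
only once (e.g. at screening).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError, GroupTooSmallError
from .study import Study


@dataclass
class GroupingConfig:
    """Tunables of group discovery.

    min_group_size
        Smallest acceptable number of eligible subjects (default 25).
    max_missing_ratio
        Largest tolerated fraction of missing entries per subject over the
        group's visits (default 0.30).
    improvement_ratio
        Minimum relative gain in eligible subjects required to accept an
        additional, shorter group (default 0.20, inclusive).
    """

    min_group_size: int = 25
    max_missing_ratio: float = 0.30
    improvement_ratio: float = 0.20

    def __post_init__(self) -> None:
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if not 0 <= self.max_missing_ratio <= 1:
            raise ValueError("max_missing_ratio must be in [0, 1]")
        if self.improvement_ratio <= 0:
            raise ValueError("improvement_ratio must be > 0")


@dataclass
class TimeSeriesGroup:
    """One comparable set of equal-length series.

    ``values`` is a subjects x visits DataFrame (rows indexed by subject_id,
    columns by visit_index) with NaN for missing entries.  ``subject_sites``
    maps each member subject to its site.
    """

    parameter: str
    visit_indices: list[int]
    subject_ids: list[str]
    values: pd.DataFrame = field(repr=False)
    subject_sites: pd.Series = field(repr=False)

    @property
    def group_id(self) -> str:
        return f"{self.parameter}:L{len(self.visit_indices)}"

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def __len__(self) -> int:
        return len(self.visit_indices)


def _value_pivot(study: Study, parameter: str) -> pd.DataFrame:
    df = study.records
    sub = df[df["parameter"] == parameter]
    if sub.empty:
        raise DataError(f"unknown parameter: {parameter!r}")
    return sub.pivot(index="subject_id", columns="visit_index", values="value")


def _eligible_mask(pivot: pd.DataFrame, visit_indices: list[int], max_missing_ratio: float) -> pd.Series:
    window = pivot.reindex(columns=visit_indices)
    present = window.notna().sum(axis=1)
    missing_ratio = 1.0 - present / len(visit_indices)
    # a subject with no observed value in the window is never eligible,
    # whatever the ratio cap
    return (missing_ratio <= max_missing_ratio + 1e-12) & (present > 0)


def eligible_subjects(
    study: Study,
    parameter: str,
    visit_indices: list[int],
    max_missing_ratio: float,
) -> set[str]:
    """Subjects whose missing fraction over ``visit_indices`` is within the cap.

    A visit with no record counts as missing.
    """
    if not visit_indices:
        raise ValueError("visit_indices must be non-empty")
    pivot = _value_pivot(study, parameter)
    mask = _eligible_mask(pivot, list(visit_indices), max_missing_ratio)
    return set(pivot.index[mask])


def _build_group(
    study: Study, pivot: pd.DataFrame, parameter: str, visit_indices: list[int], mask: pd.Series
) -> TimeSeriesGroup:
    subjects = sorted(pivot.index[mask])
    values = pivot.reindex(index=subjects, columns=visit_indices)
    sites = study.subject_sites().reindex(subjects)
    return TimeSeriesGroup(
        parameter=parameter,
        visit_indices=list(visit_indices),
        subject_ids=subjects,
        values=values,
        subject_sites=sites,
    )


def auto_group(study: Study, parameter: str, config: GroupingConfig | None = None) -> list[TimeSeriesGroup]:
    """Discover time-series groups for one parameter, longest first.

    Candidate windows are schedule prefixes [1..L]; L runs from the maximum
    observed visit index down to 1.  The first window reaching
    ``min_group_size`` is accepted; a shorter window is then accepted only if
    its eligible count exceeds the last accepted count by at least
    ``improvement_ratio`` (relative, inclusive).  Ties in count keep the
    longer window.  Returns an empty list when no window qualifies.
    """
    config = config or GroupingConfig()
    pivot = _value_pivot(study, parameter)
    max_visit = int(pivot.columns.max())

    groups: list[TimeSeriesGroup] = []
    last_count: int | None = None
    for length in range(max_visit, 0, -1):
        window = list(range(1, length + 1))
        mask = _eligible_mask(pivot, window, config.max_missing_ratio)
        count = int(mask.sum())
        if count < config.min_group_size:
            continue
        if last_count is None:
            accept = True
        else:
            accept = count >= last_count * (1.0 + config.improvement_ratio) - 1e-9
        if accept:
            groups.append(_build_group(study, pivot, parameter, window, mask))
            last_count = count
    return groups


def manual_group(
    study: Study,
    parameter: str,
    visit_indices: list[int],
    config: GroupingConfig | None = None,
) -> TimeSeriesGroup:
    """Build the group over exactly ``visit_indices``.

    Raises
    ------
    GroupTooSmallError
        When fewer than ``min_group_size`` subjects are eligible; the error
        carries the eligible count.
    """
    config = config or GroupingConfig()
    if not visit_indices:
        raise ValueError("visit_indices must be non-empty")
    visit_indices = list(visit_indices)
    pivot = _value_pivot(study, parameter)
    mask = _eligible_mask(pivot, visit_indices, config.max_missing_ratio)
    count = int(mask.sum())
    if count < config.min_group_size:
        raise GroupTooSmallError(count, config.min_group_size)
    return _build_group(study, pivot, parameter, visit_indices, mask)


def groups_to_json(groups: list[TimeSeriesGroup]) -> list[dict]:
    """JSON-serialisable listing of groups (parameter, visits, subject ids)."""
    return [
        {
            "group_id": g.group_id,
            "parameter": g.parameter,
            "visit_indices": [int(v) for v in g.visit_indices],
            "subject_ids": list(g.subject_ids),
        }
        for g in groups
    ]


def groups_from_json(study: Study, listing: list[dict], config: GroupingConfig | None = None) -> list[TimeSeriesGroup]:
    """Rebuild groups from a JSON listing against a study."""
    return [
        manual_group(study, item["parameter"], item["visit_indices"], config)
        for item in listing
    ]
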