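"""The six per-subject time-series features.

Each subject's series within a group is summarised into up to six scalars:

``average``
    Arithmetic mean — detects systematic shifts (e.g. lab calibration bias).
``sd``
    Sample standard deviation (n-1) — implausible fluctuation.
``range``
    max - min — magnitude/unit errors.
``unique_value_ratio``
    distinct / non-missing count — duplication or excessive rounding.
``autocorrelation``
    Lag-1 Pearson autocorrelation over consecutive-visit pairs — artificial
    linearity (e.g. a site adding a constant to the previous measurement).
``lof``
    Local outlier factor of the subject's (imputed) series among all series
    in the group — the only context-dependent feature; ~1 for inliers, > 1
    in locally sparse regions.

All features skip missing values; a feature whose precondition fails is
recorded as NaN and simply drops out of downstream site tests.  Equality for
the unique-value ratio is exact floating equality: rounding in the data is
precisely the signal sought, so no tolerance is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .errors import ConfigurationError
from .grouping import TimeSeriesGroup

FEATURE_NAMES = (
    "average",
    "sd",
    "range",
    "unique_value_ratio",
    "autocorrelation",
    "lof",
)

#: reachability-distance floor for exactly duplicated series
_LOF_EPS = 1e-12


@dataclass
class FeatureMatrix:
    """Per-subject feature values for one time-series group.

    ``values`` is a subjects x features DataFrame (NaN = undefined);
    ``subject_sites`` maps subjects to sites for the scoring stage.
    """

    group_id: str
    parameter: str
    values: pd.DataFrame = field(repr=False)
    subject_sites: pd.Series = field(repr=False)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


# -- context-free features ----------------------------------------------------


def ts_average(series) -> float:
    """Mean of the non-missing values; NaN if all missing."""
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    return float(x.mean()) if x.size else math.nan


def ts_sd(series) -> float:
    """Sample SD (denominator n-1); NaN with fewer than 2 non-missing values."""
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    return float(x.std(ddof=1)) if x.size >= 2 else math.nan


def ts_range(series) -> float:
    """max - min over non-missing values; NaN if all missing.

    For a length-1 series this is 0 only if the single value is observed;
    group-level emission of the range for length-1 groups is suppressed in
    :func:`compute_features` (a single value carries no dispersion signal).
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    return float(x.max() - x.min()) if x.size else math.nan


def unique_value_ratio(series) -> float:
    """distinct / non-missing count, in (0, 1]; NaN if all missing."""
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if not x.size:
        return math.nan
    return float(np.unique(x).size / x.size)


def ts_autocorrelation(series) -> float:
    """Lag-1 Pearson autocorrelation over consecutive schedule positions.

    Pairs (t, t+1) enter only when both values are observed.  Requires at
    least 2 valid pairs and non-zero variance in both lagged subvectors;
    otherwise NaN.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        return math.nan
    a, b = x[:-1], x[1:]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return math.nan
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


# -- local outlier factor ------------------------------------------------------


def impute_group_values(values: pd.DataFrame) -> np.ndarray:
    """Replace missing entries with the per-visit median across subjects.

    The per-visit median preserves the group's location structure at each
    time point without inventing within-subject trends.  A visit column with
    no observed value at all falls back to the overall median (0 when the
    whole matrix is empty).
    """
    arr = values.to_numpy(dtype=float)
    col_med = np.nanmedian(np.where(np.isfinite(arr), arr, np.nan), axis=0)
    overall = np.nanmedian(arr) if np.isfinite(arr).any() else 0.0
    col_med = np.where(np.isfinite(col_med), col_med, overall)
    out = np.where(np.isfinite(arr), arr, np.broadcast_to(col_med, arr.shape))
    return out


def lof_scores(group_values, k: int) -> np.ndarray:
    """Local outlier factor of each row among all rows (Euclidean distance).

    Implements the classical definition: k-distance, reachability distance
    reach_k(a, b) = max(kdist(b), d(a, b)), local reachability density
    lrd(a) = 1 / mean reachability of a's k nearest neighbours, and
    LOF(a) = mean(lrd(neighbours)) / lrd(a).  Mean reachability is floored at
    1e-12 so exactly duplicated series do not divide by zero.

    Returns all-NaN when there are fewer than k+1 rows.
    """
    X = np.asarray(group_values, dtype=float)
    n = X.shape[0]
    if n < k + 1:
        return np.full(n, np.nan)
    D = squareform(pdist(X))
    # neighbour ranks excluding self; stable argsort makes ties deterministic
    order = np.argsort(D + np.eye(n) * (D.max() + 1.0), axis=1, kind="stable")
    knn = order[:, :k]
    kdist = D[np.arange(n), order[:, k - 1]]
    reach = np.maximum(kdist[knn], D[np.arange(n)[:, None], knn])
    lrd = 1.0 / np.maximum(reach.mean(axis=1), _LOF_EPS)
    return lrd[knn].mean(axis=1) / lrd


# -- assembly ------------------------------------------------------------------


def _matrix_features(values: pd.DataFrame, enabled: tuple[str, ...], k_lof: int | None) -> pd.DataFrame:
    """Vectorised feature computation over a subjects x visits matrix."""
    arr = values.to_numpy(dtype=float)
    n, length = arr.shape
    finite = np.isfinite(arr)
    counts = finite.sum(axis=1)
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        if "average" in enabled:
            s = np.where(finite, arr, 0.0).sum(axis=1)
            out["average"] = np.where(counts > 0, s / np.maximum(counts, 1), np.nan)
        if "sd" in enabled:
            mean = np.where(finite, arr, 0.0).sum(axis=1) / np.maximum(counts, 1)
            ss = np.where(finite, (arr - mean[:, None]) ** 2, 0.0).sum(axis=1)
            out["sd"] = np.where(counts >= 2, np.sqrt(ss / np.maximum(counts - 1, 1)), np.nan)
        if "range" in enabled:
            mx = np.where(finite, arr, -np.inf).max(axis=1)
            mn = np.where(finite, arr, np.inf).min(axis=1)
            rng = np.where(counts > 0, mx - mn, np.nan)
            if length == 1:
                rng = np.full(n, np.nan)  # no dispersion information
            out["range"] = rng
        if "unique_value_ratio" in enabled:
            out["unique_value_ratio"] = np.array(
                [unique_value_ratio(arr[i]) for i in range(n)]
            )
        if "autocorrelation" in enabled:
            out["autocorrelation"] = np.array(
                [ts_autocorrelation(arr[i]) for i in range(n)]
            )
        if "lof" in enabled:
            k = k_lof if k_lof is not None else min(20, n - 1)
            out["lof"] = (
                lof_scores(impute_group_values(values), k) if k >= 1 else np.full(n, np.nan)
            )
    cols = [f for f in enabled]
    return pd.DataFrame(out, index=values.index)[cols]


def compute_features(
    group: TimeSeriesGroup,
    enabled: tuple[str, ...] = FEATURE_NAMES,
    k_lof: int | None = None,
) -> FeatureMatrix:
    """Apply every enabled feature to every subject of a group.

    Undefined values (failed preconditions) are NaN.  For length-1 groups the
    sd, range, unique-value-ratio and autocorrelation columns are entirely
    undefined; average and LOF remain meaningful.  The LOF neighbourhood
    defaults to k = min(20, n_subjects - 1).
    """
    if not enabled:
        raise ConfigurationError("at least one feature must be enabled")
    unknown = set(enabled) - set(FEATURE_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown features: {sorted(unknown)}")
    values = _matrix_features(group.values, tuple(enabled), k_lof)
    if len(group.visit_indices) == 1:
        for col in ("sd", "unique_value_ratio", "autocorrelation"):
            if col in values:
                values[col] = np.nan
    return FeatureMatrix(
        group_id=group.group_id,
        parameter=group.parameter,
        values=values,
        subject_sites=group.subject_sites,
    )
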