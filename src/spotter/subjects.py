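"""Subject-level outlier screening.

Two complementary views surface individual anomalous subjects within a
time-series group: a 2-D similarity embedding (classical metric MDS of the
Euclidean distances between imputed series) where outliers sit far from the
cloud, and a two-sided extremity ranking of feature values measured in
robust units, |value - median| / MAD.  Robust location/scale is used so a
single outlier cannot mask itself by inflating the spread estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .features import FeatureMatrix, impute_group_values
from .grouping import TimeSeriesGroup

logger = logging.getLogger(__name__)


@dataclass
class SubjectOutlierReport:
    group_id: str
    coordinates: pd.DataFrame = field(repr=False)  # subjects x 2
    isolation: pd.Series = field(repr=False)       # mean distance to k NN
    feature_ranks: pd.DataFrame = field(repr=False)  # 1 = most extreme


def subject_distances(group: TimeSeriesGroup) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix over imputed series vectors."""
    if group.n_subjects < 2:
        raise ValueError("need at least 2 subjects for distances")
    X = impute_group_values(group.values)
    D = squareform(pdist(X))
    return pd.DataFrame(D, index=group.subject_ids, columns=group.subject_ids)


def similarity_coordinates(distances: pd.DataFrame) -> pd.DataFrame:
    """Classical metric MDS (principal coordinates) to 2 dimensions.

    Double-centers the squared distance matrix, takes the top-2 eigenpairs,
    and scales eigenvectors by sqrt(eigenvalue) (negative eigenvalues clip to
    zero).  The axis sign is fixed so the entry of largest magnitude on each
    axis is positive, making the embedding deterministic up to that
    convention.  Distances between points generated in <= 2 dimensions are
    reproduced exactly.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a similarity embedding")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:2]
    lam = np.clip(evals[idx], 0.0, None)
    coords = evecs[:, idx] * np.sqrt(lam)
    for a in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, a]))
        if coords[j, a] < 0:
            coords[:, a] = -coords[:, a]
    return pd.DataFrame(coords, index=distances.index, columns=["dim1", "dim2"])


def isolation_statistic(distances: pd.DataFrame, k: int = 5) -> pd.Series:
    """Mean distance to each subject's k nearest neighbours (self excluded)."""
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    k = min(k, n - 1)
    Dx = D + np.eye(n) * (D.max() + 1.0)
    nearest = np.sort(Dx, axis=1)[:, :k]
    return pd.Series(nearest.mean(axis=1), index=distances.index)


def rank_extreme_subjects(features: FeatureMatrix, feature: str, top_n: int | None = None) -> list[str]:
    """Subjects ordered by two-sided extremity |value - median| / MAD, descending.

    Zero MAD (e.g. heavily rounded data) falls back to |value - median|
    ordering with a logged notice.  Ties and all-equal columns order
    deterministically by subject id; undefined values rank last.
    """
    vals = features.values[feature]
    defined = vals.dropna()
    if defined.empty:
        raise ValueError(f"feature {feature!r} undefined for every subject")
    med = float(defined.median())
    mad = float((defined - med).abs().median())
    if mad == 0:
        logger.info("rank_extreme_subjects: MAD = 0 for %r; using absolute deviation", feature)
        extremity = (vals - med).abs()
    else:
        extremity = (vals - med).abs() / mad
    # sort by subject id first so the extremity sort breaks ties deterministically
    order = (
        pd.DataFrame({"e": extremity.fillna(-np.inf)})
        .sort_index()
        .sort_values("e", ascending=False, kind="mergesort")
    )
    ranked = list(order.index)
    return ranked[:top_n] if top_n is not None else ranked


def feature_rank_table(features: FeatureMatrix) -> pd.DataFrame:
    """Per-feature extremity ranks (1 = most extreme) for every subject."""
    out = {}
    for feature in features.feature_names:
        try:
            ranked = rank_extreme_subjects(features, feature)
        except ValueError:
            out[feature] = pd.Series(np.nan, index=features.values.index)
            continue
        out[feature] = pd.Series(
            np.arange(1, len(ranked) + 1), index=ranked, dtype=float
        ).reindex(features.values.index)
    return pd.DataFrame(out)


def subject_outlier_report(group: TimeSeriesGroup, features: FeatureMatrix, k: int = 5) -> SubjectOutlierReport:
    """Assemble the similarity embedding, isolation statistic and feature ranks."""
    D = subject_distances(group)
    return SubjectOutlierReport(
        group_id=group.group_id,
        coordinates=similarity_coordinates(D),
        isolation=isolation_statistic(D, k=k),
        feature_ranks=feature_rank_table(features),
    )
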