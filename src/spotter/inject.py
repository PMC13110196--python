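"""Site-level anomaly injection for the simulation benchmark.

Each injector distorts the measurements of a chosen parameter at a small set
of target sites, leaving every other site bit-identical and never touching
the record structure (count, missingness pattern, visit grid).  The scalar
*degree* controls intensity; every injector is the identity at degree 0.
The six anomaly types pair one-to-one with the six time-series features:

========================  =====================================================
average                   x' = x + m_s * d  (m_s = pre-injection site mean)
sd                        x' = x + s * m_s * d,  s random sign per observation
range                     one random visit per subject gets x + s * |m_s| * d
unique_value_ratio        a fraction d of later observations is overwritten
                          with the subject's first observed value
autocorrelation           x'_t = x_t + d * x_{t-1}  (original predecessor)
lof                       a fraction d of subjects is redrawn from a random
                          non-normal distribution rescaled to the subject's
                          mean and range
========================  =====================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .study import Study

logger = logging.getLogger(__name__)

ANOMALY_TYPES = (
    "average",
    "sd",
    "range",
    "unique_value_ratio",
    "autocorrelation",
    "lof",
)

#: distributions available to the lof injector; each takes (rng, n, lo, hi)
#: and returns raw draws that are subsequently rescaled to the subject's
#: original mean and range
_LOF_POOL = {
    "uniform": lambda rng, n, lo, hi: rng.uniform(lo, hi, n),
    "exponential": lambda rng, n, lo, hi: rng.exponential(1.0, n),
    "constant_jitter": lambda rng, n, lo, hi: 1.0 + 0.01 * rng.standard_normal(n),
    "two_point": lambda rng, n, lo, hi: rng.choice([lo, hi], n),
}


@dataclass
class AnomalyScenario:
    """The injection recipe for one simulation iteration."""

    anomaly_type: str
    degree: float
    parameter: str
    target_sites: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.anomaly_type not in ANOMALY_TYPES:
            raise ConfigurationError(f"unknown anomaly type: {self.anomaly_type!r}")
        if self.degree < 0:
            raise ConfigurationError("degree must be >= 0")


def draw_target_sites(study: Study, n_sites: int, rng: np.random.Generator) -> list[str]:
    """Uniformly draw ``n_sites`` distinct target sites."""
    sites = study.sites
    if n_sites > len(sites):
        raise DataError(f"cannot draw {n_sites} target sites from {len(sites)}")
    return sorted(str(s) for s in rng.choice(sites, size=n_sites, replace=False))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _site_means(df: pd.DataFrame, scenario: AnomalyScenario) -> pd.Series:
    """Pre-injection mean of all non-missing parameter values per target site."""
    sel = df[(df["parameter"] == scenario.parameter) & df["site_id"].isin(scenario.target_sites)]
    return sel.groupby("site_id")["value"].mean()


def _target_rows(df: pd.DataFrame, scenario: AnomalyScenario, site: str) -> pd.Series:
    return (
        (df["parameter"] == scenario.parameter)
        & (df["site_id"] == site)
        & df["value"].notna()
    )


def _check_targets(study: Study, scenario: AnomalyScenario) -> None:
    if not scenario.target_sites:
        raise ConfigurationError("scenario has no target sites")
    missing = set(scenario.target_sites) - set(study.sites)
    if missing:
        raise DataError(f"target sites not in study: {sorted(missing)}")


def inject_average(study: Study, scenario: AnomalyScenario) -> Study:
    """Shift every target-site value by the site mean times the degree."""
    _check_targets(study, scenario)
    df = study.records.copy()
    means = _site_means(df, scenario)
    for site in scenario.target_sites:
        if site not in means.index or np.isnan(means[site]):
            logger.warning("inject_average: site %s has no data for %r; skipped",
                           site, scenario.parameter)
            continue
        rows = _target_rows(df, scenario, site)
        df.loc[rows, "value"] += means[site] * scenario.degree
    return Study(df)


def inject_sd(study: Study, scenario: AnomalyScenario) -> Study:
    """Add site_mean * degree with an independent random sign per observation."""
    _check_targets(study, scenario)
    rng = np.random.default_rng(scenario.seed)
    df = study.records.copy()
    means = _site_means(df, scenario)
    for site in scenario.target_sites:
        if site not in means.index or np.isnan(means[site]):
            logger.warning("inject_sd: site %s has no data for %r; skipped",
                           site, scenario.parameter)
            continue
        rows = _target_rows(df, scenario, site)
        signs = rng.choice([-1.0, 1.0], size=int(rows.sum()))
        df.loc[rows, "value"] += signs * means[site] * scenario.degree
    return Study(df)


def inject_range(study: Study, scenario: AnomalyScenario) -> Study:
    """Add one outlier data point per target-site subject.

    A uniformly chosen non-missing visit gets x + s * |site_mean| * degree
    with a random sign; every other visit is untouched.  Scaling the
    extremity by the site mean keeps degrees comparable across parameters
    with different units.
    """
    _check_targets(study, scenario)
    rng = np.random.default_rng(scenario.seed)
    df = study.records.copy()
    means = _site_means(df, scenario)
    for site in scenario.target_sites:
        if site not in means.index or np.isnan(means[site]):
            logger.warning("inject_range: site %s has no data for %r; skipped",
                           site, scenario.parameter)
            continue
        rows = _target_rows(df, scenario, site)
        for _, idx in df.index[rows].to_series().groupby(df.loc[rows, "subject_id"], sort=True):
            pick = idx.iloc[rng.integers(len(idx))]
            sign = rng.choice([-1.0, 1.0])
            df.loc[pick, "value"] += sign * abs(means[site]) * scenario.degree
    return Study(df)


def inject_unique(study: Study, scenario: AnomalyScenario) -> Study:
    """Overwrite a fraction of later observations with the first observed value.

    The degree is the replacement ratio, clamped to [0, 1].  The first
    observation is kept; round-half-up(degree * (n - 1)) of the remaining
    non-missing values, chosen uniformly, are replaced.
    """
    _check_targets(study, scenario)
    ratio = min(max(scenario.degree, 0.0), 1.0)
    rng = np.random.default_rng(scenario.seed)
    df = study.records.copy()
    for site in scenario.target_sites:
        rows = _target_rows(df, scenario, site)
        sub = df[rows].sort_values("visit_index")
        for _, grp in sub.groupby("subject_id", sort=True):
            first_value = grp["value"].iloc[0]
            later = grp.index[1:]
            n_replace = _round_half_up(ratio * len(later))
            if n_replace:
                chosen = rng.choice(later, size=n_replace, replace=False)
                df.loc[chosen, "value"] = first_value
    return Study(df)


def inject_autocorrelation(study: Study, scenario: AnomalyScenario) -> Study:
    """Add degree * (original preceding value) to each value.

    The predecessor is the value at visit_index - 1 *before* injection (no
    cascading, keeping the transform linear); first visits and values whose
    predecessor is missing or absent stay unchanged.
    """
    _check_targets(study, scenario)
    df = study.records.copy()
    for site in scenario.target_sites:
        rows = _target_rows(df, scenario, site)
        sub = df[rows]
        prev = sub.set_index(["subject_id", "visit_index"])["value"]
        pred_key = list(zip(sub["subject_id"], sub["visit_index"] - 1))
        pred = prev.reindex(pred_key).to_numpy()
        add = np.where(np.isfinite(pred), pred, 0.0) * scenario.degree
        df.loc[rows, "value"] = sub["value"].to_numpy() + add
    return Study(df)


def inject_lof(study: Study, scenario: AnomalyScenario) -> Study:
    """Redraw a fraction of target-site subjects from a non-normal distribution.

    The degree is the affected-subject ratio, clamped to [0, 1].  Each
    affected subject's series is replaced with draws from one distribution
    chosen uniformly from the pool (uniform over the subject's range,
    exponential, near-constant, two-point at min/max), then shifted/scaled so
    the mean matches the subject's original mean exactly and the spread
    matches the original range (degenerate draw ranges collapse to the mean).
    """
    _check_targets(study, scenario)
    ratio = min(max(scenario.degree, 0.0), 1.0)
    rng = np.random.default_rng(scenario.seed)
    df = study.records.copy()
    pool_names = sorted(_LOF_POOL)
    for site in scenario.target_sites:
        rows = _target_rows(df, scenario, site)
        subjects = sorted(df.loc[rows, "subject_id"].unique())
        n_affected = _round_half_up(ratio * len(subjects))
        if not n_affected:
            continue
        affected = rng.choice(subjects, size=n_affected, replace=False)
        for subj in affected:
            idx = df.index[rows & (df["subject_id"] == subj)]
            x = df.loc[idx, "value"].to_numpy(dtype=float)
            lo, hi, mean = float(x.min()), float(x.max()), float(x.mean())
            name = pool_names[rng.integers(len(pool_names))]
            raw = np.asarray(_LOF_POOL[name](rng, len(x), lo, hi), dtype=float)
            draw_range = raw.max() - raw.min()
            if draw_range > 0 and hi > lo:
                new = (raw - raw.mean()) * ((hi - lo) / draw_range) + mean
            else:
                new = raw - raw.mean() + mean
            df.loc[idx, "value"] = new
    return Study(df)


_INJECTORS = {
    "average": inject_average,
    "sd": inject_sd,
    "range": inject_range,
    "unique_value_ratio": inject_unique,
    "autocorrelation": inject_autocorrelation,
    "lof": inject_lof,
}


def inject(study: Study, scenario: AnomalyScenario) -> Study:
    """Apply the scenario's anomaly type to the study."""
    return _INJECTORS[scenario.anomaly_type](study, scenario)
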