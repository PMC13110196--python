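"""Site-level anomaly scoring.

Three methods turn a feature matrix into per-site verdicts:

* ``ks`` — two-sided two-sample Kolmogorov–Smirnov test of each site's
  feature values against the pooled values of all other sites (asymptotic
  p-value; sites of any size >= 1 are tested).
* ``lmm`` — an intercept-only linear mixed model with nested random
  intercepts (site within country within region).  Each entity's random
  effect is simulated from its conditional (posterior) distribution; the
  median and SD of the draws give a two-sided normal-approximation p-value
  for deviation from zero, p = 2 * Phi(-|median| / sd).
* ``average`` — each site's mean feature value; sites strictly outside
  [Q1 - m*IQR, Q3 + m*IQR] of the site means are flagged (no p-value).

For the p-value methods, all raw p-values of one scoring run (all sites x
features x groups) form one family corrected with Benjamini–Yekutieli, which
is valid under the arbitrary dependence created by re-using the same data
across tests.  The score is -log10 of the adjusted p; a site x feature is
flagged when its maximum score across groups reaches the threshold
(default 1.3, i.e. adjusted p ~ 0.05).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

METHODS = ("ks", "lmm", "average")

#: floor applied to adjusted p-values before taking the log
_P_FLOOR = 1e-300


@dataclass
class ScoringConfig:
    """Scoring options: method, flag threshold, IQR fence multiplier,
    number of conditional-distribution draws for the mixed model, and the
    RNG seed for those draws."""

    method: str = "ks"
    score_threshold: float = 1.3
    iqr_multiplier: float = 1.5
    lmm_draws: int = 1000
    seed: int = 0
    fdr_method: str = "fdr_by"  # escape hatch; "fdr_by" is the supported default

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown scoring method: {self.method!r}")
        if self.score_threshold <= 0 or self.iqr_multiplier <= 0:
            raise ConfigurationError("score_threshold and iqr_multiplier must be > 0")


# -- primitives ----------------------------------------------------------------


def ks_site_pvalue(site_values, other_values) -> tuple[float, float]:
    """Two-sample K-S D statistic and asymptotic p for one site vs the rest.

    NaN feature values are dropped first; an empty side makes the site
    untestable and returns (nan, nan).
    """
    a = np.asarray(site_values, dtype=float)
    b = np.asarray(other_values, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        return (float("nan"), float("nan"))
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def by_adjust(pvalues) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values.

    NaN entries pass through untouched; defined entries must lie in [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_by")[1]
    return out


def ctas_score(adjusted_p: float) -> float:
    """-log10 of an adjusted p-value (p floored at 1e-300); NaN passes through."""
    if np.isnan(adjusted_p):
        return float("nan")
    return float(-np.log10(max(adjusted_p, _P_FLOOR)))


# -- mixed model ---------------------------------------------------------------


def _fit_nested_lmm(df: pd.DataFrame):
    """Fit y ~ 1 with random intercepts for the hierarchy levels that vary.

    Returns (levels, effects, intercept_se) where effects maps
    level -> {entity: (mean, sd)} of the conditional distribution of that
    entity's random effect and intercept_se is the REML standard error of
    the fixed intercept.
    """
    n_regions = df["region_id"].nunique()
    n_countries = df["country_id"].nunique()

    if n_regions > 1:
        groups, vc = "region_id", {"country": "0 + C(country_id)", "site": "0 + C(site_id)"}
        modeled = ["region", "country", "site"]
    elif n_countries > 1:
        groups, vc = "country_id", {"site": "0 + C(site_id)"}
        modeled = ["country", "site"]
    else:
        groups, vc = "site_id", None
        modeled = ["site"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            "value ~ 1", df, groups=groups, re_formula="1", vc_formula=vc
        )
        fit = model.fit(reml=True, method="powell")

    effects: dict[str, dict[str, tuple[float, float]]] = {lvl: {} for lvl in modeled}
    re_means = fit.random_effects
    re_covs = fit.random_effects_cov
    group_level = modeled[0]
    for grp, means in re_means.items():
        sds = pd.Series(np.sqrt(np.maximum(np.diag(np.asarray(re_covs[grp])), 0.0)),
                        index=means.index)
        for name, mean in means.items():
            if name.startswith("country["):
                lvl, ent = "country", name.split("[", 2)[-1].rstrip("]").split("[")[-1]
            elif name.startswith("site["):
                lvl, ent = "site", name.split("[", 2)[-1].rstrip("]").split("[")[-1]
            else:  # the group-level random intercept row
                lvl, ent = group_level, str(grp)
            effects[lvl][ent] = (float(mean), float(sds[name]))
    intercept_se = float(np.asarray(fit.bse_fe)[0])
    return modeled, effects, intercept_se


def lmm_site_pvalues(
    features: FeatureMatrix,
    hierarchy: pd.DataFrame,
    config: ScoringConfig,
    feature: str,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.Series]:
    """Conditional-simulation p-values for sites, countries and regions.

    Fits the nested intercept-only mixed model on one feature column, draws
    ``config.lmm_draws`` simulated random effects per entity from the
    conditional normal distribution, and converts the median and SD of the
    draws into a two-sided p-value.  Each draw adds the fixed intercept's
    sampling noise: entity effects are deviations from the fitted grand
    intercept, and when a few extreme sites drag that intercept, ignoring
    its uncertainty would make every compliant site "deviate" significantly
    (this is how R tools such as arm::sim simulate random effects).
    Hierarchy levels without variation (single country / single region) get
    p = 1.  Degenerate fits (zero variance) yield p = 1 for every entity,
    with a logged warning.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    values = features.values[feature]
    sites = features.subject_sites
    df = pd.DataFrame({
        "value": values.to_numpy(dtype=float),
        "site_id": sites.reindex(values.index).to_numpy(),
    }).dropna(subset=["value"])
    df["country_id"] = df["site_id"].map(hierarchy["country_id"])
    df["region_id"] = df["site_id"].map(hierarchy["region_id"])

    all_sites = hierarchy.index
    all_countries = hierarchy["country_id"].unique()
    all_regions = hierarchy["region_id"].unique()
    ones = {
        "site": pd.Series(1.0, index=all_sites),
        "country": pd.Series(1.0, index=all_countries),
        "region": pd.Series(1.0, index=all_regions),
    }

    if len(df) < 2 or df["site_id"].nunique() < 2 or float(np.var(df["value"])) < 1e-24:
        if len(df) >= 2:
            logger.warning("lmm: degenerate feature column %r, returning p = 1", feature)
        return ones

    try:
        modeled, effects, intercept_se = _fit_nested_lmm(df)
    except Exception as exc:  # singular fits on pathological features
        logger.warning("lmm fit failed for %r (%s); returning p = 1", feature, exc)
        return ones

    out = dict(ones)
    for lvl in modeled:
        ser = ones[lvl].copy()
        for ent, (mean, sd) in effects[lvl].items():
            total_sd = float(np.hypot(sd, intercept_se))
            draws = rng.normal(mean, total_sd, config.lmm_draws)
            med, s = float(np.median(draws)), float(np.std(draws))
            ser[ent] = 1.0 if s == 0 else float(2.0 * stats.norm.sf(abs(med) / s))
        out[lvl] = ser
    return out


# -- average-feature method ----------------------------------------------------


def average_site_flags(features: FeatureMatrix, iqr_multiplier: float, feature: str) -> pd.Series:
    """IQR-fence outlier flags on per-site mean feature values.

    Sites strictly outside [Q1 - m*IQR, Q3 + m*IQR] of the site means are
    flagged.  With fewer than 4 sites having a defined mean the quartiles are
    meaningless: every flag is False and a warning is logged.
    """
    vals = features.values[feature]
    site_means = vals.groupby(features.subject_sites.reindex(vals.index)).mean()
    defined = site_means.dropna()
    flags = pd.Series(False, index=site_means.index)
    if len(defined) < 4:
        logger.warning(
            "average method: only %d sites with defined %r mean; no flags",
            len(defined), feature,
        )
        return flags
    q1, q3 = np.percentile(defined, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
    flags.loc[defined.index] = (defined < lo) | (defined > hi)
    return flags


# -- full scoring run ----------------------------------------------------------


def _seed_for(base: int, *parts) -> int:
    """Stable sub-seed derived from a base seed and string parts (< 2^31)."""
    h = zlib.crc32("|".join(str(p) for p in parts).encode())
    return (base * 2654435761 + h) % (2**31 - 1)


def score_sites(
    features_by_group: list[FeatureMatrix],
    hierarchy: pd.DataFrame,
    config: ScoringConfig,
) -> pd.DataFrame:
    """Score every (site x feature x group) with the configured method.

    Returns the full score table with columns site_id, level, feature,
    group_id, method, raw_p, adjusted_p, score, flagged.  For the p-value
    methods the BY family is all site-level raw p-values of this run, and a
    site x feature is flagged when its maximum score over groups reaches
    ``config.score_threshold``.  Country/region rows (lmm only) are adjusted
    within their own level's family and never drive site flags.  For the
    average method ``flagged`` is the per-group IQR verdict OR-ed over groups.
    """
    if config.method not in METHODS:
        raise ConfigurationError(f"unknown scoring method: {config.method!r}")
    if not features_by_group:
        raise ConfigurationError("score_sites needs at least one feature matrix")

    rows: list[dict] = []
    for fm in features_by_group:
        site_of = fm.subject_sites
        for feature in fm.feature_names:
            vals = fm.values[feature]
            if config.method == "ks":
                for site in hierarchy.index:
                    mask = (site_of.reindex(vals.index) == site).to_numpy()
                    d, p = ks_site_pvalue(vals[mask], vals[~mask])
                    rows.append(dict(site_id=site, level="site", feature=feature,
                                     group_id=fm.group_id, raw_p=p))
            elif config.method == "lmm":
                rng = np.random.default_rng(
                    _seed_for(config.seed, fm.group_id, feature))
                pvals = lmm_site_pvalues(fm, hierarchy, config, feature, rng=rng)
                for site, p in pvals["site"].items():
                    rows.append(dict(site_id=site, level="site", feature=feature,
                                     group_id=fm.group_id, raw_p=float(p)))
                for lvl in ("country", "region"):
                    for ent, p in pvals.get(lvl, pd.Series(dtype=float)).items():
                        rows.append(dict(site_id=ent, level=lvl, feature=feature,
                                         group_id=fm.group_id, raw_p=float(p)))
            else:  # average
                flags = average_site_flags(fm, config.iqr_multiplier, feature)
                for site in hierarchy.index:
                    rows.append(dict(site_id=site, level="site", feature=feature,
                                     group_id=fm.group_id, raw_p=np.nan,
                                     flagged=bool(flags.get(site, False))))

    table = pd.DataFrame(rows)
    table["method"] = config.method

    if config.method == "average":
        table["adjusted_p"] = np.nan
        table["score"] = np.nan
        # site x feature verdict: flagged in ANY group
        any_flag = table.groupby(["site_id", "feature"])["flagged"].transform("max")
        table["flagged"] = any_flag.astype(bool)
    else:
        table["adjusted_p"] = np.nan
        for lvl in table["level"].unique():
            m = table["level"] == lvl
            table.loc[m, "adjusted_p"] = by_adjust(table.loc[m, "raw_p"])
        table["score"] = table["adjusted_p"].map(ctas_score)
        site_rows = table["level"] == "site"
        max_score = (
            table[site_rows]
            .groupby(["site_id", "feature"])["score"]
            .transform("max")
        )
        table["flagged"] = False
        table.loc[site_rows, "flagged"] = (max_score >= config.score_threshold).fillna(False)

    cols = ["site_id", "level", "feature", "group_id", "method",
            "raw_p", "adjusted_p", "score", "flagged"]
    return table[cols]


def flagged_sites(score_table: pd.DataFrame, feature: str | None = None) -> set[str]:
    """Site ids flagged in a score table, optionally restricted to one feature."""
    t = score_table[score_table["level"] == "site"]
    if feature is not None:
        t = t[t["feature"] == feature]
    return set(t.loc[t["flagged"], "site_id"])
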