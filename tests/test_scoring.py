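import math

import numpy as np
import pandas as pd
import pytest

from spotter.errors import ConfigurationError
from spotter.features import FeatureMatrix, compute_features
from spotter.grouping import GroupingConfig, manual_group
from spotter.scoring import (
    ScoringConfig,
    average_site_flags,
    by_adjust,
    ctas_score,
    flagged_sites,
    ks_site_pvalue,
    lmm_site_pvalues,
    score_sites,
)
from spotter.synth import ParameterSpec, SynthConfig, generate_study

from . import oracles


def _feature_matrix(values_by_site: dict[str, list[float]], feature="average") -> FeatureMatrix:
    """One-feature matrix with one subject per value."""
    rows, sites = {}, {}
    i = 0
    for site, vals in values_by_site.items():
        for v in vals:
            sid = f"P{i:03d}"
            rows[sid] = v
            sites[sid] = site
            i += 1
    values = pd.DataFrame({feature: pd.Series(rows)})
    return FeatureMatrix(group_id="ALT:L4", parameter="ALT",
                         values=values, subject_sites=pd.Series(sites))


def _hierarchy(sites, country="C1", region="R1") -> pd.DataFrame:
    return pd.DataFrame(
        {"country_id": country, "region_id": region}, index=pd.Index(sites, name="site_id")
    )


class TestKS:
    def test_identical_samples(self):
        d, p = ks_site_pvalue([1, 2, 3], [1, 2, 3])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        from scipy import stats

        d, p = ks_site_pvalue(np.arange(8), np.arange(100, 108))
        assert d == 1.0
        exact = oracles.ks_d1_exact_pvalue(8, 8)
        # the reported asymptotic p never exceeds the enumerated exact value
        assert 0.0 <= p <= exact
        # and scipy's exact mode reproduces the enumeration oracle
        p_exact = stats.ks_2samp(np.arange(8), np.arange(100, 108), method="exact").pvalue
        assert p_exact == pytest.approx(exact, rel=1e-12)

    def test_nan_dropped(self):
        d, p = ks_site_pvalue([1.0, math.nan], [1.0, 2.0, math.nan])
        assert np.isfinite(d) and np.isfinite(p)

    def test_empty_side_untestable(self):
        d, p = ks_site_pvalue([], [1.0, 2.0])
        assert math.isnan(d) and math.isnan(p)


class TestBYAdjust:
    def test_single_value_unchanged(self):
        assert by_adjust([0.04])[0] == pytest.approx(0.04, abs=1e-12)

    def test_worked_example(self):
        got = by_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(got, [0.055, 0.055, 0.055], atol=1e-12)

    def test_matches_step_up_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            np.testing.assert_allclose(by_adjust(p), oracles.by_step_up_oracle(p), atol=1e-12)

    def test_conservative_and_monotone(self, rng):
        p = rng.random(30)
        adj = by_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_nan_passthrough(self):
        got = by_adjust([0.01, math.nan, 0.02])
        assert math.isnan(got[1])
        np.testing.assert_allclose(got[[0, 2]], oracles.by_step_up_oracle([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_adjust([0.5, 1.5])


class TestScore:
    def test_threshold_identity(self):
        assert ctas_score(0.05) == pytest.approx(1.30103, abs=1e-5)

    @pytest.mark.parametrize("p,expected", [(1.0, 0.0), (0.001, 3.0)])
    def test_powers_of_ten(self, p, expected):
        assert ctas_score(p) == pytest.approx(expected, abs=1e-12)

    def test_zero_floored(self):
        assert ctas_score(0.0) == pytest.approx(300.0)

    def test_strictly_decreasing(self, rng):
        p = np.sort(rng.random(50))
        scores = [ctas_score(v) for v in p]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestLMM:
    def _null_matrix(self, rng, n_sites=20, n_per_site=10):
        return _feature_matrix({
            f"S{i:02d}": list(rng.normal(0, 1, n_per_site)) for i in range(n_sites)
        })

    def test_null_calibration(self, rng):
        """Pure-noise features: few sites reach p < 0.05."""
        hits = total = 0
        cfg = ScoringConfig(method="lmm", seed=1)
        for _ in range(25):
            fm = self._null_matrix(rng)
            p = lmm_site_pvalues(fm, _hierarchy(fm.subject_sites.unique()), cfg, "average")["site"]
            hits += int((p < 0.05).sum())
            total += len(p)
        assert hits / total <= 0.10

    def test_signal_recovery(self, rng):
        fm = self._null_matrix(rng)
        shifted = fm.values.copy()
        target = fm.subject_sites == "S03"
        shifted.loc[target[target].index, "average"] += 10.0
        fm2 = FeatureMatrix("ALT:L4", "ALT", shifted, fm.subject_sites)
        cfg = ScoringConfig(method="lmm", seed=2)
        p = lmm_site_pvalues(fm2, _hierarchy(fm.subject_sites.unique()), cfg, "average")["site"]
        assert p.idxmin() == "S03"
        assert p.min() < 1e-3

    def test_degenerate_hierarchy_levels(self, rng):
        fm = self._null_matrix(rng, n_sites=6)
        cfg = ScoringConfig(method="lmm", seed=3)
        out = lmm_site_pvalues(fm, _hierarchy(fm.subject_sites.unique()), cfg, "average")
        assert (out["country"] == 1.0).all()
        assert (out["region"] == 1.0).all()

    def test_constant_feature_all_one(self, rng):
        fm = _feature_matrix({f"S{i}": [1.0] * 5 for i in range(6)})
        cfg = ScoringConfig(method="lmm", seed=4)
        out = lmm_site_pvalues(fm, _hierarchy(fm.subject_sites.unique()), cfg, "average")
        assert (out["site"] == 1.0).all()

    def test_nested_hierarchy_recovers_site(self, rng):
        """Multi-country data routes through the nested model and still finds
        the shifted site."""
        vals, sites, countries = {}, {}, {}
        i = 0
        for c in range(3):
            for s in range(4):
                site = f"C{c}S{s}"
                shift = 8.0 if site == "C1S2" else 0.0
                for v in rng.normal(shift, 1, 8):
                    sid = f"P{i:03d}"
                    vals[sid], sites[sid] = v, site
                    i += 1
                countries[site] = f"C{c}"
        fm = FeatureMatrix("ALT:L4", "ALT",
                           pd.DataFrame({"average": pd.Series(vals)}), pd.Series(sites))
        hier = pd.DataFrame({"country_id": pd.Series(countries), "region_id": "R1"})
        hier.index.name = "site_id"
        cfg = ScoringConfig(method="lmm", seed=5)
        out = lmm_site_pvalues(fm, hier, cfg, "average")
        assert out["site"].idxmin() == "C1S2"
        assert out["site"].min() < 1e-3
        assert len(out["country"]) == 3

    def test_deterministic_for_seed(self, rng):
        fm = self._null_matrix(rng, n_sites=8)
        hier = _hierarchy(fm.subject_sites.unique())
        cfg = ScoringConfig(method="lmm", seed=9)
        a = lmm_site_pvalues(fm, hier, cfg, "average")["site"]
        b = lmm_site_pvalues(fm, hier, cfg, "average")["site"]
        pd.testing.assert_series_equal(a, b)


class TestAverageFlags:
    def test_obvious_outlier(self):
        fm = _feature_matrix({f"S{i}": [1.0] for i in range(9)} | {"S9": [50.0]})
        flags = average_site_flags(fm, 1.5, "average")
        assert flags["S9"]
        assert flags.sum() == 1

    def test_all_equal_none_flagged(self):
        fm = _feature_matrix({f"S{i}": [2.0, 2.0] for i in range(6)})
        assert not average_site_flags(fm, 1.5, "average").any()

    def test_boundary_value_not_flagged(self):
        # site means [0, 0, 10, 10, 25]: Q1=0, Q3=10, upper fence 10+1.5*10=25
        fm = _feature_matrix({"S0": [0.0], "S1": [0.0], "S2": [10.0],
                              "S3": [10.0], "S4": [25.0]})
        assert not average_site_flags(fm, 1.5, "average").any()

    def test_beyond_boundary_flagged(self):
        fm = _feature_matrix({"S0": [0.0], "S1": [0.0], "S2": [10.0],
                              "S3": [10.0], "S4": [26.0]})
        flags = average_site_flags(fm, 1.5, "average")
        assert flags["S4"] and flags.sum() == 1

    def test_too_few_sites_no_flags(self):
        fm = _feature_matrix({"S0": [1.0], "S1": [2.0], "S2": [90.0]})
        assert not average_site_flags(fm, 1.5, "average").any()


@pytest.fixture(scope="module")
def study_groups():
    cfg = SynthConfig(n_sites=8, subjects_per_site=8, n_visits=6,
                          parameters=(ParameterSpec("ALT", 30, 8, 0.2, 5),),
                      missing_rate=0.0, staggered_fraction=0.0,
                      unscheduled_rate=0.0, screen_failure_rate=0.0, seed=21)
    study = generate_study(cfg)
    g1 = manual_group(study, "ALT", [1, 2, 3, 4, 5, 6], GroupingConfig(min_group_size=5))
    g2 = manual_group(study, "ALT", [1, 2, 3], GroupingConfig(min_group_size=5))
    return study, [compute_features(g) for g in (g1, g2)]


class TestScoreSites:
    def test_family_matches_oracle(self, study_groups):
        study, feats = study_groups
        table = score_sites(feats, study.site_hierarchy(), ScoringConfig(method="ks"))
        site_rows = table[table["level"] == "site"]
        raw = site_rows["raw_p"].to_numpy()
        ok = np.isfinite(raw)
        np.testing.assert_allclose(
            site_rows["adjusted_p"].to_numpy()[ok],
            oracles.by_step_up_oracle(raw[ok]),
            atol=1e-12,
        )

    def test_score_is_log_of_adjusted(self, study_groups):
        study, feats = study_groups
        table = score_sites(feats, study.site_hierarchy(), ScoringConfig(method="ks"))
        defined = table.dropna(subset=["adjusted_p"])
        np.testing.assert_allclose(
            defined["score"], -np.log10(np.maximum(defined["adjusted_p"], 1e-300)), atol=1e-12
        )
        assert (defined["adjusted_p"] >= defined["raw_p"] - 1e-15).all()

    def test_max_over_groups_flagging(self):
        """A site extreme in only one of two groups is still flagged."""
        rng = np.random.default_rng(0)
        fm1 = _feature_matrix({f"S{i}": list(rng.normal(0, 1, 10)) for i in range(10)})
        shifted = fm1.values.copy()
        target = fm1.subject_sites == "S4"
        shifted.loc[target[target].index, "average"] += 50.0
        fm_hot = FeatureMatrix("ALT:L6", "ALT", shifted, fm1.subject_sites)
        fm_cold = _feature_matrix({f"S{i}": list(rng.normal(0, 1, 10)) for i in range(10)})
        fm_cold.group_id = "ALT:L3"
        table = score_sites([fm_hot, fm_cold], _hierarchy([f"S{i}" for i in range(10)]),
                            ScoringConfig(method="ks"))
        assert "S4" in flagged_sites(table, "average")
        per_group = table[(table["site_id"] == "S4") & (table["feature"] == "average")]
        assert per_group["flagged"].all()  # flag is a site x feature verdict

    def test_all_null_p_nothing_flagged(self):
        fm = _feature_matrix({f"S{i}": [3.0, 3.0] for i in range(6)})
        table = score_sites([fm], _hierarchy([f"S{i}" for i in range(6)]),
                            ScoringConfig(method="ks"))
        assert (table["raw_p"].dropna() == 1.0).all()
        assert (table["score"].dropna() == 0.0).all()
        assert not table["flagged"].any()

    def test_average_method_any_group_rule(self):
        fm1 = _feature_matrix({f"S{i}": [1.0] for i in range(9)} | {"S9": [50.0]})
        fm2 = _feature_matrix({f"S{i}": [1.0] for i in range(9)} | {"S9": [1.0]})
        fm2.group_id = "ALT:L1"
        table = score_sites([fm1, fm2], _hierarchy([f"S{i}" for i in range(10)]),
                            ScoringConfig(method="average"))
        assert flagged_sites(table) == {"S9"}
        assert table["raw_p"].isna().all() and table["score"].isna().all()

    def test_unknown_method_rejected(self, study_groups):
        study, feats = study_groups
        with pytest.raises(ConfigurationError):
            ScoringConfig(method="bogus")
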