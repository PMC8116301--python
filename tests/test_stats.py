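"""Outlier screening, group tests, ROC/cutpoint, correlation and QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import (
    iqr_flags,
    mann_whitney_enumeration,
    pairwise_auc,
    rank_pearson,
    youden_scan,
)
from glycomody import synth
from glycomody.stats import (
    HIGHER,
    LOWER,
    CutpointClassifier,
    bonferroni,
    covariate_checks,
    evaluate_biomarkers,
    flag_outliers_iqr,
    interlab_concordance,
    mann_whitney,
    optimal_cutpoint,
    qc_cv,
    roc,
    spearman,
)


class TestOutliers:
    def test_one_to_five_has_no_outliers(self):
        assert not flag_outliers_iqr([1, 2, 3, 4, 5]).any()

    def test_extreme_value_flagged(self):
        flags = flag_outliers_iqr([1, 2, 3, 4, 100])
        assert list(flags) == [False, False, False, False, True]

    def test_identical_values_never_flagged(self):
        assert not flag_outliers_iqr([3.0] * 10).any()

    def test_small_group_warns_and_skips(self):
        with pytest.warns(UserWarning, match="not screened"):
            flags = flag_outliers_iqr([1, 2, 1000])
        assert not flags.any()

    def test_nan_never_flagged(self):
        flags = flag_outliers_iqr([1, 2, 3, 4, np.nan, 100])
        assert not flags[4] and flags[5]

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=60),
           st.sampled_from([1.0, 1.5, 3.0]))
    def test_matches_brute_force_quartile_oracle(self, values, k):
        np.testing.assert_array_equal(flag_outliers_iqr(values, k=k),
                                      iqr_flags(values, k=k))


class TestMannWhitney:
    def test_exact_small_sample_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(1.0 / 3.0)
        assert res.u == 0.0

    def test_identical_multisets_symmetric(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(a, a)
        assert res.u == len(a) ** 2 / 2
        assert res.p_value >= 0.99

    def test_exact_and_asymptotic_agree_at_n8(self, rng):
        a = rng.permutation(np.arange(16.0))[:8]
        b = np.setdiff1d(np.arange(16.0), a)
        p_exact = mann_whitney(a, b, mode="exact").p_value
        p_asym = mann_whitney(a, b, mode="asymptotic").p_value
        assert abs(p_exact - p_asym) < 0.02

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            n1, n2 = rng.integers(2, 6, 2)
            pool = rng.permutation(np.arange(20.0))[:n1 + n2]
            a, b = pool[:n1], pool[n1:]
            u_ref, p_ref = mann_whitney_enumeration(a, b)
            res = mann_whitney(a, b)
            assert res.mode == "exact"
            assert res.u == u_ref
            assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_ties_force_asymptotic_mode(self):
        res = mann_whitney([1, 2, 2], [2, 3, 4])
        assert res.mode == "asymptotic"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestBonferroni:
    def test_scaling_and_clamp(self):
        np.testing.assert_allclose(bonferroni([0.01], m=5), [0.05])
        np.testing.assert_allclose(bonferroni([0.5], m=10), [1.0])

    def test_m_one_is_identity(self):
        np.testing.assert_allclose(bonferroni([0.3], m=1), [0.3])

    def test_default_family_is_length(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.02]), [0.02, 0.04])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestRoc:
    def test_perfect_separation(self):
        rr = roc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert rr.auc == 1.0
        assert rr.sensitivity == 1.0 and rr.specificity == 1.0

    def test_identical_scores_give_half(self):
        rr = roc([5.0] * 6, [True, False] * 3)
        assert rr.auc == pytest.approx(0.5)

    def test_pairwise_oracle_example(self):
        # cases {2,3} vs controls {1,2}: (1 + 0.5 + 1 + 1)/4 = 0.875
        rr = roc([2, 3, 1, 2], [True, True, False, False], direction=HIGHER)
        assert rr.auc == pytest.approx(0.875)
        assert rr.auc == pytest.approx(pairwise_auc([2, 3], [1, 2]))

    def test_curve_endpoints_and_monotonicity(self, rng):
        rr = roc(rng.normal(size=40), rng.random(40) < 0.4)
        assert (rr.fpr[0], rr.tpr[0]) == (0.0, 0.0)
        assert (rr.fpr[-1], rr.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(rr.fpr) >= 0).all() and (np.diff(rr.tpr) >= 0).all()
        assert 0.0 <= rr.auc <= 1.0

    def test_auto_direction_detects_lower_case_scores(self, rng):
        cases = rng.normal(0.05, 0.01, 20)
        controls = rng.normal(0.12, 0.01, 50)
        rr = roc(np.concatenate([cases, controls]),
                 [True] * 20 + [False] * 50)
        assert rr.direction == LOWER and rr.auc > 0.9

    def test_direction_safety_under_score_inversion(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.3
        rr1 = roc(scores, labels)
        rr2 = roc(-scores, labels)
        assert rr1.direction != rr2.direction
        assert rr1.auc == pytest.approx(rr2.auc, abs=1e-12)
        assert rr1.sensitivity == pytest.approx(rr2.sensitivity)
        assert rr1.specificity == pytest.approx(rr2.specificity)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [True, True, True])

    def test_auc_u_identity_with_ties(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 20, 2)
            a = rng.integers(0, 6, n1).astype(float)
            b = rng.integers(0, 6, n2).astype(float)
            rr = roc(np.concatenate([a, b]),
                     [True] * n1 + [False] * n2, direction=HIGHER)
            u = mann_whitney(a, b).u
            assert abs(rr.auc - u / (n1 * n2)) < 1e-12


class TestCutpoint:
    def test_midpoint_convention_perfect_separation(self):
        rr = roc([0.02, 0.05, 0.11, 0.15, 0.2],
                 [True, True, False, False, False], direction=LOWER)
        assert rr.cutoff == pytest.approx(0.08)
        assert rr.sensitivity == 1.0 and rr.specificity == 1.0

    def test_tie_broken_toward_higher_specificity(self):
        rr = roc([1.0, 3.0, 2.0, 4.0], [True, True, False, False],
                 direction=LOWER)
        # J ties at cutoffs 1.5 (spec 1.0) and 3.5 (spec 0.5)
        assert rr.cutoff == pytest.approx(1.5)
        assert rr.specificity == 1.0

    def test_matches_exhaustive_youden_scan(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 10, 30).astype(float)
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            rr = roc(scores, labels, direction=HIGHER)
            j = rr.sensitivity + rr.specificity
            assert j == pytest.approx(youden_scan(scores, labels, False),
                                      abs=1e-12)

    def test_classifier_estimator(self, rng):
        cases = rng.normal(0.04, 0.01, 30)
        controls = rng.normal(0.12, 0.02, 70)
        X = np.concatenate([cases, controls]).reshape(-1, 1)
        y = np.array([True] * 30 + [False] * 70)
        clf = CutpointClassifier().fit(X, y)
        assert clf.direction_ == LOWER and clf.auc_ > 0.95
        pred = clf.predict(X)
        acc = (pred == y).mean()
        assert acc > 0.9
        from sklearn.base import clone

        assert clone(clf).direction == clf.direction


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.linspace(0, 5, 20)
        assert spearman(x, np.exp(x)) == 1.0
        assert spearman(x, -x) == -1.0

    def test_rank_example(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_matches_rank_pearson_oracle(self, rng):
        x = rng.integers(0, 10, 50).astype(float)  # ties included
        y = x + rng.normal(0, 3, 50)
        assert spearman(x, y) == pytest.approx(rank_pearson(x, y), abs=1e-12)

    def test_pairwise_complete(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, 2.0, 3.0, 4.0, np.nan]
        assert spearman(x, y) == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])


class TestInterlab:
    def test_inversion_flagged(self, rng):
        a = pd.DataFrame({"T": rng.uniform(size=30)})
        b = pd.DataFrame({"T": -a["T"]})
        out = interlab_concordance(a, b)
        assert out.loc["T", "spearman_r"] == -1.0
        assert bool(out.loc["T", "direction_inverted"])

    def test_no_shared_columns_rejected(self):
        with pytest.raises(ValueError):
            interlab_concordance(pd.DataFrame({"A": [1.0, 2, 3]}),
                                 pd.DataFrame({"B": [1.0, 2, 3]}))


class TestQcCv:
    def frame(self, rows, plates):
        df = pd.DataFrame(rows, columns=["p1", "p2"])
        df.insert(0, "plate", plates)
        return df

    def test_identical_replicates_zero_cv(self):
        df = self.frame([[0.5, 0.5]] * 6, ["a"] * 3 + ["b"] * 3)
        report, summary = qc_cv(df)
        assert (report["intra_cv_pct"] == 0).all()
        assert (report["inter_cv_pct"] == 0).all()
        assert summary.mean_intra_cv_pct == 0.0

    def test_single_plate_cv_is_sd_over_mean(self):
        df = pd.DataFrame({"plate": ["a"] * 3, "p1": [9.0, 10.0, 11.0]})
        report, _ = qc_cv(df)
        assert report.loc["p1", "intra_cv_pct"] == pytest.approx(10.0)
        assert np.isnan(report.loc["p1", "inter_cv_pct"])  # needs >= 2 plates

    def test_low_intensity_peak_excluded_from_summary(self):
        rows = [[0.5, 0.005]] * 6  # p2 averages 0.5% relative intensity
        df = self.frame(rows, ["a"] * 3 + ["b"] * 3)
        _, summary = qc_cv(df)
        assert summary.n_peaks_included == 1

    def test_missing_plate_column_rejected(self):
        with pytest.raises(ValueError):
            qc_cv(pd.DataFrame({"p1": [1.0]}))

    def test_generator_cvs_recovered(self, default_peak_table):
        trips = synth.generate_triplicates(default_peak_table.iloc[0], 32,
                                           intra_cv=0.04, inter_cv=0.06,
                                           seed=3)
        _, summary = qc_cv(trips)
        assert summary.mean_intra_cv_pct == pytest.approx(4.0, rel=0.25)
        assert summary.mean_inter_cv_pct == pytest.approx(6.0, rel=0.25)


@pytest.fixture(scope="module")
def cohort_tables():
    cohort = synth.generate_cohort(synth.CohortSpec(seed=21))
    df = synth.cohort_to_frame(cohort)
    traits = df[list(synth.SINGLE_TRAITS)]
    return traits, df["group"], df


class TestEvaluateBiomarkers:

    def test_separated_cohort_high_auc(self, cohort_tables):
        traits, groups, _ = cohort_tables
        report, _ = evaluate_biomarkers(traits, groups,
                                        comparisons=[("damaging", "none")])
        assert (report["auc"] > 0.8).all()
        assert (report["direction"] == LOWER).all()
        assert (report["p_bonferroni"] < 0.05).all()

    def test_report_grid_shape(self, cohort_tables):
        traits, groups, _ = cohort_tables
        report, _ = evaluate_biomarkers(traits, groups)
        assert len(report) == len(traits.columns) * 2
        assert set(report["comparison"]) == {"damaging:none", "damaging:benign"}

    def test_vus_classification_definition(self, cohort_tables):
        traits, groups, _ = cohort_tables
        report, vus = evaluate_biomarkers(traits, groups)
        assert set(vus["trait"]) == set(traits.columns)
        first = report[report["comparison"] == "damaging:none"].set_index("trait")
        for _, row in vus.iterrows():
            cutoff = first.loc[row["trait"], "cutoff"]
            assert row["classified_pathogenic"] == (row["value"] < cutoff)

    def test_missing_group_rejected(self, cohort_tables):
        traits, groups, _ = cohort_tables
        with pytest.raises(ValueError, match="absent"):
            evaluate_biomarkers(traits, groups,
                                comparisons=[("damaging", "nonexistent")])

    def test_outliers_excluded_per_trait(self, cohort_tables):
        traits, groups, _ = cohort_tables
        spiked = traits.copy()
        target = spiked.index[groups.to_numpy() == "none"][0]
        spiked.loc[target, "A3FG3S2"] = 0.99  # far outside the group fences
        report, _ = evaluate_biomarkers(spiked, groups,
                                        comparisons=[("damaging", "none")])
        row = report.set_index("trait").loc["A3FG3S2"]
        assert row["n_control"] < (groups == "none").sum()
        assert row["n_outliers_removed"] >= 1
        other = report.set_index("trait").loc["A3FG3S3"]
        assert other["n_control"] >= row["n_control"]

    def test_covariate_checks_smoke(self, cohort_tables):
        traits, _, df = cohort_tables
        out = covariate_checks(traits, df)
        assert set(out.columns) == {"spearman_age", "p_sex"}
        assert out["spearman_age"].between(-1, 1).all()
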