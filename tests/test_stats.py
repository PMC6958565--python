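import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cranioflow.cohort_defaults import NORMATIVE_GROUPS
from cranioflow.stats import (
    build_report,
    classify_correlation,
    compare_groups,
    correlate,
    exclude_outliers,
)


class TestOutlierExclusion:
    def test_all_equal_values_kept(self):
        kept, excluded = exclude_outliers([5.0] * 6)
        assert excluded == []
        assert len(kept) == 6

    def test_mean_centred_bounds_match_brute_force(self):
        """The mean-centred 1.5·IQR interval is applied verbatim; with an
        extreme value dragging the mean, the oracle-computed bounds
        exclude every point of {1..5, 100} (the Tukey median variant
        keeps the bulk and drops only 100)."""
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 100.0]
        q1, q3 = np.percentile(vals, [25, 75])
        lo, hi = np.mean(vals) - 1.5 * (q3 - q1), np.mean(vals) + 1.5 * (q3 - q1)
        expected = [i for i, v in enumerate(vals) if v < lo or v > hi]
        kept, excluded = exclude_outliers(vals)
        assert excluded == expected
        # median-centred variant: only the extreme value goes
        kept_m, excluded_m = exclude_outliers(vals, use_median=True)
        assert excluded_m == [5]
        np.testing.assert_array_equal(kept_m, vals[:5])

    def test_moderate_outlier_with_mean_centre(self):
        """With a mild outlier the verbatim rule behaves like the Tukey
        variant: bounds verified against direct computation."""
        vals = [10.0, 11.0, 12.0, 13.0, 14.0, 19.0]
        q1, q3 = np.percentile(vals, [25, 75])
        lo, hi = np.mean(vals) - 1.5 * (q3 - q1), np.mean(vals) + 1.5 * (q3 - q1)
        kept, excluded = exclude_outliers(vals)
        assert excluded == [i for i, v in enumerate(vals) if v < lo or v > hi] == [5]

    def test_symmetric_in_bounds_identity(self):
        vals = [-2.0, -1.0, 0.0, 1.0, 2.0]
        kept, excluded = exclude_outliers(vals)
        assert excluded == []
        np.testing.assert_array_equal(kept, vals)

    def test_zero_iqr_with_spread_excludes_nothing(self):
        vals = [5.0] * 8 + [50.0]
        kept, excluded = exclude_outliers(vals)
        assert excluded == []
        assert len(kept) == 9

    def test_requires_four_values(self):
        with pytest.raises(ValueError):
            exclude_outliers([1.0, 2.0, 3.0])

    def test_cohort_like_data_matches_brute_force_bounds(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(700, 120, 18), [1500.0]])
        q1, q3 = np.percentile(vals, [25, 75])
        lo, hi = vals.mean() - 1.5 * (q3 - q1), vals.mean() + 1.5 * (q3 - q1)
        kept, excluded = exclude_outliers(vals)
        assert excluded == [i for i, v in enumerate(vals) if v < lo or v > hi]
        assert 18 in excluded  # the gross outlier always goes

    def test_idempotent_on_mild_outlier_fixture(self):
        vals = [10.0, 11.0, 12.0, 13.0, 14.0, 19.0]
        kept, excluded = exclude_outliers(vals)
        assert excluded == [5]
        kept2, excluded2 = exclude_outliers(kept)
        assert excluded2 == []


class TestGroupComparison:
    def test_identical_paired_samples_not_significant(self):
        x = np.arange(10.0)
        res = compare_groups(x, x, design="paired")
        assert res.p_value == 1.0
        assert not res.significant

    def test_normal_samples_use_t_test(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.normal(0, 1, 16), rng.normal(0, 1, 19))
        assert res.test == "t"

    def test_heavy_tailed_sample_takes_nonparametric_branch(self):
        rng = np.random.default_rng(8)
        x = rng.standard_cauchy(30)
        y = rng.normal(0, 1, 30)
        res = compare_groups(x, y)
        assert res.test == "mann-whitney"
        res_p = compare_groups(x, y, design="paired")
        assert res_p.test == "wilcoxon"

    def test_power_for_one_sd_shift_at_study_sizes(self):
        """Two normal groups one SD apart at n = 16 vs 19 are detected at
        the 0.05 level in at least 80% of 500 simulations."""
        rng = np.random.default_rng(123)
        hits = sum(
            compare_groups(rng.normal(0, 1, 16), rng.normal(1, 1, 19)).significant
            for _ in range(500)
        )
        assert hits / 500 >= 0.8

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            compare_groups([1.0] * 5, [1.0] * 6, design="paired")

    def test_significance_stars(self):
        rng = np.random.default_rng(1)
        res = compare_groups(rng.normal(0, 1, 20), rng.normal(5, 1, 20))
        assert res.stars == "***"


class TestCorrelation:
    @pytest.mark.parametrize("r, expected", [
        (0.73, "strong"),
        (0.50, "moderate"),
        (0.30, "weak"),
        (0.95, "very strong"),
        (0.10, "below-weak"),
        (-0.73, "strong"),
        (0.8999, "strong"),
        (0.90, "very strong"),
    ])
    def test_strength_bands(self, r, expected):
        assert classify_correlation(r) == expected

    @given(st.floats(-1.0, 1.0))
    def test_classification_exhaustive_and_exclusive(self, r):
        assert classify_correlation(r) in (
            "below-weak", "weak", "moderate", "strong", "very strong")

    def test_exact_linear_data(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 6, 8, 10]})
        res = correlate(df, "x", "y")
        assert res.r == pytest.approx(1.0)
        assert res.strength == "very strong"
        assert res.significant

    def test_missing_values_dropped_pairwise(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, np.nan, 6],
                           "y": [1.1, 2.2, 2.8, 4.3, 5.0, np.nan]})
        res = correlate(df, "x", "y")
        assert res.n == 4

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 5, "y": [1.0, 2, 3, 4, 5]})
        with pytest.raises(ValueError):
            correlate(df, "x", "y")


@pytest.fixture(scope="module")
def truth_table():
    from cranioflow.synthetic import make_cohort
    _, truth = make_cohort(16, 19, seed=77)
    return truth


class TestCohortReport:

    def test_group_means_within_2se_of_configured(self, truth_table):
        report = build_report(truth_table, exclude=False)
        for group, n in (("HYV", 16), ("HEV", 19)):
            sub = truth_table[truth_table.group == group]
            for metric in ("extra_acbf", "intra_vcbf", "spinal_csf_sv"):
                mean, sd = NORMATIVE_GROUPS[group][metric]
                assert abs(sub[metric].mean() - mean) < 2 * sd / np.sqrt(n)

    def test_report_has_all_sections(self, truth_table):
        report = build_report(truth_table)
        assert len(report.summary) == 15  # every metric summarized
        assert set(report.paired.group) == {"HYV", "HEV"}
        assert len(report.correlations) == 6  # 3 pairs x 2 groups
        md = report.to_markdown()
        assert "No multiple-testing correction" in md

    def test_single_group_between_columns_na(self, truth_table):
        report = build_report(truth_table[truth_table.group == "HYV"])
        assert (report.summary["between test"] == "n/a").all()

    def test_drainage_fraction_of_normative_young_means(self):
        """Group-mean sinus drainage IntraVCBF/IntraACBF for a normative
        young cohort with zero variance is 478/670 = 71.3%."""
        from cranioflow.synthetic import make_cohort
        params = {g: {k: (mu, 0.0) for k, (mu, sd) in NORMATIVE_GROUPS[g].items()}
                  for g in NORMATIVE_GROUPS}
        _, truth = make_cohort(4, 4, seed=0, group_params=params)
        report = build_report(truth, exclude=False)
        row = report.ratios[report.ratios.group == "HYV"].iloc[0]
        assert row["sinus drainage IntraVCBF/IntraACBF (%)"] == pytest.approx(
            100 * 478 / 670, rel=0.01)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            build_report(pd.DataFrame({"group": []}))
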