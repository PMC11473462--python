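"""Median splits, horizon splits and the group-comparison tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ctbca import (
    characterize_groups,
    compare_index_expression,
    dagostino_pearson,
    fisher_exact_2x2,
    mann_whitney_u,
    median_split,
    simulate_cohort,
    split_by_survival_horizon,
    t_test_two_sided,
    CohortSpec,
)
from ctbca.errors import DegenerateInputError, SampleSizeError


class TestMedianSplit:
    def test_rule_application(self):
        s = median_split([1, 2, 3])
        assert s.cutoff == 2
        assert list(s.labels) == ["low", "high", "high"]

    def test_71_distinct_values(self, rng):
        values = rng.permutation(np.arange(71, dtype=float))
        s = median_split(values)
        assert (s.n_low, s.n_high) == (35, 36)

    def test_all_equal_all_high(self):
        s = median_split([5.0] * 6)
        assert s.n_high == 6 and s.n_low == 0

    def test_even_n_mean_of_middle(self):
        s = median_split([1.0, 2.0, 3.0, 4.0])
        assert s.cutoff == 2.5
        assert (s.n_low, s.n_high) == (2, 2)

    def test_too_small(self):
        with pytest.raises(DegenerateInputError):
            median_split([1.0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60, unique=True))
    def test_distinct_counts_differ_at_most_one(self, values):
        s = median_split(values)
        assert abs(s.n_low - s.n_high) <= 1


class TestHorizonSplit:
    def _cohort(self, times, events):
        return pd.DataFrame({"time": times, "event": events})

    def test_one_per_group(self):
        short, long_, excl = split_by_survival_horizon(
            self._cohort([12.0, 70.0], [1, 1]), 60.0
        )
        assert len(short) == 1 and len(long_) == 1 and excl == 0

    def test_censored_before_horizon_excluded(self):
        short, long_, excl = split_by_survival_horizon(
            self._cohort([30.0], [0]), 60.0
        )
        assert len(short) == 0 and len(long_) == 0 and excl == 1

    def test_all_after_horizon(self):
        short, long_, excl = split_by_survival_horizon(
            self._cohort([70.0, 80.0, 61.0], [1, 0, 1]), 60.0
        )
        assert len(long_) == 3 and len(short) == 0 and excl == 0


class TestDagostinoPearson:
    def test_matches_scipy_reference(self, rng):
        x = rng.normal(size=1000)
        mine = dagostino_pearson(x)
        ref = stats.normaltest(x)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)

    def test_strong_skew_rejected(self, rng):
        x = rng.exponential(size=1000)
        assert dagostino_pearson(x).p_value < 0.001

    def test_small_sample_error(self, rng):
        with pytest.raises(SampleSizeError):
            dagostino_pearson(rng.normal(size=10))

    def test_oracle_sweep(self, rng):
        for _ in range(20):
            x = rng.standard_t(df=rng.integers(3, 30), size=rng.integers(25, 400))
            assert dagostino_pearson(x).p_value == pytest.approx(
                stats.normaltest(x).pvalue, abs=1e-8
            )


class TestTTest:
    def test_identical_samples(self):
        r = t_test_two_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0 and r.p_value == 1

    def test_hand_computed(self):
        # pooled t for [1,2,3] vs [4,5,6]: t = -3/sqrt(2/3) = -3.674..., df 4
        r = t_test_two_sided([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.6742346141747673, abs=1e-10)
        assert r.p_value == pytest.approx(2 * stats.t.sf(3.6742346141747673, 4), abs=1e-12)

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_oracle_agreement(self, rng, equal_var):
        for _ in range(100):
            x = rng.normal(0, 1, size=rng.integers(3, 40))
            y = rng.normal(0.3, 2, size=rng.integers(3, 40))
            mine = t_test_two_sided(x, y, equal_var=equal_var)
            ref = stats.ttest_ind(x, y, equal_var=equal_var)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_pooled_variance(self):
        with pytest.raises(DegenerateInputError):
            t_test_two_sided([1.0, 1.0], [2.0, 2.0])


class TestMannWhitney:
    def test_exact_small_case(self):
        # all 6 rank assignments of {1,2} vs {3,4}: P(U <= 0) = 1/6, two-sided 1/3
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(1 / 3, abs=1e-12)
        assert r.test_name == "mann_whitney_exact"

    def test_symmetry_under_swap(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=11)
        assert mann_whitney_u(x, y).p_value == pytest.approx(
            mann_whitney_u(y, x).p_value, abs=1e-12
        )

    def test_exact_matches_scipy(self, rng):
        for _ in range(30):
            x = rng.permutation(np.arange(100.0))[: rng.integers(2, 12)]
            y = rng.permutation(np.arange(100.0, 200.0))[: rng.integers(2, 12)]
            mine = mann_whitney_u(x, y)
            assert mine.test_name == "mann_whitney_exact"
            ref = stats.mannwhitneyu(x, y, method="exact")
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_sample_matches_scipy(self, rng):
        x = rng.normal(size=150)
        y = rng.normal(0.2, size=180)
        mine = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, method="asymptotic")
        assert mine.test_name == "mann_whitney_normal"
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-6)

    def test_ties_route_to_normal_approx(self, rng):
        x = rng.integers(0, 4, size=25).astype(float)
        y = rng.integers(0, 4, size=25).astype(float)
        mine = mann_whitney_u(x, y)
        assert mine.test_name == "mann_whitney_normal"
        ref = stats.mannwhitneyu(x, y, method="asymptotic")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-6)


class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_enumerated_three_tables(self):
        # margins (2,2)/(2,2): tables have a=0,1,2 with probs 1/6, 4/6, 1/6
        assert fisher_exact_2x2([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_margin(self):
        with pytest.raises(DegenerateInputError):
            fisher_exact_2x2([[0, 0], [3, 4]])

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_transpose_and_swap_invariance(self, a, b, c, d):
        t = np.array([[a, b], [c, d]])
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            return
        p = fisher_exact_2x2(t).p_value
        assert fisher_exact_2x2(t.T).p_value == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2(t[::-1, ::-1]).p_value == pytest.approx(p, rel=1e-9)

    def test_scipy_oracle_sweep(self, rng):
        for _ in range(50):
            t = rng.integers(0, 40, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact_2x2(t).p_value == pytest.approx(
                stats.fisher_exact(t).pvalue, rel=1e-7
            )


class TestNullCalibration:
    """Rejection rates at alpha = 0.05 under the null, 2000 fixed-seed reps."""

    def test_t_and_mannwhitney_nominal(self):
        rng = np.random.default_rng(42)
        rej_t = rej_m = 0
        n = 2000
        for _ in range(n):
            x, y = rng.normal(size=35), rng.normal(size=36)
            rej_t += t_test_two_sided(x, y).p_value < 0.05
            rej_m += mann_whitney_u(x, y).p_value < 0.05
        assert 0.035 <= rej_t / n <= 0.065
        assert 0.035 <= rej_m / n <= 0.065

    def test_fisher_near_nominal_large_counts(self):
        # Fisher is conservative by discreteness; with large margins the
        # rejection rate approaches the nominal level from below.
        rng = np.random.default_rng(42)
        rej = 0
        n = 2000
        for _ in range(n):
            a, b = rng.binomial(400, 0.5), rng.binomial(400, 0.5)
            rej += fisher_exact_2x2([[a, 400 - a], [b, 400 - b]]).p_value < 0.05
        assert 0.035 <= rej / n <= 0.065


class TestIndexExpressionComparison:
    def _cohort_with_index(self, short_vals, long_vals):
        n1, n2 = len(short_vals), len(long_vals)
        df = pd.DataFrame(
            {
                "time": [10.0] * n1 + [100.0] * n2,
                "event": [1] * n1 + [0] * n2,
            }
        )
        for name in ("sarcopenia_index", "fat_index", "myosteatosis_index",
                     "mediastinal_fat_index", "pulmonary_fat_index"):
            df[name] = np.concatenate([short_vals, long_vals])
        return df

    def test_normal_groups_route_to_t(self, rng):
        df = self._cohort_with_index(rng.normal(2, 0.3, 60), rng.normal(2, 0.3, 60))
        out = compare_index_expression(df, horizon=60.0)
        assert (out["test"] == "t_test_pooled").all()

    def test_skewed_group_routes_to_mannwhitney(self, rng):
        df = self._cohort_with_index(rng.exponential(1.0, 60), rng.normal(2, 0.3, 60))
        out = compare_index_expression(df, horizon=60.0)
        assert (out["test"].str.startswith("mann_whitney")).all()

    def test_identical_groups_p_one(self, rng):
        vals = rng.normal(2, 0.3, 40)
        df = self._cohort_with_index(vals, vals)
        out = compare_index_expression(df, horizon=60.0)
        assert (out["p_value"] == 1.0).all()


class TestCharacterizeGroups:
    def test_null_covariates_mostly_nonsignificant(self):
        hits = total = 0
        for seed in range(8):
            cohort = simulate_cohort(CohortSpec(n=71, seed=seed))
            split_values = cohort["pulmonary_fat_index"].to_numpy()
            out = characterize_groups(cohort, median_split(split_values))
            p = out["p_value"].dropna()
            hits += (p < 0.05).sum()
            total += p.size
        # no simulated covariate correlates with PFI: type-I behaviour
        assert hits / total < 0.15

    def test_constant_categorical_flagged_not_fatal(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["diabetes"] = 1  # constant in both groups -> zero margin
        out = characterize_groups(
            cohort, median_split(cohort["pulmonary_fat_index"].to_numpy())
        )
        row = out[out["covariate"] == "diabetes"].iloc[0]
        assert row["test"].startswith("error")
        others = out[out["covariate"] != "diabetes"]
        assert others["p_value"].notna().all()

    def test_counts_sum_to_n(self, small_cohort):
        split = median_split(small_cohort["fat_index"].to_numpy())
        out = characterize_groups(small_cohort, split)
        cat = out[out["kind"] == "categorical"]
        for _, row in cat.iterrows():
            assert row["n_low"] + row["n_high"] == len(small_cohort)
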