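"""Quartiles, linear trends, gender contrasts, tallies and regressions."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dietq.model import ReferenceValue, ReferenceValues
from dietq.stats import (
    assign_quartiles,
    compare_genders,
    compare_to_reference,
    pearson_chi2_2x2,
    polynomial_linear_contrast,
    regress_behavior,
    tally_guidelines,
    trend_by_quartile,
)


class TestQuartiles:
    def test_ordered_split_of_distinct_scores(self):
        q = assign_quartiles([(str(i), float(i)) for i in range(1, 9)])
        assert q["1"] == q["2"] == "Q1"
        assert q["7"] == q["8"] == "Q4"

    def test_minimum_lands_in_q1(self):
        scores = [("a", 50.0), ("b", 12.0), ("c", 70.0), ("d", 33.0), ("e", 90.0)]
        assert assign_quartiles(scores)["b"] == "Q1"

    def test_tied_scores_split_by_stable_order(self):
        q = assign_quartiles([(f"p{i}", 5.0) for i in range(8)])
        assert [q[f"p{i}"] for i in range(8)] == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_partition_is_exhaustive_and_near_equal(self):
        rng = np.random.default_rng(0)
        ids = [f"p{i}" for i in range(230)]
        q = assign_quartiles(list(zip(ids, rng.normal(size=230))))
        sizes = pd.Series(list(q.values())).value_counts()
        assert sorted(q) == sorted(ids)
        assert sizes.max() - sizes.min() <= 1

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles([("a", 1.0), ("b", 2.0), ("c", 3.0)])


def _balanced(values_by_group):
    y, labels = [], []
    for q, vals in zip(("Q1", "Q2", "Q3", "Q4"), values_by_group):
        y.extend(vals)
        labels.extend([q] * len(vals))
    return np.array(y), labels


class TestTrend:
    def test_flat_group_means_give_zero_slope(self):
        y, labels = _balanced([[1, 2, 3]] * 4)
        res = trend_by_quartile(y, labels)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_coded_ols_on_random_balanced_data(self):
        # independent closed form: slope = Sxy/Sxx, t = slope/SE, p from t(n-2)
        rng = np.random.default_rng(17)
        for _ in range(50):
            groups = [rng.normal(loc=rng.uniform(-2, 2), size=10) for _ in range(4)]
            y, labels = _balanced(groups)
            x = np.repeat([1.0, 2.0, 3.0, 4.0], 10)
            sxx = ((x - x.mean()) ** 2).sum()
            slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
            resid = y - (y.mean() + slope * (x - x.mean()))
            se = math.sqrt((resid**2).sum() / (len(y) - 2) / sxx)
            p = 2 * sps.t.sf(abs(slope / se), len(y) - 2)
            res = trend_by_quartile(y, labels)
            assert res.slope == pytest.approx(slope, abs=1e-6)
            assert res.se == pytest.approx(se, abs=1e-6)
            assert res.p == pytest.approx(p, abs=1e-6)

    def test_rising_score_profile_yields_significant_trend(self):
        # quartile means/SDs shaped like a strongly graded diet-quality profile
        rng = np.random.default_rng(4)
        specs = [(34.0, 4.1), (42.4, 1.6), (48.1, 2.0), (56.4, 4.9)]
        groups = []
        for mean, sd in specs:
            g = rng.normal(size=20)
            groups.append((g - g.mean()) / g.std(ddof=1) * sd + mean)
        y, labels = _balanced(groups)
        res = trend_by_quartile(y, labels)
        assert res.slope > 0
        assert res.p < 0.001

    def test_contrast_proportional_to_slope_when_balanced(self):
        rng = np.random.default_rng(23)
        groups = [rng.normal(loc=m, size=12) for m in (1.0, 2.0, 2.5, 4.0)]
        y, labels = _balanced(groups)
        L, _ = polynomial_linear_contrast(y, labels)
        res = trend_by_quartile(y, labels)
        # c = (-3,-1,1,3) on indices 1..4: L = 10 * slope for balanced groups
        assert L == pytest.approx(10.0 * res.slope, rel=1e-9)

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(31)
        y, labels = _balanced([rng.normal(loc=m, size=8) for m in (0, 1, 3, 4)])
        base = trend_by_quartile(y, labels)
        shifted = trend_by_quartile(y + 100.0, labels)
        scaled = trend_by_quartile(3.0 * y, labels)
        assert shifted.slope == pytest.approx(base.slope, abs=1e-9)
        assert scaled.slope == pytest.approx(3.0 * base.slope, rel=1e-9)

    def test_missing_quartile_group_rejected(self):
        with pytest.raises(ValueError, match="Q4"):
            trend_by_quartile([1.0, 2.0, 3.0], ["Q1", "Q2", "Q3"])


def _scores_frame(n_m=6, n_f=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for sex, n in (("male", n_m), ("female", n_f)):
        for i in range(n):
            score = float(rng.uniform(0, 10))
            rows.append(
                {
                    "participant_id": f"{sex[0]}{i}",
                    "sex": sex,
                    "sodium": score,
                    "met_sodium": score > 5,
                    "total": float(rng.uniform(20, 80)),
                    "ssb_ml_per_week": float(rng.uniform(0, 2000)),
                    "takeaway_ordinal": int(rng.integers(0, 4)),
                }
            )
    return pd.DataFrame(rows)


class TestGenderComparison:
    def test_identical_samples_give_null_statistics(self):
        df = _scores_frame()
        df.loc[df.sex == "female", ["sodium", "met_sodium"]] = (
            df.loc[df.sex == "male", ["sodium", "met_sodium"]].to_numpy()
        )
        out = compare_genders(df, components=["sodium"])
        row = out.iloc[0]
        assert row.t_stat == pytest.approx(0.0, abs=1e-12)
        assert row.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_chi2_matches_closed_form_on_any_2x2(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        for a, b, c, d in [(11, 78, 40, 101), (5, 5, 5, 5), (30, 10, 12, 28)]:
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            chi2, _ = pearson_chi2_2x2(a, a + b, c, c + d)
            assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_sodium_met_proportions_differ_significantly(self):
        # 11/89 males vs 40/141 females meeting the sodium guideline
        chi2, p = pearson_chi2_2x2(11, 89, 40, 141)
        assert p < 0.05

    def test_absent_sex_rejected(self):
        df = _scores_frame(n_f=0)
        with pytest.raises(ValueError, match="female"):
            compare_genders(df, components=["sodium"])


def test_tally_matches_direct_recount():
    df = _scores_frame(n_m=20, n_f=20, seed=3)
    out = tally_guidelines(df)
    row = out[out.component == "sodium"].iloc[0]
    assert row.n_met == int(df.met_sodium.sum())
    assert row.pct_met == round(100.0 * df.met_sodium.mean(), 1)


class TestBehaviorRegression:
    def test_slope_equals_cov_over_var_closed_form(self):
        df = pd.DataFrame(
            {
                "total": [50.0, 48.0, 44.0, 41.0, 35.0],
                "ssb_ml_per_week": [0.0, 250.0, 500.0, 1000.0, 2000.0],
                "takeaway_ordinal": [0, 1, 1, 2, 3],
            }
        )
        out = regress_behavior(df)
        x = df.ssb_ml_per_week.to_numpy()
        y = df.total.to_numpy()
        expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert out["ssb_ml_per_week"].slope == pytest.approx(expected, rel=1e-12)

    def test_permuted_predictor_is_null(self):
        rng = np.random.default_rng(8)
        n = 230
        df = pd.DataFrame(
            {
                "total": rng.normal(45, 9, size=n),
                "ssb_ml_per_week": rng.lognormal(6, 1, size=n),
                "takeaway_ordinal": rng.integers(0, 4, size=n),
            }
        )
        rejections = 0
        for _ in range(100):
            df["ssb_ml_per_week"] = rng.permutation(df["ssb_ml_per_week"].to_numpy())
            if regress_behavior(df)["ssb_ml_per_week"].p < 0.05:
                rejections += 1
        assert rejections <= 12  # ≈5% nominal false-positive rate

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame(
            {"total": [1.0, 2.0, 3.0], "ssb_ml_per_week": [5.0, 5.0, 5.0]}
        )
        with pytest.raises(ValueError, match="constant"):
            regress_behavior(df)


class TestReferenceComparison:
    def test_cohort_equal_to_constants_gives_zero_differences(self):
        ref = ReferenceValues(
            values={"vegetables_g": ReferenceValue(value=172.8, unit="g/day", source="survey")}
        )
        df = pd.DataFrame({"vegetables_g": [172.8] * 5})
        out = compare_to_reference(df, ref)
        assert out.difference.iloc[0] == pytest.approx(0.0)

    def test_empty_reference_warns_and_returns_empty(self):
        df = pd.DataFrame({"vegetables_g": [1.0]})
        with pytest.warns(UserWarning):
            out = compare_to_reference(df, ReferenceValues(values={}))
        assert out.empty

    def test_missing_key_skipped_with_warning(self):
        ref = ReferenceValues(
            values={"nonexistent": ReferenceValue(value=1.0, source="survey")}
        )
        df = pd.DataFrame({"vegetables_g": [1.0]})
        with pytest.warns(UserWarning, match="nonexistent"):
            out = compare_to_reference(df, ref)
        assert out.empty
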