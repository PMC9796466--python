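"""Comparison statistics: preparation ops, exact tests, models, FDR."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from actimood.stats import (
    ModelSpec,
    bh_fdr,
    chi_squared_table,
    condense_categories,
    fisher_exact_2x2,
    fit_group_logistic,
    make_quintiles,
    multinomial_discrepancy,
    neuroticism_score,
    oneway_anova_raw,
    oneway_anova_summary,
    sleep_discrepancy,
)


class TestQuintiles:
    def test_one_to_ten(self):
        labels = make_quintiles(list(range(1, 11)))
        assert list(labels) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_inversion_reverses_extremes(self):
        values = np.linspace(0.5, 0.9, 50)
        labels = make_quintiles(values, invert=True)
        assert labels.iloc[-1] == 1  # the highest raw value lands in bin 1
        assert labels.iloc[0] == 5

    def test_missing_preserved(self):
        labels = make_quintiles([1, 2, 3, 4, 5, 6, np.nan])
        assert np.isnan(labels.iloc[-1])

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            make_quintiles([1, 1, 1, 2, 2])

    @given(st.integers(min_value=1, max_value=40), st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50)
    def test_balanced_bins_when_divisible(self, m, seed):
        """With n divisible by 5 and no ties, bin sizes differ by at most 1."""
        rng = np.random.default_rng(seed)
        values = rng.permutation(rng.normal(size=5 * m))
        counts = make_quintiles(values).value_counts()
        assert counts.max() - counts.min() <= 1


class TestCondense:
    @pytest.mark.parametrize(
        "kind, raw, expected",
        [
            ("chronotype", "definitely_morning", "early"),
            ("chronotype", "more_morning", "intermediate"),
            ("chronotype", "more_evening", "intermediate"),
            ("chronotype", "definitely_evening", "late"),
            ("happiness", "extremely_happy", "happy"),
            ("happiness", "moderately_unhappy", "unhappy"),
            ("getting_up", "fairly_easy", "not_difficult"),
            ("getting_up", "not_at_all_easy", "difficult"),
        ],
    )
    def test_mappings(self, kind, raw, expected):
        assert condense_categories(kind, raw) == expected

    @pytest.mark.parametrize("nonresponse", ["do_not_know", "prefer_not_answer"])
    def test_nonresponse_excluded(self, nonresponse):
        assert condense_categories("chronotype", nonresponse) is None

    def test_unknown_code_named(self):
        with pytest.raises(ValueError, match="owl"):
            condense_categories("chronotype", "owl")

    def test_vectorised(self):
        out = condense_categories("happiness", pd.Series(["very_happy", None, "very_unhappy"]))
        assert list(out) == ["happy", None, "unhappy"]


class TestNeuroticism:
    def test_extremes(self):
        assert neuroticism_score([1] * 12) == 12
        assert neuroticism_score([0] * 12) == 0

    def test_any_missing_makes_score_missing(self):
        items = [1] * 11 + [None]
        assert np.isnan(neuroticism_score(items))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="12"):
            neuroticism_score([1] * 13)


class TestSleepDiscrepancy:
    @pytest.mark.parametrize(
        "subj, obj, expected",
        [
            (8, 7.4, "overestimation"),  # objective rounds to 7
            (7, 7.2, "accurate"),
            (6, 7.6, "underestimation"),  # objective rounds to 8
            (7, 6.5, "accurate"),  # half rounds up
        ],
    )
    def test_categories(self, subj, obj, expected):
        cat, _ = sleep_discrepancy(subj, obj, "never")
        assert cat == expected

    def test_regular_napper_excluded(self):
        cat, minutes = sleep_discrepancy(8, 7.0, "regular")
        assert cat == "excluded"
        assert np.isnan(minutes)

    def test_missing_measure_excluded(self):
        assert sleep_discrepancy(np.nan, 7.0, "never")[0] == "excluded"
        assert sleep_discrepancy(8, np.nan, "never")[0] == "excluded"

    def test_unrounded_minutes(self):
        _, minutes = sleep_discrepancy(8, 7.4, "never")
        assert minutes == pytest.approx((8 - 7.4) * 60)


def bh_oracle(p):
    """Independent step-up oracle: adj_(i) = min_{j>=i} p_(j) * n / j, capped at 1."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestBHFDR:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    def test_order_invariance_all_permutations(self):
        """BH equals the step-up oracle on every permutation of 7 p-values."""
        base = [0.001, 0.011, 0.039, 0.041, 0.27, 0.49, 0.74]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(bh_fdr(perm), bh_oracle(perm), atol=1e-12)


def hypergeom_fisher_oracle(a, b, c, d):
    """Two-sided exact p by direct hypergeometric enumeration (exact integers)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, r1)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    probs = {k: math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    threshold = p_obs + p_obs // 10**12  # integer-exact relative tolerance
    total = sum(v for v in probs.values() if v <= threshold)
    return float(Fraction(total, denom))


class TestFisherExact:
    def test_balanced_table(self):
        or_, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_sparse_long_sleep_table(self):
        """Tiny long-sleep cell: OR below 1 and p from the exact null."""
        or_, p = fisher_exact_2x2([[2, 283], [345, 14964]])
        assert or_ < 1.0
        assert p == pytest.approx(hypergeom_fisher_oracle(2, 283, 345, 14964), abs=1e-9)

    def test_empty_margin_undefined(self):
        or_, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert np.isnan(or_)
        assert p == 1.0

    def test_matches_enumeration_oracle_exhaustively(self):
        """p-values agree with exact enumeration on all small tables."""
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(hypergeom_fisher_oracle(a, b, c, d), abs=1e-9)


class TestChiSquared:
    def test_proportional_rows_give_zero(self):
        stat, df, v = chi_squared_table([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared_table([[0, 0], [3, 4]])

    def test_agrees_with_manual_formula(self):
        rng = np.random.default_rng(2)
        c = rng.integers(5, 50, (3, 4)).astype(float)
        stat, df, _ = chi_squared_table(c)
        expected = np.outer(c.sum(1), c.sum(0)) / c.sum()
        assert stat == pytest.approx(((c - expected) ** 2 / expected).sum(), rel=1e-12)
        assert df == 6


class TestAnova:
    def test_identical_means_give_zero_f(self):
        f, _, eta2 = oneway_anova_summary([5.0, 5.0, 5.0], [1.0, 1.2, 0.9], [30, 40, 50])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert eta2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_variance_undefined(self):
        f, _, _ = oneway_anova_summary([1.0, 2.0], [0.0, 0.0], [10, 10])
        assert np.isnan(f)

    def test_summary_equals_raw_f_oneway(self):
        """Summary-statistic route reproduces scipy's raw-data F to 1e-9."""
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc, 2.0, n) for loc, n in [(0.0, 25), (0.5, 40), (1.0, 31)]]
        f_summary, _, _ = oneway_anova_raw(groups)
        f_scipy = sps.f_oneway(*groups).statistic
        assert f_summary == pytest.approx(f_scipy, abs=1e-9)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            oneway_anova_summary([1.0], [0.5], [10])


def two_group_frame(counts):
    """Build a long participant frame from a 2x2 of (exposed, unexposed) rows."""
    (a, b), (c, d) = counts
    return pd.DataFrame({
        "group": ["BD"] * (a + b) + ["CONTROL"] * (c + d),
        "x": [1] * a + [0] * b + [1] * c + [0] * d,
    })


class TestGroupLogistic:
    def test_unadjusted_or_equals_cross_product(self):
        counts = ((40, 60), (25, 75))
        df = two_group_frame(counts)
        spec = ModelSpec(comparison="BD_vs_control", exposure="x",
                         exposure_type="continuous", adjustment="unadjusted")
        res = fit_group_logistic(df, spec)
        assert len(res) == 1
        cross = (40 * 75) / (60 * 25)
        assert res[0].or_ == pytest.approx(cross, rel=1e-6)
        assert res[0].ci_low <= res[0].or_ <= res[0].ci_high

    def test_no_variation_flagged(self):
        df = two_group_frame(((0, 100), (0, 100)))
        spec = ModelSpec(comparison="BD_vs_control", exposure="x",
                         exposure_type="continuous", adjustment="unadjusted")
        res = fit_group_logistic(df, spec)
        assert not res[0].converged
        assert "variation" in res[0].note

    def test_unknown_comparison_rejected(self):
        with pytest.raises(ValueError, match="comparison"):
            fit_group_logistic(pd.DataFrame({"group": [], "x": []}),
                               ModelSpec(comparison="A_vs_B", exposure="x"))

    def test_covariate_sets(self):
        partly = ModelSpec(comparison="BD_vs_UM", exposure="x", adjustment="partly")
        fully = ModelSpec(comparison="BD_vs_UM", exposure="x", adjustment="fully",
                          objective=True)
        assert partly.covariate_terms() == [
            "age", "C(sex)", "townsend", "C(education)", "C(ethnicity)"]
        assert "C(season)" in fully.covariate_terms()
        assert "bmi" in fully.covariate_terms()
        assert "C(season)" not in partly.covariate_terms()

    def test_null_exposure_ci_covers_one(self):
        """With exposure independent of group the 95% CI covers 1 about 95% of
        the time."""
        rng = np.random.default_rng(10)
        covered = 0
        reps = 120
        for _ in range(reps):
            df = pd.DataFrame({
                "group": ["BD"] * 150 + ["CONTROL"] * 150,
                "x": rng.binomial(1, 0.4, 300),
            })
            spec = ModelSpec(comparison="BD_vs_control", exposure="x",
                             exposure_type="continuous", adjustment="unadjusted")
            r = fit_group_logistic(df, spec)[0]
            covered += int(r.ci_low <= 1.0 <= r.ci_high)
        assert 0.90 <= covered / reps <= 0.99


class TestMultinomialDiscrepancy:
    def _simulate(self, or_over, n=4000, seed=1):
        rng = np.random.default_rng(seed)
        base = np.array([0.40, 0.35, 0.25])  # accurate / under / over
        bd = base * np.array([1.0, 1.0, or_over])
        bd /= bd.sum()
        cats = np.array(["accurate", "underestimation", "overestimation"])
        return pd.DataFrame({
            "group": ["BD"] * n + ["CONTROL"] * n,
            "discrepancy_cat": np.concatenate([
                rng.choice(cats, n, p=bd), rng.choice(cats, n, p=base)]),
        })

    def test_recovers_injected_overestimation_effect(self):
        df = self._simulate(or_over=1.5, seed=1)
        res = multinomial_discrepancy(df, adjustment="unadjusted", objective=False)
        over = [r for r in res if r.level == "overestimation" and r.comparison == "BD_vs_control"]
        assert len(over) == 1
        log_or = np.log(over[0].or_)
        se = (np.log(over[0].ci_high) - np.log(over[0].ci_low)) / (2 * 1.96)
        assert abs(log_or - np.log(1.5)) <= 2 * se

    def test_null_effects_near_one(self):
        df = self._simulate(or_over=1.0, seed=2)
        res = multinomial_discrepancy(df, adjustment="unadjusted", objective=False)
        for r in res:
            assert r.ci_low <= 1.0 <= r.ci_high

    def test_degenerate_two_category_outcome(self):
        df = pd.DataFrame({
            "group": ["BD", "CONTROL"] * 50,
            "discrepancy_cat": ["accurate", "overestimation"] * 50,
        })
        with pytest.raises(ValueError, match="binary"):
            multinomial_discrepancy(df, adjustment="unadjusted", objective=False)
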