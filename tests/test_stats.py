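"""Inference primitives against independent oracles.

Fisher is checked against brute-force enumeration of all same-margin
tables, Wilcoxon against full sign-assignment enumeration, and the
survival machinery against lifelines.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcpanel.errors import DegenerateDataError, RangeError
from ctcpanel.stats import (
    ContingencyTable2x2,
    chi_square_2x2,
    cox_score_test,
    cox_univariate,
    fisher_exact_2x2,
    km_estimate,
    km_median_survival,
    logrank_test,
    median_split,
    truncate_p,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# oracles


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive same-margin table enumeration
    with exact rational point probabilities."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point_prob(k):
        return (
            Fraction(math.factorial(r1), math.factorial(k) * math.factorial(r1 - k))
            * Fraction(math.factorial(r2),
                       math.factorial(c1 - k) * math.factorial(r2 - (c1 - k)))
            / Fraction(math.factorial(n),
                       math.factorial(c1) * math.factorial(n - c1))
        )

    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    p_obs = point_prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = point_prob(k)
        if pk <= p_obs * (1 + Fraction(1, 10**7)):
            total += pk
    return float(min(total, Fraction(1)))


def wilcoxon_oracle(diffs):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    if n == 0:
        return 1.0
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p = 2 * min((ws <= w_obs).sum(), (ws >= w_obs).sum()) / 2**n
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Fisher / chi-square


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((2, 12, 4, 1), 0.0172858617131063),
            ((6, 4, 0, 9), 0.0108359133126935),
            ((4, 9, 2, 4), 1.0),
        ],
    )
    def test_worked_examples(self, table, expected):
        res = fisher_exact_2x2(ContingencyTable2x2(*table))
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 31))
            cuts = sorted(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            p_pkg = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
            assert p_pkg == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_point_probabilities_sum_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            r1, r2 = rng.integers(1, 15, size=2)
            c1 = int(rng.integers(1, r1 + r2))
            total = sum(
                math.comb(r1, k) * math.comb(r2, c1 - k)
                for k in range(max(0, c1 - r2), min(r1, c1) + 1)
            )
            assert total == math.comb(r1 + r2, c1)  # Vandermonde, exactly

    def test_degenerate_margin_gives_p_one(self):
        res = fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4))
        assert res.p_value == 1.0 and "degenerate_margin" in res.flags

    def test_negative_count_rejected(self):
        with pytest.raises(RangeError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestChiSquare:
    def test_yates_worked_example(self):
        res = chi_square_2x2(ContingencyTable2x2(3, 5, 1, 7), yates=True)
        assert res.statistic == pytest.approx(1 / 3, abs=1e-12)
        assert res.p_value == pytest.approx(0.5637, abs=2e-4)

    def test_perfect_independence(self):
        res = chi_square_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_perfect_association_statistic_is_n(self):
        assert chi_square_2x2(ContingencyTable2x2(10, 0, 0, 10)).statistic == 20.0

    def test_zero_margin_undefined(self):
        with pytest.raises(DegenerateDataError):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))

    def test_matches_scipy(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(1, 20, size=4)
            for yates in (False, True):
                res = chi_square_2x2(ContingencyTable2x2(*t), yates=yates)
                ref = chi2_contingency(np.array(t).reshape(2, 2), correction=yates)
                assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
                assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Wilcoxon


class TestWilcoxon:
    def test_all_positive_five(self):
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5]).p_value == 0.0625

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0 and "all_zero" in res.flags

    @given(
        st.lists(st.integers(min_value=1, max_value=10 * 6), min_size=1, max_size=8,
                 unique=True),
        st.integers(min_value=0, max_value=255),
    )
    @settings(max_examples=80, deadline=None)
    def test_exact_p_matches_enumeration(self, mags, signbits):
        diffs = [m if (signbits >> i) & 1 else -m for i, m in enumerate(mags)]
        res = wilcoxon_signed_rank(diffs)
        assert res.method == "wilcoxon_exact"
        assert res.p_value == pytest.approx(wilcoxon_oracle(diffs), abs=1e-12)

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=8,
                    unique=True),
           st.integers(min_value=0, max_value=255))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, mags, signbits):
        diffs = [m if (signbits >> i) & 1 else -m for i, m in enumerate(mags)]
        neg = [-d for d in diffs]
        assert wilcoxon_signed_rank(diffs).p_value == wilcoxon_signed_rank(neg).p_value

    def test_large_sample_matches_scipy_normal_approximation(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1.0, size=40)
        res = wilcoxon_signed_rank(d)
        ref = scipy_wilcoxon(d, correction=False, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tied_magnitudes_still_exact_for_small_n(self):
        # two equal positives: mid-ranks 1.5/1.5, W+ = 3,
        # P(W+ >= 3) = 1/4 -> two-sided 0.5
        res = wilcoxon_signed_rank([1, 1])
        assert res.method == "wilcoxon_exact"
        assert res.p_value == 0.5

    def test_large_n_uses_normal_approximation(self):
        res = wilcoxon_signed_rank(list(range(1, 26)))
        assert res.method == "wilcoxon_normal"


# ---------------------------------------------------------------------------
# survival


class TestKaplanMeier:
    def test_all_events_is_complement_of_ecdf(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(curve.survival_prob, [2 / 3, 1 / 3, 0.0])

    def test_censoring_worked_example(self):
        curve = km_estimate([1, 2], [True, False])
        assert list(curve.event_times) == [1.0]
        assert np.allclose(curve.survival_prob, [0.5])

    def test_no_events_survival_stays_one(self):
        curve = km_estimate([1, 2, 3], [False, False, False])
        assert curve.event_times.size == 0 and curve.survival_at(10) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            km_estimate([], [])

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(100, size=57)
        curve = km_estimate(t, np.ones_like(t, dtype=bool))
        for time, s in zip(curve.event_times, curve.survival_prob):
            assert s == pytest.approx(np.mean(t > time), abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(23)
        t = rng.weibull(1.3, size=80) * 100
        e = rng.random(80) < 0.7
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for time, s in zip(curve.event_times, curve.survival_prob):
            assert s == pytest.approx(float(kmf.survival_function_at_times(time).iloc[0]),
                                      abs=1e-10)

    def test_median_survival(self):
        curve = km_estimate([10, 20, 30, 40], [1, 1, 1, 1])
        assert km_median_survival(curve) == 20.0
        no_events = km_estimate([10, 20], [False, False])
        assert math.isnan(km_median_survival(no_events))


class TestLogrank:
    def test_two_subject_worked_example(self):
        res = logrank_test(["A", "B"], [1, 2], [True, True])
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.3173, abs=2e-4)

    def test_identical_groups_statistic_zero(self):
        t = [5, 10, 15, 5, 10, 15]
        e = [1, 1, 0, 1, 1, 0]
        g = ["A"] * 3 + ["B"] * 3
        assert logrank_test(g, t, e).statistic == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(50, 40)
        e = rng.random(40) < 0.8
        g = rng.random(40) < 0.5
        r1 = logrank_test(g, t, e)
        r2 = logrank_test(~g, t, e)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.p_value == r2.p_value

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(50, 30) + 1
        e = rng.random(30) < 0.7
        g = rng.random(30) < 0.5
        r1 = logrank_test(g, t, e)
        r2 = logrank_test(g, np.log(t) + 5, e)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_one_group_empty_rejected(self):
        with pytest.raises(DegenerateDataError):
            logrank_test(["A", "A"], [1, 2], [True, True])

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(17)
        t = rng.weibull(1.2, 60) * 100
        e = rng.random(60) < 0.75
        g = rng.random(60) < 0.4
        res = logrank_test(g, t, e)
        ref = ll_logrank(t[g], t[~g], e[g], e[~g])
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)


class TestCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(DegenerateDataError, match="flat|constant"):
            cox_univariate([1, 2, 3], [1, 1, 1], [2.0, 2.0, 2.0])

    def test_symmetric_groups_give_unit_hazard_ratio(self):
        t = [5, 10, 15, 5, 10, 15]
        e = [1, 1, 1, 1, 1, 1]
        x = [0, 0, 0, 1, 1, 1]
        res = cox_univariate(t, e, x)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_score_test_equals_logrank_on_tie_free_binary(self):
        rng = np.random.default_rng(31)
        t = rng.permutation(np.arange(1, 41)).astype(float)  # tie-free
        e = rng.random(40) < 0.8
        x = (rng.random(40) < 0.5).astype(float)
        score = cox_score_test(t, e, x)
        lr = logrank_test(x, t, e)
        assert score.statistic == pytest.approx(lr.statistic, abs=1e-6)

    def test_perfect_separation_flagged(self):
        t = [1, 2, 3, 10, 11, 12]
        e = [1, 1, 1, 1, 1, 1]
        x = [1, 1, 1, 0, 0, 0]
        res = cox_univariate(t, e, x)
        assert not res.converged and "monotone_likelihood" in res.flags
        assert math.isinf(res.hazard_ratio)

    def test_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(13)
        x = (rng.random(80) < 0.5).astype(float)
        t = rng.exponential(100 * np.exp(-0.7 * x))
        e = rng.random(80) < 0.8
        res = cox_univariate(t, e, x)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.coef == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
        assert res.se == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-6)

    def test_fewer_than_two_events_rejected(self):
        with pytest.raises(DegenerateDataError):
            cox_univariate([1, 2, 3], [1, 0, 0], [0, 1, 0])


# ---------------------------------------------------------------------------
# dichotomization / reporting


class TestMedianSplit:
    def test_even_count(self):
        labels = median_split([1, 2, 3, 4])
        assert list(labels) == ["LOW", "LOW", "HIGH", "HIGH"]

    def test_tie_at_median_goes_low(self):
        labels = median_split([1, 2, 2, 5])
        assert list(labels) == ["LOW", "LOW", "LOW", "HIGH"]

    def test_missing_stays_missing(self):
        labels = median_split([1.0, float("nan"), 3.0])
        assert labels[1] is None and labels[0] == "LOW" and labels[2] == "HIGH"

    def test_constant_values_warn_all_low(self):
        with pytest.warns(UserWarning):
            labels = median_split([4, 4, 4])
        assert all(l == "LOW" for l in labels)

    def test_all_missing_rejected(self):
        with pytest.raises(DegenerateDataError):
            median_split([float("nan")] * 3)


class TestTruncateP:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.017286, 0.01), (0.569231, 0.56), (1.0, 1.0),
         (0.0573, 0.05), (0.140867, 0.14), (0.999, 0.99)],
    )
    def test_floor_rule(self, p, expected):
        assert truncate_p(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            truncate_p(0.0)
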