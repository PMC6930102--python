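"""Concordance, tau-b against a pair-enumeration oracle, trends, MCID flags."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from frailtykit import (
    CATEGORIES,
    CrossTab3x3,
    agreement,
    concordance,
    crosstab,
    fit_age_trend,
    kendall_tau_b,
    summarize_trajectories,
)

TABLE3 = np.array([[178, 57, 1], [14, 108, 21], [0, 4, 18]])


def taub_oracle(a, b):
    """Exhaustive O(n^2) pair enumeration with marginal tie corrections."""
    n = len(a)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (a[i] - a[j]) * (b[i] - b[j])
            conc += s > 0
            disc += s < 0
    n0 = n * (n - 1) // 2
    n1 = sum(t * (t - 1) // 2 for t in Counter(a).values())
    n2 = sum(t * (t - 1) // 2 for t in Counter(b).values())
    if n0 == n1 or n0 == n2:
        return None
    return (conc - disc) / math.sqrt((n0 - n1) * (n0 - n2))


class TestCrossTab:
    def test_printed_cross_tabulation_totals(self):
        ct = CrossTab3x3(TABLE3)
        assert ct.grand_total == 401
        assert ct.row_totals.tolist() == [236, 143, 22]
        assert ct.col_totals.tolist() == [192, 169, 40]

    def test_identical_vectors_are_diagonal(self):
        labels = ["non-frail"] * 5 + ["pre-frail"] * 3 + ["frail"] * 2
        ct = crosstab(labels, labels)
        assert np.trace(ct.counts) == 10
        assert ct.counts.sum() - np.trace(ct.counts) == 0

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            crosstab([], [])
        with pytest.raises(ValueError):
            crosstab(["frail"], ["frail", "frail"])
        with pytest.raises(ValueError):
            crosstab(["robust"], ["frail"])


class TestAgreement:
    def test_printed_table_agreement(self):
        count, frac = agreement(CrossTab3x3(TABLE3))
        assert count == 304
        assert round(100 * frac, 1) == 75.8

    def test_perfect_and_zero_agreement(self):
        diag = np.diag([5, 6, 7])
        assert agreement(CrossTab3x3(diag))[1] == 1.0
        anti = np.array([[0, 0, 3], [0, 0, 0], [4, 0, 0]])
        assert agreement(CrossTab3x3(anti))[1] == 0.0

    def test_agreement_equals_pairwise_label_equality(self):
        rng = np.random.default_rng(5)
        a = rng.choice(CATEGORIES, size=200)
        b = rng.choice(CATEGORIES, size=200)
        _, frac = agreement(crosstab(a, b))
        assert frac == pytest.approx(np.mean(a == b))


class TestTauB:
    def test_perfect_diagonal_is_one(self):
        res = kendall_tau_b(CrossTab3x3(np.diag([10, 20, 5])))
        assert res.tau == pytest.approx(1.0)

    def test_independence_outer_product_near_zero(self):
        rows = np.array([2, 3, 5])
        cols = np.array([4, 1, 5])
        ct = CrossTab3x3(np.outer(rows, cols))
        res = kendall_tau_b(ct)
        a, b = ct.to_pairs()
        assert res.tau == pytest.approx(taub_oracle(list(a), list(b)), abs=1e-12)
        assert abs(res.tau) < 0.02

    def test_printed_table_matches_oracle_and_scipy(self):
        ct = CrossTab3x3(TABLE3)
        res = kendall_tau_b(ct)
        a, b = ct.to_pairs()
        assert res.tau == pytest.approx(taub_oracle(list(a), list(b)), abs=1e-12)
        sp = stats.kendalltau(a, b)
        assert res.tau == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p_value < 0.001

    def test_sign_flips_when_one_axis_reversed(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 30, size=(3, 3))
        counts[0, 0] += 25  # ensure non-degenerate association
        res = kendall_tau_b(CrossTab3x3(counts))
        flipped = kendall_tau_b(CrossTab3x3(counts[:, ::-1]))
        assert flipped.tau == pytest.approx(-res.tau)

    def test_degenerate_table_reported_as_undefined(self):
        counts = np.zeros((3, 3), int)
        counts[1] = [5, 8, 2]  # all mass in one row
        res = kendall_tau_b(CrossTab3x3(counts))
        assert res.tau is None and "degenerate" in res.note

    @settings(max_examples=50, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 12), min_size=9, max_size=9),
    )
    def test_formula_equals_oracle_on_random_tables(self, counts):
        ct = CrossTab3x3(np.array(counts).reshape(3, 3))
        if ct.grand_total < 2:
            return
        res = kendall_tau_b(ct)
        a, b = ct.to_pairs()
        oracle = taub_oracle(list(a), list(b))
        if oracle is None:
            assert res.tau is None
        else:
            assert res.tau == pytest.approx(oracle, abs=1e-12)

    def test_permutation_p_small_for_strong_association(self):
        ct = CrossTab3x3(np.diag([20, 20, 20]))
        res = kendall_tau_b(ct, method="permutation", n_resamples=999, rng=3)
        assert res.p_value < 0.01


class TestConcordanceReport:
    def test_bundles_table_agreement_and_tau(self):
        report = concordance(CrossTab3x3(TABLE3))
        d = report.as_dict()
        assert d["n"] == 401
        assert d["agreement_count"] == 304
        assert d["tau_b"] == pytest.approx(0.6831, abs=1e-4)


class TestAgeTrend:
    def test_exact_line_recovered_to_machine_precision(self):
        ages = np.arange(50, 86, dtype=float)
        fi = -0.1618 + 0.0040 * ages
        fit = fit_age_trend(ages, fi)
        assert fit.intercept == pytest.approx(-0.1618, abs=1e-12)
        assert fit.slope == pytest.approx(0.0040, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_prediction_at_90_flags_extrapolation(self):
        ages = np.arange(50, 86, dtype=float)
        fit = fit_age_trend(ages, -0.1618 + 0.0040 * ages)
        value, extrapolated = fit.predict(90)
        assert value == pytest.approx(0.1982, abs=1e-9)
        assert extrapolated
        assert not fit.predict(70)[1]

    def test_exponential_form_recovers_loglinear_data(self):
        ages = np.arange(50, 86, dtype=float)
        fi = np.exp(-5.0 + 0.04 * ages)
        fit = fit_age_trend(ages, fi, form="exponential")
        assert fit.intercept == pytest.approx(-5.0, abs=1e-10)
        assert fit.slope == pytest.approx(0.04, abs=1e-12)
        assert fit.predict(60)[0] == pytest.approx(np.exp(-5.0 + 2.4))

    def test_exponential_form_drops_zero_fi_with_count(self):
        ages = np.array([50.0, 55, 60, 65, 70])
        fi = np.array([0.0, 0.1, 0.12, 0.2, 0.3])
        fit = fit_age_trend(ages, fi, form="exponential")
        assert fit.n_excluded == 1 and fit.n_obs == 4

    def test_mean_by_age_granularity(self):
        ages = np.repeat([50, 60, 70], 4)
        fi = np.concatenate([[0.0, 0.2], [0.1, 0.3], [0.2, 0.4]]).repeat(2)
        fit = fit_age_trend(ages, fi, granularity="mean-by-age")
        assert fit.n_obs == 3
        assert fit.slope == pytest.approx(0.01, abs=1e-12)

    def test_identical_ages_rejected(self):
        with pytest.raises(ValueError):
            fit_age_trend([60, 60, 60], [0.1, 0.2, 0.3])

    def test_simulated_slope_recovered_without_bias(self):
        # linear-model simulation at n = 1e4: estimate within 4 SE of truth
        rng = np.random.default_rng(99)
        ages = rng.integers(50, 86, size=10_000).astype(float)
        fi = -0.1618 + 0.0040 * ages + rng.normal(0, 0.05, size=ages.size)
        fit = fit_age_trend(ages, fi)
        se = 0.05 / np.sqrt(np.sum((ages - ages.mean()) ** 2))
        assert fit.slope == pytest.approx(0.0040, abs=4 * se)


class TestTrajectories:
    def _daily(self, series_by_cat):
        rows = []
        for cat, (pf, ut) in series_by_cat.items():
            sid = f"{cat}-1"
            for day, (p, u) in enumerate(zip(pf, ut)):
                rows.append({"subject_id": sid, "day": day, "pf": p, "utility": u})
        return pd.DataFrame(rows), {f"{c}-1": c for c in series_by_cat}

    def test_printed_day1_changes_not_clinically_meaningful(self):
        daily, cats = self._daily(
            {"non-frail": ([92.4, 90.3, 92.2], [0.92, 0.875, 0.921])}
        )
        out = summarize_trajectories(daily, cats)
        day1 = out[out["day"] == 1].iloc[0]
        assert day1["pf_change"] == pytest.approx(-2.1)
        assert day1["utility_change"] == pytest.approx(-0.045)
        assert not day1["pf_mcid"] and not day1["utility_mcid"]

    def test_change_exactly_at_threshold_is_flagged(self):
        daily, cats = self._daily({"frail": ([50.0, 46.7], [0.6, 0.526])})
        out = summarize_trajectories(daily, cats)
        day1 = out[out["day"] == 1].iloc[0]
        assert day1["pf_change"] == pytest.approx(-3.3)
        assert day1["pf_mcid"]  # |change| >= 3.3 inclusive
        assert day1["utility_mcid"]  # |-0.074| reaches the utility threshold

    def test_missing_day0_rejected(self):
        daily = pd.DataFrame(
            [{"subject_id": "s", "day": 1, "pf": 90.0, "utility": 0.9}]
        )
        with pytest.raises(ValueError, match="Day 0"):
            summarize_trajectories(daily, {"s": "non-frail"})

    def test_absent_category_omitted(self):
        daily, cats = self._daily({"non-frail": ([90.0, 89.0], [0.9, 0.89])})
        out = summarize_trajectories(daily, cats)
        assert set(out["category"]) == {"non-frail"}
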