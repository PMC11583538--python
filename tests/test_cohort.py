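"""Cohort statistics: Mann-Whitney-U, chi-square, PTV matching and summaries.

Oracles are independent of the implementation: the exact MWU p-value comes
from explicit enumeration of rank assignments, the chi-square from its 2x2
closed form, and the optimal matching from brute force over all injections.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pneumodose.cohort import (
    PatientRecord,
    SUMMARY_COLUMNS,
    chi_square_test,
    mann_whitney_u,
    match_pairs_by_ptv,
    records_from_csv,
    records_to_csv,
    summarize_cohort,
)
from pneumodose.dosimetry import LungMetrics, PtpDoseMetrics


def enumerate_mwu_p(x, y) -> float:
    """Exact two-sided MWU p by enumeration of all rank assignments (tie-free)."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    u_obs = sum(xi > yj for xi in x for yj in y)
    combined = sorted(x + y)
    null_u = []
    for x_pos in itertools.combinations(range(n + m), n):
        xs = [combined[i] for i in x_pos]
        ys = [combined[i] for i in range(n + m) if i not in x_pos]
        null_u.append(sum(xi > yj for xi in xs for yj in ys))
    null_u = np.array(null_u)
    mean_u = n * m / 2
    dev = abs(u_obs - mean_u)
    return float((np.abs(null_u - mean_u) >= dev - 1e-12).sum() / len(null_u))


def _record(pid, group, ptv, intent="definitive", **kw) -> PatientRecord:
    return PatientRecord(pid, group, intent, ptv, **kw)


def _metrics(auc=3000.0, mean=30.0) -> PtpDoseMetrics:
    return PtpDoseMetrics(100.0, 60.0, 60.0, 30.0, mean, 40.0, 30.0, 30.0, auc)


# ---------------------------------------------------------------------------
# Mann-Whitney-U
# ---------------------------------------------------------------------------

class TestMannWhitneyU:
    @pytest.mark.parametrize("x,y,u_expected,p_expected", [
        ([1, 2], [3, 4], 0.0, 1 / 3),
        ([1, 4], [2, 3], 2.0, 1.0),
    ])
    def test_enumeration_examples(self, x, y, u_expected, p_expected):
        u, p = mann_whitney_u(x, y)
        assert u == u_expected
        assert p == pytest.approx(p_expected, abs=1e-9)
        assert p == pytest.approx(enumerate_mwu_p(x, y), abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 7), rng.integers(2, 7)
        vals = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free
        x, y = vals[:n], vals[n:]
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(enumerate_mwu_p(x, y), abs=1e-9)

    def test_identical_samples_with_ties_near_one(self):
        x = [1.0, 2.0, 2.0, 3.0] * 4  # 16 + 16 values -> asymptotic path
        _, p = mann_whitney_u(x, x)
        assert p >= 0.99

    def test_exact_vs_asymptotic_agreement_n10(self):
        # for tie-free n = m = 10 the two p-values agree within 0.02
        from scipy import stats
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = rng.permutation(np.arange(20.0))
            x, y = vals[:10], vals[10:]
            p_exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact").pvalue
            _, p_mine = mann_whitney_u(x, y)  # n+m = 20 -> exact path
            assert p_mine == pytest.approx(p_exact, abs=1e-12)
            p_asym = stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue
            worst = max(worst, abs(p_exact - p_asym))
        assert worst < 0.02

    def test_type_i_error_calibrated(self):
        # under the null the test at alpha=0.05 rejects in 5% +/- 1.5% of cohorts
        rng = np.random.default_rng(1234)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.normal(size=16)
            y = rng.normal(size=16)
            _, p = mann_whitney_u(x, y)
            rejections += p < 0.05
        assert 0.035 <= rejections / n_sim <= 0.065

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

class TestChiSquare:
    def test_worked_example(self):
        chi2, df, p = chi_square_test([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(60 * 300 ** 2 / 30 ** 4)
        assert df == 1
        assert p == pytest.approx(0.0098, abs=2e-4)

    def test_identical_proportions(self):
        chi2, _, p = chi_square_test([[10, 10], [20, 20]])
        assert chi2 == 0.0
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_closed_form_equality(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 60, 4)
        chi2, _, _ = chi_square_test([[a, b], [c, d]])
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# PTV matching
# ---------------------------------------------------------------------------

def brute_force_min_total(ptv_a, ptv_b) -> float:
    """Minimum total |dPTV| over all injections of the smaller into the larger."""
    small, large = sorted([list(ptv_a), list(ptv_b)], key=len)
    return min(
        sum(abs(s - l) for s, l in zip(small, perm))
        for perm in itertools.permutations(large, len(small))
    )


class TestMatching:
    def test_worked_example(self):
        a = [_record("A1", "RCT_ICI", 100.0), _record("A2", "RCT_ICI", 500.0)]
        b = [_record("B1", "RCT", 110.0), _record("B2", "RCT", 480.0),
             _record("B3", "RCT", 900.0)]
        res = match_pairs_by_ptv(a, b)
        assert res.total_abs_ptv_diff_cm3 == pytest.approx(30.0)
        assert set(res.pairs) == {("A1", "B1"), ("A2", "B2")}

    def test_identical_ptvs_zero_discrepancy(self):
        a = [_record(f"A{i}", "RCT_ICI", v) for i, v in enumerate([100, 300, 700])]
        b = [_record(f"B{i}", "RCT", v) for i, v in enumerate([100, 300, 700])]
        res = match_pairs_by_ptv(a, b)
        assert res.total_abs_ptv_diff_cm3 == 0.0
        assert set(res.pairs) == {("A0", "B0"), ("A1", "B1"), ("A2", "B2")}

    def test_equidistant_tie_prefers_lower_patient_id(self):
        a = [_record("A1", "RCT_ICI", 200.0)]
        b = [_record("B1", "RCT", 150.0), _record("B2", "RCT", 250.0)]
        res = match_pairs_by_ptv(a, b)
        assert res.pairs == [("A1", "B1")]

    @pytest.mark.parametrize("seed", range(50))
    def test_optimal_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(1, 7), rng.integers(1, 7)
        pa = rng.uniform(50, 1200, na)
        pb = rng.uniform(50, 1200, nb)
        a = [_record(f"A{i}", "RCT_ICI", v) for i, v in enumerate(pa)]
        b = [_record(f"B{i}", "RCT", v) for i, v in enumerate(pb)]
        res = match_pairs_by_ptv(a, b)
        assert len(res.pairs) == min(na, nb)
        assert res.total_abs_ptv_diff_cm3 == pytest.approx(
            brute_force_min_total(pa, pb), rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetric_under_group_swap(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = [_record(f"A{i}", "RCT_ICI", v)
             for i, v in enumerate(rng.uniform(50, 1200, 5))]
        b = [_record(f"B{i}", "RCT", v)
             for i, v in enumerate(rng.uniform(50, 1200, 3))]
        fwd = match_pairs_by_ptv(a, b)
        rev = match_pairs_by_ptv(b, a)
        assert {frozenset(p) for p in fwd.pairs} == {frozenset(p) for p in rev.pairs}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            match_pairs_by_ptv([], [_record("B1", "RCT", 100.0)])


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

class TestSummarize:
    def _cohort(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        records = []
        for g, tag in (("RCT_ICI", "A"), ("RCT", "B")):
            for i in range(n):
                records.append(_record(
                    f"{tag}{i}", g, float(rng.uniform(100, 900)),
                    pneumonitis=True, grade=int(rng.integers(1, 4)),
                    onset_days=int(rng.integers(10, 200)),
                    metrics=_metrics(auc=float(rng.normal(3000, 500))),
                    lung=LungMetrics(12.0, 18.0)))
        return records

    def test_descriptive_statistics(self):
        recs = [_record(f"P{i}", "RCT", float(v), pneumonitis=True,
                        metrics=_metrics(auc=float(v)))
                for i, v in enumerate([1, 2, 3])]
        df = summarize_cohort(recs, ["auc_gy_pct"])
        row = df.iloc[0]
        assert (row["mean"], row["sd"], row["median"]) == (2.0, 1.0, 2.0)
        assert (row["min"], row["max"], row["n"]) == (1.0, 3.0, 3)

    def test_single_group_has_no_p_value(self):
        recs = [_record(f"P{i}", "RCT", 100.0 + i) for i in range(6)]
        df = summarize_cohort(recs, ["ptv_cm3"])
        assert df["test"].eq("").all()
        assert df["p_value"].isna().all()

    def test_small_groups_suppress_p_values(self):
        recs = self._cohort(n=4)
        df = summarize_cohort(recs, ["auc_gy_pct"], min_n_for_tests=5)
        assert df["p_value"].isna().all()

    def test_p_values_match_direct_test_calls(self):
        recs = self._cohort(n=8)
        df = summarize_cohort(recs, ["auc_gy_pct", "pneumonitis"])
        auc_a = [r.metrics.auc_gy_pct for r in recs if r.group == "RCT_ICI"]
        auc_b = [r.metrics.auc_gy_pct for r in recs if r.group == "RCT"]
        _, p_direct = mann_whitney_u(auc_a, auc_b)
        auc_rows = df[df["variable"] == "auc_gy_pct"]
        assert auc_rows["p_value"].unique() == pytest.approx([p_direct])
        assert set(auc_rows["test"]) == {"MWU"}

    def test_schema(self):
        df = summarize_cohort(self._cohort(), ["auc_gy_pct", "ptv_cm3"])
        assert list(df.columns) == SUMMARY_COLUMNS

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError, match="unknown variable"):
            summarize_cohort(self._cohort(), ["not_a_variable"])

    def test_record_invariants(self):
        with pytest.raises(ValueError, match="pneumonitis"):
            _record("P1", "RCT", 100.0, pneumonitis=False, metrics=_metrics())
        with pytest.raises(ValueError, match="grade"):
            _record("P1", "RCT", 100.0, pneumonitis=False, grade=2)
        with pytest.raises(ValueError, match="group"):
            _record("P1", "XXX", 100.0)


def test_records_csv_round_trip(tmp_path):
    recs = [
        _record("P1", "RCT_ICI", 321.5, pneumonitis=True, grade=2, onset_days=90,
                metrics=_metrics(), lung=LungMetrics(11.5, 17.4)),
        _record("P2", "RCT", 400.0),  # no pneumonitis, no metrics
    ]
    path = records_to_csv(recs, tmp_path / "records.csv")
    back = records_from_csv(path)
    assert [r.patient_id for r in back] == ["P1", "P2"]
    assert back[0].metrics.auc_gy_pct == pytest.approx(3000.0)
    assert back[0].grade == 2 and back[0].onset_days == 90
    assert back[1].metrics is None and back[1].grade is None
    assert back[1].ptv_cm3 == pytest.approx(400.0)
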