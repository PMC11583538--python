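"""Group-level statistics for the pneumonitis cohort.

Numeric variables are compared with two-sided Mann-Whitney-U tests (exact by
enumeration when n+m <= 20 and tie-free, otherwise the tie-corrected normal
approximation with continuity correction); categorical variables with Pearson's
chi-square (no continuity correction, df = 1 for 2x2 tables). Significance at
p < alpha (default 0.05). Patients are matched one-to-one across groups by
planning target volume (PTV) with an assignment that minimizes the total
absolute PTV discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .dosimetry import LungMetrics, PtpDoseMetrics

GROUPS = ("RCT_ICI", "RCT")
INTENTS = ("definitive", "palliative")


@dataclass
class PatientRecord:
    """Per-patient clinical metadata plus (optional) dosimetric metrics."""

    patient_id: str
    group: str
    intent: str
    ptv_cm3: float
    pneumonitis: bool = False
    grade: int | None = None
    onset_days: int | None = None
    metrics: PtpDoseMetrics | None = None
    lung: LungMetrics | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.intent not in INTENTS:
            raise ValueError(f"intent must be one of {INTENTS}, got {self.intent!r}")
        if self.ptv_cm3 <= 0:
            raise ValueError("ptv_cm3 must be > 0")
        if self.metrics is not None and not self.pneumonitis:
            raise ValueError("dosimetric PTP metrics require pneumonitis=True")
        if self.grade is not None and not self.pneumonitis:
            raise ValueError("pneumonitis grade requires pneumonitis=True")


@dataclass
class MatchedPairs:
    """One-to-one PTV matching between the two groups."""

    pairs: list[tuple[str, str]]  # (group_a patient_id, group_b patient_id)
    total_abs_ptv_diff_cm3: float


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney-U test.

    Returns (U, p) with U counted for ``x`` (pairs x_i > y_j plus half the
    ties). Exact p by enumeration for small tie-free samples (n+m <= 20),
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (x.size + y.size <= 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction on a contingency table."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must contain non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero row or column margin")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_pairs_by_ptv(group_a: list[PatientRecord],
                       group_b: list[PatientRecord]) -> MatchedPairs:
    """Optimal one-to-one PTV matching of the smaller group into the larger.

    Minimizes the total absolute PTV difference (assignment problem); exact at
    cohort scale. Ties between equally good assignments break toward ascending
    patient_id via an infinitesimal index perturbation.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = sorted(group_a, key=lambda r: r.patient_id)
    b = sorted(group_b, key=lambda r: r.patient_id)
    swapped = len(a) > len(b)
    rows, cols = (b, a) if swapped else (a, b)
    cost = np.abs(np.subtract.outer([r.ptv_cm3 for r in rows],
                                    [c.ptv_cm3 for c in cols]))
    eps = 1e-12 * max(1.0, float(cost.max()))
    tie_break = np.add.outer(np.arange(len(rows)) * len(cols), np.arange(len(cols)))
    ridx, cidx = linear_sum_assignment(cost + eps * tie_break)
    total = float(cost[ridx, cidx].sum())
    if swapped:
        pairs = [(cols[j].patient_id, rows[i].patient_id) for i, j in zip(ridx, cidx)]
    else:
        pairs = [(rows[i].patient_id, cols[j].patient_id) for i, j in zip(ridx, cidx)]
    pairs.sort()
    return MatchedPairs(pairs, total)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _metric(attr):
    return lambda r: getattr(r.metrics, attr) if r.metrics is not None else None


def _lung(attr):
    return lambda r: getattr(r.lung, attr) if r.lung is not None else None


#: Numeric summary variables (column names mirror the cohort table rows).
NUMERIC_VARIABLES: dict = {
    "v_ptp_cm3": _metric("volume_cm3"),
    "v20_ptp_eqd2_cm3": _metric("v20_cm3"),
    "mean_eqd2_ptp_gy": _metric("mean_eqd2_gy"),
    "hd_fraction_pct": _metric("hd_fraction_pct"),
    "id_fraction_pct": _metric("id_fraction_pct"),
    "ld_fraction_pct": _metric("ld_fraction_pct"),
    "auc_gy_pct": _metric("auc_gy_pct"),
    "mld_total_lung_gy": _lung("mld_gy"),
    "v20_total_lung_pct": _lung("v20_pct"),
    "ptv_cm3": lambda r: r.ptv_cm3,
    "onset_days": lambda r: r.onset_days,
}

#: Categorical (boolean) summary variables, tested with chi-square.
CATEGORICAL_VARIABLES: dict = {
    "pneumonitis": lambda r: r.pneumonitis,
    "grade_ge2": lambda r: (r.grade >= 2) if r.grade is not None else None,
}

DEFAULT_VARIABLES = list(NUMERIC_VARIABLES)

SUMMARY_COLUMNS = ["variable", "group", "n", "mean", "sd", "median", "min", "max",
                   "test", "p_value", "significant"]


def summarize_cohort(
    records: list[PatientRecord],
    variables: list[str] | None = None,
    alpha: float = 0.05,
    min_n_for_tests: int = 5,
) -> pd.DataFrame:
    """Per-variable, per-group descriptive statistics with between-group tests.

    Returns a long-format table (one row per variable x group) with mean, sample
    SD (n-1), median, min, max, the test applied and its two-sided p-value.
    p-values are suppressed (left empty) when fewer than two groups are present
    or any group has n < ``min_n_for_tests``, mirroring the small-subgroup
    convention of matched-pair reporting.
    """
    variables = variables if variables is not None else DEFAULT_VARIABLES
    rows = []
    present_groups = [g for g in GROUPS if any(r.group == g for r in records)]
    for var in variables:
        if var in NUMERIC_VARIABLES:
            accessor, kind = NUMERIC_VARIABLES[var], "numeric"
        elif var in CATEGORICAL_VARIABLES:
            accessor, kind = CATEGORICAL_VARIABLES[var], "categorical"
        else:
            known = sorted(list(NUMERIC_VARIABLES) + list(CATEGORICAL_VARIABLES))
            raise KeyError(f"unknown variable {var!r}; known variables: {known}")
        samples = {
            g: [v for r in records if r.group == g
                for v in [accessor(r)] if v is not None]
            for g in present_groups
        }
        samples = {g: s for g, s in samples.items() if s}
        testable = (len(samples) == 2
                    and all(len(s) >= min_n_for_tests for s in samples.values()))
        test_name, p = "", np.nan
        if testable:
            (sa, sb) = (samples[g] for g in samples)
            if kind == "numeric":
                test_name = "MWU"
                _, p = mann_whitney_u(sa, sb)
            else:
                counts = [[sum(bool(v) for v in s), sum(not v for v in s)]
                          for s in (sa, sb)]
                table = np.asarray(counts)
                if np.any(table.sum(axis=0) == 0):
                    test_name, p = "", np.nan
                else:
                    test_name = "Chi-square"
                    _, _, p = chi_square_test(table)
        for g, s in samples.items():
            arr = np.asarray(s, dtype=float)
            rows.append({
                "variable": var,
                "group": g,
                "n": int(arr.size),
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "median": float(np.median(arr)),
                "min": float(arr.min()),
                "max": float(arr.max()),
                "test": test_name,
                "p_value": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


# ---------------------------------------------------------------------------
# Record <-> CSV
# ---------------------------------------------------------------------------

_METRIC_FIELDS = ["volume_cm3", "v20_pct", "v20_cm3", "v40_pct", "mean_eqd2_gy",
                  "ld_fraction_pct", "id_fraction_pct", "hd_fraction_pct", "auc_gy_pct"]
_LUNG_FIELDS = ["mld_gy", "v20_pct"]


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in sorted(records, key=lambda r: r.patient_id):
        row = {
            "patient_id": r.patient_id, "group": r.group, "intent": r.intent,
            "ptv_cm3": r.ptv_cm3, "pneumonitis": int(r.pneumonitis),
            "grade": r.grade if r.grade is not None else "",
            "onset_days": r.onset_days if r.onset_days is not None else "",
        }
        for f in _METRIC_FIELDS:
            row[f"ptp_{f}"] = getattr(r.metrics, f) if r.metrics else ""
        for f in _LUNG_FIELDS:
            row[f"lung_{f}"] = getattr(r.lung, f) if r.lung else ""
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_csv(records: list[PatientRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False, float_format="%.6f")
    return path


def _opt(value, cast):
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    return cast(value)


def records_from_csv(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    records = []
    for _, row in df.iterrows():
        metrics = None
        if _opt(row.get("ptp_volume_cm3"), float) is not None:
            metrics = PtpDoseMetrics(**{f: float(row[f"ptp_{f}"]) for f in _METRIC_FIELDS})
        lung = None
        if _opt(row.get("lung_mld_gy"), float) is not None:
            lung = LungMetrics(**{f: float(row[f"lung_{f}"]) for f in _LUNG_FIELDS})
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            group=str(row["group"]),
            intent=str(row["intent"]),
            ptv_cm3=float(row["ptv_cm3"]),
            pneumonitis=bool(int(row["pneumonitis"])),
            grade=_opt(row.get("grade"), lambda v: int(float(v))),
            onset_days=_opt(row.get("onset_days"), lambda v: int(float(v))),
            metrics=metrics,
            lung=lung,
        ))
    return records
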