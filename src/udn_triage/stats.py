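"""Cohort-comparison statistics: Welch t tests from group summaries,
2x2 chi-square tests, Bonferroni adjustment, and a full accepted vs
not-accepted cohort summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cohort import MONTH_DAYS, Application


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=arr.size)


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0 or self.total == 0:
            raise ValueError("counts must be non-negative with a positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def welch_t(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float, float]:
    """Unequal-variance (Welch) two-sample t test from group summaries.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    if v1 + v2 == 0.0:
        raise ValueError("both group variances are zero; t is undefined")
    t = (g1.mean - g2.mean) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def chi2_2x2(tab: ContingencyTable2x2, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (optional Yates correction)."""
    obs = np.array([[tab.a, tab.b], [tab.c, tab.d]])
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    res = sps.chi2_contingency(obs, correction=correction)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p) for m comparisons."""
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    adj = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        adj.append(min(1.0, m * p))
    return adj


def summarize_cohort(apps: Sequence[Application], alpha: float = 0.05) -> dict:
    """Accepted vs not-accepted cohort summary.

    Per-label mean (SD) with a Welch t test for the five continuous
    indicators (age at application, age at onset, disease duration, prior
    visits, and processing time in months when recorded review days are
    present), plus per-category symptom counts/percentages with
    Bonferroni-adjusted 2x2 chi-square tests across all tested categories.
    """
    if not apps:
        raise ValueError("empty cohort")
    groups = {label: [a for a in apps if a.label == label]
              for label in ("accepted", "not_accepted")}
    if min(len(g) for g in groups.values()) == 0:
        raise ValueError("cohort must contain both admission labels")

    def values(label: str, fn) -> np.ndarray:
        return np.array([fn(a) for a in groups[label]], dtype=float)

    indicators = {
        "age_at_application": lambda a: a.age_at_application,
        "age_at_onset": lambda a: a.age_at_onset,
        "duration": lambda a: a.duration,
        "prior_visits": lambda a: a.prior_visits,
    }
    if all(a.recorded_review_day is not None for a in apps):
        indicators["processing_time_months"] = (
            lambda a: (a.recorded_review_day - a.submission_day) / MONTH_DAYS)

    report: dict = {"n": {label: len(g) for label, g in groups.items()},
                    "continuous": {}, "symptoms": {}}
    for name, fn in indicators.items():
        row: dict = {}
        summaries = {}
        for label in groups:
            v = values(label, fn)
            if v.size >= 2:
                summaries[label] = GroupSummary.from_values(v)
                row[label] = {"mean": summaries[label].mean, "sd": summaries[label].sd}
            else:
                row[label] = {"mean": float(v.mean()), "sd": None}
        if len(summaries) == 2:
            try:
                t, df, p = welch_t(summaries["accepted"], summaries["not_accepted"])
                row["t"], row["df"], row["p"] = t, df, p
            except ValueError:
                row["t"] = row["p"] = None
        else:
            row["t"] = row["p"] = None
            row["warning"] = "SD undefined for a group with fewer than 2 applications"
        report["continuous"][name] = row

    categories = sorted({a.symptom_category for a in apps})
    raw: dict[str, dict] = {}
    testable = []
    for cat in categories:
        counts = {label: sum(a.symptom_category == cat for a in groups[label])
                  for label in groups}
        row = {label: {"count": counts[label],
                       "percent": 100.0 * counts[label] / len(groups[label])}
               for label in groups}
        tab_counts = (counts["accepted"], len(groups["accepted"]) - counts["accepted"],
                      counts["not_accepted"], len(groups["not_accepted"]) - counts["not_accepted"])
        if counts["accepted"] + counts["not_accepted"] > 0 and \
                min(tab_counts[1] + tab_counts[3], 1) > 0:
            try:
                chi2, p = chi2_2x2(ContingencyTable2x2(*tab_counts))
                row["chi2"], row["p"] = chi2, p
                testable.append(cat)
            except ValueError:
                row["chi2"] = row["p"] = None
        else:
            row["chi2"] = row["p"] = None
        raw[cat] = row
    m = len(testable)
    if m:
        adjusted = bonferroni([raw[c]["p"] for c in testable], m)
        for cat, p_adj in zip(testable, adjusted):
            raw[cat]["p_bonferroni"] = p_adj
            raw[cat]["significant"] = p_adj < alpha
    report["symptoms"] = raw
    report["n_symptom_tests"] = m
    return report


def format_summary(report: dict) -> str:
    """Human-readable cohort table (accepted vs not accepted)."""
    lines = [
        f"{'Indicator':<28}{'Accepted (n=%d)' % report['n']['accepted']:>22}"
        f"{'Not accepted (n=%d)' % report['n']['not_accepted']:>24}{'Statistic':>16}"
    ]
    for name, row in report["continuous"].items():
        def fmt(cell):
            sd = f"{cell['sd']:.2f}" if cell["sd"] is not None else "NA"
            return f"{cell['mean']:.2f} ({sd})"
        stat = f"t = {row['t']:.1f}" if row.get("t") is not None else ""
        lines.append(f"{name:<28}{fmt(row['accepted']):>22}"
                     f"{fmt(row['not_accepted']):>24}{stat:>16}")
    lines.append("Symptoms, No. (%)")
    for cat, row in report["symptoms"].items():
        def fmtc(cell):
            return f"{cell['count']} ({cell['percent']:.1f})"
        stat = ""
        if row.get("chi2") is not None and row.get("significant"):
            stat = f"chi2 = {row['chi2']:.2f}"
        lines.append(f"  {cat:<26}{fmtc(row['accepted']):>22}"
                     f"{fmtc(row['not_accepted']):>24}{stat:>16}")
    return "\n".join(lines)
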