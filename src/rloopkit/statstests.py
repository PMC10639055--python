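"""Statistical tests and summaries for foci-count experiments.

Random-cell comparisons use a non-parametric Mann–Whitney U test;
before/after measurements on the same cells use a paired t-test;
independent group comparisons use a Welch two-sample t-test.  All tests
are two-sided, with significance marked as * (p < 0.05), ** (p < 0.01)
and *** (p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class StatsError(ValueError):
    pass


@dataclass
class ConditionSample:
    """Per-cell values for one experimental condition."""

    condition: str
    values: np.ndarray
    paired_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise StatsError(f"condition {self.condition!r} has no values")
        if not np.all(np.isfinite(self.values)):
            raise StatsError(f"condition {self.condition!r} has non-finite values")
        if self.paired_ids is not None and len(self.paired_ids) != len(self.values):
            raise StatsError("paired_ids must match values in length")


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    method: str = ""
    flags: list[str] = field(default_factory=list)


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(a, b) -> TestResult:
    """Mann–Whitney U with midrank ties.

    The two-sided p-value is exact (full enumeration of rank
    arrangements) when the smaller sample has at most 8 values and
    there are no ties; otherwise the tie-corrected normal approximation
    with continuity correction is used.  The chosen path is recorded in
    ``method``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both samples must be non-empty")
    exact = min(len(a), len(b)) <= 8 and not _has_ties(np.concatenate([a, b]))
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
    )


def paired_t(before, after, ids=None) -> TestResult:
    """Paired t-test on within-pair differences (df = n - 1).

    Zero differences everywhere give t = 0, p = 1; identical nonzero
    differences (zero variance) are reported as p -> 0 with a
    degenerate-variance flag.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if ids is not None:
        ids = list(ids)
        if len(ids) != len(before) or len(set(ids)) != len(ids):
            raise StatsError("pairing error: ids must be unique and match values")
    if len(before) != len(after):
        raise StatsError("pairing error: unequal sample lengths")
    if len(before) < 2:
        raise StatsError("need at least 2 pairs")
    diffs = after - before
    if np.all(diffs == 0):
        return TestResult(test="paired_t", statistic=0.0, p_value=1.0)
    if diffs.std(ddof=1) == 0:
        return TestResult(
            test="paired_t",
            statistic=float(np.sign(diffs.mean()) * np.inf),
            p_value=0.0,
            flags=["degenerate_variance"],
        )
    res = stats.ttest_rel(after, before)
    return TestResult(
        test="paired_t", statistic=float(res.statistic), p_value=float(res.pvalue)
    )


def two_sample_t(a, b) -> TestResult:
    """Welch two-sample t-test (Welch–Satterthwaite df), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need at least 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    stat = float(res.statistic)
    flags = []
    if np.isnan(p):  # both groups constant
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        stat = 0.0 if p == 1.0 else float(np.sign(a.mean() - b.mean()) * np.inf)
        flags.append("degenerate_variance")
    return TestResult(test="two_sample_t", statistic=stat, p_value=p, flags=flags)


def significance_marks(p: float) -> str:
    """``n.s.`` / ``*`` / ``**`` / ``***`` at 0.05 / 0.01 / 0.001
    (strict inequalities; the most extreme applicable mark)."""
    if not 0 <= p <= 1:
        raise StatsError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def summarize_counts(samples: list[ConditionSample]) -> pd.DataFrame:
    """Per-condition n, mean, SD, median and linear-interpolation
    quartiles, as a tidy table."""
    if not samples:
        raise StatsError("need at least one sample")
    rows = []
    for s in samples:
        v = s.values
        rows.append(
            {
                "condition": s.condition,
                "n": len(v),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else None,
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
        )
    return pd.DataFrame(rows)
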