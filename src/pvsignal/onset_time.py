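"""Time-to-onset summaries and between-group comparisons.

Onset is measured in weeks from therapy initiation to event onset.  The
raw distribution is right-skewed, so between-group location tests run on
log-transformed weeks: a variance-ratio F pre-test at alpha = 0.05 picks
the pooled two-sample t-test (equal variances) or Welch's t-test, and
three or more groups are compared with one-way ANOVA on the log scale.

Summaries report the median and quartiles (linear-interpolation
quantiles), the proportion falling in the bins <=12, (12,24], (24,48],
>48 weeks, and the cumulative proportion at the 12/24/48-week cutoffs.
Onsets of exactly 0 weeks (same-day onset) are set to 0.5 weeks before
the log transform so they stay in the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "OnsetSummary",
    "OnsetTestResult",
    "CUTOFFS",
    "summarize_onset",
    "compare_onset_two",
    "compare_onset_many",
]

CUTOFFS = (12.0, 24.0, 48.0)

#: Same-day onsets are moved to half a week before taking logs.
ZERO_ONSET_WEEKS = 0.5

VARIANCE_GATE_ALPHA = 0.05


@dataclass(frozen=True)
class OnsetSummary:
    n: int
    median_weeks: float | None
    q1_weeks: float | None
    q3_weeks: float | None
    #: proportions in bins <=12, (12,24], (24,48], >48 (sum to 1)
    bin_proportions: tuple[float, float, float, float] | None
    #: cumulative proportion of onsets <= cutoff for cutoffs 12, 24, 48
    cumulative: dict[float, float] | None


@dataclass(frozen=True)
class OnsetTestResult:
    test_name: str  # pooled_t | welch_t | anova
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    variance_gate_p: float | None = None


def summarize_onset(onsets: Sequence[float]) -> OnsetSummary:
    """Median/IQR and bin proportions of onset weeks; empty input allowed."""
    arr = np.asarray(onsets, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("onset weeks must be non-negative")
    if arr.size == 0:
        return OnsetSummary(0, None, None, None, None, None)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    bins = (
        float(np.mean(arr <= 12)),
        float(np.mean((arr > 12) & (arr <= 24))),
        float(np.mean((arr > 24) & (arr <= 48))),
        float(np.mean(arr > 48)),
    )
    cumulative = {c: float(np.mean(arr <= c)) for c in CUTOFFS}
    return OnsetSummary(int(arr.size), float(med), float(q1), float(q3), bins, cumulative)


def _log_weeks(group: Sequence[float], label: str) -> np.ndarray:
    arr = np.asarray(group, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError(f"{label}: onset weeks must be non-negative")
    arr = np.where(arr == 0, ZERO_ONSET_WEEKS, arr)
    if arr.size < 2:
        raise ValueError(f"{label}: need at least 2 usable onset values, got {arr.size}")
    return np.log(arr)


def _variance_gate_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p of the variance-ratio F test on log-weeks."""
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        return 1.0
    if vy == 0 or vx == 0:
        return 0.0
    f = vx / vy
    cdf = stats.f.cdf(f, x.size - 1, y.size - 1)
    return float(2 * min(cdf, 1 - cdf))


def compare_onset_two(
    group_a: Sequence[float], group_b: Sequence[float]
) -> OnsetTestResult:
    """Two-group comparison of log onset times (gated pooled-t / Welch).

    The equality-of-variances F test at alpha = 0.05 selects the pooled
    two-sample t-test when it does not reject, Welch's t-test otherwise;
    the p-value is two-sided.
    """
    x = _log_weeks(group_a, "group_a")
    y = _log_weeks(group_b, "group_b")
    gate_p = _variance_gate_p(x, y)
    equal_var = gate_p >= VARIANCE_GATE_ALPHA
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        # both groups constant and identical: no evidence of a difference
        name = "pooled_t" if equal_var else "welch_t"
        return OnsetTestResult(name, 0.0, float(x.size + y.size - 2), 1.0, gate_p)
    if equal_var:
        t, p = stats.ttest_ind(x, y, equal_var=True)
        df: float = x.size + y.size - 2
        name = "pooled_t"
    else:
        t, p = stats.ttest_ind(x, y, equal_var=False)
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        name = "welch_t"
    return OnsetTestResult(name, float(t), float(df), float(p), gate_p)


def compare_onset_many(groups: Sequence[Sequence[float]]) -> OnsetTestResult:
    """One-way ANOVA of log onset times across three or more groups."""
    if len(groups) < 3:
        raise ValueError(
            "compare_onset_many needs >= 3 groups; use compare_onset_two for two"
        )
    logged = [_log_weeks(g, f"group_{i}") for i, g in enumerate(groups)]
    total_n = sum(g.size for g in logged)
    grand = np.concatenate(logged)
    if np.ptp(grand) == 0:
        # every observation identical: no between- or within-group variation
        return OnsetTestResult(
            "anova", 0.0, (float(len(groups) - 1), float(total_n - len(groups))), 1.0
        )
    f, p = stats.f_oneway(*logged)
    df = (float(len(groups) - 1), float(total_n - len(groups)))
    return OnsetTestResult("anova", float(f), df, float(p))
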