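"""Case/non-case disproportionality statistics for signal detection.

The unit of analysis is the 2x2 contingency table over de-duplicated
reports::

                      matching query   not matching
    selected exposure       A               B
    everything else         C               D

with N = A+B+C+D and the expected cell count under independence
N_expected = (A+B)(A+C)/N.  Two statistics quantify disproportionate
reporting:

* the information component (IC) from the Bayesian confidence propagation
  neural network (BCPNN) framework,

      IC = log2[(A + 0.5) / (N_expected + 0.5)],

  with asymptotic 95% credibility bounds

      IC025 = IC - 3.3 (A+0.5)^(-1/2) - 2   (A+0.5)^(-3/2)
      IC975 = IC + 2.4 (A+0.5)^(-1/2) - 0.5 (A+0.5)^(-3/2)

  (an exact variant via gamma-distribution quantiles is available with
  ``method="gamma"``).  IC025 > 0 is the conventional signal threshold;
  the 0.5 shrinkage makes the IC conservative for rare events.

* the reporting odds ratio ROR = AD/BC with the Woolf (log-normal) 95%
  confidence interval exp(ln ROR +/- 1.96 sqrt(1/A+1/B+1/C+1/D)).  The
  ROR is non-estimable when any cell is zero (no continuity correction;
  a minimum-count rule A >= 3 gates significance instead).

Signal strength is categorized by IC025 thresholds 0, 3 and 5
(none / weak / moderate / strong); the thresholds themselves can be
re-derived from a set of positive IC025 values with
:func:`cluster_ic025` (deterministic one-dimensional 3-means).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .icsr_model import Report, ReportSet
from .term_catalog import GroupQuery, TermCatalog, match_report

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "build_contingency",
    "information_component",
    "ic_credible_bounds",
    "reporting_odds_ratio",
    "classify_signal",
    "signal_result",
    "screen_spectrum",
    "compare_subgroups",
    "cluster_ic025",
]

Category = Literal["none", "weak", "moderate", "strong"]

#: Minimum observed count for a ROR to be eligible for significance.
MIN_COUNT = 3


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case/non-case counts at report level."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_expected(self) -> float:
        """Expected count in cell A under row/column independence."""
        if self.n == 0:
            raise ValueError("n_expected undefined for an empty table")
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class SignalResult:
    """IC and ROR statistics for one (exposure, query) pair."""

    exposure: str
    query: str
    table: ContingencyTable
    ic: float
    ic025: float
    ic975: float
    ror: float  # nan when non-estimable
    ror_low: float
    ror_high: float
    ror_estimable: bool
    ic_significant: bool
    ror_significant: bool
    category: Category


def build_contingency(
    reports: ReportSet,
    exposure_selector: Callable[[Report], bool],
    query: GroupQuery,
) -> ContingencyTable:
    """Count reports into the 2x2 table; one report goes to exactly one cell."""
    a = b = c = d = 0
    for report in reports:
        exposed = exposure_selector(report)
        matching = match_report(report, query)
        if exposed and matching:
            a += 1
        elif exposed:
            b += 1
        elif matching:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def information_component(table: ContingencyTable) -> float:
    """IC in bits; defined even for a = 0 thanks to the 0.5 shrinkage."""
    if table.n == 0:
        raise ValueError("information component undefined for an empty table")
    return math.log2((table.a + 0.5) / (table.n_expected + 0.5))


def ic_credible_bounds(
    ic: float, a: int, method: Literal["approx", "gamma"] = "approx"
) -> tuple[float, float]:
    """95% credibility bounds (IC025, IC975) for an IC point value.

    ``approx`` uses the asymptotic expansion in the observed count; it is
    the primary method.  ``gamma`` takes log2 of the 2.5%/97.5% quantiles
    of a Gamma(a + 0.5) posterior with rate ``n_expected + 0.5`` (the rate
    is recovered from the IC point value, since 2^IC = (a+0.5)/(n_e+0.5)).
    """
    if a < 0:
        raise ValueError(f"count a must be >= 0, got {a}")
    if method == "approx":
        s = a + 0.5
        lower = ic - 3.3 * s ** -0.5 - 2.0 * s ** -1.5
        upper = ic + 2.4 * s ** -0.5 - 0.5 * s ** -1.5
        return lower, upper
    if method == "gamma":
        shape = a + 0.5
        rate = shape / 2.0 ** ic  # = n_expected + 0.5
        q = stats.gamma.ppf([0.025, 0.975], shape, scale=1.0 / rate)
        return float(np.log2(q[0])), float(np.log2(q[1]))
    raise ValueError(f"unknown method {method!r}")


def reporting_odds_ratio(
    table: ContingencyTable,
) -> tuple[float, float, float, bool]:
    """ROR with Woolf 95% CI; ``(nan, nan, nan, False)`` if any cell is 0."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return math.nan, math.nan, math.nan, False
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = 1.959963984540054 * se
    return ror, ror * math.exp(-half), ror * math.exp(half), True


def classify_signal(ic025: float) -> Category:
    """Signal-strength category from the IC lower bound (0/3/5 thresholds)."""
    if ic025 <= 0:
        return "none"
    if ic025 < 3:
        return "weak"
    if ic025 < 5:
        return "moderate"
    return "strong"


def signal_result(
    exposure: str,
    query_name: str,
    table: ContingencyTable,
    interval_method: Literal["approx", "gamma"] = "approx",
) -> SignalResult:
    """Assemble the full statistic set for one (exposure, query) table."""
    ic = information_component(table)
    ic025, ic975 = ic_credible_bounds(ic, table.a, method=interval_method)
    ror, ror_low, ror_high, estimable = reporting_odds_ratio(table)
    return SignalResult(
        exposure=exposure,
        query=query_name,
        table=table,
        ic=ic,
        ic025=ic025,
        ic975=ic975,
        ror=ror,
        ror_low=ror_low,
        ror_high=ror_high,
        ror_estimable=estimable,
        ic_significant=ic025 > 0,
        ror_significant=bool(estimable and ror_low > 1 and table.a >= MIN_COUNT),
        category=classify_signal(ic025),
    )


def screen_spectrum(
    reports: ReportSet,
    catalog: TermCatalog,
    exposures: Sequence[tuple[str, Callable[[Report], bool]]],
    queries: Sequence[GroupQuery] | None = None,
    interval_method: Literal["approx", "gamma"] = "approx",
) -> list[SignalResult]:
    """One SignalResult per (exposure, query) pair, sorted by descending IC025.

    ``exposures`` is a list of (label, selector) pairs; ``queries`` defaults
    to every named group plus every preferred term of the catalog.
    """
    if queries is None:
        queries = [catalog.group(name) for name in catalog.group_names()] + [
            catalog.pt_query(term) for term in sorted(catalog.terms)
        ]
    results = [
        signal_result(
            label,
            query.name,
            build_contingency(reports, selector, query),
            interval_method=interval_method,
        )
        for label, selector in exposures
        for query in queries
    ]
    results.sort(key=lambda r: (-r.ic025, r.exposure, r.query))
    return results


def compare_subgroups(
    reports: ReportSet,
    selector_a: Callable[[Report], bool],
    selector_b: Callable[[Report], bool],
    query: GroupQuery,
    label_a: str = "group_a",
    label_b: str = "group_b",
    interval_method: Literal["approx", "gamma"] = "approx",
) -> SignalResult:
    """Head-to-head ROR of two disjoint exposure groups for one query.

    The analysis restricts to reports selected by either group: group A is
    the "selected drug" row, group B the contrast row.  Raises ValueError
    if any report matches both selectors.
    """
    a = b = c = d = 0
    for report in reports:
        in_a = selector_a(report)
        in_b = selector_b(report)
        if in_a and in_b:
            raise ValueError(
                f"subgroup selectors overlap on report {report.report_id!r}"
            )
        if not (in_a or in_b):
            continue
        matching = match_report(report, query)
        if in_a:
            a += matching
            b += not matching
        else:
            c += matching
            d += not matching
    table = ContingencyTable(a, b, c, d)
    return signal_result(
        f"{label_a} vs {label_b}", query.name, table, interval_method=interval_method
    )


def cluster_ic025(values: Iterable[float]) -> tuple[float, float]:
    """Three-cluster boundaries for positive IC025 values (1-D 3-means).

    Deterministic Lloyd iteration initialized at (min, median, max); in one
    dimension the clusters are contiguous in sorted order, and the returned
    boundaries are the midpoints between adjacent cluster extremes.
    """
    vals = np.sort(np.asarray(list(values), dtype=float))
    if vals.size and vals[0] <= 0:
        raise ValueError("cluster_ic025 expects strictly positive values")
    if np.unique(vals).size < 3:
        raise ValueError("need at least 3 distinct positive values to form 3 clusters")
    centers = np.array([vals[0], float(np.median(vals)), vals[-1]])
    labels = np.zeros(vals.size, dtype=int)
    for _ in range(200):
        new_labels = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for k in range(3):
            members = vals[labels == k]
            if members.size:
                centers[k] = members.mean()
        centers.sort()
    lo = vals[labels == 0]
    mid = vals[labels == 1]
    hi = vals[labels == 2]
    if not (lo.size and mid.size and hi.size):
        raise ValueError("degenerate clustering: an empty cluster remained")
    return (lo.max() + mid.min()) / 2, (mid.max() + hi.min()) / 2
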