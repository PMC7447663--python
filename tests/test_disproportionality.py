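"""IC, ROR, contingency construction, categorization, clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvsignal import (
    ContingencyTable,
    ReportSet,
    build_contingency,
    classify_signal,
    cluster_ic025,
    compare_subgroups,
    ic_credible_bounds,
    information_component,
    reporting_odds_ratio,
    screen_spectrum,
    signal_result,
)
from pvsignal.term_catalog import GroupQuery, builtin_catalog

from conftest import mk_report


def has_drug(name):
    return lambda r: name in r.drugs


E_QUERY = GroupQuery("E", frozenset({"e"}))


class TestBuildContingency:
    def test_hand_counted_fixture(self, six_reports):
        t = build_contingency(six_reports, has_drug("x"), E_QUERY)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)

    def test_empty_report_set(self):
        t = build_contingency(ReportSet(), has_drug("x"), E_QUERY)
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)

    def test_exposure_matching_nothing(self, six_reports):
        t = build_contingency(six_reports, has_drug("z"), E_QUERY)
        assert t.a == 0 and t.b == 0 and t.c + t.d == len(six_reports)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_equals_independent_vector_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 80))
        reports = ReportSet(
            mk_report(
                f"R{i}",
                drugs=tuple(
                    d for d in ("x", "y", "z") if rng.random() < 0.5
                ) or ("y",),
                events=tuple(
                    e for e in ("e", "f", "g") if rng.random() < 0.5
                ) or ("f",),
            )
            for i in range(n)
        )
        t = build_contingency(reports, has_drug("x"), E_QUERY)
        exposed = np.array([has_drug("x")(r) for r in reports])
        matching = np.array(["e" in r.events for r in reports])
        assert t.a == int((exposed & matching).sum())
        assert t.b == int((exposed & ~matching).sum())
        assert t.c == int((~exposed & matching).sum())
        assert t.d == int((~exposed & ~matching).sum())
        assert t.n == n


class TestInformationComponent:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((10, 10, 10, 10), 0.0),
            ((50, 950, 150, 98850), 4.3363),
            ((0, 100, 50, 99850), -0.1375),
        ],
    )
    def test_hand_evaluated_values(self, cells, expected):
        ic = information_component(ContingencyTable(*cells))
        assert ic == pytest.approx(expected, abs=1e-4)

    def test_zero_on_any_independence_table(self):
        # outer-product tables (alpha*beta, alpha*gamma, delta*beta, delta*gamma)
        rng = np.random.default_rng(5)
        for _ in range(50):
            al, be, ga, de = rng.integers(1, 30, size=4)
            t = ContingencyTable(al * be, al * ga, de * be, de * ga)
            assert t.n_expected == t.a
            assert information_component(t) == 0.0

    def test_monotone_in_observed_count(self):
        low = information_component(ContingencyTable(10, 990, 1000, 98000))
        high = information_component(ContingencyTable(40, 960, 970, 98030))
        assert high > low

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            information_component(ContingencyTable(0, 0, 0, 0))


class TestCredibleBounds:
    def test_derived_small_count_values(self):
        lo, hi = ic_credible_bounds(2.0, 4)
        assert lo == pytest.approx(0.2349, abs=1e-4)
        assert hi == pytest.approx(3.0790, abs=1e-4)

    def test_bounds_bracket_the_point_estimate(self):
        for a in (1, 5, 50, 1000):
            lo, hi = ic_credible_bounds(1.7, a)
            assert lo < 1.7 < hi

    def test_width_shrinks_with_count(self):
        widths = []
        for a in (3, 10, 100, 1000):
            lo, hi = ic_credible_bounds(2.0, a)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_gamma_method_agrees_for_large_counts(self):
        # the asymptotic bounds are slightly wider than the exact gamma
        # quantiles; agreement tightens as the count grows
        for a, ic in ((200, 3.0), (747, 6.74), (1077, 4.22)):
            lo_a, hi_a = ic_credible_bounds(ic, a)
            lo_g, hi_g = ic_credible_bounds(ic, a, method="gamma")
            assert lo_g == pytest.approx(lo_a, abs=0.05)
            assert hi_g == pytest.approx(hi_a, abs=0.05)
            assert lo_g >= lo_a - 1e-9

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ic_credible_bounds(1.0, -1)


class TestReportingOddsRatio:
    def test_proportional_rows_give_unity(self):
        ror, *_ = reporting_odds_ratio(ContingencyTable(10, 20, 5, 10))
        assert ror == pytest.approx(1.0)

    def test_hand_evaluated_point_estimate(self):
        ror, *_ = reporting_odds_ratio(ContingencyTable(30, 70, 10, 90))
        assert ror == pytest.approx(3.8571, abs=1e-4)

    def test_hand_evaluated_woolf_interval(self):
        ror, lo, hi, ok = reporting_odds_ratio(ContingencyTable(20, 80, 10, 160))
        assert ok
        assert ror == pytest.approx(4.0)
        assert lo == pytest.approx(1.788, abs=1e-3)
        assert hi == pytest.approx(8.948, abs=1e-3)

    @pytest.mark.parametrize("cells", [(0, 5, 5, 5), (5, 0, 5, 5), (5, 5, 0, 5), (5, 5, 5, 0)])
    def test_zero_cell_is_non_estimable_not_an_error(self, cells):
        ror, lo, hi, ok = reporting_odds_ratio(ContingencyTable(*cells))
        assert not ok and math.isnan(ror) and math.isnan(lo) and math.isnan(hi)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_sign_agreement_with_ic(self, seed):
        # ROR > 1  <=>  ad > bc  <=>  a > n_expected  <=>  IC > 0
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(5, 200, size=4))
        t = ContingencyTable(a, b, c, d)
        ror, *_ = reporting_odds_ratio(t)
        ic = information_component(t)
        assert (ror > 1) == (t.a > t.n_expected) == (ic > 0) or a * d == b * c


@pytest.mark.parametrize(
    "ic025,category",
    [
        (8.05, "strong"),
        (5.0, "strong"),
        (4.52, "moderate"),
        (3.0, "moderate"),
        (1.14, "weak"),
        (0.19, "weak"),
        (0.0, "none"),
        (-0.5, "none"),
    ],
)
def test_signal_categories(ic025, category):
    assert classify_signal(ic025) == category


class TestClusterIc025:
    def test_well_separated_values(self):
        lo, hi = cluster_ic025([1.0, 1.1, 3.9, 4.0, 6.9, 7.0])
        assert lo == pytest.approx(2.5)
        assert hi == pytest.approx(5.45)

    def test_point_mass_triplets(self):
        lo, hi = cluster_ic025([1, 1, 1, 4, 4, 4, 9, 9, 9])
        assert (lo, hi) == (2.5, 6.5)

    def test_matches_exhaustive_contiguous_partition_search(self):
        rng = np.random.default_rng(11)
        values = np.sort(rng.uniform(0.1, 9.0, size=12))

        def within_ss(chunk):
            return float(((chunk - chunk.mean()) ** 2).sum())

        best, best_cuts = math.inf, None
        for i in range(1, 11):
            for j in range(i + 1, 12):
                ss = within_ss(values[:i]) + within_ss(values[i:j]) + within_ss(values[j:])
                if ss < best:
                    best, best_cuts = ss, (i, j)
        i, j = best_cuts
        expected = (
            (values[i - 1] + values[i]) / 2,
            (values[j - 1] + values[j]) / 2,
        )
        lo, hi = cluster_ic025(values)
        assert (lo, hi) == pytest.approx(expected)

    def test_clusters_contiguous_in_sorted_order(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0.01, 10, size=40)
        lo, hi = cluster_ic025(values)
        assert 0 < lo < hi < 10
        s = np.sort(values)
        # boundaries fall strictly between adjacent observed values
        assert ((s < lo).sum() > 0) and ((s > hi).sum() > 0)

    def test_requires_three_distinct_positive_values(self):
        with pytest.raises(ValueError):
            cluster_ic025([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            cluster_ic025([-1.0, 2.0, 3.0])


class TestCompareSubgroups:
    def _reports(self, n_a_match, n_a, n_b_match, n_b):
        reports = []
        for i in range(n_a):
            events = ("e",) if i < n_a_match else ("f",)
            reports.append(mk_report(f"A{i}", drugs=("a",), events=events))
        for i in range(n_b):
            events = ("e",) if i < n_b_match else ("f",)
            reports.append(mk_report(f"B{i}", drugs=("b",), events=events))
        return ReportSet(reports)

    def test_identical_proportions_give_unity(self):
        rs = self._reports(10, 50, 10, 50)
        res = compare_subgroups(rs, has_drug("a"), has_drug("b"), E_QUERY)
        assert res.ror == pytest.approx(1.0)

    def test_hand_evaluated_ror(self):
        rs = self._reports(30, 100, 10, 100)
        res = compare_subgroups(rs, has_drug("a"), has_drug("b"), E_QUERY)
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (30, 70, 10, 90)
        assert res.ror == pytest.approx(3.857, abs=1e-3)

    def test_overlapping_selectors_rejected(self):
        rs = ReportSet([mk_report("R1", drugs=("a", "b"), events=("e",))])
        with pytest.raises(ValueError, match="overlap"):
            compare_subgroups(rs, has_drug("a"), has_drug("b"), E_QUERY)

    def test_reports_outside_both_groups_excluded(self):
        rs = self._reports(30, 100, 10, 100)
        extra = ReportSet(list(rs) + [mk_report("C1", drugs=("c",), events=("e",))])
        res = compare_subgroups(extra, has_drug("a"), has_drug("b"), E_QUERY)
        assert res.table.n == 200


class TestScreenSpectrum:
    def test_minimum_count_rule_blocks_small_counts(self):
        # a = 2 with a huge odds ratio must not be ROR-significant
        reports = [mk_report(f"X{i}", drugs=("x",), events=("e",)) for i in range(2)]
        reports += [mk_report(f"W{i}", drugs=("x",), events=("f",)) for i in range(30)]
        reports += [mk_report(f"Y{i}", drugs=("y",), events=("f",)) for i in range(200)]
        reports += [mk_report("Z0", drugs=("y",), events=("e",))]
        res = signal_result(
            "x", "E", build_contingency(ReportSet(reports), has_drug("x"), E_QUERY)
        )
        assert res.table.a == 2
        assert res.ror_estimable and res.ror_low > 1
        assert res.ror_significant is False

    def test_results_sorted_and_composable(self, six_reports, catalog):
        rs = ReportSet(
            [
                mk_report("R1", drugs=("nivolumab",), events=("hypothyroidism",)),
                mk_report("R2", drugs=("nivolumab",), events=("nausea",)),
                mk_report("R3", drugs=("metformin",), events=("hypothyroidism",)),
                mk_report("R4", drugs=("metformin",), events=("nausea",)),
            ]
        )
        exposures = [("nivolumab", has_drug("nivolumab"))]
        results = screen_spectrum(rs, catalog, exposures)
        assert [r.ic025 for r in results] == sorted(
            (r.ic025 for r in results), reverse=True
        )
        for res in results:
            direct = signal_result(
                res.exposure,
                res.query,
                build_contingency(
                    rs, has_drug("nivolumab"),
                    catalog.group(res.query) if res.query in catalog.groups
                    else catalog.pt_query(res.query),
                ),
            )
            assert res == direct
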