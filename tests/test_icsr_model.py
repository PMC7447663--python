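"""Report data model, I/O, de-duplication and exposure classification."""

import random

import pytest

from pvsignal import (
    Report,
    ReportSet,
    SchemaError,
    classify_exposure,
    deduplicate,
    flag_fatal,
    load_reports,
    write_reports,
)
from pvsignal.icsr_model import UNKNOWN

from conftest import mk_report

CSV_HEADER = (
    "report_id,drug,event,year,gender,age_group,region,notifier,"
    "indication,onset_weeks,outcomes\n"
)


def write_csv(path, rows):
    path.write_text(CSV_HEADER + "".join(r + "\n" for r in rows), encoding="utf-8")


class TestLoadReports:
    def test_rows_sharing_an_id_merge_into_one_report(self, tmp_path):
        p = tmp_path / "db.csv"
        write_csv(
            p,
            [
                "R1,nivolumab,hypothyroidism,2018,male,,,,,,",
                "R1,ipilimumab,hypothyroidism,2018,male,,,,,,",
                "R1,nivolumab,hypophysitis,2018,male,,,,,,",
            ],
        )
        rs = load_reports(p, "csv")
        assert len(rs) == 1
        (r,) = rs
        assert r.drugs == {"nivolumab", "ipilimumab"}
        assert r.events == {"hypothyroidism", "hypophysitis"}
        assert r.year == 2018 and r.gender == "male"

    def test_empty_file_with_header_gives_empty_set(self, tmp_path):
        p = tmp_path / "db.csv"
        write_csv(p, [])
        assert len(load_reports(p, "csv")) == 0

    def test_row_order_does_not_affect_result(self, tmp_path):
        rows = [
            "R1,nivolumab,hypothyroidism,2018,male,,Europe,,,,",
            "R2,ipilimumab,hypophysitis,2017,,over65,,,,12.0,recovered",
            "R1,nivolumab,thyroiditis,,female,,,,,,",
            "R2,ipilimumab,adrenal insufficiency,,,,,,,,",
        ]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_csv(p1, rows)
        shuffled = rows[:]
        random.Random(7).shuffle(shuffled)
        write_csv(p2, shuffled)
        a, b = load_reports(p1), load_reports(p2)
        assert len(a) == 2 and a == b

    def test_missing_required_column_names_the_field(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text("report_id,drug\nR1,nivolumab\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="event"):
            load_reports(p, "csv")

    def test_unparseable_onset_reports_row_index(self, tmp_path):
        p = tmp_path / "db.csv"
        write_csv(p, ["R1,nivolumab,hypothyroidism,,,,,,,twelve,"])
        with pytest.raises(ValueError, match="row 1"):
            load_reports(p, "csv")


@pytest.mark.parametrize("fmt", ["csv", "jsonl"])
def test_write_then_load_round_trips(tmp_path, fmt):
    rs = ReportSet(
        [
            mk_report(
                "R1",
                drugs=("nivolumab", "ipilimumab"),
                events=("hypophysitis", "thyroiditis"),
                year=2017,
                gender="female",
                age_group="over65",
                region="Asia",
                notifier="health_professional",
                indication="malignant melanoma",
                onset_weeks=9.5,
                outcomes=frozenset({"recovered"}),
            ),
            mk_report("R2", drugs=("metformin",), events=("nausea",)),
        ]
    )
    p = tmp_path / f"db.{fmt}"
    write_reports(rs, p, fmt)
    assert load_reports(p, fmt) == rs


class TestDeduplicate:
    def test_removes_repeated_ids(self):
        rs = ReportSet([mk_report("R1"), mk_report("R1"), mk_report("R2")])
        out = deduplicate(rs)
        assert sorted(out.report_ids()) == ["R1", "R2"]

    def test_idempotent_on_unique_set(self):
        rs = ReportSet([mk_report("R1"), mk_report("R2")])
        assert deduplicate(rs) == rs
        assert deduplicate(deduplicate(rs)) == deduplicate(rs)

    def test_keeps_most_complete_record(self):
        sparse = mk_report("R1")
        full = mk_report("R1", gender="male", year=2018)
        out = deduplicate(ReportSet([sparse, full]))
        assert list(out) == [full]

    def test_first_seen_wins_on_ties(self):
        a = mk_report("R1", gender="male")
        b = mk_report("R1", gender="female")
        assert list(deduplicate(ReportSet([a, b]))) == [a]


class TestClassifyExposure:
    @pytest.mark.parametrize(
        "drugs,label",
        [
            (("ipilimumab",), "ipilimumab_mono"),
            (("nivolumab",), "nivolumab_mono"),
            (("ipilimumab", "nivolumab"), "combination"),
            (("ipilimumab", "durvalumab"), "combination"),
            (("nivolumab", "pembrolizumab"), "other_multi_ici"),
            (("nivolumab", "atezolizumab"), "other_multi_ici"),
            (("metformin",), "non_ici"),
        ],
    )
    def test_labels(self, drugs, label):
        assert classify_exposure(mk_report(drugs=drugs)) == label

    @pytest.mark.parametrize(
        "drugs",
        [("ipilimumab",), ("ipilimumab", "nivolumab"), ("nivolumab", "pembrolizumab")],
    )
    def test_non_ici_comedication_ignored(self, drugs):
        base = classify_exposure(mk_report(drugs=drugs))
        with_comed = classify_exposure(
            mk_report(drugs=drugs + ("metformin", "paracetamol"))
        )
        assert base == with_comed


@pytest.mark.parametrize(
    "outcomes,expected",
    [
        ({"death"}, True),
        ({"life_threatening"}, True),
        ({"recovered"}, False),
        ({"hospitalization", "recovered"}, True),
        ({UNKNOWN}, False),
        ({"not_recovered"}, False),
    ],
)
def test_flag_fatal(outcomes, expected):
    assert flag_fatal(mk_report(outcomes=frozenset(outcomes))) is expected


def test_report_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        mk_report(drugs=())
    with pytest.raises(ValueError):
        mk_report(events=())
    with pytest.raises(ValueError):
        mk_report(onset_weeks=-1.0)
    with pytest.raises(ValueError):
        mk_report(gender="m")
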