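import pytest

from pvsignal import Report, ReportSet, builtin_catalog


def mk_report(rid="R1", drugs=("drugx",), events=("hypothyroidism",), **kw):
    return Report(
        report_id=rid, drugs=frozenset(drugs), events=frozenset(events), **kw
    )


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture
def six_reports():
    """Reports with exposure drug X vs Y and events E/F for 2x2 counting."""
    return ReportSet(
        [
            mk_report("R1", drugs=("x",), events=("e",)),
            mk_report("R2", drugs=("x",), events=("f",)),
            mk_report("R3", drugs=("y",), events=("e",)),
            mk_report("R4", drugs=("y",), events=("f",)),
            mk_report("R5", drugs=("x",), events=("e", "f")),
            mk_report("R6", drugs=("y",), events=("f",)),
        ]
    )
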