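"""Data model and I/O for individual case safety reports (ICSRs).

A spontaneous-report database holds one record per report, each carrying
the suspected drugs, the coded adverse-event terms, and report-level
attributes (year, demographics, onset time, final outcomes).  This module
defines the :class:`Report` record, the :class:`ReportSet` container,
CSV / JSON-lines readers and writers, de-duplication, exposure-class
assignment for immune checkpoint inhibitor (ICI) therapy, and the
fatal-outcome flag.

Conventions
-----------
* Missing values are explicit ``"unknown"`` sentinels (or ``None`` for
  onset and year), never silently dropped; percentage denominators
  downstream count only known values.
* Drug and event names are canonicalized by lower-casing and trimming;
  matching against catalogs is exact (no fuzzy matching).
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Literal, Mapping

__all__ = [
    "UNKNOWN",
    "FATAL_OUTCOMES",
    "DEFAULT_ICI_CATALOG",
    "MONO_LABELS",
    "Report",
    "ReportSet",
    "SchemaError",
    "load_reports",
    "write_reports",
    "deduplicate",
    "classify_exposure",
    "classify_drug_set",
    "flag_fatal",
]

UNKNOWN = "unknown"

GENDERS = frozenset({"male", "female", UNKNOWN})
AGE_GROUPS = frozenset({"under65", "over65", UNKNOWN})
REGIONS = frozenset({"Americas", "Asia", "Europe", "Oceania", "Africa", UNKNOWN})
NOTIFIERS = frozenset({"health_professional", "other", UNKNOWN})
OUTCOME_LABELS = frozenset(
    {
        "death",
        "life_threatening",
        "hospitalization",
        "other_medically_critical",
        "not_recovered",
        "recovered",
        UNKNOWN,
    }
)

#: Outcome labels that make a report "fatal" in the regulatory sense:
#: death, life-threatening, hospitalization (initial or prolonged), or any
#: other medically critical condition.
FATAL_OUTCOMES = frozenset(
    {"death", "life_threatening", "hospitalization", "other_medically_critical"}
)

#: Drug-name -> checkpoint-target class for the five ICI agents analyzed.
DEFAULT_ICI_CATALOG: Mapping[str, str] = {
    "ipilimumab": "CTLA4",
    "nivolumab": "PD1",
    "pembrolizumab": "PD1",
    "atezolizumab": "PDL1",
    "durvalumab": "PDL1",
}

MONO_LABELS = tuple(f"{drug}_mono" for drug in DEFAULT_ICI_CATALOG)

COMBINATION = "combination"
OTHER_MULTI_ICI = "other_multi_ici"
NON_ICI = "non_ici"


class SchemaError(ValueError):
    """Raised when an input file lacks a required column or field."""


def _canon(name: str) -> str:
    return name.strip().lower()


@dataclass(frozen=True)
class Report:
    """One individual case safety report (after coding, before or after dedup).

    ``drugs`` holds the suspected drugs, ``events`` the coded event
    preferred terms; both are non-empty frozensets of canonical
    (lower-cased, trimmed) strings.  One report may carry several drugs
    and several events.
    """

    report_id: str
    drugs: frozenset[str]
    events: frozenset[str]
    year: int | None = None
    gender: str = UNKNOWN
    age_group: str = UNKNOWN
    region: str = UNKNOWN
    notifier: str = UNKNOWN
    indication: str = UNKNOWN
    onset_weeks: float | None = None
    outcomes: frozenset[str] = frozenset({UNKNOWN})

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        object.__setattr__(self, "drugs", frozenset(_canon(d) for d in self.drugs))
        object.__setattr__(self, "events", frozenset(_canon(e) for e in self.events))
        object.__setattr__(self, "outcomes", frozenset(self.outcomes))
        if not self.drugs:
            raise ValueError(f"report {self.report_id}: drugs must be non-empty")
        if not self.events:
            raise ValueError(f"report {self.report_id}: events must be non-empty")
        if self.onset_weeks is not None and self.onset_weeks < 0:
            raise ValueError(
                f"report {self.report_id}: onset_weeks must be >= 0, "
                f"got {self.onset_weeks}"
            )
        for name, value, allowed in (
            ("gender", self.gender, GENDERS),
            ("age_group", self.age_group, AGE_GROUPS),
            ("region", self.region, REGIONS),
            ("notifier", self.notifier, NOTIFIERS),
        ):
            if value not in allowed:
                raise ValueError(f"report {self.report_id}: invalid {name} {value!r}")
        if not self.outcomes or not self.outcomes <= OUTCOME_LABELS:
            raise ValueError(
                f"report {self.report_id}: invalid outcomes {set(self.outcomes)}"
            )

    def missing_count(self) -> int:
        """Number of missing report-level attributes (used for dedup ties)."""
        n = 0
        n += self.year is None
        n += self.gender == UNKNOWN
        n += self.age_group == UNKNOWN
        n += self.region == UNKNOWN
        n += self.notifier == UNKNOWN
        n += self.indication == UNKNOWN
        n += self.onset_weeks is None
        n += self.outcomes == frozenset({UNKNOWN})
        return n


class ReportSet:
    """Ordered collection of reports; equality ignores order (multiset)."""

    def __init__(self, reports: Iterable[Report] = ()) -> None:
        self._reports: list[Report] = list(reports)

    def __len__(self) -> int:
        return len(self._reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self._reports)

    def __getitem__(self, i: int) -> Report:
        return self._reports[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        return Counter(self._reports) == Counter(other._reports)

    def __repr__(self) -> str:
        return f"ReportSet(n={len(self._reports)})"

    def report_ids(self) -> list[str]:
        return [r.report_id for r in self._reports]


_CSV_HEADER = [
    "report_id",
    "drug",
    "event",
    "year",
    "gender",
    "age_group",
    "region",
    "notifier",
    "indication",
    "onset_weeks",
    "outcomes",
]

_REQUIRED = ("report_id", "drug", "event")


def _parse_onset(raw: str, row_index: int) -> float | None:
    if raw in ("", UNKNOWN):
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"unparseable onset_weeks {raw!r} at row {row_index}") from None


def _sentinel(raw: str | None) -> str:
    return _canon(raw) if raw not in (None, "") else UNKNOWN


def _region_sentinel(raw: str | None) -> str:
    if raw in (None, ""):
        return UNKNOWN
    raw = raw.strip()
    return raw if raw in REGIONS else UNKNOWN


def _merge_rows(rows: list[dict], row_indices: list[int]) -> Report:
    """Collapse long-form rows sharing one report_id into a single Report.

    The first non-missing value wins for each report-level attribute, so
    the result does not depend on how drug/event rows are interleaved.
    """
    drugs: set[str] = set()
    events: set[str] = set()
    outcomes: set[str] = set()
    attrs: dict = {}
    for row, idx in zip(rows, row_indices):
        if row.get("drug"):
            drugs.add(row["drug"])
        if row.get("event"):
            events.add(row["event"])
        for out in (row.get("outcomes") or "").split("|"):
            out = out.strip()
            if out and out != UNKNOWN:
                outcomes.add(out)
        raw_year = row.get("year")
        if "year" not in attrs and raw_year not in (None, "", UNKNOWN):
            attrs["year"] = int(raw_year)
        for key, conv in (
            ("gender", _sentinel),
            ("age_group", _sentinel),
            ("notifier", _sentinel),
            ("indication", _sentinel),
        ):
            val = conv(row.get(key))
            if key not in attrs and val != UNKNOWN:
                attrs[key] = val
        region = _region_sentinel(row.get("region"))
        if "region" not in attrs and region != UNKNOWN:
            attrs["region"] = region
        onset = _parse_onset(str(row.get("onset_weeks") or ""), idx)
        if "onset_weeks" not in attrs and onset is not None:
            attrs["onset_weeks"] = onset
    return Report(
        report_id=rows[0]["report_id"],
        drugs=frozenset(drugs),
        events=frozenset(events),
        year=attrs.get("year"),
        gender=attrs.get("gender", UNKNOWN),
        age_group=attrs.get("age_group", UNKNOWN),
        region=attrs.get("region", UNKNOWN),
        notifier=attrs.get("notifier", UNKNOWN),
        indication=attrs.get("indication", UNKNOWN),
        onset_weeks=attrs.get("onset_weeks"),
        outcomes=frozenset(outcomes) or frozenset({UNKNOWN}),
    )


def load_reports(path: str | Path, format: Literal["csv", "jsonl"] = "csv") -> ReportSet:
    """Read a report database from CSV (long form) or JSON-lines.

    CSV is one row per (report, drug, event) observation; rows are grouped
    by ``report_id`` (row order does not matter) and report-level attributes
    take the first non-missing value.  JSON-lines is one object per report
    record with ``drugs``/``events``/``outcomes`` as arrays; records sharing
    a report_id are kept as distinct entries (duplicates), which
    :func:`deduplicate` resolves.

    Raises
    ------
    SchemaError
        If a required column/field (report_id, drug, event) is absent.
    ValueError
        If an onset_weeks value cannot be parsed (message names the row).
    """
    path = Path(path)
    if format == "csv":
        return _load_csv(path)
    if format == "jsonl":
        return _load_jsonl(path)
    raise ValueError(f"unknown format {format!r}")


def _load_csv(path: Path) -> ReportSet:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _REQUIRED:
            if col not in header:
                raise SchemaError(f"missing required column {col!r} in {path}")
        groups: dict[str, tuple[list[dict], list[int]]] = {}
        for idx, row in enumerate(reader, start=1):
            rid = (row.get("report_id") or "").strip()
            if not rid:
                raise SchemaError(f"empty report_id at row {idx}")
            row["report_id"] = rid
            rows, idxs = groups.setdefault(rid, ([], []))
            rows.append(row)
            idxs.append(idx)
    return ReportSet(_merge_rows(rows, idxs) for rows, idxs in groups.values())


def _load_jsonl(path: Path) -> ReportSet:
    reports: list[Report] = []
    with path.open(encoding="utf-8") as fh:
        for idx, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            for key in ("report_id", "drugs", "events"):
                if key not in obj:
                    raise SchemaError(f"missing required field {key!r} at line {idx}")
            onset = obj.get("onset_weeks")
            if onset is not None and not isinstance(onset, (int, float)):
                onset = _parse_onset(str(onset), idx)
            reports.append(
                Report(
                    report_id=str(obj["report_id"]),
                    drugs=frozenset(obj["drugs"]),
                    events=frozenset(obj["events"]),
                    year=obj.get("year"),
                    gender=obj.get("gender") or UNKNOWN,
                    age_group=obj.get("age_group") or UNKNOWN,
                    region=obj.get("region") or UNKNOWN,
                    notifier=obj.get("notifier") or UNKNOWN,
                    indication=obj.get("indication") or UNKNOWN,
                    onset_weeks=onset,
                    outcomes=frozenset(obj.get("outcomes") or [UNKNOWN]),
                )
            )
    return ReportSet(reports)


def write_reports(
    reports: ReportSet, path: str | Path, format: Literal["csv", "jsonl"] = "csv"
) -> None:
    """Write reports in the dialect :func:`load_reports` reads.

    CSV emits one row per (report, drug, event) pair in sorted order;
    note CSV cannot represent two distinct records under one report_id
    (use JSON-lines for not-yet-deduplicated sets).
    """
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for r in reports:
                shared = [
                    r.year if r.year is not None else "",
                    r.gender,
                    r.age_group,
                    r.region,
                    r.notifier,
                    r.indication,
                    r.onset_weeks if r.onset_weeks is not None else "",
                    "|".join(sorted(r.outcomes)),
                ]
                for drug in sorted(r.drugs):
                    for event in sorted(r.events):
                        writer.writerow([r.report_id, drug, event, *shared])
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in reports:
                obj = {
                    "report_id": r.report_id,
                    "drugs": sorted(r.drugs),
                    "events": sorted(r.events),
                    "year": r.year,
                    "gender": r.gender,
                    "age_group": r.age_group,
                    "region": r.region,
                    "notifier": r.notifier,
                    "indication": r.indication,
                    "onset_weeks": r.onset_weeks,
                    "outcomes": sorted(r.outcomes),
                }
                fh.write(json.dumps(obj, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def deduplicate(reports: ReportSet) -> ReportSet:
    """Keep one record per report_id: the most complete, first-seen on ties.

    Completeness is the number of known report-level attributes
    (:meth:`Report.missing_count`).  Idempotent; output order follows first
    occurrence of each ID.
    """
    best: dict[str, tuple[int, int, Report]] = {}
    order: list[str] = []
    for pos, r in enumerate(reports):
        key = r.report_id
        cand = (r.missing_count(), pos, r)
        if key not in best:
            best[key] = cand
            order.append(key)
        elif cand[0] < best[key][0]:
            best[key] = cand
    return ReportSet(best[k][2] for k in order)


def classify_exposure(
    report: Report, ici_catalog: Mapping[str, str] = DEFAULT_ICI_CATALOG
) -> str:
    """Assign exactly one exposure-class label to a report.

    Rules (non-ICI co-medication is ignored):

    * no ICI drug                       -> ``non_ici``
    * anti-CTLA-4 plus >=1 anti-PD-1/PD-L1 -> ``combination``
    * exactly one ICI drug              -> ``<drug>_mono``
    * several ICIs without the combination pattern -> ``other_multi_ici``
      (e.g. anti-PD-1 together with anti-PD-L1 but no anti-CTLA-4)
    """
    return classify_drug_set(report.drugs, ici_catalog)


def classify_drug_set(
    drugs: frozenset[str], ici_catalog: Mapping[str, str] = DEFAULT_ICI_CATALOG
) -> str:
    """Exposure label straight from a drug set (same rules as
    :func:`classify_exposure`)."""
    ici = {d: ici_catalog[d] for d in drugs if d in ici_catalog}
    if not ici:
        return NON_ICI
    classes = set(ici.values())
    if "CTLA4" in classes and classes & {"PD1", "PDL1"}:
        return COMBINATION
    if len(ici) == 1:
        (drug,) = ici
        return f"{drug}_mono"
    return OTHER_MULTI_ICI


def flag_fatal(report: Report) -> bool:
    """True iff any recorded outcome is death, life-threatening,
    hospitalization, or another medically critical condition."""
    return bool(report.outcomes & FATAL_OUTCOMES)
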