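"""Miniature open catalog of endocrine adverse-event preferred terms.

Regulatory databases code events with the licensed MedDRA dictionary and
aggregate preferred terms (PTs) into named group queries.  MedDRA itself
cannot be redistributed, so this module ships a small open catalog keyed
by exact lower-case strings: the endocrine PTs the analysis needs plus the
named groups (ICI-DM, thyroid dysfunction, hypophysitis/hypopituitarism,
adrenal insufficiency, and the union of all endocrine terms).

A report matches a group query when any of its events is a member; a
report with several member terms still counts once (the unit of counting
is the report case, not the event).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .icsr_model import Report

__all__ = ["TermCatalog", "GroupQuery", "builtin_catalog", "match_report"]

# Grouped insulin-deficient diabetes terms ("ICI-DM").
_ICI_DM = (
    "type 1 diabetes mellitus",
    "diabetes mellitus",
    "fulminant type 1 diabetes mellitus",
    "diabetic ketoacidosis",
)

_THYROID = ("hypothyroidism", "hyperthyroidism", "thyroiditis")

_PITUITARY = (
    "hypophysitis",
    "hypopituitarism",
    "lymphocytic hypophysitis",
    "pituitary enlargement",
)

_ADRENAL = (
    "adrenal insufficiency",
    "primary adrenocortical insufficiency",
    "secondary adrenocortical insufficiency",
    "acute adrenocortical insufficiency",
)

_OTHER_TERMS = (
    "thyrotoxic crisis",
    "basedow's disease",
    "diabetes insipidus",
    "hypoparathyroidism",
    "hypogonadism",
    "inappropriate antidiuretic hormone secretion",
)

ENDOCRINE_ALL = "endocrine_all"


@dataclass(frozen=True)
class GroupQuery:
    """A named set of preferred terms queried together."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group query {self.name!r} has no members")


@dataclass(frozen=True)
class TermCatalog:
    """Preferred terms plus named group queries over them."""

    terms: frozenset[str]
    groups: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            extra = members - self.terms
            if extra:
                raise ValueError(
                    f"group {name!r} has members outside the term list: {sorted(extra)}"
                )

    def group(self, name: str) -> GroupQuery:
        return GroupQuery(name, frozenset(self.groups[name]))

    def pt_query(self, term: str) -> GroupQuery:
        """A single preferred term as its own query."""
        if term not in self.terms:
            raise KeyError(f"unknown preferred term {term!r}")
        return GroupQuery(term, frozenset({term}))

    def group_names(self) -> list[str]:
        return sorted(self.groups)

    # -- serialization: {terms: [...], groups: {name: [...]}} ----------------

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "terms": sorted(self.terms),
            "groups": {name: sorted(members) for name, members in self.groups.items()},
        }
        text = (
            json.dumps(payload, indent=2, sort_keys=True)
            if path.suffix == ".json"
            else yaml.safe_dump(payload, sort_keys=True)
        )
        path.write_text(text, encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "TermCatalog":
        path = Path(path)
        raw = path.read_text(encoding="utf-8")
        payload = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls(
            terms=frozenset(payload["terms"]),
            groups={n: frozenset(m) for n, m in payload["groups"].items()},
        )


def builtin_catalog() -> TermCatalog:
    """The built-in endocrine catalog.

    Groups: ``ICI-DM`` (insulin-deficient diabetes), ``thyroid_dysfunction``,
    ``hypophysitis_hypopituitarism``, ``adrenal_insufficiency_group``, and
    ``endocrine_all`` (every catalog term).
    """
    terms = frozenset(_ICI_DM + _THYROID + _PITUITARY + _ADRENAL + _OTHER_TERMS)
    groups = {
        "ICI-DM": frozenset(_ICI_DM),
        "thyroid_dysfunction": frozenset(_THYROID),
        "hypophysitis_hypopituitarism": frozenset(_PITUITARY),
        "adrenal_insufficiency_group": frozenset(_ADRENAL),
        ENDOCRINE_ALL: terms,
    }
    return TermCatalog(terms=terms, groups=groups)


def match_report(report: Report, query: GroupQuery) -> bool:
    """True iff the report carries at least one member term of the query."""
    return bool(report.events & query.members)
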