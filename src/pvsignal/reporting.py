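"""Descriptive summaries and end-to-end pipeline orchestration.

``descriptive_summary`` produces a Table-1-style stratified description
of a de-duplicated report set: counts and percentages per year, gender,
age group, region, notifier, indication and final outcome, plus the
male:female ratio, the fatal fraction and the recovered fraction — for
the total set and for each exposure class.  Percentages follow the
"n/N (%)" convention: denominators count only reports with a known value
for the field.

``run_pipeline`` wires the whole analysis: load (or generate) ->
de-duplicate -> classify exposure -> descriptive table -> IC/ROR spectrum
screen -> subgroup ROR comparisons -> onset summaries and tests, writing
deterministic TSV/JSON exports and a machine-readable run log.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Mapping, Optional

from pydantic import BaseModel, Field

from . import __version__
from .icsr_model import (
    DEFAULT_ICI_CATALOG,
    FATAL_OUTCOMES,
    MONO_LABELS,
    UNKNOWN,
    Report,
    ReportSet,
    classify_exposure,
    deduplicate,
    flag_fatal,
    load_reports,
    write_reports,
)
from .term_catalog import TermCatalog, builtin_catalog
from .disproportionality import SignalResult, compare_subgroups, screen_spectrum
from .onset_time import OnsetSummary, OnsetTestResult, compare_onset_many, compare_onset_two, summarize_onset
from .synthetic import GeneratorConfig, default_config, generate_database

__all__ = [
    "DescriptiveTable",
    "StratumSummary",
    "descriptive_summary",
    "RunConfig",
    "run_pipeline",
]

_CATEGORICAL_FIELDS = ("year", "gender", "age_group", "region", "notifier", "indication")

#: final-outcome labels counted as "outcome reported"
_FINAL_OUTCOMES = FATAL_OUTCOMES | {"not_recovered", "recovered"}

HEADLINE_CLASSES = MONO_LABELS + ("combination",)


@dataclass(frozen=True)
class StratumSummary:
    """Counts for one stratum (total or one exposure class)."""

    label: str
    n: int
    #: field -> category -> (count, known-value denominator)
    tables: Mapping[str, Mapping[str, tuple[int, int]]]
    male_female_ratio: float | None  # rounded to 1 decimal; None if no females
    fatal: tuple[int, int]  # (fatal count, reports with a final outcome)
    recovered: tuple[int, int]

    @property
    def fatal_fraction(self) -> float | None:
        num, den = self.fatal
        return num / den if den else None

    @property
    def recovered_fraction(self) -> float | None:
        num, den = self.recovered
        return num / den if den else None


@dataclass(frozen=True)
class DescriptiveTable:
    strata: Mapping[str, StratumSummary]

    @property
    def total(self) -> StratumSummary:
        return self.strata["total"]


def _is_known(report: Report, field: str) -> bool:
    value = getattr(report, field)
    return value is not None and value != UNKNOWN


def _summarize_stratum(label: str, reports: list[Report]) -> StratumSummary:
    tables: dict[str, dict[str, tuple[int, int]]] = {}
    for field in _CATEGORICAL_FIELDS:
        counts: dict[str, int] = {}
        denom = 0
        for r in reports:
            if _is_known(r, field):
                denom += 1
                key = str(getattr(r, field))
                counts[key] = counts.get(key, 0) + 1
        tables[field] = {k: (v, denom) for k, v in sorted(counts.items())}
    male = tables["gender"].get("male", (0, 0))[0]
    female = tables["gender"].get("female", (0, 0))[0]
    ratio = round(male / female, 1) if female else None
    with_outcome = [r for r in reports if r.outcomes & _FINAL_OUTCOMES]
    fatal = sum(flag_fatal(r) for r in with_outcome)
    recovered = sum("recovered" in r.outcomes for r in with_outcome)
    return StratumSummary(
        label=label,
        n=len(reports),
        tables=tables,
        male_female_ratio=ratio,
        fatal=(fatal, len(with_outcome)),
        recovered=(recovered, len(with_outcome)),
    )


def descriptive_summary(
    reports: ReportSet,
    classifier: Callable[[Report], str] | None = None,
) -> DescriptiveTable:
    """Table-1-style description of a de-duplicated report set.

    ``classifier`` maps a report to its exposure-class label (defaults to
    :func:`~pvsignal.icsr_model.classify_exposure` with the built-in ICI
    catalog); one stratum per observed label plus a ``total`` stratum.
    """
    if classifier is None:
        classifier = classify_exposure
    by_class: dict[str, list[Report]] = {}
    all_reports = list(reports)
    for r in all_reports:
        by_class.setdefault(classifier(r), []).append(r)
    strata = {"total": _summarize_stratum("total", all_reports)}
    for label in sorted(by_class):
        strata[label] = _summarize_stratum(label, by_class[label])
    return DescriptiveTable(strata=strata)


# ---------------------------------------------------------------------------
# pipeline


class RunConfig(BaseModel):
    """Single configuration object for an end-to-end run.

    Exactly one input source applies: ``input_path`` (an existing report
    file) or ``generator`` (a synthetic-database configuration); with
    neither, the default generator conditions are used at ``seed``.
    """

    seed: int = 0
    output_dir: str
    input_path: Optional[str] = None
    input_format: Literal["csv", "jsonl"] = "csv"
    generator: Optional[GeneratorConfig] = None
    catalog_path: Optional[str] = None
    interval_method: Literal["approx", "gamma"] = "approx"
    exposure_classes: tuple[str, ...] = HEADLINE_CLASSES
    export_reports: bool = False


def _fmt(x: object, digits: int = 2) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return str(x).lower()
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return f"{x:.{digits}f}"
    return str(x)


def _signal_row(s: SignalResult) -> dict:
    t = s.table
    return {
        "exposure": s.exposure,
        "query": s.query,
        "a": t.a,
        "b": t.b,
        "c": t.c,
        "d": t.d,
        "n_expected": t.n_expected,
        "ic": s.ic,
        "ic025": s.ic025,
        "ic975": s.ic975,
        "ror": None if not s.ror_estimable else s.ror,
        "ror_low": None if not s.ror_estimable else s.ror_low,
        "ror_high": None if not s.ror_estimable else s.ror_high,
        "ic_significant": s.ic_significant,
        "ror_significant": s.ror_significant,
        "category": s.category,
    }


def _write_tsv(path: Path, rows: list[dict], float_digits: int = 2) -> None:
    if not rows:
        path.write_text("", encoding="utf-8")
        return
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append("\t".join(_fmt(row[c], float_digits) for c in cols))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_json(path: Path, payload: object) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )


def _descriptive_rows(table: DescriptiveTable) -> list[dict]:
    rows: list[dict] = []
    for label, stratum in table.strata.items():
        for field, cats in stratum.tables.items():
            for cat, (count, denom) in cats.items():
                rows.append(
                    {
                        "stratum": label,
                        "field": field,
                        "category": cat,
                        "count": count,
                        "denominator": denom,
                        "percent": 100 * count / denom if denom else None,
                    }
                )
        rows.append(
            {
                "stratum": label, "field": "summary", "category": "n",
                "count": stratum.n, "denominator": stratum.n, "percent": 100.0,
            }
        )
        for name, (num, den) in (("fatal", stratum.fatal), ("recovered", stratum.recovered)):
            rows.append(
                {
                    "stratum": label, "field": "final_outcome", "category": name,
                    "count": num, "denominator": den,
                    "percent": 100 * num / den if den else None,
                }
            )
        if stratum.male_female_ratio is not None:
            rows.append(
                {
                    "stratum": label, "field": "summary", "category": "male_female_ratio",
                    "count": None, "denominator": None,
                    "percent": None,
                }
            )
            rows[-1]["count"] = stratum.male_female_ratio
    return rows


def _descriptive_payload(table: DescriptiveTable) -> dict:
    return {
        label: {
            "n": s.n,
            "tables": {f: {c: list(v) for c, v in cats.items()} for f, cats in s.tables.items()},
            "male_female_ratio": s.male_female_ratio,
            "fatal": list(s.fatal),
            "recovered": list(s.recovered),
        }
        for label, s in table.strata.items()
    }


def _onset_groups(catalog: TermCatalog) -> list[str]:
    return [g for g in catalog.group_names() if g != "endocrine_all"]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all exports.

    Returns the run log (also written as ``run_log.json``), which records
    the master seed, the package version, and record counts at each stage.
    Identical configurations (including seed) produce byte-identical
    exports.  On stage failure, partially written outputs are removed and
    a RuntimeError naming the stage is raised.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log: dict = {"seed": config.seed, "version": __version__, "stages": {}}

    def stage(name: str, fn: Callable):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - stage name must propagate
            for p in written:
                p.unlink(missing_ok=True)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def _load() -> ReportSet:
        if config.input_path is not None:
            return load_reports(config.input_path, config.input_format)
        gen = config.generator or default_config(seed=config.seed)
        return generate_database(gen)

    raw = stage("load", _load)
    log["stages"]["n_loaded"] = len(raw)

    reports = stage("deduplicate", lambda: deduplicate(raw))
    log["stages"]["n_after_dedup"] = len(reports)

    catalog = stage(
        "catalog",
        lambda: TermCatalog.from_file(config.catalog_path)
        if config.catalog_path
        else builtin_catalog(),
    )

    labels: dict[str, str] = stage(
        "classify",
        lambda: {r.report_id: classify_exposure(r, DEFAULT_ICI_CATALOG) for r in reports},
    )
    class_counts: dict[str, int] = {}
    for lab in labels.values():
        class_counts[lab] = class_counts.get(lab, 0) + 1
    log["stages"]["exposure_counts"] = dict(sorted(class_counts.items()))

    table = stage(
        "descriptive",
        lambda: descriptive_summary(reports, lambda r: labels[r.report_id]),
    )

    def _spectrum() -> list[SignalResult]:
        exposures = [
            (lab, (lambda r, lab=lab: labels[r.report_id] == lab))
            for lab in config.exposure_classes
        ]
        return screen_spectrum(
            reports, catalog, exposures, interval_method=config.interval_method
        )

    spectrum = stage("spectrum", _spectrum)
    log["stages"]["n_spectrum_pairs"] = len(spectrum)
    log["stages"]["n_ic_significant"] = sum(s.ic_significant for s in spectrum)

    def _subgroups() -> list[SignalResult]:
        pd_mono = {f"{d}_mono" for d, c in DEFAULT_ICI_CATALOG.items() if c in ("PD1", "PDL1")}
        ctla4_mono = {f"{d}_mono" for d, c in DEFAULT_ICI_CATALOG.items() if c == "CTLA4"}
        mono = pd_mono | ctla4_mono
        comparisons = [
            ("anti_pd1_pdl1_mono", pd_mono, "anti_ctla4_mono", ctla4_mono),
            ("combination", {"combination"}, "monotherapy", mono),
        ]
        results = []
        for name_a, set_a, name_b, set_b in comparisons:
            for gname in _onset_groups(catalog):
                results.append(
                    compare_subgroups(
                        reports,
                        lambda r, s=set_a: labels[r.report_id] in s,
                        lambda r, s=set_b: labels[r.report_id] in s,
                        catalog.group(gname),
                        label_a=name_a,
                        label_b=name_b,
                        interval_method=config.interval_method,
                    )
                )
        return results

    subgroups = stage("subgroups", _subgroups)

    def _onset() -> tuple[list[dict], list[dict]]:
        summary_rows: list[dict] = []
        test_rows: list[dict] = []
        for gname in _onset_groups(catalog):
            query = catalog.group(gname)
            per_class: dict[str, list[float]] = {}
            for r in reports:
                if r.onset_weeks is None or not (r.events & query.members):
                    continue
                lab = labels[r.report_id]
                if lab in config.exposure_classes:
                    per_class.setdefault(lab, []).append(r.onset_weeks)
            for lab in sorted(per_class):
                s: OnsetSummary = summarize_onset(per_class[lab])
                summary_rows.append(
                    {
                        "query": gname,
                        "exposure": lab,
                        "n": s.n,
                        "median_weeks": s.median_weeks,
                        "q1_weeks": s.q1_weeks,
                        "q3_weeks": s.q3_weeks,
                        "p_le_12": s.bin_proportions[0] if s.bin_proportions else None,
                        "p_12_24": s.bin_proportions[1] if s.bin_proportions else None,
                        "p_24_48": s.bin_proportions[2] if s.bin_proportions else None,
                        "p_gt_48": s.bin_proportions[3] if s.bin_proportions else None,
                    }
                )
            usable = {k: v for k, v in sorted(per_class.items()) if len(v) >= 2}
            result: OnsetTestResult | None = None
            if len(usable) >= 3:
                result = compare_onset_many(list(usable.values()))
            elif len(usable) == 2:
                a, b = usable.values()
                result = compare_onset_two(a, b)
            if result is not None:
                df = result.df
                test_rows.append(
                    {
                        "query": gname,
                        "groups": ",".join(usable),
                        "test": result.test_name,
                        "statistic": result.statistic,
                        "df": df if isinstance(df, float) else f"{df[0]:g},{df[1]:g}",
                        "p_value": result.p_value,
                        "variance_gate_p": result.variance_gate_p,
                    }
                )
        return summary_rows, test_rows

    onset_summaries, onset_tests = stage("onset", _onset)

    def _write_all() -> None:
        def emit(path: Path, writer: Callable[[Path], None]) -> None:
            written.append(path)
            writer(path)

        if config.export_reports and config.input_path is None:
            emit(outdir / "reports.jsonl", lambda p: write_reports(raw, p, "jsonl"))
        emit(outdir / "descriptive.tsv", lambda p: _write_tsv(p, _descriptive_rows(table), 1))
        emit(outdir / "descriptive.json", lambda p: _write_json(p, _descriptive_payload(table)))
        spectrum_rows = [_signal_row(s) for s in spectrum]
        emit(outdir / "spectrum.tsv", lambda p: _write_tsv(p, spectrum_rows))
        emit(outdir / "spectrum.json", lambda p: _write_json(p, spectrum_rows))
        emit(outdir / "subgroups.tsv", lambda p: _write_tsv(p, [_signal_row(s) for s in subgroups]))
        emit(outdir / "onset_summary.tsv", lambda p: _write_tsv(p, onset_summaries))
        emit(outdir / "onset_tests.tsv", lambda p: _write_tsv(p, onset_tests, 4))
        emit(outdir / "run_log.json", lambda p: _write_json(p, log))

    stage("write", _write_all)
    return log
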