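"""Synthetic spontaneous-report database generator.

Real pharmacovigilance databases are access-restricted, so every stage of
the pipeline is exercised on generated individual case safety reports that
reproduce the statistical structure the analysis assumes:

* each report draws a set of suspected drugs (independent Bernoulli per
  drug, with an explicit probability of carrying the anti-CTLA-4 plus
  anti-PD-1/PD-L1 combination) and a set of event preferred terms
  (independent Bernoulli per term, so multi-event reports arise
  naturally); empty draws are rejection-resampled;
* planted drug-event signals multiply the event's baseline reporting
  probability by a relative reporting-rate factor lambda when the drug is
  present, which is what the downstream IC/ROR statistics estimate;
* onset weeks are log-normal per (exposure class, event group), because
  the onset analysis runs on the log scale;
* configurable per-field missingness, duplicate report injection, and a
  report-year distribution skewed toward recent years.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` substreams, so databases are
bit-reproducible and each stage's draws are independent of the others.

The default configuration emulates an ICI pharmacovigilance slice: five
checkpoint inhibitors at low exposure prevalence among common
co-medications, endocrine preferred terms at rare baseline rates with
planted ICI-endocrine signals of the magnitude seen in real spontaneous
data, missingness comparable to real report completeness, and a 3%
duplicate rate.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .icsr_model import UNKNOWN, Report, ReportSet, classify_drug_set
from .term_catalog import builtin_catalog

__all__ = [
    "DrugSpec",
    "EventSpec",
    "SignalSpec",
    "OnsetParams",
    "GeneratorConfig",
    "default_config",
    "generate_database",
    "inject_duplicates",
]


class DrugSpec(BaseModel):
    """One drug on the menu: name, optional ICI class, marginal exposure."""

    name: str
    ici_class: Optional[Literal["CTLA4", "PD1", "PDL1"]] = None
    prevalence: float = Field(ge=0.0, le=1.0)


class EventSpec(BaseModel):
    """One preferred term and its baseline reporting probability per report."""

    term: str
    baseline: float = Field(ge=0.0, le=1.0)


class SignalSpec(BaseModel):
    """Planted disproportionality: event probability is baseline * multiplier
    (clipped to [0, 1]) whenever the drug is present."""

    drug: str
    event: str
    multiplier: float = Field(ge=0.0)

    @field_validator("multiplier")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not np.isfinite(v):
            raise ValueError("multiplier must be finite")
        return v


class OnsetParams(BaseModel):
    """Log-normal onset-time parameters (natural-log weeks)."""

    log_mean: float
    log_sd: float = Field(gt=0.0)


class GeneratorConfig(BaseModel):
    n_reports: int = Field(ge=1)
    drug_menu: list[DrugSpec]
    event_menu: list[EventSpec]
    signal_specs: list[SignalSpec] = []
    combo_probability: float = Field(default=0.0, ge=0.0, le=1.0)
    #: keyed "<exposure class>:<group>", "<exposure class>", or "default"
    onset_model: dict[str, OnsetParams] = {"default": OnsetParams(log_mean=2.3, log_sd=0.8)}
    duplicate_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    #: per-field probability of masking to the unknown/missing sentinel
    missing_rates: dict[str, float] = {}
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if not self.drug_menu:
            raise ValueError("drug_menu must be non-empty")
        if not self.event_menu:
            raise ValueError("event_menu must be non-empty")
        for f, p in self.missing_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missing rate for {f!r} must be in [0,1], got {p}")
        known = {spec.name for spec in self.drug_menu}
        for sig in self.signal_specs:
            if sig.drug not in known:
                raise ValueError(f"signal drug {sig.drug!r} not on drug menu")
        if not any(e.baseline > 0 for e in self.event_menu):
            raise ValueError("at least one event needs baseline > 0")
        return self


# Empirically plausible study conditions: ICI exposure is rare relative to
# the whole database, endocrine PTs are rare events, and the planted
# multipliers give IC values in the 2-7 bit range seen for real signals.
_DEFAULT_DRUGS = [
    DrugSpec(name="ipilimumab", ici_class="CTLA4", prevalence=0.015),
    DrugSpec(name="nivolumab", ici_class="PD1", prevalence=0.035),
    DrugSpec(name="pembrolizumab", ici_class="PD1", prevalence=0.02),
    DrugSpec(name="atezolizumab", ici_class="PDL1", prevalence=0.005),
    DrugSpec(name="durvalumab", ici_class="PDL1", prevalence=0.005),
    DrugSpec(name="metformin", prevalence=0.08),
    DrugSpec(name="atorvastatin", prevalence=0.10),
    DrugSpec(name="amoxicillin", prevalence=0.12),
    DrugSpec(name="lisinopril", prevalence=0.09),
    DrugSpec(name="paracetamol", prevalence=0.25),
]

_DEFAULT_EVENTS = [
    EventSpec(term="hypothyroidism", baseline=0.002),
    EventSpec(term="hyperthyroidism", baseline=0.0012),
    EventSpec(term="thyroiditis", baseline=0.0004),
    EventSpec(term="hypophysitis", baseline=0.0002),
    EventSpec(term="hypopituitarism", baseline=0.0002),
    EventSpec(term="adrenal insufficiency", baseline=0.0006),
    EventSpec(term="type 1 diabetes mellitus", baseline=0.0008),
    EventSpec(term="fulminant type 1 diabetes mellitus", baseline=0.0001),
    EventSpec(term="diabetic ketoacidosis", baseline=0.001),
    # common background reactions keeping endocrine terms rare overall
    EventSpec(term="nausea", baseline=0.18),
    EventSpec(term="headache", baseline=0.15),
    EventSpec(term="rash", baseline=0.12),
    EventSpec(term="fatigue", baseline=0.14),
]

_DEFAULT_SIGNALS = [
    SignalSpec(drug="ipilimumab", event="hypophysitis", multiplier=90.0),
    SignalSpec(drug="ipilimumab", event="hypopituitarism", multiplier=50.0),
    SignalSpec(drug="ipilimumab", event="adrenal insufficiency", multiplier=35.0),
    SignalSpec(drug="nivolumab", event="hypothyroidism", multiplier=18.0),
    SignalSpec(drug="nivolumab", event="hyperthyroidism", multiplier=22.0),
    SignalSpec(drug="nivolumab", event="thyroiditis", multiplier=40.0),
    SignalSpec(drug="nivolumab", event="fulminant type 1 diabetes mellitus", multiplier=60.0),
    SignalSpec(drug="nivolumab", event="type 1 diabetes mellitus", multiplier=20.0),
    SignalSpec(drug="pembrolizumab", event="hypothyroidism", multiplier=15.0),
    SignalSpec(drug="pembrolizumab", event="hyperthyroidism", multiplier=18.0),
    SignalSpec(drug="pembrolizumab", event="type 1 diabetes mellitus", multiplier=18.0),
    SignalSpec(drug="atezolizumab", event="hypothyroidism", multiplier=12.0),
    SignalSpec(drug="durvalumab", event="hyperthyroidism", multiplier=20.0),
]

# Onset medians around 9-10 weeks for anti-CTLA-4, more dispersed and later
# for anti-PD-1, earlier again under combination therapy.
_DEFAULT_ONSET = {
    "default": OnsetParams(log_mean=np.log(10.0), log_sd=0.9),
    "ipilimumab_mono": OnsetParams(log_mean=np.log(9.0), log_sd=0.6),
    "nivolumab_mono": OnsetParams(log_mean=np.log(14.0), log_sd=1.1),
    "pembrolizumab_mono": OnsetParams(log_mean=np.log(12.0), log_sd=1.0),
    "combination": OnsetParams(log_mean=np.log(8.0), log_sd=0.8),
    "nivolumab_mono:thyroid_dysfunction": OnsetParams(log_mean=np.log(5.0), log_sd=0.9),
}

_DEFAULT_MISSING = {
    "gender": 0.06,
    "age_group": 0.26,
    "region": 0.0,
    "notifier": 0.03,
    "indication": 0.12,
    "onset_weeks": 0.55,
    "outcomes": 0.41,
}

_YEARS = np.arange(2011, 2020)
_YEAR_P = np.array([0.004, 0.013, 0.013, 0.029, 0.067, 0.111, 0.262, 0.428, 0.073])


def default_config(n_reports: int = 50_000, seed: int = 0) -> GeneratorConfig:
    """Default study conditions (see module docstring)."""
    return GeneratorConfig(
        n_reports=n_reports,
        drug_menu=list(_DEFAULT_DRUGS),
        event_menu=list(_DEFAULT_EVENTS),
        signal_specs=list(_DEFAULT_SIGNALS),
        combo_probability=0.004,
        onset_model=dict(_DEFAULT_ONSET),
        duplicate_rate=0.03,
        missing_rates=dict(_DEFAULT_MISSING),
        seed=seed,
    )


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ["drugs", "combo", "events", "onset", "fields", "duplicates"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _resample_empty(rng: np.random.Generator, draws: np.ndarray, p: np.ndarray) -> None:
    """Redraw all-zero rows in place until every row has >= 1 success.

    ``p`` is (n, k) per-row probabilities; rows whose probabilities are all
    zero cannot succeed and get their highest-probability column forced on
    (degenerate configs only).
    """
    for _ in range(10_000):
        empty = ~draws.any(axis=1)
        if not empty.any():
            return
        idx = np.flatnonzero(empty)
        dead = p[idx].sum(axis=1) == 0
        if dead.any():
            forced = idx[dead]
            draws[forced, p[forced].argmax(axis=1)] = True
            idx = idx[~dead]
            if idx.size == 0:
                continue
        draws[idx] = rng.random((idx.size, p.shape[1])) < p[idx]
    raise RuntimeError("rejection resampling failed to produce non-empty draws")


def generate_database(config: GeneratorConfig) -> ReportSet:
    """Draw a fully synthetic report database; bit-reproducible given seed.

    Exactly ``n_reports`` base reports are produced; duplicate injection
    (``duplicate_rate``) then appends doubled records on top, so the
    returned set has >= n_reports records and exactly n_reports unique IDs.
    """
    rngs = _substreams(config.seed)
    n = config.n_reports
    drug_names = [d.name for d in config.drug_menu]
    drug_p = np.array([d.prevalence for d in config.drug_menu])

    drug_draws = rngs["drugs"].random((n, len(drug_names))) < drug_p
    _resample_empty(rngs["drugs"], drug_draws, np.broadcast_to(drug_p, drug_draws.shape).copy())

    # combination therapy: force anti-CTLA-4 plus one anti-PD-1/PD-L1
    ctla4 = [i for i, d in enumerate(config.drug_menu) if d.ici_class == "CTLA4"]
    partners = [i for i, d in enumerate(config.drug_menu) if d.ici_class in ("PD1", "PDL1")]
    if config.combo_probability > 0 and ctla4 and partners:
        combo_rng = rngs["combo"]
        combo_mask = combo_rng.random(n) < config.combo_probability
        rows = np.flatnonzero(combo_mask)
        if rows.size:
            drug_draws[rows, ctla4[0]] = True
            partner_p = drug_p[partners]
            partner_p = partner_p / partner_p.sum() if partner_p.sum() > 0 else None
            chosen = combo_rng.choice(partners, size=rows.size, p=partner_p)
            drug_draws[rows, chosen] = True

    event_terms = [e.term for e in config.event_menu]
    event_p = np.broadcast_to(
        np.array([e.baseline for e in config.event_menu]), (n, len(event_terms))
    ).copy()
    col_of = {t: j for j, t in enumerate(event_terms)}
    drug_col = {d: i for i, d in enumerate(drug_names)}
    for sig in config.signal_specs:
        if sig.event not in col_of:
            continue
        has_drug = drug_draws[:, drug_col[sig.drug]]
        j = col_of[sig.event]
        event_p[has_drug, j] = np.clip(event_p[has_drug, j] * sig.multiplier, 0.0, 1.0)
    event_draws = rngs["events"].random(event_p.shape) < event_p
    _resample_empty(rngs["events"], event_draws, event_p)

    ici_catalog = {
        d.name: d.ici_class for d in config.drug_menu if d.ici_class is not None
    }
    catalog = builtin_catalog()
    group_of_term: dict[str, str] = {}
    # specific groups only: the catch-all union would shadow them
    for gname in catalog.group_names():
        if gname == "endocrine_all":
            continue
        for t in catalog.groups[gname]:
            group_of_term.setdefault(t, gname)

    onset_rng = rngs["onset"]
    field_rng = rngs["fields"]
    years = field_rng.choice(_YEARS, size=n, p=_YEAR_P)
    genders = field_rng.choice(["male", "female"], size=n, p=[0.6, 0.4])
    ages = field_rng.choice(["under65", "over65"], size=n, p=[0.5, 0.5])
    regions = field_rng.choice(
        ["Americas", "Asia", "Europe", "Oceania", "Africa"],
        size=n,
        p=[0.30, 0.234, 0.438, 0.027, 0.001],
    )
    notifiers = field_rng.choice(["health_professional", "other"], size=n, p=[0.88, 0.12])
    indications = field_rng.choice(
        ["malignant melanoma", "lung cancer", "renal cell carcinoma", "other"],
        size=n,
        p=[0.40, 0.36, 0.06, 0.18],
    )
    outcome_choices = field_rng.choice(
        ["recovered", "not_recovered", "death", "life_threatening"],
        size=n,
        p=[0.69, 0.28, 0.02, 0.01],
    )
    miss = {
        f: field_rng.random(n) < config.missing_rates.get(f, 0.0)
        for f in ("gender", "age_group", "region", "notifier", "indication",
                  "onset_weeks", "outcomes")
    }
    normals = onset_rng.standard_normal(n)

    id_width = max(6, len(str(n)))
    reports: list[Report] = []
    default_onset = config.onset_model.get("default", OnsetParams(log_mean=2.3, log_sd=0.8))
    for i in range(n):
        drugs = frozenset(drug_names[j] for j in np.flatnonzero(drug_draws[i]))
        events = frozenset(event_terms[j] for j in np.flatnonzero(event_draws[i]))
        label = classify_drug_set(drugs, ici_catalog)
        group = next(
            (group_of_term[t] for t in sorted(events) if t in group_of_term), None
        )
        params = None
        if group is not None:
            params = config.onset_model.get(f"{label}:{group}")
        if params is None:
            params = config.onset_model.get(label, default_onset)
        onset = None
        if not miss["onset_weeks"][i]:
            onset = float(np.exp(params.log_mean + params.log_sd * normals[i]))
        reports.append(
            Report(
                report_id=f"R{i:0{id_width}d}",
                drugs=drugs,
                events=events,
                year=int(years[i]),
                gender=UNKNOWN if miss["gender"][i] else str(genders[i]),
                age_group=UNKNOWN if miss["age_group"][i] else str(ages[i]),
                region=UNKNOWN if miss["region"][i] else str(regions[i]),
                notifier=UNKNOWN if miss["notifier"][i] else str(notifiers[i]),
                indication=UNKNOWN if miss["indication"][i] else str(indications[i]),
                onset_weeks=onset,
                outcomes=(
                    frozenset({UNKNOWN})
                    if miss["outcomes"][i]
                    else frozenset({str(outcome_choices[i])})
                ),
            )
        )
    result = ReportSet(reports)
    if config.duplicate_rate > 0:
        dup_seed = int(rngs["duplicates"].integers(0, 2**31 - 1))
        result = inject_duplicates(result, config.duplicate_rate, dup_seed)
    return result


_MASKABLE = ("gender", "age_group", "region", "notifier", "indication",
              "onset_weeks", "outcomes")


def inject_duplicates(reports: ReportSet, rate: float, seed: int) -> ReportSet:
    """Append a near-copy (same report_id, one extra field masked) of a
    random fraction ``rate`` of reports; :func:`~pvsignal.icsr_model.deduplicate`
    recovers a set of the original size."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0,1], got {rate}")
    rng = np.random.default_rng(seed)
    out = list(reports)
    for r in reports:
        if rng.random() >= rate:
            continue
        known = [
            f
            for f in _MASKABLE
            if (
                getattr(r, f) is not None
                and getattr(r, f) != UNKNOWN
                and getattr(r, f) != frozenset({UNKNOWN})
            )
        ]
        if known:
            f = known[int(rng.integers(len(known)))]
            masked = frozenset({UNKNOWN}) if f == "outcomes" else (
                None if f in ("onset_weeks",) else UNKNOWN
            )
            copy = Report(
                **{
                    **{fld: getattr(r, fld) for fld in (
                        "report_id", "drugs", "events", "year", "gender", "age_group",
                        "region", "notifier", "indication", "onset_weeks", "outcomes")},
                    f: masked,
                }
            )
        else:
            copy = r
        out.append(copy)
    return ReportSet(out)
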