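"""Built-in synthetic reference datasets.

``synthetic_case_series`` reconstructs, field by field, the marginal
demographic structure of a large real-world census of ICI-associated
endocrine adverse-event reports (6,089 de-duplicated cases).  Each field
is assigned independently in index blocks, so every marginal count is
exact while the joint distribution across fields carries no information;
the set exists so descriptive summaries can be checked against known
marginal arithmetic without access to any restricted database.
"""

from __future__ import annotations

from .icsr_model import UNKNOWN, Report, ReportSet

__all__ = ["synthetic_case_series"]

_N = 6089

# exposure class -> (count, drug set)
_EXPOSURE_BLOCKS = [
    ("ipilimumab_mono", 1115, frozenset({"ipilimumab"})),
    ("nivolumab_mono", 2449, frozenset({"nivolumab"})),
    ("pembrolizumab_mono", 1342, frozenset({"pembrolizumab"})),
    ("durvalumab_mono", 111, frozenset({"durvalumab"})),
    ("atezolizumab_mono", 110, frozenset({"atezolizumab"})),
    ("combination", 962, frozenset({"ipilimumab", "nivolumab"})),
]

_YEAR_BLOCKS = [
    (2011, 23), (2012, 80), (2013, 79), (2014, 174), (2015, 407),
    (2016, 676), (2017, 1595), (2018, 2612), (2019, 443),
]

_GENDER_BLOCKS = [("male", 3432), ("female", 2279), (UNKNOWN, 378)]
_AGE_BLOCKS = [("under65", 2233), ("over65", 2275), (UNKNOWN, 1581)]
_REGION_BLOCKS = [
    ("Americas", 1826), ("Asia", 1427), ("Europe", 2665),
    ("Oceania", 170), ("Africa", 1),
]
_NOTIFIER_BLOCKS = [("health_professional", 5220), ("other", 686), (UNKNOWN, 183)]
_INDICATION_BLOCKS = [
    ("malignant melanoma", 2328), ("lung cancer", 1912),
    ("renal cell carcinoma", 330), ("other", 778), (UNKNOWN, 741),
]
_OUTCOME_BLOCKS = [
    (frozenset({"death"}), 64),
    (frozenset({"not_recovered"}), 1025),
    (frozenset({"recovered"}), 2483),
    (frozenset({UNKNOWN}), 2517),
]


def _expand(blocks, total=_N):
    values = []
    for value, count, *_ in blocks:
        values.extend([value] * count)
    if len(values) != total:
        raise AssertionError(f"block counts sum to {len(values)}, expected {total}")
    return values


def synthetic_case_series() -> ReportSet:
    """Synthetic 6,089-report set with exact field-wise marginal counts.

    Every report carries one endocrine event term; drugs encode the
    exposure class.  Fields are mutually independent (block assignment),
    so only marginal summaries are meaningful.
    """
    drugs = []
    for _, count, drugset in _EXPOSURE_BLOCKS:
        drugs.extend([drugset] * count)
    years = _expand(_YEAR_BLOCKS)
    genders = _expand(_GENDER_BLOCKS)
    ages = _expand(_AGE_BLOCKS)
    regions = _expand(_REGION_BLOCKS)
    notifiers = _expand(_NOTIFIER_BLOCKS)
    indications = _expand(_INDICATION_BLOCKS)
    outcomes = _expand(_OUTCOME_BLOCKS)
    if len(drugs) != _N:
        raise AssertionError("exposure blocks do not sum to the series size")
    reports = [
        Report(
            report_id=f"S{i:04d}",
            drugs=drugs[i],
            events=frozenset({"hypothyroidism"}),
            year=years[i],
            gender=genders[i],
            age_group=ages[i],
            region=regions[i],
            notifier=notifiers[i],
            indication=indications[i],
            outcomes=outcomes[i],
        )
        for i in range(_N)
    ]
    return ReportSet(reports)
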