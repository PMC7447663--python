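# Methods

## The case/non-case design

`pvsignal` analyses spontaneous-report databases: collections of
individual case safety reports (ICSRs), each carrying suspected drugs,
coded adverse-event preferred terms (PTs), and report-level attributes.
Disproportionality analysis asks whether a selected event (or group of
events) makes up a larger share of the reports for a selected exposure
than of the reports for everything else in the database. The unit of
counting is the *report case*: a report contributes once to a cell even
when several of its PTs belong to the queried group.

For an (exposure, query) pair the de-duplicated database partitions into
a 2×2 table

|                    | matching query | not matching |
|--------------------|---------------|--------------|
| selected exposure  | A             | B            |
| everything else    | C             | D            |

with N = A+B+C+D and expected count under independence
N_e = (A+B)(A+C)/N.

## Statistics

**Information component (IC).** From the Bayesian confidence propagation
neural network (BCPNN) framework,

    IC = log2[(A + 0.5) / (N_e + 0.5)]        (bits).

The 0.5 shrinkage pulls the estimate toward 0 for small counts, which is
what makes the IC a conservative screen for rare events in large
databases. Its 95% credibility bounds use the asymptotic expansion in
the observed count,

    IC025 = IC − 3.3 (A+0.5)^(−1/2) − 2   (A+0.5)^(−3/2)
    IC975 = IC + 2.4 (A+0.5)^(−1/2) − 0.5 (A+0.5)^(−3/2),

the standard closed form used in practice for BCPNN intervals. An exact
variant (`method="gamma"`) takes log2 of the 2.5%/97.5% quantiles of a
Gamma(A+0.5) posterior with rate N_e+0.5; the asymptotic bounds are
slightly wider (by ≈0.03 bits at A = 200, shrinking as A grows), and the
exact variant exists as a cross-check, not the default. IC025 > 0 is the
signal threshold.

**Signal strength.** Positive IC025 values are categorized with
thresholds 3 and 5 (weak / moderate / strong). The thresholds can be
re-derived from any set of positive IC025 values with `cluster_ic025`,
a deterministic one-dimensional 3-means: Lloyd iteration initialized at
(min, median, max) — in one dimension clusters are contiguous in sorted
order, and the initialization removes seed sensitivity — with the
reported boundaries the midpoints between adjacent cluster extremes.

**Reporting odds ratio (ROR).** ROR = AD/BC with the Woolf interval
exp(ln ROR ± 1.96 √(1/A+1/B+1/C+1/D)). A zero cell makes the ROR
non-estimable (flag, not exception); no continuity correction is
applied, because significance is additionally gated by the minimum-count
rule A ≥ 3 together with CI lower bound > 1. The two statistics agree in
sign of association (ROR > 1 ⇔ AD > BC ⇔ A > N_e ⇔ IC > 0), which is
asserted as a property test.

**Division of labour.** IC flags signals against the whole database
(conservative for rare events); ROR compares two explicit subgroups
head-to-head (`compare_subgroups`: the analysis restricts to reports in
either subgroup, which must be disjoint).

## Exposure classification

Five immune checkpoint inhibitors are built in: ipilimumab (anti-CTLA-4),
nivolumab and pembrolizumab (anti-PD-1), atezolizumab and durvalumab
(anti-PD-L1). A report is `combination` when it carries an anti-CTLA-4
drug plus at least one anti-PD-1/PD-L1 drug; a single ICI gives
`<drug>_mono`; several ICIs without the combination pattern (e.g.
anti-PD-1 plus anti-PD-L1) give `other_multi_ici`, which is excluded from
the headline classes; non-ICI co-medication is ignored for the label.
Attribution of a report carrying both ICI and non-ICI suspected drugs to
the ICI is an assumption of this package (the convention cannot be
recovered from counts alone).

## De-duplication

Duplicates are records sharing a report ID. The kept record is the one
with the fewest missing report-level attributes, first-seen on ties —
deterministic and auditable. The operation is idempotent. Any rule
keyed on record linkage (same patient, different IDs) is out of scope.

## Term catalog

MedDRA is licensed and cannot ship; the built-in catalog is a miniature
open stand-in: ~21 endocrine PTs keyed by exact lower-case strings and
five group queries (ICI-DM = type 1 diabetes mellitus, diabetes
mellitus, fulminant type 1 diabetes mellitus, diabetic ketoacidosis;
thyroid dysfunction; hypophysitis/hypopituitarism; the adrenal
insufficiency family; and the union of all terms). Catalogs are
user-replaceable YAML/JSON ({terms, groups}); there is no SOC/HLT
hierarchy and no fuzzy name matching.

## Time to onset

Onset is weeks from therapy initiation to event onset. Summaries use
linear-interpolation quantiles (the common default; IQR values depend on
this choice, so it is fixed and stated). Bin proportions cover ≤12,
(12,24], (24,48], >48 weeks; "within 12 weeks" means onset ≤ 12, and an
onset of exactly 0 falls in the first bin so the bins partition.

Between-group tests run on log-weeks. Onsets of exactly 0 are set to
0.5 weeks (half the resolution unit) before the transform, keeping
same-day onsets in the analysis deterministically. For two groups, a
two-sided variance-ratio F test at α = 0.05 selects the pooled t-test
(not rejected) or Welch's t-test (rejected) — a uniform selection policy,
since "equal variances" needs an operational rule. Three or more groups
use one-way ANOVA on log-weeks. The t statistic is invariant to the
logarithm base. Degenerate all-identical inputs return statistic 0,
p = 1 rather than NaN.

## Descriptive tables

`descriptive_summary` produces Table-1-style counts and percentages per
stratum (total plus each exposure class) for year, gender, age group,
region, notifier, indication and final outcome. Denominators follow the
n/N convention: only reports with a known value for the field count.
The male:female ratio is rounded to one decimal; the fatal fraction uses
the regulatory definition (death, life-threatening, hospitalization, or
other medically critical condition) among reports with any final outcome
recorded. Human-readable TSV exports round percentages to one decimal
and IC/ROR to two; JSON exports keep full precision.

## Synthetic database generator

The generator exists so every downstream stage is testable without a
restricted database. Per report: drugs are independent Bernoulli draws
from the menu's marginal prevalences; events are independent Bernoulli
per PT with probability baseline × multiplier when a signal drug is
present (clipped to [0,1]); empty drug or event draws are
rejection-resampled, so the realized marginal of drug i is exactly
p_i / P(at least one drug) — the law the calibration tests check against.
A configurable probability forces the ipilimumab + anti-PD-1/PD-L1
combination. Onset weeks are log-normal with parameters looked up by
`"<class>:<group>"`, then `"<class>"`, then `"default"` (specific groups
only; the catch-all union group does not participate). Missingness is
independent per field; duplicate injection re-emits a fraction of
reports under the same ID with one extra field masked. All draws flow
from one master seed through named `SeedSequence` substreams, so
databases are bit-reproducible and adding a stage never perturbs
another's stream.

**Default conditions** (`default_config`): 50,000 reports; the five ICIs
at prevalences 0.5–3.5% among five common co-medications (8–25%); nine
endocrine PTs at baselines 1×10⁻⁴–2×10⁻³ per report next to four common
background reactions (12–18%); thirteen planted ICI-endocrine signals
with multipliers 12–90, giving IC values in the 2–7 bit range typical of
real endocrine ICI signals; onset medians near 9 weeks for anti-CTLA-4,
later and more dispersed for anti-PD-1 except early thyroid events, and
earlier again under combination; missingness roughly matching real
report completeness (e.g. 55% missing onset, 41% missing outcome); 3%
duplicates. These are fixed study conditions, not tuning knobs.

**What the generator does not emulate:** correlated drug co-prescription,
reporting trends over calendar time, region- or notifier-dependent
reporting quality, term misspellings, and duplicates with *different*
IDs. Passing tests therefore demonstrate correctness of the statistics
and the pipeline under the stated sampling model, not robustness to
real-world coding noise or confounding (indication bias in particular is
absent by construction).

## Reference marginal series

`datasets.synthetic_case_series()` is a synthetic 6,089-report set whose
field-wise marginal counts follow a large real-world census of
ICI-associated endocrine ADR reports (exposure-class sizes, year, gender,
age, region, notifier, indication and outcome counts). Fields are
assigned independently in index blocks: every marginal is exact, the
joint distribution is meaningless. It exists to validate descriptive
arithmetic (ratios, n/N percentages) against known totals.

## Pipeline and determinism

`run_pipeline` chains load (or generate) → de-duplicate → classify →
descriptive table → spectrum screen → subgroup comparisons → onset
summaries and tests, writing TSV/JSON exports plus a run log (seed,
package version, per-stage record counts). All iteration orders are
deterministic and floats serialize reproducibly, so identical
configurations give byte-identical exports. A failing stage removes
partial outputs and raises an error naming the stage.

## Problem sizes used in validation

The validation suite runs at sizes chosen to give stable operating
characteristics: Woolf CI coverage over 1,000 null tables with binomial
rows (n = 2,000, p = 0.1); planted-signal recovery over 20 replicates of
100,000 reports (multiplier 10, baseline 10⁻³, exposure prevalence 0.05)
with a 20-replicate null screen at 50,000 reports; onset-test type-I
error over 1,000 replicates (two groups of 200; three groups of 50);
exhaustive-loop cross-checks at up to 500 reports. Marginal-calibration
checks use ±3 standard errors around the generator's exact conditional
law.

## Known limitations

* Exact-string term matching only; real databases need coding QC first.
* No multiple-testing correction is applied by default (the spectrum
  export carries raw counts so users can apply their own); the IC025
  criterion itself provides the conservatism.
* The IC credibility bounds are the asymptotic form; for A ≤ ~5 the
  gamma variant is the better reference.
* `compare_subgroups` adjusts for nothing: it is a crude reporting-odds
  contrast, not a causal estimate.
* CSV round-trips lose duplicate records that share a report ID (one
  Report per ID on load); use JSON-lines for raw, not-yet-deduplicated
  sets.
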