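# pvsignal

Disproportionality analysis for pharmacovigilance: signal detection on
spontaneous adverse-event report databases, built around the endocrine
toxicity of immune checkpoint inhibitors (ICIs).

Spontaneous-report databases collect individual case safety reports
(ICSRs) of suspected adverse drug reactions worldwide. Because there is
no denominator of treated patients, associations are screened by
*disproportionality*: is an event over-represented among the reports for
a drug, compared with the rest of the database? `pvsignal` implements
the two standard statistics on the report-level 2×2 case/non-case table
(A = exposure & event, B = exposure only, C = event only, D = neither;
N_e = (A+B)(A+C)/N):

* **Information component (IC)**, from the BCPNN framework:
  `IC = log2[(A+0.5)/(N_e+0.5)]`, with 95% credibility bounds
  `IC025 = IC − 3.3(A+0.5)^(−1/2) − 2(A+0.5)^(−3/2)` and
  `IC975 = IC + 2.4(A+0.5)^(−1/2) − 0.5(A+0.5)^(−3/2)`.
  `IC025 > 0` flags a signal; thresholds 3 and 5 grade it weak /
  moderate / strong.
* **Reporting odds ratio (ROR)** `= AD/BC` with the Woolf interval
  `exp(ln ROR ± 1.96 √(1/A+1/B+1/C+1/D))`, significant when the CI lower
  bound exceeds 1 and A ≥ 3.

Around the statistics sits a complete, reproducible pipeline: ICSR data
model with CSV/JSON-lines I/O, de-duplication, ICI exposure-class
assignment (monotherapy / anti-CTLA-4 + anti-PD-1/PD-L1 combination), an
open miniature endocrine term catalog with group queries, spectrum
screening, head-to-head subgroup RORs, time-to-onset analysis on the log
scale (gated pooled/Welch t and ANOVA), Table-1-style descriptive
summaries, and a seeded synthetic ICSR generator with planted signals so
everything is testable without access to a restricted database.

Intended users: pharmacovigilance analysts and methods researchers who
want auditable, tested building blocks rather than a black box.

## Worked example

```python
from pvsignal import (ContingencyTable, information_component,
                      ic_credible_bounds, reporting_odds_ratio,
                      classify_signal)

table = ContingencyTable(a=50, b=950, c=150, d=98_850)
ic = information_component(table)
ic025, ic975 = ic_credible_bounds(ic, table.a)
ror, lo, hi, _ = reporting_odds_ratio(table)
print(f"IC  = {ic:.2f} bits, 95% CI ({ic025:.2f}, {ic975:.2f})")
print(f"ROR = {ror:.1f}, 95% CI ({lo:.1f}, {hi:.1f})")
print("category:", classify_signal(ic025))
```

prints

```
IC  = 4.34 bits, 95% CI (3.87, 4.67)
ROR = 34.7, 95% CI (25.0, 48.1)
category: moderate
```

The event was reported 50 times with the drug against 2 expected under
independence — about 4.3 doublings (bits) more often than expected — and
the credibility interval stays well above 0, a moderate-strength signal
(`3 ≤ IC025 < 5`).

The `examples/` directory has one short script per capability:
single-table statistics, spectrum screening on synthetic data, subgroup
comparison, onset-time analysis, and the full pipeline. A thin CLI
mirrors the pipeline:

```bash
pvsignal simulate --seed 1 --n-reports 20000 --out db.csv
pvsignal analyze --input db.csv --outdir results/ --seed 1
```

## Layout

```
src/pvsignal/
  icsr_model.py          report model, I/O, dedup, exposure classes
  term_catalog.py        open endocrine PT catalog and group queries
  synthetic.py           seeded ICSR generator with planted signals
  disproportionality.py  IC, ROR, screening, clustering
  onset_time.py          onset summaries and log-scale tests
  reporting.py           descriptive tables, pipeline orchestration
  datasets.py            synthetic reference marginal series
  cli.py                 thin command-line wrapper
docs/methods.md          models, assumptions, defaults, limitations
```
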