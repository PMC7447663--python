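"""Time-to-onset summaries and log-scale group comparison.

Summarizes onset weeks of thyroid dysfunction per exposure class on a
synthetic database and tests whether onset location differs between
classes (ANOVA on log-weeks).
"""

from pvsignal import (
    builtin_catalog,
    classify_exposure,
    compare_onset_many,
    deduplicate,
    default_config,
    generate_database,
    summarize_onset,
)

db = deduplicate(generate_database(default_config(n_reports=40_000, seed=3)))
members = builtin_catalog().groups["thyroid_dysfunction"]

per_class: dict[str, list[float]] = {}
for r in db:
    if r.onset_weeks is not None and r.events & members:
        per_class.setdefault(classify_exposure(r), []).append(r.onset_weeks)

print(f"{'exposure':<22}{'n':>5}{'median':>9}{'IQR':>14}{'<=12w':>8}")
for label in sorted(per_class):
    s = summarize_onset(per_class[label])
    print(
        f"{label:<22}{s.n:>5}{s.median_weeks:>8.1f}w"
        f"  ({s.q1_weeks:.1f}-{s.q3_weeks:.1f})w"
        f"{s.bin_proportions[0]:>8.0%}"
    )

groups = [v for v in per_class.values() if len(v) >= 2]
res = compare_onset_many(groups)
print()
print(f"ANOVA on log-weeks: F = {res.statistic:.2f}, df = {res.df}, "
      f"p = {res.p_value:.3g}")
print("A small p indicates onset timing differs between exposure classes")
print("(the generator gives anti-PD-1 thyroid events an earlier onset).")
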