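"""Head-to-head reporting odds ratio between therapy subgroups.

Compares combination therapy (anti-CTLA-4 plus anti-PD-1/PD-L1) against
any ICI monotherapy for the whole endocrine spectrum, restricted to
reports in either subgroup.
"""

from pvsignal import (
    builtin_catalog,
    classify_exposure,
    compare_subgroups,
    deduplicate,
    default_config,
    generate_database,
)

db = deduplicate(generate_database(default_config(n_reports=50_000, seed=2)))
labels = {r.report_id: classify_exposure(r) for r in db}
mono = {l for l in set(labels.values()) if l.endswith("_mono")}

res = compare_subgroups(
    db,
    lambda r: labels[r.report_id] == "combination",
    lambda r: labels[r.report_id] in mono,
    builtin_catalog().group("endocrine_all"),
    label_a="combination",
    label_b="monotherapy",
)

t = res.table
print(f"2x2 table (combination vs monotherapy): a={t.a} b={t.b} c={t.c} d={t.d}")
if res.ror_estimable:
    print(f"ROR = {res.ror:.2f}, 95% CI ({res.ror_low:.2f}, {res.ror_high:.2f})")
    print(f"significant (CI low > 1 and a >= 3): {res.ror_significant}")
print()
print("ROR > 1 means endocrine events make up a larger share of combination-")
print("therapy reports than of monotherapy reports in this database.")
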