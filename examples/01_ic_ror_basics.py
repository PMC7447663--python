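"""Information component and reporting odds ratio on a single 2x2 table.

Builds the case/non-case table for a hypothetical drug-event pair and
prints both disproportionality statistics with their interval estimates.
"""

from pvsignal import (
    ContingencyTable,
    classify_signal,
    ic_credible_bounds,
    information_component,
    reporting_odds_ratio,
)

# 50 reports with the drug AND the event, 950 with the drug only,
# 150 with the event under other drugs, 98,850 with neither.
table = ContingencyTable(a=50, b=950, c=150, d=98_850)

ic = information_component(table)
ic025, ic975 = ic_credible_bounds(ic, table.a)
ror, lo, hi, estimable = reporting_odds_ratio(table)

print(f"observed count a      : {table.a}")
print(f"expected under indep. : {table.n_expected:.2f}")
print(f"IC  = {ic:.2f} bits, 95% CI ({ic025:.2f}, {ic975:.2f})")
print(f"ROR = {ror:.1f}, 95% CI ({lo:.1f}, {hi:.1f})")
print(f"signal category       : {classify_signal(ic025)}")
print()
print("The event is reported ~20x more often with this drug than expected")
print("under independence; IC025 > 3 makes this a moderate-to-strong signal.")
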