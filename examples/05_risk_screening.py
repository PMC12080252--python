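"""PNEC and risk-quotient screening from a chronic EC10.

A chemical with chronic EC10 = 15 µg/L is screened with the default
assessment factor of 100 against an environmental concentration of
0.8 µg/L (the low end of concentrations reported for contaminated sites).
"""

from daphtk.risk import assess

assessment = assess("BCRB-like", ec10_ug_per_l=15.0, af=100.0,
                    mec_ug_per_l=0.8, mw=217.27)

print(f"EC10  = {assessment.ec10_ug_per_l} µg/L, AF = {assessment.af:.0f}")
print(f"PNEC  = {assessment.pnec_ug_per_l * 1000:.0f} ng/L "
      f"({assessment.pnec_pmol_per_l:.0f} pmol/L)")
print(f"RQ    = {assessment.rq:.1f} ({'exceeds' if assessment.rq_exceeds else 'below'} 1)")
print(f"REACH 'toxic to aquatic life' (EC10 < 10 µg/L): {assessment.reach_toxic}")

print(
    "\nPNEC = EC10/AF is the concentration below which no adverse effect is\n"
    "expected; RQ = MEC/PNEC > 1 flags potential risk at measured\n"
    "environmental concentrations."
)
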