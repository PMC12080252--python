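"""Depuration kinetics and kinetic BAF from a body-burden time series.

Uses the bundled synthetic series of a fast eliminator (true k2 = 0.10/h):
fits k2 from ln(body burden) vs time, corrects for growth dilution,
derives times to steady state and the lipid-normalized bioaccumulation
factor, and checks for an elimination plateau.
"""

from daphtk.data import data_path
from daphtk.toxicokinetics import baf, complete_tk_fit, detect_plateau, read_body_burden_csv

df = read_body_burden_csv(data_path("body_burden_synthetic.csv"))
series = df[df["chemical_id"] == "FAST"]

fit = complete_tk_fit(series)
print(f"k2   = {fit.k2:.4f} /h (SE {fit.k2_se:.4f}, R² {fit.r2:.3f})")
print(f"kg   = {fit.kg:.4f} /h (growth dilution)")
print(f"k2g  = {fit.k2g:.4f} /h (growth-corrected depuration)")
print(f"t50  = {fit.t50:.1f} h, t95 = {fit.t95:.1f} h (from {fit.k_for_ss})")

suggestions = detect_plateau(series)
print(f"plateau suggestions: {suggestions or 'none (clean first-order decay)'}")

uptake = series[series["phase"] == "uptake"]
cd_end = uptake.loc[uptake["time_h"] == uptake["time_h"].max(), "cd_ug_per_kg"].mean()
result = baf(cd_end, cw=5.0, f_lipid=0.015)
print(
    f"BAF* = {result.baf:,.0f} L/kg, log BAF*_L5% = {result.log_baf_l5:.2f} "
    f"(lipid-normalized 1.5% → 5%)"
)

print(
    "\nk2 is the slope of ln(C_D) over depuration time; subtracting the growth\n"
    "rate kg removes apparent loss caused by the animal growing. t95 says how\n"
    "long an uptake phase must be to approach steady state."
)
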