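"""Simulate the bimodal dung excretion curve and integrate it.

Builds the default two-pulse excretion model (peaks near days 14 and 84),
draws triplicate measurements on the study's 8 sampling days, and computes
the area under the curve on a weekly time axis by natural-cubic-spline
integration, with the trapezoid value as a cross-check.
"""

import numpy as np

import dungfauna as df

design = df.DEFAULT_DESIGN
params = df.ExcretionModelParams()
profile = df.simulate_excretion_profile(
    params, np.asarray(design.sampling_days, dtype=float), replicates=3, seed=42
)

print("day   mean (ng/g fw)   min     max")
for t, m, lo, hi in zip(
    profile.times_d, profile.mean_ng_g, profile.min_ng_g, profile.max_ng_g
):
    print(f"{int(t):>3d}   {m:10.1f}   {lo:7.1f} {hi:7.1f}")

auc = df.spline_auc(profile)
print(f"\nspline AUC    : {auc.auc_ng_wk_per_g_fw:8.1f} ng·wk/g fw")
print(f"trapezoid AUC : {auc.trapezoid_ng_wk_per_g_fw:8.1f} ng·wk/g fw")
print(f"              = {df.sig3(auc.auc_mg_wk_per_kg_fw)} mg·wk/kg fw")
print(
    "\nThe two pulses reflect the sustained-release formulation: an early"
    "\nrelease peak (~day 14) and a depot peak (~day 84); the AUC is the"
    "\ntotal residue exposure per gram of fresh dung over the 20-week trial."
)
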