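"""Simulate a full trial, screen it, and build the per-taxon results table.

Shows the three screening rules (disrupted pats out, colonizing beetles
flagged, rare taxa dropped) and the per-taxon inference: pooled-rank one-way
ANOVA over sampling days, one-sided Dunnett comparisons against the day-0
control when the omnibus test rejects, and the duration-of-effect label.
"""

import numpy as np

import dungfauna as df

design = df.DEFAULT_DESIGN
profile = df.simulate_excretion_profile(
    df.ExcretionModelParams(), np.asarray(design.sampling_days, float),
    replicates=3, seed=7,
)
records = df.simulate_emergence(design, profile, df.default_taxa(), seed=7)
config = df.AnalysisConfig(mc_draws=50_000, seed=7)

flagged, retained, report = df.screen(records, design, config)
print(f"pats in trial            : {report.pats_in}")
print(f"pats removed (disrupted) : {report.pats_removed_disrupted}")
print(f"colonizer records flagged: {report.records_flagged_colonizer}")
print(f"taxa retained            : {report.taxa_retained}/{report.taxa_in}")
print(f"retained pats per day    : {report.retained_pats_per_day}")

balance = df.colonizer_balance_check(flagged)
print(f"\ncolonizer balance across days: P = {balance.p_value:.2f} "
      "(non-significant = colonization unbiased by residues)")

table = df.taxon_analysis(flagged, retained, config, design)
print("\ntaxon table (mean day-0 vs day-140, ranked ANOVA p, duration):")
for _, row in table.iterrows():
    print(
        f"  {row['taxon']:<15s} d0 {row['mean_d0']:5.1f} -> d140 "
        f"{row['mean_d140']:5.1f}   p={row['p_ranked']:.2e}  "
        f"{row['duration_of_effect']}"
    )
print(
    "\n'≥ 140 d' = emergence still significantly below the pre-treatment"
    "\ncontrol at the final sampling day; 'no effect' = the omnibus rank"
    "\nANOVA (or every one-sided comparison) was non-significant."
)
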