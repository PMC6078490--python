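"""Community-level analysis: abundance, richness and Hill's ¹D per pat.

Computes per-pat community metrics from a screened synthetic trial and runs
the rank ANOVA + one-sided Dunnett chain for each metric, reporting how long
each community property stays suppressed relative to the day-0 control.
"""

import numpy as np

import dungfauna as df

design = df.DEFAULT_DESIGN
profile = df.simulate_excretion_profile(
    df.ExcretionModelParams(), np.asarray(design.sampling_days, float),
    replicates=3, seed=11,
)
records = df.simulate_emergence(design, profile, df.default_taxa(), seed=11)
config = df.AnalysisConfig(mc_draws=50_000, seed=11)
flagged, retained, _ = df.screen(records, design, config)

metrics = df.community_metrics_table(flagged)
print("per-day community means (developed insects only):")
print(
    metrics.groupby("sampling_day")[["abundance", "richness", "hill_1d"]]
    .mean()
    .round(2)
)

tests = df.community_tests(metrics, config, design)
print("\nmetric     ANOVA p (ranks)   duration of suppression")
for metric, res in tests.items():
    print(
        f"{metric:<10s} {res['anova'].p_value:>12.2e}   {res['duration'].label}"
    )
print(
    "\nHill's ¹D = exp(Shannon H') is the effective number of equally common"
    "\ntaxa in a pat: it equals richness for a perfectly even community and"
    "\nfalls toward 1 as one taxon dominates."
)
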