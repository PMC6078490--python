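# Methods

## Study design the package assumes

One herd is dosed once; dung is sampled pre-treatment (day 0) and on a
strictly increasing set of post-treatment days (default
{7, 14, 28, 56, 84, 112, 140}).  Each sampling day contributes
`pats_per_day` (default 12) standardized pats that are field-exposed and
then held in emergence cages with weekly collections for `emergence_weeks`
(default 10) weeks.  Day 0 is the shared control for every comparison.
The design object validates these invariants and is the single source of
the constants used by every stage.

## Screening rules

* **Disruption** is a pat-level property: all records of a disrupted pat
  are removed, and the per-day surviving pat counts are logged so the
  group sizes entering inference are auditable.
* **Colonizers**: beetle (Coleoptera) records with emergence week ≤ 4 are
  flagged, not deleted — the colonizer-balance check needs them.  The
  window compares against the 1-based collection week.  Other orders are
  never flagged: flies abandon disturbed pats, so trapped flies developed
  in place.  A beetle taxon that genuinely completed development within 4
  weeks would be misflagged; the rule is applied exactly as stated, and the
  default simulator places developed beetle emergence in weeks 5–10 so the
  premise holds in synthetic data.
* **Taxon inclusion**: a taxon is analysed iff its non-colonizer total is
  ≥ `inclusion_min_total` (default 10) **or** its mean count per day-0 pat
  is ≥ `inclusion_min_per_control_pat` (default 1).  "Per control pat" is
  read as the mean over day-0 pats; both thresholds are configurable.  The
  rule is monotone: adding individuals never removes a retained taxon.

## Community metrics

Per pat: abundance (sum of non-colonizer counts), richness (number of taxa
with positive counts; families plus Collembola at order level), and Hill's
¹D = exp(H′) with H′ the Shannon index on natural logarithms.  ¹D is 1 for
a single-taxon pat, equals richness exactly for even communities, and is
scale-invariant in the counts.  An empty pat has abundance and richness 0
and ¹D recorded as missing; empty pats stay on the roster for abundance
and richness tests and are dropped only from the diversity test.

## Rank-transform inference

All group comparisons pool the observations across sampling days, replace
them by mid-ranks (ties share the average rank), and run a classic one-way
F test on the ranks.  This rank-transform ANOVA is robust to the extreme
heteroscedasticity and non-normality of emergence counts while keeping the
familiar F machinery.  Degenerate input (all observations identical) is
defined as F = 0, p = 1; zero within-group variance with distinct means
gives F = ∞, p = 0.  Reported means and standard errors are always
computed from the un-ranked data.

### Many-to-one (Dunnett) comparisons

When the omnibus test rejects at `alpha`, each post-treatment day is
compared to the day-0 control on the ranked scale with

t_i = (x̄_i − x̄_0) / √(s² (1/n_i + 1/n_0)),

s² the pooled within-group variance on N − k − 1 degrees of freedom.
Under the joint null the t_i are equicorrelated multivariate t
(corr λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀))).  Familywise-adjusted one-sided p-values
are estimated by Monte Carlo: `mc_draws` (default 10⁵) samples of
(Z₀,…,Z_k, χ²_df) reproduce the joint null exactly for arbitrary
unbalanced n's, and pᵢ = P(min_j T_j ≤ t_i) (sidedness "less"; "greater"
and "two" are symmetric).  The Monte-Carlo standard error of an adjusted p
near 0.05 at 10⁵ draws is ≈ 0.0007.  The default sidedness is "less"
because the scientific question is suppression relative to the
pre-treatment control; means above the control are deliberately not
flagged by the default test, and sidedness is configurable for attraction
effects.  Pats lost to screening give unequal n and are handled natively;
nothing is imputed.  A Shapiro–Wilk normality check is available as a
logged diagnostic only — the pipeline always ranks.

### Duration of effect

The ordered one-sided significance flags collapse to a label: no day
significant → "no effect"; final day significant → "≥ D d" with D the last
design day; otherwise "L–U d" with L the **last** significant day and U
the next design day.  Non-contiguous significance therefore resolves to
the final significant day; the flags themselves remain available for
inspection.

### Colonizer balance

Per-pat colonizer totals (over the full pat roster, zeros included) are
compared across sampling days with the same rank-ANOVA engine.  A
non-significant result supports the assumption that residues did not bias
field colonization across days.

## Pharmacokinetics and mass balance

The excretion AUC integrates a natural cubic interpolating spline through
(t/7 weeks, concentration) analytically piecewise over the sampled range,
so its units are ng·wk·g⁻¹ fresh weight; the trapezoid value is reported
alongside as a cross-check (the two agree exactly on affine data and
converge on smooth curves as points are refined).  Negative spline
excursions between knots are integrated as-is with a warning — clamping
would silently change the AUC's meaning.  Unit conversion to mg·wk·kg⁻¹
is ×10⁻³, with 3-significant-figure display rounding kept separate from
full-precision arithmetic.

The mass balance chains: average BW = bw₀ + gain·duration/2; dry-matter
intake = average BW × intake fraction (default 0.022 kg DM per kg BW per
d); indigestible DM × (1/dung DM fraction, default 0.205) = fresh dung
output per day (×7 per week); tallied mg = AUC (mg·wk·kg⁻¹) × weekly
output; recovery % = 100 × tallied / dose.  The **dose** denominator uses
the treatment-day body weight bw₀ (the dose was set that day), while the
dung-output chain uses the trial-average weight — with the defaults
(374 kg, 1 kg/d, 140 d) this yields 444 kg average BW, 14.3 kg/d and
100.1 kg/wk dung output, and 67.9% recovery from an AUC of
2.537 mg·wk·kg⁻¹.

`recovery_range` propagates two uncertainty sources the point estimate
ignores: the replicate min/max concentration envelopes and the spread of
treatment-day body weights (±`bw_sd_kg`).  How the BW spread should enter such a range is underdetermined, so the
package documents one defensible construction: the low bound combines the
min-envelope AUC with dung output at bw₀ − sd and the dose at bw₀ + sd;
the high bound is symmetric.  The bounds always bracket the point estimate
and widen monotonically with the envelope; they are *a* defensible
interval, not a uniquely determined one.

## Synthetic-data generator

* **Excretion curve**: two log-normal-in-time pulses,
  c(t) = baseline + Σₖ Aₖ exp(−(ln t/pₖ)²/2wₖ²), smooth, positive and
  right-skewed.  The defaults (A₁ = 184 at day 14, w₁ = 0.71; A₂ = 180 at
  day 84, w₂ = 0.26; baseline 0) were solved so the mean curve passes
  through the four calibration points 184/82/188/27 ng·g⁻¹ at days
  14/56/84/140.  Replicate noise is multiplicative lognormal with unit
  mean and CV 0.15 (typical analytical replicate scatter); day 0 is
  pre-treatment dung and is forced to exactly zero.
* **Counts**: per pat × taxon, negative binomial (size = `dispersion`,
  default 1.0 — strongly overdispersed, matching the extreme
  heteroscedasticity of real emergence counts) around
  baseline_mean × 1/(1 + (c/EC50)^h), then split multinomially over weekly
  collections.  Baseline means are the study community's control-day means
  per pat.  The EC50s are **illustrative**: no per-taxon dose–response was
  ever measured, so they are set to reproduce the qualitative sensitivity
  pattern — highly sensitive taxa at 5 ng·g⁻¹ (strong suppression even at
  the post-treatment trough, so their effect persists through the final
  day), intermediate taxa (Scarabaeidae, Stratiomyidae) at 45 ng·g⁻¹ with
  a steeper slope (suppressed while the curve is high, recovering near the
  trough), and tolerant taxa (Sphaeroceridae, Collembola) at ≥ 5·10⁵.
  These values satisfy the generator's calibration contract — strictly
  sensitive taxa (EC50 ≤ trough, baseline ≥ 5) are recovered as suppressed
  through the final day and effectively insensitive taxa as unaffected in
  ≥ 90% of seeded runs — and should not be read as field EC50s.
* **Colonizers**: Poisson extra counts for beetle taxa, uniform over weeks
  1–4, independent of concentration, so the colonizer-balance check is
  null by construction.
* **Disruption**: each pat independently with probability 10/96, the rate
  observed in the motivating field trial.
* **Randomness**: one user seed, split by `numpy.random.SeedSequence`
  spawning into independent sub-streams (profile, emergence, inference
  Monte Carlo; per-taxon seeds derive from the analysis seed and taxon
  index), so identical seeds give byte-identical tables.

What the generator does *not* emulate: spatial grid/column effects,
between-animal variation in excretion, taxon interactions (predation,
competition within pats), attraction effects (means above control, which
the one-sided test deliberately ignores), weather-driven emergence timing,
and oviposition by colonizers inside cages.  Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
count model, not field realism of any particular EC50.

## Numerical and testing choices

Problem sizes were chosen to keep the full suite and the acceptance script
fast while leaving the Monte-Carlo error well below the tolerances tested:
10⁴ simulated null datasets (familywise-error band 0.04–0.06 is ±18 SE
wide at that size), 10⁵ joint-null draws for adjusted p-values, 50 seeded
trials for end-to-end recovery, and 600–1000 pats for moment checks.
Ranks use scipy's mid-rank convention; the ANOVA is computed from explicit
sums of squares so the degenerate constant-data rule is exact; spline
integration is scipy's `CubicSpline.integrate` with natural boundary
conditions.  Two-point profiles fall back to the chord (the natural spline
through two points).  scipy's own Dunnett implementation is used in the
test suite as an independent oracle against the Monte-Carlo engine, never
as the implementation.

## Known limitations

* The duration label compresses non-contiguous significance patterns.
* The one-sided default cannot detect attraction (increases over control).
* The inclusion threshold, applied before inference, conditions later
  tests on observed abundance; this mirrors standard practice but is not
  corrected for.
* Monte-Carlo adjusted p-values have resolution 1/`mc_draws`; p-values
  below ~10⁻⁵ at the default draws are reported as 0 and should be read as
  "< 10⁻⁵".
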