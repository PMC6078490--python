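"""Community metrics and many-to-one rank-based inference.

The inference engine mirrors a robust workflow for heteroscedastic,
non-normal count data: every response is pooled mid-rank transformed
(Conover–Iman rank transform) before a classic one-way ANOVA on sampling
day, and — when the omnibus test rejects — a one-sided Dunnett many-to-one
comparison asks on which post-treatment days emergence falls below the
pre-treatment (day-0) control.  Reported means and standard errors are
always from the un-ranked data.

Dunnett adjusted p-values are evaluated by seeded Monte Carlo over the joint
null of the k correlated comparison statistics (correlation λᵢλⱼ with
λᵢ = sqrt(nᵢ/(nᵢ+n₀))), which handles unbalanced group sizes exactly rather
than through balanced-table approximations.

The ordered significance flags are then collapsed to a duration-of-effect
label: "no effect", "≥ D d" when suppression persists through the final
sampling day D, or "L–U d" where L is the last significant day and U the
first subsequent non-significant day.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AnalysisConfig,
    EmergenceRecord,
    SamplingDesign,
    ValidationError,
    logger,
)

COMMUNITY_METRICS = ("abundance", "richness", "hill_1d")


@dataclass
class CommunityMetrics:
    """Per-pat abundance, taxon richness and Hill's ¹D = exp(Shannon H′)."""

    pat_id: str
    sampling_day: int
    abundance: int
    richness: int
    hill_1d: float  # NaN for an empty pat


@dataclass
class RankAnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class DunnettResult:
    """One-sided (or two-sided) many-to-one comparison vs the day-0 control.

    ``means``/``ses`` are on the un-ranked scale; ``p_adjusted`` are
    familywise Monte-Carlo adjusted p-values; ``significant`` applies the
    config's alpha.
    """

    days: tuple[int, ...]
    means: tuple[float, ...]
    ses: tuple[float, ...]
    control_mean: float
    control_se: float
    statistics: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    significant: tuple[bool, ...]
    alpha: float
    sidedness: str


@dataclass
class DurationOfEffect:
    label: str
    last_significant_day: int | None = None
    first_nonsignificant_after: int | None = None


def hill_diversity(counts) -> float:
    """Hill's ¹D: exp of the Shannon index (natural log) over positive counts."""
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    if c.size == 0:
        return float("nan")
    p = c / c.sum()
    return float(np.exp(-np.sum(p * np.log(p))))


def community_metrics(
    pat_records: list[EmergenceRecord],
) -> CommunityMetrics:
    """Metrics for one pat's records (disrupted pats / colonizers pre-excluded)."""
    if not pat_records:
        raise ValidationError("community_metrics needs at least one record")
    pat_id = pat_records[0].pat_id
    day = pat_records[0].sampling_day
    per_taxon: dict[str, int] = defaultdict(int)
    for r in pat_records:
        per_taxon[r.taxon] += r.count
    counts = [c for c in per_taxon.values() if c > 0]
    return CommunityMetrics(
        pat_id=pat_id,
        sampling_day=day,
        abundance=int(sum(counts)),
        richness=len(counts),
        hill_1d=hill_diversity(counts),
    )


def community_metrics_table(records: list[EmergenceRecord]) -> pd.DataFrame:
    """Per-pat metrics for all pats, excluding colonizer-flagged counts.

    The pat roster is taken from all records (including colonizer-only and
    zero-count rows), so empty pats stay in the design with abundance 0.
    """
    by_pat: dict[tuple[str, int], list[EmergenceRecord]] = defaultdict(list)
    for r in records:
        by_pat[(r.pat_id, r.sampling_day)]  # touch: keep pat on the roster
        if not r.colonizer:
            by_pat[(r.pat_id, r.sampling_day)].append(r)
    rows = []
    for (pat_id, day), recs in sorted(by_pat.items()):
        if recs:
            m = community_metrics(recs)
        else:
            m = CommunityMetrics(pat_id, day, 0, 0, float("nan"))
        rows.append((m.pat_id, m.sampling_day, m.abundance, m.richness, m.hill_1d))
    return pd.DataFrame(
        rows, columns=["pat_id", "sampling_day", "abundance", "richness", "hill_1d"]
    )


def rank_transform(values) -> np.ndarray:
    """Pooled mid-ranks (ties share the average rank)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("rank_transform needs at least one value")
    return stats.rankdata(v)


def anova_on_ranks(groups: list[np.ndarray]) -> RankAnovaResult:
    """One-way F test on the pooled mid-ranks of the supplied groups.

    Constant data (zero total variance) is defined as F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValidationError("anova_on_ranks needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    ranks = rank_transform(pooled)
    sizes = [g.size for g in groups]
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    n_total = pooled.size
    k = len(groups)
    grand = ranks.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in split)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in split)
    df_between, df_within = k - 1, n_total - k
    if ss_within <= 1e-12 * max(1.0, ss_between + ss_within):
        if ss_between <= 1e-12:
            return RankAnovaResult(0.0, df_between, df_within, 1.0)
        return RankAnovaResult(float("inf"), df_between, df_within, 0.0)
    if df_within < 1:
        raise ValidationError("not enough observations for within-group variance")
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return RankAnovaResult(float(f), df_between, df_within, p)


def normality_diagnostic(groups: dict[int, np.ndarray]) -> dict[int, float]:
    """Shapiro–Wilk p-value per group, logged only.

    Purely diagnostic: the pipeline always rank-transforms regardless of the
    outcome, so this gate never changes results.  Groups too small or
    constant are reported as NaN.
    """
    out: dict[int, float] = {}
    for day, values in sorted(groups.items()):
        v = np.asarray(values, dtype=float)
        if v.size < 3 or np.ptp(v) == 0:
            out[day] = float("nan")
            continue
        out[day] = float(stats.shapiro(v).pvalue)
    worst = np.nanmin(list(out.values())) if out else float("nan")
    logger.info("normality_diagnostic: smallest Shapiro-Wilk p = %.4g", worst)
    return out


def _simulate_comparison_stats(
    ns: np.ndarray, n_control: int, df: int, draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws × k matrix of the joint-null many-to-one t statistics."""
    z0 = rng.standard_normal(draws)
    z = rng.standard_normal((draws, ns.size))
    s = np.sqrt(rng.chisquare(df, size=draws) / df)
    scale = np.sqrt(1.0 / ns + 1.0 / n_control)
    return (z / np.sqrt(ns) - (z0 / np.sqrt(n_control))[:, None]) / (
        s[:, None] * scale
    )


def dunnett_critical_value(
    ns, n_control: int, alpha: float, sidedness: str, mc_draws: int, seed: int
) -> float:
    """Familywise critical value for the min (or max) comparison statistic."""
    ns = np.asarray(ns, dtype=float)
    df = int(ns.sum() + n_control - ns.size - 1)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = _simulate_comparison_stats(ns, n_control, df, mc_draws, rng)
    if sidedness == "less":
        return float(np.quantile(t.min(axis=1), alpha))
    if sidedness == "greater":
        return float(np.quantile(t.max(axis=1), 1 - alpha))
    return float(np.quantile(np.abs(t).max(axis=1), 1 - alpha))


def dunnett_many_to_one(
    control,
    treatments: dict[int, np.ndarray],
    config: AnalysisConfig,
    unranked_control=None,
    unranked_treatments: dict[int, np.ndarray] | None = None,
) -> DunnettResult:
    """Many-to-one comparison of each treatment day against the shared control.

    ``control``/``treatments`` carry the (rank-transformed) response used for
    the statistics; ``unranked_*`` optionally supply the raw scale used only
    for the reported means and SEs (defaulting to the supplied data).
    Adjusted p-values come from ``config.mc_draws`` Monte-Carlo samples of the
    correlated joint null, seeded by ``config.seed``.
    """
    control = np.asarray(control, dtype=float)
    if not treatments:
        raise ValidationError("dunnett_many_to_one needs >= 1 treatment group")
    days = tuple(sorted(treatments))
    groups = [np.asarray(treatments[d], dtype=float) for d in days]
    ns = np.array([g.size for g in groups], dtype=float)
    n0 = control.size
    n_total = int(ns.sum() + n0)
    k = len(groups)
    df = n_total - k - 1
    if df < 1:
        raise ValidationError("pooled within-group variance undefined (df < 1)")
    ss_within = ((control - control.mean()) ** 2).sum() + sum(
        ((g - g.mean()) ** 2).sum() for g in groups
    )
    s2 = ss_within / df
    diffs = np.array([g.mean() - control.mean() for g in groups])
    scale = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(scale > 0, diffs / np.where(scale > 0, scale, 1.0),
                         np.where(diffs == 0, 0.0, np.sign(diffs) * np.inf))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    t_null = _simulate_comparison_stats(ns, n0, df, config.mc_draws, rng)
    if config.sidedness == "less":
        ref = t_null.min(axis=1)
        p_adj = np.array([np.mean(ref <= t) for t in t_obs])
    elif config.sidedness == "greater":
        ref = t_null.max(axis=1)
        p_adj = np.array([np.mean(ref >= t) for t in t_obs])
    else:
        ref = np.abs(t_null).max(axis=1)
        p_adj = np.array([np.mean(ref >= abs(t)) for t in t_obs])
    raw_control = control if unranked_control is None else np.asarray(
        unranked_control, dtype=float
    )
    raw_groups = (
        groups
        if unranked_treatments is None
        else [np.asarray(unranked_treatments[d], dtype=float) for d in days]
    )
    means = tuple(float(g.mean()) for g in raw_groups)
    ses = tuple(
        float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else float("nan")
        for g in raw_groups
    )
    return DunnettResult(
        days=days,
        means=means,
        ses=ses,
        control_mean=float(raw_control.mean()),
        control_se=float(raw_control.std(ddof=1) / np.sqrt(raw_control.size))
        if raw_control.size > 1
        else float("nan"),
        statistics=tuple(float(t) for t in t_obs),
        p_adjusted=tuple(float(p) for p in p_adj),
        significant=tuple(bool(p < config.alpha) for p in p_adj),
        alpha=config.alpha,
        sidedness=config.sidedness,
    )


def duration_of_effect(
    result: DunnettResult, design: SamplingDesign
) -> DurationOfEffect:
    """Collapse ordered significance flags to a duration label.

    Non-contiguous significance is resolved by taking the final significant
    day as the lower bound L.
    """
    days = result.days
    sig = dict(zip(days, result.significant))
    sig_days = [d for d in days if sig[d]]
    if not sig_days:
        return DurationOfEffect("no effect")
    last = sig_days[-1]
    if last == days[-1]:
        return DurationOfEffect(f"≥ {last} d", last_significant_day=last)
    upper = next(d for d in days if d > last)
    return DurationOfEffect(
        f"{last}–{upper} d",
        last_significant_day=last,
        first_nonsignificant_after=upper,
    )


def _per_pat_totals(
    records: list[EmergenceRecord],
    colonizers_only: bool = False,
) -> dict[tuple[str, int], int]:
    """Per-pat totals over the full pat roster (absent taxa count as zero)."""
    totals: dict[tuple[str, int], int] = {}
    for r in records:
        key = (r.pat_id, r.sampling_day)
        totals.setdefault(key, 0)
        if r.colonizer == colonizers_only:
            totals[key] += r.count
    return totals


def _group_by_day(totals: dict[tuple[str, int], int]) -> dict[int, np.ndarray]:
    by_day: dict[int, list[int]] = defaultdict(list)
    for (_, day), v in sorted(totals.items()):
        by_day[day].append(v)
    return {d: np.asarray(v, dtype=float) for d, v in sorted(by_day.items())}


def colonizer_balance_check(records: list[EmergenceRecord]) -> RankAnovaResult:
    """ANOVA (on ranks) of per-pat colonizer totals across sampling days.

    A non-significant result supports the assumption that drug residues did
    not bias field colonization across sampling days.
    """
    if not any(r.colonizer for r in records):
        raise ValidationError("no colonizer-flagged records available")
    totals = _per_pat_totals(records, colonizers_only=True)
    groups = list(_group_by_day(totals).values())
    return anova_on_ranks(groups)


def _ranked_day_groups(
    by_day: dict[int, np.ndarray],
) -> dict[int, np.ndarray]:
    days = sorted(by_day)
    pooled = np.concatenate([by_day[d] for d in days])
    ranks = rank_transform(pooled)
    sizes = np.cumsum([by_day[d].size for d in days])[:-1]
    return dict(zip(days, np.split(ranks, sizes)))


def many_to_one_analysis(
    by_day: dict[int, np.ndarray], config: AnalysisConfig, design: SamplingDesign
) -> dict:
    """Rank ANOVA, then (if significant) ranked Dunnett and a duration label.

    When the omnibus test does not reject, no post hoc comparison is run and
    the duration is "no effect".
    """
    if 0 not in by_day:
        raise ValidationError("day-0 control group required")
    anova = anova_on_ranks([by_day[d] for d in sorted(by_day)])
    out = {"anova": anova, "dunnett": None}
    if anova.p_value < config.alpha:
        ranked = _ranked_day_groups(by_day)
        dunnett = dunnett_many_to_one(
            ranked[0],
            {d: ranked[d] for d in ranked if d != 0},
            config,
            unranked_control=by_day[0],
            unranked_treatments={d: by_day[d] for d in by_day if d != 0},
        )
        out["dunnett"] = dunnett
        out["duration"] = duration_of_effect(dunnett, design)
    else:
        out["duration"] = DurationOfEffect("no effect")
    return out


def community_tests(
    metrics: pd.DataFrame, config: AnalysisConfig, design: SamplingDesign
) -> dict[str, dict]:
    """Run the rank ANOVA + Dunnett chain for abundance, richness and ¹D.

    Pats with undefined diversity (empty pats) are dropped from the ¹D test
    only.
    """
    results = {}
    for metric in COMMUNITY_METRICS:
        sub = metrics.dropna(subset=[metric])
        by_day = {
            int(day): g[metric].to_numpy(dtype=float)
            for day, g in sub.groupby("sampling_day")
        }
        results[metric] = many_to_one_analysis(by_day, config, design)
    return results


def taxon_analysis(
    records: list[EmergenceRecord],
    retained_taxa: list[str],
    config: AnalysisConfig,
    design: SamplingDesign,
) -> pd.DataFrame:
    """Per-taxon abundance tests: mean ± SE per day, ranked p, duration label.

    Input records must already be screened (disrupted pats removed,
    colonizers flagged); colonizer-flagged counts are excluded from the
    per-pat totals.  Per-taxon Monte-Carlo seeds are derived from
    ``config.seed`` so results are reproducible and taxa independent.
    """
    roster = sorted({(r.pat_id, r.sampling_day) for r in records})
    by_taxon: dict[str, dict[tuple[str, int], int]] = {
        t: {key: 0 for key in roster} for t in retained_taxa
    }
    order_of: dict[str, str] = {}
    for r in records:
        order_of.setdefault(r.taxon, r.order)
        if r.colonizer or r.taxon not in by_taxon:
            continue
        by_taxon[r.taxon][(r.pat_id, r.sampling_day)] += r.count
    rows = []
    for i, taxon in enumerate(retained_taxa):
        by_day = _group_by_day(by_taxon[taxon])
        sub_config = AnalysisConfig(
            alpha=config.alpha,
            inclusion_min_total=config.inclusion_min_total,
            inclusion_min_per_control_pat=config.inclusion_min_per_control_pat,
            mc_draws=config.mc_draws,
            seed=int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0]
                     % (2**31)),
            sidedness=config.sidedness,
        )
        res = many_to_one_analysis(by_day, sub_config, design)
        row = {
            "taxon": taxon,
            "order": order_of.get(taxon, ""),
            "p_ranked": res["anova"].p_value,
            "duration_of_effect": res["duration"].label,
        }
        for d in sorted(by_day):
            g = by_day[d]
            row[f"mean_d{d}"] = float(g.mean())
            row[f"se_d{d}"] = (
                float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else float("nan")
            )
        rows.append(row)
        logger.info(
            "taxon_analysis: %s p=%.4g duration=%s",
            taxon,
            res["anova"].p_value,
            res["duration"].label,
        )
    return pd.DataFrame(rows)


def simulate_familywise_error(
    ns,
    n_control: int,
    alpha: float = 0.05,
    n_sims: int = 10_000,
    mc_draws: int = 100_000,
    seed: int = 0,
    rank: bool = True,
) -> float:
    """Empirical familywise type-I error of the one-sided procedure.

    Simulates ``n_sims`` global-null datasets (iid normal groups with the
    given unbalanced sizes), optionally pooled-rank transforms each, computes
    the many-to-one statistics against the shared critical value, and returns
    the fraction of datasets with any rejection.
    """
    ns = np.asarray(ns, dtype=float)
    seeds = np.random.SeedSequence(seed).spawn(2)
    crit = dunnett_critical_value(
        ns, n_control, alpha, "less", mc_draws,
        int(seeds[0].generate_state(1)[0] % (2**31)),
    )
    rng = np.random.default_rng(seeds[1])
    n_total = int(ns.sum()) + n_control
    k = ns.size
    df = n_total - k - 1
    data = rng.standard_normal((n_sims, n_total))
    if rank:
        data = stats.rankdata(data, axis=1)
    bounds = np.concatenate([[0], np.cumsum(np.concatenate([[n_control], ns]))]).astype(int)
    means = np.stack(
        [data[:, bounds[j]: bounds[j + 1]].mean(axis=1) for j in range(k + 1)], axis=1
    )
    ss_within = sum(
        ((data[:, bounds[j]: bounds[j + 1]] - means[:, [j]]) ** 2).sum(axis=1)
        for j in range(k + 1)
    )
    s2 = ss_within / df
    scale = np.sqrt(s2[:, None] * (1.0 / ns + 1.0 / n_control)[None, :])
    t = (means[:, 1:] - means[:, [0]]) / scale
    return float(np.mean(t.min(axis=1) <= crit))
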