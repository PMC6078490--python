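"""The three data-screening rules applied before any inference.

1. Pats disrupted in the field (wildlife damage) are removed outright —
   disruption confounds emergence.
2. Beetles collected within the first ``colonizer_window_weeks`` weekly
   collections cannot have completed egg-to-adult development in the pat and
   are flagged as field colonizers.  Adult flies vacate a disturbed pat, so
   every fly collected is assumed to have developed in the pat and is never
   flagged.
3. Taxa are analysed only when they are common enough for a test to have
   power: at least ``inclusion_min_total`` individuals overall, or a mean of
   at least ``inclusion_min_per_control_pat`` individuals per control
   (day-0) pat.  Colonizer-flagged counts do not contribute to these totals.

Colonizer records are flagged rather than deleted so that the
colonizer-balance check can still use them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

from .core import (
    COLEOPTERA,
    AnalysisConfig,
    EmergenceRecord,
    SamplingDesign,
    ValidationError,
    logger,
)


@dataclass
class ScreeningReport:
    pats_in: int = 0
    pats_removed_disrupted: int = 0
    records_flagged_colonizer: int = 0
    taxa_in: int = 0
    taxa_retained: int = 0
    retained_pats_per_day: dict[int, int] | None = None
    taxon_totals: dict[str, int] | None = None

    def to_dict(self) -> dict:
        return {
            "pats_in": self.pats_in,
            "pats_removed_disrupted": self.pats_removed_disrupted,
            "records_flagged_colonizer": self.records_flagged_colonizer,
            "taxa_in": self.taxa_in,
            "taxa_retained": self.taxa_retained,
            "retained_pats_per_day": self.retained_pats_per_day,
            "taxon_totals": self.taxon_totals,
        }


def exclude_disrupted(
    records: list[EmergenceRecord],
) -> tuple[list[EmergenceRecord], ScreeningReport]:
    """Drop every record of a disrupted pat; report surviving pats per day."""
    pats = {(r.pat_id, r.sampling_day) for r in records}
    disrupted_pats = {(r.pat_id, r.sampling_day) for r in records if r.disrupted}
    kept = [r for r in records if not r.disrupted]
    per_day: dict[int, int] = defaultdict(int)
    for _, day in pats - disrupted_pats:
        per_day[day] += 1
    report = ScreeningReport(
        pats_in=len(pats),
        pats_removed_disrupted=len(disrupted_pats),
        retained_pats_per_day=dict(sorted(per_day.items())),
    )
    logger.info(
        "exclude_disrupted: %d -> %d pats (%d removed)",
        report.pats_in,
        report.pats_in - report.pats_removed_disrupted,
        report.pats_removed_disrupted,
    )
    return kept, report


def flag_colonizers(
    records: list[EmergenceRecord], design: SamplingDesign
) -> list[EmergenceRecord]:
    """Flag beetle records in the colonizer window; other orders untouched.

    Idempotent and order-preserving; returns new record objects.
    """
    out = []
    for r in records:
        is_colonizer = (
            r.order == COLEOPTERA and r.emergence_week <= design.colonizer_window_weeks
        )
        out.append(replace(r, colonizer=is_colonizer))
    n = sum(r.colonizer for r in out)
    logger.info("flag_colonizers: %d of %d records flagged", n, len(out))
    return out


def select_taxa(
    records: list[EmergenceRecord], config: AnalysisConfig
) -> tuple[list[str], dict[str, int]]:
    """Retain taxa abundant enough to analyse.

    A taxon is retained iff its developed (non-colonizer) total is at least
    ``inclusion_min_total``, or its mean developed count per day-0 pat is at
    least ``inclusion_min_per_control_pat``.  Raises if no day-0 pats exist
    (the per-control-pat clause would be undefined).
    """
    control_pats = {r.pat_id for r in records if r.sampling_day == 0}
    if not control_pats:
        raise ValidationError("no day-0 pats present; inclusion threshold undefined")
    totals: dict[str, int] = defaultdict(int)
    control_totals: dict[str, int] = defaultdict(int)
    taxa_seen: list[str] = []
    for r in records:
        if r.taxon not in totals:
            taxa_seen.append(r.taxon)
            totals[r.taxon] = 0
        if r.colonizer:
            continue
        totals[r.taxon] += r.count
        if r.sampling_day == 0:
            control_totals[r.taxon] += r.count
    retained = [
        t
        for t in taxa_seen
        if totals[t] >= config.inclusion_min_total
        or control_totals[t] / len(control_pats) >= config.inclusion_min_per_control_pat
    ]
    logger.info("select_taxa: %d of %d taxa retained", len(retained), len(taxa_seen))
    return retained, dict(totals)


def screen(
    records: list[EmergenceRecord],
    design: SamplingDesign,
    config: AnalysisConfig,
) -> tuple[list[EmergenceRecord], list[str], ScreeningReport]:
    """Full screening pipeline: drop disrupted pats, flag colonizers, pick taxa."""
    kept, report = exclude_disrupted(records)
    flagged = flag_colonizers(kept, design)
    report.records_flagged_colonizer = sum(r.colonizer for r in flagged)
    retained, totals = select_taxa(flagged, config)
    report.taxa_in = len(totals)
    report.taxa_retained = len(retained)
    report.taxon_totals = totals
    return flagged, retained, report
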