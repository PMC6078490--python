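"""CSV and flat-config readers/writers for the pipeline's tidy tables.

All tables are comma-separated UTF-8 with a header row.  The emergence table
is one row per (pat, taxon, week) observation; the concentration table is one
row per (sampling day, replicate).  Config files are flat YAML key/value
mappings whose keys match the dataclass field names; a missing file or key
falls back to the study defaults.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DEFAULT_DESIGN,
    ConcentrationProfile,
    EmergenceRecord,
    SamplingDesign,
    SchemaError,
    ValidationError,
    logger,
)

_EMERGENCE_COLUMNS = (
    "pat_id",
    "sampling_day",
    "order",
    "taxon",
    "emergence_week",
    "count",
    "disrupted",
)


def read_emergence_table(
    path: str | Path, design: SamplingDesign = DEFAULT_DESIGN
) -> list[EmergenceRecord]:
    """Read and validate a pat-level emergence table.

    Rows are validated against the sampling design: unknown sampling days,
    blank or negative counts, and out-of-range emergence weeks are rejected
    with the offending row number (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    for col in _EMERGENCE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"emergence table is missing column '{col}'")
    colonizer_col = (
        df["colonizer"].tolist() if "colonizer" in df.columns else [False] * len(df)
    )
    valid_days = set(design.sampling_days)
    records: list[EmergenceRecord] = []
    rows = zip(
        df["pat_id"],
        df["sampling_day"],
        df["order"],
        df["taxon"],
        df["emergence_week"],
        df["count"],
        df["disrupted"],
        colonizer_col,
    )
    for i, (pat, day, order, taxon, week, count, disrupted, colonizer) in enumerate(
        rows, start=1
    ):
        if pd.isna(count) or str(count).strip() == "":
            raise ValidationError(f"row {i}: blank count")
        count = int(count)
        if count < 0:
            raise ValidationError(f"row {i}: negative count {count}")
        day = int(day)
        if day not in valid_days:
            raise ValidationError(f"row {i}: sampling_day {day} not in design")
        week = int(week)
        if not 1 <= week <= design.emergence_weeks:
            raise ValidationError(f"row {i}: emergence_week {week} out of range")
        records.append(
            EmergenceRecord(
                pat_id=str(pat),
                sampling_day=day,
                order=str(order),
                taxon=str(taxon),
                emergence_week=week,
                count=count,
                disrupted=bool(disrupted),
                colonizer=bool(colonizer),
            )
        )
    logger.info("read_emergence_table: %d records from %s", len(records), path)
    return records


def write_emergence_table(records: list[EmergenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "pat_id": [r.pat_id for r in records],
            "sampling_day": [r.sampling_day for r in records],
            "order": [r.order for r in records],
            "taxon": [r.taxon for r in records],
            "emergence_week": [r.emergence_week for r in records],
            "count": [r.count for r in records],
            "disrupted": [r.disrupted for r in records],
            "colonizer": [r.colonizer for r in records],
        }
    )
    df.to_csv(path, index=False)
    logger.info("write_emergence_table: %d records to %s", len(records), path)


def read_concentration_table(path: str | Path) -> ConcentrationProfile:
    """Read a replicate-level concentration table and aggregate per day.

    Expects columns sampling_day, replicate, conc_ng_per_g_fw; replicates are
    collapsed to mean/min/max per day and days are sorted ascending.
    """
    df = pd.read_csv(path)
    for col in ("sampling_day", "replicate", "conc_ng_per_g_fw"):
        if col not in df.columns:
            raise SchemaError(f"concentration table is missing column '{col}'")
    if df["conc_ng_per_g_fw"].isna().any():
        bad = int(df.index[df["conc_ng_per_g_fw"].isna()][0]) + 1
        raise ValidationError(f"row {bad}: blank concentration")
    if (df["conc_ng_per_g_fw"] < 0).any():
        bad = int(df.index[df["conc_ng_per_g_fw"] < 0][0]) + 1
        raise ValidationError(f"row {bad}: negative concentration")
    if df.empty:
        raise ValidationError("concentration table has no rows")
    agg = (
        df.groupby("sampling_day")["conc_ng_per_g_fw"]
        .agg(["mean", "min", "max", "size"])
        .sort_index()
    )
    if (agg["size"] == 0).any():
        raise ValidationError("a sampling day has zero replicates")
    profile = ConcentrationProfile(
        times_d=agg.index.to_numpy(dtype=float),
        mean_ng_g=agg["mean"].to_numpy(),
        min_ng_g=agg["min"].to_numpy(),
        max_ng_g=agg["max"].to_numpy(),
    )
    logger.info(
        "read_concentration_table: %d days x %d rows from %s",
        len(agg),
        len(df),
        path,
    )
    return profile


def write_concentration_table(
    profile: ConcentrationProfile, path: str | Path, replicates_per_day: int = 1
) -> None:
    """Write a profile back out as a replicate table (mean repeated)."""
    rows = []
    for t, m in zip(profile.times_d, profile.mean_ng_g):
        for rep in range(1, replicates_per_day + 1):
            rows.append((int(t), rep, m))
    pd.DataFrame(rows, columns=["sampling_day", "replicate", "conc_ng_per_g_fw"]).to_csv(
        path, index=False
    )


def replicate_table_from_draws(
    times_d: np.ndarray, draws: np.ndarray
) -> pd.DataFrame:
    """Tidy replicate table from a (days x replicates) concentration array."""
    rows = []
    for t, reps in zip(times_d, draws):
        for j, c in enumerate(reps, start=1):
            rows.append((int(t), j, float(c)))
    return pd.DataFrame(rows, columns=["sampling_day", "replicate", "conc_ng_per_g_fw"])


def load_config(path: str | Path | None) -> dict:
    """Load a flat key/value config file; absent path means all defaults."""
    if path is None:
        return {}
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise SchemaError("config file must be a flat key: value mapping")
    return data
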