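"""Domain types and experimental-design constants.

The study design these types describe: cattle dosed once with a
sustained-release avermectin, dung collected pre-treatment (day 0, the
control) and on seven post-treatment days; 12 standardized pats formed per
sampling day, field-exposed, then caged so that every adult insect completing
development in a pat is collected weekly for 10 weeks.  Beetles already
present in a pat when it was caged ("colonizers") show up in the first four
weekly collections, before egg-to-adult development is possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np

logger = logging.getLogger("dungfauna")

COLEOPTERA = "COLEOPTERA"
DIPTERA = "DIPTERA"
COLLEMBOLA = "COLLEMBOLA"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row or parameter violates a domain invariant."""


@dataclass(frozen=True)
class SamplingDesign:
    """Sampling layout: which days dung was collected and how pats were caged.

    Defaults are the study design: days {0, 7, 14, 28, 56, 84, 112, 140}
    post-treatment (day 0 = pre-treatment control), 12 pats per day, weekly
    cage collections for 10 weeks, and a 4-week window that identifies
    colonizing beetles.
    """

    sampling_days: tuple[int, ...] = (0, 7, 14, 28, 56, 84, 112, 140)
    pats_per_day: int = 12
    emergence_weeks: int = 10
    colonizer_window_weeks: int = 4

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.sampling_days)
        if len(days) < 2 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("sampling_days must be strictly increasing")
        if 0 not in days:
            raise ValidationError("sampling_days must contain day 0 (control)")
        object.__setattr__(self, "sampling_days", days)
        for name in ("pats_per_day", "emergence_weeks", "colonizer_window_weeks"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")

    @property
    def treatment_days(self) -> tuple[int, ...]:
        return tuple(d for d in self.sampling_days if d != 0)


DEFAULT_DESIGN = SamplingDesign()


@dataclass
class EmergenceRecord:
    """One taxon count from one weekly cage collection of one pat."""

    pat_id: str
    sampling_day: int
    order: str
    taxon: str
    emergence_week: int
    count: int
    disrupted: bool = False
    colonizer: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(f"count must be >= 0, got {self.count}")
        if self.emergence_week < 1:
            raise ValidationError(
                f"emergence_week must be >= 1, got {self.emergence_week}"
            )


@dataclass
class ConcentrationProfile:
    """Dung drug-residue time series, ng per g fresh weight.

    ``mean_ng_g`` is the replicate mean per sampling day; ``min_ng_g`` and
    ``max_ng_g`` are the optional replicate envelopes.
    """

    times_d: np.ndarray
    mean_ng_g: np.ndarray
    min_ng_g: np.ndarray | None = None
    max_ng_g: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_d = np.asarray(self.times_d, dtype=float)
        self.mean_ng_g = np.asarray(self.mean_ng_g, dtype=float)
        if self.times_d.ndim != 1 or self.times_d.size < 1:
            raise ValidationError("times_d must be a non-empty 1-d sequence")
        if np.any(np.diff(self.times_d) <= 0):
            raise ValidationError("times_d must be strictly increasing")
        for name in ("mean_ng_g", "min_ng_g", "max_ng_g"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.times_d.shape:
                raise ValidationError(f"{name} must match times_d in length")
            if np.any(arr < 0):
                raise ValidationError(f"{name} contains negative concentrations")

    def conc_at(self, day: float, which: str = "mean") -> float:
        """Concentration at an exact sampled day (no interpolation)."""
        arr = self._series(which)
        idx = np.nonzero(self.times_d == day)[0]
        if idx.size == 0:
            raise ValidationError(f"day {day} not in profile")
        return float(arr[idx[0]])

    def _series(self, which: str) -> np.ndarray:
        arr = {"mean": self.mean_ng_g, "min": self.min_ng_g, "max": self.max_ng_g}[
            which
        ]
        if arr is None:
            raise ValidationError(f"profile has no '{which}' envelope")
        return arr


def _from_mapping(cls, mapping):
    known = {f.name for f in fields(cls)}
    kwargs = {k: v for k, v in mapping.items() if k in known}
    return cls(**kwargs)


@dataclass(frozen=True)
class MassBalanceParams:
    """Constants of the drug mass-balance chain.

    Defaults are the reference trial's values: 374 kg body weight at treatment,
    1 kg/d gain over a 140-d trial, 1 mg/kg subcutaneous dose, diet dry-matter
    intake 2.2% of BW per day, 30% of diet DM indigestible, and dung
    fresh weight that is 20.5% dry matter.
    """

    bw0_kg: float = 374.0
    gain_kg_per_d: float = 1.0
    trial_duration_d: float = 140.0
    dose_mg_per_kg: float = 1.0
    dm_intake_frac_of_bw: float = 0.022
    indigestible_frac_of_dm: float = 0.30
    dung_dm_frac: float = 0.205

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"{f.name} must be strictly positive")
        for name in ("dm_intake_frac_of_bw", "indigestible_frac_of_dm", "dung_dm_frac"):
            if not 0 < getattr(self, name) < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_mapping(cls, mapping) -> "MassBalanceParams":
        return _from_mapping(cls, mapping)


@dataclass(frozen=True)
class AnalysisConfig:
    """Inference settings shared by the screening and testing stages.

    ``sidedness`` applies to the many-to-one comparisons: "less" asks whether
    treated days fall below the day-0 control (suppression), the study's
    question.  ``mc_draws`` sizes the Monte-Carlo evaluation of the joint
    null used for familywise-adjusted p-values.
    """

    alpha: float = 0.05
    inclusion_min_total: int = 10
    inclusion_min_per_control_pat: float = 1.0
    mc_draws: int = 100_000
    seed: int = 0
    sidedness: str = "less"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.sidedness not in ("less", "greater", "two"):
            raise ValidationError("sidedness must be 'less', 'greater' or 'two'")
        if self.mc_draws < 1:
            raise ValidationError("mc_draws must be positive")

    @classmethod
    def from_mapping(cls, mapping) -> "AnalysisConfig":
        return _from_mapping(cls, mapping)
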