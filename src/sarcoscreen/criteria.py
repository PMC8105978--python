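"""AWGS2019 reference-standard sarcopenia classification.

The Asian Working Group for Sarcopenia 2019 consensus diagnoses sarcopenia as
low appendicular skeletal muscle mass index (ASMI < 7.0 kg/m² in men,
< 5.7 kg/m² in women, by bioimpedance) together with either low muscle
strength (grip < 28 kg men, < 18 kg women) or low physical performance
(usual gait speed < 1.0 m/s). All comparisons are strict "<": a value exactly
at the cut is normal. Severe sarcopenia (all three components low) is exposed
as a derived flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .cohort import ParticipantRecord, Sex

__all__ = ["CriteriaThresholds", "SarcopeniaStatus", "classify_awgs2019", "classify_cohort"]


@dataclass(frozen=True)
class CriteriaThresholds:
    """Diagnostic cut-offs; defaults are the AWGS2019 consensus values."""

    asmi_cut_male: float = 7.0     # kg/m²
    asmi_cut_female: float = 5.7   # kg/m²
    grip_cut_male: float = 28.0    # kg
    grip_cut_female: float = 18.0  # kg
    gait_cut: float = 1.0          # m/s

    def __post_init__(self) -> None:
        for name in ("asmi_cut_male", "asmi_cut_female", "grip_cut_male",
                     "grip_cut_female", "gait_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.asmi_cut_male < self.asmi_cut_female:
            warnings.warn("male ASMI cut-off below female cut-off", stacklevel=2)
        if self.grip_cut_male < self.grip_cut_female:
            warnings.warn("male grip cut-off below female cut-off", stacklevel=2)


@dataclass(frozen=True)
class SarcopeniaStatus:
    """Component flags and the composite diagnosis.

    ``sarcopenic`` is low mass AND (low strength OR low performance);
    ``severe`` additionally requires all three components low.
    """

    low_mass: bool
    low_strength: bool
    low_performance: bool

    @property
    def sarcopenic(self) -> bool:
        return self.low_mass and (self.low_strength or self.low_performance)

    @property
    def severe(self) -> bool:
        return self.low_mass and self.low_strength and self.low_performance


def classify_awgs2019(
    record: ParticipantRecord,
    thresholds: CriteriaThresholds | None = None,
) -> SarcopeniaStatus:
    """Classify one participant against the AWGS2019 reference standard.

    Depends only on sex, ASMI, grip strength and gait speed; every threshold
    comparison is strict less-than.
    """
    t = thresholds if thresholds is not None else CriteriaThresholds()
    if record.sex == Sex.MALE:
        asmi_cut, grip_cut = t.asmi_cut_male, t.grip_cut_male
    elif record.sex == Sex.FEMALE:
        asmi_cut, grip_cut = t.asmi_cut_female, t.grip_cut_female
    else:  # pragma: no cover
        raise ValueError(f"unknown sex: {record.sex!r}")
    return SarcopeniaStatus(
        low_mass=record.asmi < asmi_cut,
        low_strength=record.grip < grip_cut,
        low_performance=record.gait_speed < t.gait_cut,
    )


def classify_cohort(
    records: Sequence[ParticipantRecord],
    thresholds: CriteriaThresholds | None = None,
) -> list[SarcopeniaStatus]:
    """Vectorised convenience: classify every record in a cohort."""
    t = thresholds if thresholds is not None else CriteriaThresholds()
    return [classify_awgs2019(r, t) for r in records]
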