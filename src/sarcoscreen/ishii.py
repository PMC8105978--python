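"""The Ishii sarcopenia screening score and simple anthropometric screens.

The Ishii score is a sex-specific linear combination of age, grip strength
and calf circumference (CC), originally presented as a points chart; higher
scores mean higher sarcopenia risk:

    male:   0.62 (age - 64) - 3.09 (grip - 50) - 4.64 (CC - 42)
    female: 0.80 (age - 64) - 5.09 (grip - 34) - 3.28 (CC - 42)

The original diagnostic cut-offs are >= 105 points (men) and >= 120 points
(women). A screen at a cut-off can use either the ">=" (default) or ">"
positivity convention; the result records which was used. The calf
circumference screen alone is positive at <= 34 cm (men) / <= 33 cm (women).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cohort import ParticipantRecord, Sex

__all__ = [
    "ORIGINAL_CUTOFFS",
    "CC_SCREEN_CUTOFFS",
    "ScreenResult",
    "compute_ishii_score",
    "score_record",
    "ishii_screen",
    "cc_screen",
]

#: original chart cut-offs, points
ORIGINAL_CUTOFFS: dict[Sex, float] = {Sex.MALE: 105.0, Sex.FEMALE: 120.0}

#: calf-circumference screen cut-offs (positive at or below), cm
CC_SCREEN_CUTOFFS: dict[Sex, float] = {Sex.MALE: 34.0, Sex.FEMALE: 33.0}

_COEFFS = {
    # sex -> (age coeff, grip coeff, cc coeff, age center, grip center, cc center)
    Sex.MALE: (0.62, -3.09, -4.64, 64.0, 50.0, 42.0),
    Sex.FEMALE: (0.80, -5.09, -3.28, 64.0, 34.0, 42.0),
}

Convention = Literal["ge", "gt"]


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of a score-based screen at a given cut-off."""

    score: float
    positive: bool
    cutoff_used: float
    convention: Convention


def compute_ishii_score(sex: Sex | str, age, grip, cc):
    """Evaluate the sex-specific Ishii score (points, may be negative).

    Accepts scalars or numpy arrays for ``age``, ``grip``, ``cc``; the formula
    is evaluated exactly, with no rounding or clamping.
    """
    sex = Sex.parse(sex) if not isinstance(sex, Sex) else sex
    a, g, c, a0, g0, c0 = _COEFFS[sex]
    return a * (np.asarray(age) - a0) + g * (np.asarray(grip) - g0) + c * (np.asarray(cc) - c0)


def score_record(record: ParticipantRecord) -> float:
    """Ishii score for one participant record."""
    return float(compute_ishii_score(record.sex, record.age, record.grip,
                                     record.calf_circumference))


def ishii_screen(
    score: float,
    sex: Sex | str,
    cutoff: float | Literal["original"] = "original",
    convention: Convention = "ge",
) -> ScreenResult:
    """Dichotomize a score at a cut-off.

    ``cutoff="original"`` resolves to 105 (men) / 120 (women). Positivity is
    ``score >= cutoff`` under the default "ge" convention, ``score > cutoff``
    under "gt".
    """
    sex = Sex.parse(sex) if not isinstance(sex, Sex) else sex
    cut = ORIGINAL_CUTOFFS[sex] if cutoff == "original" else float(cutoff)
    if convention == "ge":
        positive = score >= cut
    elif convention == "gt":
        positive = score > cut
    else:
        raise ValueError(f"unknown positivity convention: {convention!r}")
    return ScreenResult(score=float(score), positive=bool(positive),
                        cutoff_used=cut, convention=convention)


def cc_screen(cc: float, sex: Sex | str) -> bool:
    """Calf-circumference screen: positive at <= 34 cm (men) / <= 33 cm (women)."""
    sex = Sex.parse(sex) if not isinstance(sex, Sex) else sex
    return cc <= CC_SCREEN_CUTOFFS[sex]
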