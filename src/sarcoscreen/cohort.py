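"""Cohort tables: participant records, CSV input/output, validation, summaries.

A cohort is a list of :class:`ParticipantRecord`, one per person, holding the
raw measurements every downstream step consumes: sex, age, height, the
appendicular skeletal muscle mass index (ASMI, kg/m²), grip strength (kg),
usual gait speed (m/s) and calf circumference (cm).

Validation is complete-case: a record with a missing, unparseable or
out-of-range field is excluded (and the exclusion logged with a reason),
never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sarcoscreen")

__all__ = [
    "Sex",
    "ParticipantRecord",
    "Exclusion",
    "CohortSummary",
    "DEFAULT_SCHEMA",
    "AGE_BANDS",
    "read_cohort",
    "write_cohort",
    "records_from_frame",
    "cohort_to_frame",
    "summarize_cohort",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value: str) -> "Sex":
        v = str(value).strip().lower()
        if v in ("male", "m"):
            return cls.MALE
        if v in ("female", "f"):
            return cls.FEMALE
        raise ValueError(f"unrecognized sex code: {value!r}")


# validation bounds (sanity limits, not diagnostic thresholds)
AGE_BOUNDS = (60.0, 120.0)
HEIGHT_BOUNDS = (1.0, 2.2)
GAIT_BOUNDS = (0.0, 3.0)  # exclusive lower bound
CC_BOUNDS = (15.0, 60.0)

#: age bands used in descriptive summaries: [low, high) except the last
AGE_BANDS = (("<65", 60, 65), ("65-69", 65, 70), ("70-79", 70, 80), (">=80", 80, 121))

#: default CSV header -> field mapping
DEFAULT_SCHEMA: dict[str, str] = {
    "id": "id",
    "sex": "sex",
    "age": "age",
    "height_m": "height",
    "asmi_kg_m2": "asmi",
    "grip_kg": "grip",
    "gait_speed_m_s": "gait_speed",
    "cc_cm": "calf_circumference",
}

_FIELDS = ("id", "sex", "age", "height", "asmi", "grip", "gait_speed", "calf_circumference")
_NUMERIC_FIELDS = ("age", "height", "asmi", "grip", "gait_speed", "calf_circumference")


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's sex and raw measurements."""

    id: str
    sex: Sex
    age: float          # years
    height: float       # m
    asmi: float         # kg/m²
    grip: float         # kg
    gait_speed: float   # m/s
    calf_circumference: float  # cm

    def validate(self) -> list[str]:
        """Return a list of human-readable constraint violations (empty if valid)."""
        problems: list[str] = []
        for name in _NUMERIC_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                problems.append(f"{name} not finite: {v!r}")
                return problems
            if v <= 0:
                problems.append(f"{name} must be strictly positive, got {v}")
        lo, hi = AGE_BOUNDS
        if not (lo <= self.age <= hi):
            problems.append(f"age {self.age} outside [{lo}, {hi}]")
        lo, hi = HEIGHT_BOUNDS
        if not (lo <= self.height <= hi):
            problems.append(f"height {self.height} outside [{lo}, {hi}] m")
        if not (GAIT_BOUNDS[0] < self.gait_speed <= GAIT_BOUNDS[1]):
            problems.append(f"gait_speed {self.gait_speed} outside (0, {GAIT_BOUNDS[1]}] m/s")
        lo, hi = CC_BOUNDS
        if not (lo <= self.calf_circumference <= hi):
            problems.append(f"calf_circumference {self.calf_circumference} outside [{lo}, {hi}] cm")
        return problems


@dataclass(frozen=True)
class Exclusion:
    """A record dropped during validation, with the reasons."""

    row: int
    id: str
    reasons: tuple[str, ...]


class SchemaError(ValueError):
    """The input file's header cannot be mapped onto the required fields."""


def _invert_schema(schema: Mapping[str, str]) -> dict[str, str]:
    # field -> column name
    inv = {v: k for k, v in schema.items()}
    missing = [f for f in _FIELDS if f not in inv]
    if missing:
        raise SchemaError(f"schema does not map any column to field(s): {missing}")
    return inv


def records_from_frame(
    df: pd.DataFrame, schema: Mapping[str, str] | None = None
) -> tuple[list[ParticipantRecord], list[Exclusion]]:
    """Convert a DataFrame into validated records plus an exclusion log.

    ``schema`` maps column names to record fields (default
    :data:`DEFAULT_SCHEMA`). Rows failing parsing or validation are excluded,
    not fatal; a missing column is fatal (:class:`SchemaError`).
    """
    schema = dict(schema) if schema is not None else dict(DEFAULT_SCHEMA)
    field_to_col = _invert_schema(schema)
    absent = [c for c in field_to_col.values() if c not in df.columns]
    if absent:
        raise SchemaError(f"required column(s) missing from input: {absent}")

    records: list[ParticipantRecord] = []
    exclusions: list[Exclusion] = []
    for row_idx, (_, row) in enumerate(df.iterrows()):
        rid = str(row[field_to_col["id"]])
        reasons: list[str] = []
        try:
            sex = Sex.parse(row[field_to_col["sex"]])
        except ValueError as exc:
            reasons.append(str(exc))
            sex = None
        values: dict[str, float] = {}
        for name in _NUMERIC_FIELDS:
            raw = row[field_to_col[name]]
            try:
                v = float(raw)
            except (TypeError, ValueError):
                reasons.append(f"{name} unparseable: {raw!r}")
                continue
            if not math.isfinite(v):
                reasons.append(f"{name} missing or not finite: {raw!r}")
                continue
            values[name] = v
        if not reasons:
            rec = ParticipantRecord(id=rid, sex=sex, **values)
            reasons.extend(rec.validate())
            if not reasons:
                records.append(rec)
                continue
        exclusions.append(Exclusion(row=row_idx, id=rid, reasons=tuple(reasons)))
        logger.info("excluded row %d (id=%s): %s", row_idx, rid, "; ".join(reasons))
    return records, exclusions


def read_cohort(
    path, schema: Mapping[str, str] | None = None
) -> tuple[list[ParticipantRecord], list[Exclusion]]:
    """Read a cohort CSV and return (validated records, exclusion log)."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    return records_from_frame(df, schema)


def cohort_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Serialize records to a DataFrame in the default column dialect."""
    inv = {v: k for k, v in DEFAULT_SCHEMA.items()}
    rows = []
    for r in records:
        rows.append({
            inv["id"]: r.id,
            inv["sex"]: r.sex.value,
            inv["age"]: r.age,
            inv["height"]: r.height,
            inv["asmi"]: r.asmi,
            inv["grip"]: r.grip,
            inv["gait_speed"]: r.gait_speed,
            inv["calf_circumference"]: r.calf_circumference,
        })
    return pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA))


def write_cohort(records: Sequence[ParticipantRecord], path) -> None:
    """Write records as CSV in the default dialect (UTF-8, '.' decimals)."""
    cohort_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

_CONTINUOUS = ("height", "asmi", "grip", "gait_speed", "calf_circumference")


@dataclass
class CohortSummary:
    """Per-sex descriptive summary (age-band counts, mean ± SD, prevalence)."""

    n_total: int
    n_by_sex: dict[str, int]
    age_bands: dict[str, dict[str, tuple[int, float]]]  # sex -> band -> (count, pct)
    continuous: dict[str, dict[str, tuple[float, float | None]]]  # sex -> var -> (mean, sd)
    sarcopenia: dict[str, tuple[int, float]] = field(default_factory=dict)  # sex|overall -> (count, pct)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, n in self.n_by_sex.items():
            row: dict[str, object] = {"sex": sex, "n": n}
            for band, (cnt, pct) in self.age_bands[sex].items():
                row[f"age {band}"] = f"{cnt} ({pct:.2f})"
            for var, (mean, sd) in self.continuous[sex].items():
                row[var] = f"{mean:.2f} ± {sd:.2f}" if sd is not None else f"{mean:.2f} ± NA"
            if sex in self.sarcopenia:
                cnt, pct = self.sarcopenia[sex]
                row["sarcopenia"] = f"{cnt} ({pct:.2f})"
            rows.append(row)
        return pd.DataFrame(rows)


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def summarize_cohort(
    records: Sequence[ParticipantRecord],
    status: Sequence["object"] | None = None,
) -> CohortSummary:
    """Descriptive summary of a cohort, stratified by sex.

    ``status`` is an optional parallel sequence of objects with a boolean
    ``sarcopenic`` attribute (one per record); when given, sarcopenia counts
    and prevalence percentages are included per sex and overall.

    Means use the sample (n-1) standard deviation; SD is ``None`` for n=1.
    Percentages are rounded to 2 decimal places.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    if status is not None and len(status) != len(records):
        raise ValueError(
            f"status length {len(status)} does not match cohort length {len(records)}"
        )

    n_by_sex: dict[str, int] = {}
    age_bands: dict[str, dict[str, tuple[int, float]]] = {}
    continuous: dict[str, dict[str, tuple[float, float | None]]] = {}
    sarc: dict[str, tuple[int, float]] = {}

    for sex in (Sex.MALE, Sex.FEMALE):
        idx = [i for i, r in enumerate(records) if r.sex == sex]
        if not idx:
            continue
        n = len(idx)
        n_by_sex[sex.value] = n
        ages = np.array([records[i].age for i in idx])
        bands: dict[str, tuple[int, float]] = {}
        for label, lo, hi in AGE_BANDS:
            cnt = int(np.sum((ages >= lo) & (ages < hi)))
            bands[label] = (cnt, _round2(100.0 * cnt / n))
        age_bands[sex.value] = bands
        cont: dict[str, tuple[float, float | None]] = {}
        cont["age"] = _mean_sd(ages)
        for var in _CONTINUOUS:
            vals = np.array([getattr(records[i], var) for i in idx])
            cont[var] = _mean_sd(vals)
        continuous[sex.value] = cont
        if status is not None:
            cnt = sum(1 for i in idx if bool(status[i].sarcopenic))
            sarc[sex.value] = (cnt, _round2(100.0 * cnt / n))

    if status is not None:
        total = len(records)
        cnt = sum(1 for s in status if bool(s.sarcopenic))
        sarc["overall"] = (cnt, _round2(100.0 * cnt / total))

    return CohortSummary(
        n_total=len(records),
        n_by_sex=n_by_sex,
        age_bands=age_bands,
        continuous=continuous,
        sarcopenia=sarc,
    )


def _mean_sd(values: np.ndarray) -> tuple[float, float | None]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else None
    return mean, sd
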