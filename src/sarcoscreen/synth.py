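"""Synthetic cohort generation.

The validation study's raw data are not released, so this module generates
cohorts with the statistical structure the analysis assumes: per-sex marginal
distributions matching the published descriptive table (means ± SD for
height, ASMI, grip strength, gait speed and calf circumference; age-band
proportions for <65, 65-69, 70-79, >=80), joined by a Gaussian copula with a
configurable correlation matrix over (age, height, ASMI, grip, gait speed,
CC).

Age is drawn from its band-mixture marginal (uniform within each band,
bounded 60-92) through the copula, so it carries the configured correlation
with the other measurements. Sarcopenia status is never sampled as a label:
it is emergent, derived by the AWGS2019 classifier from the generated
measurements, which preserves the screen/reference-standard dependence the
ROC analysis needs.

The shipped default correlation matrix is a calibrated package convention —
the study reports no inter-measurement correlations — chosen so that age
degrades strength and performance moderately and the muscle-mass variables
cohere; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import ParticipantRecord, Sex
from .criteria import CriteriaThresholds, classify_cohort

__all__ = [
    "VARIABLES",
    "DEFAULT_CORRELATION",
    "SexMarginals",
    "SynthConfig",
    "default_config_from_table1",
    "generate_cohort",
    "emergent_prevalence",
    "calibrate_prevalence",
    "CalibrationError",
]

#: copula variable order
VARIABLES = ("age", "height", "asmi", "grip", "gait_speed", "cc")

#: shipped correlation matrix over VARIABLES — calibrated package convention,
#: not a study-reported quantity
DEFAULT_CORRELATION = np.array([
    #  age   height  asmi   grip   gait    cc
    [ 1.00, -0.15, -0.25, -0.35, -0.35, -0.20],  # age
    [-0.15,  1.00,  0.25,  0.35,  0.10,  0.20],  # height
    [-0.25,  0.25,  1.00,  0.50,  0.25,  0.55],  # asmi
    [-0.35,  0.35,  0.50,  1.00,  0.30,  0.35],  # grip
    [-0.35,  0.10,  0.25,  0.30,  1.00,  0.15],  # gait_speed
    [-0.20,  0.20,  0.55,  0.35,  0.15,  1.00],  # cc
])

#: age bands (years): [low, high) mixture components, overall support [60, 92]
AGE_BAND_EDGES = ((60.0, 65.0), (65.0, 70.0), (70.0, 80.0), (80.0, 92.0))

#: hard truncation bounds per non-age variable (physiological sanity)
DEFAULT_BOUNDS = {
    "height": (1.20, 2.00),
    "asmi": (2.0, 12.0),
    "grip": (5.0, 70.0),
    "gait_speed": (0.2, 2.5),
    "cc": (20.0, 50.0),
}


@dataclass(frozen=True)
class SexMarginals:
    """Per-sex marginal parameters: age-band mixture and Gaussian (mean, SD)s."""

    age_band_probs: tuple[float, float, float, float]
    height: tuple[float, float]
    asmi: tuple[float, float]
    grip: tuple[float, float]
    gait_speed: tuple[float, float]
    cc: tuple[float, float]

    def mean_sd(self, var: str) -> tuple[float, float]:
        return getattr(self, var)


@dataclass(frozen=True)
class SynthConfig:
    """Everything the generator needs; fully reproducible given ``seed``."""

    n_total: int
    male_fraction: float
    male: SexMarginals
    female: SexMarginals
    correlation: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0.0 < self.male_fraction < 1.0):
            raise ValueError("male_fraction must lie in (0, 1)")
        for sex_name in ("male", "female"):
            m: SexMarginals = getattr(self, sex_name)
            probs = np.asarray(m.age_band_probs)
            if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"{sex_name} age-band probabilities must be >= 0 and sum to 1")
            for var in VARIABLES[1:]:
                mean, sd = m.mean_sd(var)
                if sd <= 0:
                    raise ValueError(f"{sex_name} {var} SD must be positive")
                lo, hi = self.bounds[var]
                if not (lo < mean < hi):
                    raise ValueError(f"{sex_name} {var} mean {mean} outside bounds ({lo}, {hi})")
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (len(VARIABLES), len(VARIABLES)):
            raise ValueError(f"correlation must be {len(VARIABLES)}x{len(VARIABLES)}")
        if not np.allclose(R, R.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        eigvals = np.linalg.eigvalsh(R)
        if eigvals.min() <= 0:
            raise ValueError(
                f"correlation matrix not positive definite: smallest eigenvalue {eigvals.min():.3g}"
            )


# published per-sex characteristics (descriptive table of the validation study)
_TABLE1_MALE = SexMarginals(
    age_band_probs=(146 / 462, 110 / 462, 181 / 462, 25 / 462),
    height=(1.64, 0.06),
    asmi=(6.95, 1.14),
    grip=(35.66, 7.52),
    gait_speed=(1.08, 0.20),
    cc=(35.54, 2.92),
)
_TABLE1_FEMALE = SexMarginals(
    age_band_probs=(160 / 479, 130 / 479, 163 / 479, 26 / 479),
    height=(1.53, 0.06),
    asmi=(6.36, 1.27),
    grip=(22.88, 4.79),
    gait_speed=(1.02, 0.17),
    cc=(33.99, 2.89),
)


def default_config_from_table1(n_total: int = 941, seed: int = 0) -> SynthConfig:
    """Config whose marginals are exactly the study's published per-sex values.

    Cohort size defaults to the study's 941 with the observed male fraction
    462/941; the correlation matrix is the shipped calibrated default.
    """
    cfg = SynthConfig(
        n_total=n_total,
        male_fraction=462 / 941,
        male=_TABLE1_MALE,
        female=_TABLE1_FEMALE,
        seed=seed,
    )
    cfg.validate()
    return cfg


def _age_quantile(u: np.ndarray, probs: Sequence[float]) -> np.ndarray:
    """Inverse CDF of the band-mixture age marginal (uniform within bands)."""
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    cum[-1] = 1.0  # guard against round-off
    age = np.empty_like(u)
    for k, (lo, hi) in enumerate(AGE_BAND_EDGES):
        in_band = (u >= cum[k]) & (u < cum[k + 1]) if k < len(AGE_BAND_EDGES) - 1 \
            else (u >= cum[k]) & (u <= cum[k + 1])
        frac = (u[in_band] - cum[k]) / max(cum[k + 1] - cum[k], 1e-300)
        age[in_band] = lo + frac * (hi - lo)
    return age


def _draw_sex_block(
    rng: np.random.Generator,
    n: int,
    marg: SexMarginals,
    chol: np.ndarray,
    bounds: dict,
    max_rounds: int = 100,
) -> np.ndarray:
    """Draw an (n, 6) block of measurements for one sex.

    Out-of-bounds rows are redrawn (rejection keeps the copula intact for
    accepted rows); after ``max_rounds`` any stragglers are clipped.
    """
    out = np.empty((n, len(VARIABLES)))
    pending = np.arange(n)
    for _ in range(max_rounds):
        if pending.size == 0:
            break
        z = rng.standard_normal((pending.size, len(VARIABLES))) @ chol.T
        block = np.empty_like(z)
        block[:, 0] = _age_quantile(stats.norm.cdf(z[:, 0]), marg.age_band_probs)
        ok = np.ones(pending.size, dtype=bool)
        for j, var in enumerate(VARIABLES[1:], start=1):
            mean, sd = marg.mean_sd(var)
            block[:, j] = mean + sd * z[:, j]
            lo, hi = bounds[var]
            ok &= (block[:, j] >= lo) & (block[:, j] <= hi)
        out[pending] = block
        pending = pending[~ok]
    if pending.size:  # extremely heavy truncation: clip the remainder
        for j, var in enumerate(VARIABLES[1:], start=1):
            lo, hi = bounds[var]
            out[pending, j] = np.clip(out[pending, j], lo, hi)
    return out


def generate_cohort(config: SynthConfig) -> list[ParticipantRecord]:
    """Generate a synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(np.asarray(config.correlation, dtype=float))
    is_male = rng.random(config.n_total) < config.male_fraction
    n_male = int(is_male.sum())
    blocks = {
        Sex.MALE: _draw_sex_block(rng, n_male, config.male, chol, config.bounds),
        Sex.FEMALE: _draw_sex_block(rng, config.n_total - n_male, config.female,
                                    chol, config.bounds),
    }
    counters = {Sex.MALE: 0, Sex.FEMALE: 0}
    records: list[ParticipantRecord] = []
    for i in range(config.n_total):
        sex = Sex.MALE if is_male[i] else Sex.FEMALE
        row = blocks[sex][counters[sex]]
        counters[sex] += 1
        records.append(ParticipantRecord(
            id=f"S{i + 1:05d}",
            sex=sex,
            age=float(row[0]),
            height=float(row[1]),
            asmi=float(row[2]),
            grip=float(row[3]),
            gait_speed=float(row[4]),
            calf_circumference=float(row[5]),
        ))
    return records


def emergent_prevalence(
    config: SynthConfig,
    thresholds: CriteriaThresholds | None = None,
) -> float:
    """Sarcopenia prevalence the classifier yields on a cohort from ``config``."""
    cohort = generate_cohort(config)
    status = classify_cohort(cohort, thresholds)
    return sum(s.sarcopenic for s in status) / len(status)


class CalibrationError(RuntimeError):
    """Prevalence calibration failed; carries the search trace."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message + f" (trace: {trace})")
        self.trace = trace


def _shift_config(config: SynthConfig, t: float) -> SynthConfig:
    """Shift the ASMI/grip/gait means by t standard deviations, both sexes."""
    def shifted(m: SexMarginals) -> SexMarginals:
        kw = {}
        for var in ("asmi", "grip", "gait_speed"):
            mean, sd = m.mean_sd(var)
            kw[var] = (mean + t * sd, sd)
        return replace(m, **kw)
    return replace(config, male=shifted(config.male), female=shifted(config.female))


def calibrate_prevalence(
    config: SynthConfig,
    target_prevalence: float,
    tolerance: float = 0.01,
    n_calib: int = 50_000,
    thresholds: CriteriaThresholds | None = None,
    max_iter: int = 60,
) -> SynthConfig:
    """Nudge the diagnostic means until the emergent prevalence hits a target.

    A single scalar shift ``t`` (in SD units, shared by ASMI, grip and gait
    speed in both sexes) is found by bisection so that the AWGS2019
    prevalence on a size-``n_calib`` cohort generated from the shifted config
    falls within ``tolerance`` of ``target_prevalence``. The calibration
    cohort reuses ``config.seed`` (common random numbers), so the search is
    deterministic and prevalence is monotone in ``t``. SDs, correlations and
    the non-diagnostic marginals are untouched; the returned config keeps the
    caller's ``n_total``.
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target prevalence must lie strictly inside (0, 1)")
    config.validate()
    big = replace(config, n_total=n_calib)
    trace: list[tuple[float, float]] = []

    def prev_at(t: float) -> float:
        p = emergent_prevalence(_shift_config(big, t), thresholds)
        trace.append((t, p))
        return p

    p0 = prev_at(0.0)
    if abs(p0 - target_prevalence) <= tolerance:
        return config  # already on target: fixed point, unchanged
    # prevalence decreases as the means shift up
    lo, hi = -2.0, 2.0
    p_lo, p_hi = prev_at(lo), prev_at(hi)
    if not (p_hi - tolerance <= target_prevalence <= p_lo + tolerance):
        raise CalibrationError(
            f"target {target_prevalence} outside reachable range [{p_hi}, {p_lo}]", trace)
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        p_mid = prev_at(mid)
        if abs(p_mid - target_prevalence) <= tolerance:
            return _shift_config(config, mid)
        if p_mid > target_prevalence:
            lo = mid  # need a larger shift to lower prevalence
        else:
            hi = mid
    raise CalibrationError(
        f"did not converge to {target_prevalence} ± {tolerance} in {max_iter} iterations", trace)
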