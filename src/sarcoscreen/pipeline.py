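"""End-to-end validation study: classify, score, ROC, and accuracy reporting.

``run_validation_study`` reproduces the analysis flow of a screening-score
validation on any cohort: stratify by sex; classify each participant with the
AWGS2019 reference standard; compute the Ishii score; build the empirical ROC
with AUC and 95% CI; report accuracy (sensitivity, specificity, PPV, NPV,
LR+, LR-, Youden J) at the original chart cut-offs (105 men / 120 women) and
at the Youden-optimal cut-off found on the cohort itself. The report archives
the intermediate 2x2 tables so every metric is recomputable from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import ParticipantRecord, Sex, summarize_cohort, CohortSummary
from .criteria import CriteriaThresholds, classify_cohort
from .dta import (AccuracyMetrics, ContingencyTable, accuracy_metrics,
                  build_contingency, format_accuracy_report)
from .ishii import ORIGINAL_CUTOFFS, compute_ishii_score
from .roc import CiMethod, RocCurve, auc_ci, optimal_cutoff_youden, roc_curve

logger = logging.getLogger("sarcoscreen")

__all__ = ["StudyConfig", "AccuracyRow", "SexStratum", "StudyReport", "run_validation_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Conventions the study runs under; recorded verbatim in the report."""

    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    positivity_convention: str = "ge"   # "ge": score >= cut-off is positive
    ci_method: CiMethod = "delong"
    ci_level: float = 0.95
    bootstrap_n: int = 2000
    seed: int = 0
    integer_cutoff_grid: bool = False   # search Youden cut-off on integers


@dataclass(frozen=True)
class AccuracyRow:
    """One labelled accuracy row with its archived 2x2 table."""

    label: str
    cutoff: float
    table: ContingencyTable
    metrics: AccuracyMetrics


@dataclass(frozen=True)
class SexStratum:
    """Per-sex results: ROC block plus accuracy at both cut-offs."""

    sex: str
    n: int
    n_sarcopenic: int
    auc: float
    ci_low: float
    ci_high: float
    rows: tuple[AccuracyRow, ...]
    youden_cutoff: float
    roc: RocCurve


@dataclass(frozen=True)
class StudyReport:
    """Full study output: cohort summary, per-sex ROC and accuracy rows."""

    summary: CohortSummary
    strata: tuple[SexStratum, ...]
    config: StudyConfig
    warnings: tuple[str, ...] = ()

    def accuracy_rows(self) -> list[tuple[str, AccuracyMetrics]]:
        return [(r.label, r.metrics) for s in self.strata for r in s.rows]

    def to_text(self) -> str:
        lines = ["Validation study report", "=" * 23, ""]
        lines.append(self.summary.to_frame().to_string(index=False))
        lines.append("")
        for s in self.strata:
            lines.append(
                f"{s.sex}: n={s.n}, sarcopenic={s.n_sarcopenic}, "
                f"AUC={s.auc:.2f} ({self.config.ci_level:.0%} CI "
                f"{s.ci_low:.2f}-{s.ci_high:.2f}, {self.config.ci_method}), "
                f"Youden-optimal cut-off={s.youden_cutoff:g}"
            )
        lines.append("")
        lines.append(format_accuracy_report(self.accuracy_rows()))
        lines.append("")
        lines.append(f"positivity: score {'>=' if self.config.positivity_convention == 'ge' else '>'} cut-off"
                     f"; seed: {self.config.seed}")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        """JSON-serializable view; archived tables allow full recomputation."""
        def metrics_dict(m: AccuracyMetrics) -> dict:
            d = dataclasses.asdict(m)
            for k, v in d.items():
                if v is not None and math.isinf(v):
                    d[k] = "inf"
            return d

        return {
            "config": {
                "thresholds": dataclasses.asdict(self.config.thresholds),
                "positivity_convention": self.config.positivity_convention,
                "ci_method": self.config.ci_method,
                "ci_level": self.config.ci_level,
                "bootstrap_n": self.config.bootstrap_n,
                "seed": self.config.seed,
                "integer_cutoff_grid": self.config.integer_cutoff_grid,
            },
            "cohort": {
                "n_total": self.summary.n_total,
                "n_by_sex": self.summary.n_by_sex,
                "sarcopenia": {k: list(v) for k, v in self.summary.sarcopenia.items()},
            },
            "strata": [
                {
                    "sex": s.sex,
                    "n": s.n,
                    "n_sarcopenic": s.n_sarcopenic,
                    "auc": s.auc,
                    "ci": [s.ci_low, s.ci_high],
                    "youden_cutoff": s.youden_cutoff,
                    "rows": [
                        {
                            "label": r.label,
                            "cutoff": r.cutoff,
                            "table": dataclasses.asdict(r.table),
                            "metrics": metrics_dict(r.metrics),
                        }
                        for r in s.rows
                    ],
                }
                for s in self.strata
            ],
            "warnings": list(self.warnings),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def run_validation_study(
    cohort: Sequence[ParticipantRecord],
    config: StudyConfig | None = None,
) -> StudyReport:
    """Run the full sex-stratified diagnostic-accuracy validation.

    A sex stratum missing a reference class (no sarcopenic, or no healthy,
    subjects) is skipped with a logged warning rather than failing the run.
    """
    cfg = config if config is not None else StudyConfig()
    if not cohort:
        raise ValueError("cohort is empty")
    status = classify_cohort(cohort, cfg.thresholds)
    summary = summarize_cohort(cohort, status)

    strata: list[SexStratum] = []
    warnings: list[str] = []
    for sex in (Sex.MALE, Sex.FEMALE):
        idx = [i for i, r in enumerate(cohort) if r.sex == sex]
        if not idx:
            warnings.append(f"no {sex.value} participants; stratum skipped")
            logger.warning(warnings[-1])
            continue
        truth = np.array([status[i].sarcopenic for i in idx])
        if truth.all() or not truth.any():
            warnings.append(
                f"{sex.value} stratum has a single reference class; ROC skipped")
            logger.warning(warnings[-1])
            continue
        scores = np.array([
            compute_ishii_score(sex, cohort[i].age, cohort[i].grip,
                                cohort[i].calf_circumference)
            for i in idx
        ])
        curve = roc_curve(scores, truth)
        lo, hi = auc_ci(scores, truth, level=cfg.ci_level, method=cfg.ci_method,
                        n_boot=cfg.bootstrap_n, seed=cfg.seed)
        curve = dataclasses.replace(curve, ci_low=lo, ci_high=hi,
                                    ci_method=cfg.ci_method)

        grid = None
        if cfg.integer_cutoff_grid:
            grid = np.arange(math.floor(scores.min()), math.ceil(scores.max()) + 1)
        yres = optimal_cutoff_youden(scores, truth, grid=grid)

        rows = []
        for row_label, cut in (("original cut-off", ORIGINAL_CUTOFFS[sex]),
                               ("new cut-off", yres.threshold)):
            positive = scores > cut if cfg.positivity_convention == "gt" else scores >= cut
            table = build_contingency(positive, truth)
            rows.append(AccuracyRow(
                label=f"{sex.value.capitalize()} sarcopenia / {row_label}",
                cutoff=float(cut),
                table=table,
                metrics=accuracy_metrics(table),
            ))
        strata.append(SexStratum(
            sex=sex.value,
            n=len(idx),
            n_sarcopenic=int(truth.sum()),
            auc=curve.auc,
            ci_low=lo,
            ci_high=hi,
            rows=tuple(rows),
            youden_cutoff=yres.threshold,
            roc=curve,
        ))
    if not strata:
        raise ValueError("no stratum had both reference classes; nothing to report")
    return StudyReport(summary=summary, strata=tuple(strata), config=cfg,
                       warnings=tuple(warnings))
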