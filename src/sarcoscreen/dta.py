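"""Diagnostic test accuracy: 2x2 tables, metrics, and count reconstruction.

Given paired screen/reference-standard outcomes this module builds the 2x2
contingency table and derives sensitivity, specificity, predictive values,
likelihood ratios and the Youden index J = sensitivity + specificity - 1.

Predictive values are computed directly from the study's own table (observed
prevalence), not via Bayes' formula with an external prevalence. Undefined
ratios (e.g. LR+ when specificity is 1) are flagged, never silently zeroed.

``reconstruct_counts`` inverts published summary rows: it enumerates every
integer table on given class margins whose rounded sensitivity/specificity
match the printed percentages. An empty result means the printed row is not
consistent with any integer table — a finding, reported as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "AccuracyMetrics",
    "build_contingency",
    "accuracy_metrics",
    "likelihood_ratios",
    "youden",
    "round_half_up",
    "reconstruct_counts",
    "format_accuracy_report",
    "accuracy_report_frame",
]


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts for one screen at one cut-off."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("contingency table must contain at least one subject")

    @property
    def n_pos(self) -> int:
        """Reference-positive margin (tp + fn)."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        """Reference-negative margin (fp + tn)."""
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AccuracyMetrics:
    """Proportion-scale accuracy metrics; undefined entries are None."""

    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    lr_pos: float | None      # math.inf when specificity == 1 and sensitivity > 0
    lr_neg: float | None
    youden_j: float


def build_contingency(screen: Sequence[bool], truth: Sequence[bool]) -> ContingencyTable:
    """Cross-tabulate paired screen and reference-standard outcomes."""
    if len(screen) != len(truth):
        raise ValueError(f"screen length {len(screen)} != truth length {len(truth)}")
    if len(screen) == 0:
        raise ValueError("cannot build a contingency table from empty inputs")
    s = np.asarray(screen, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    return ContingencyTable(
        tp=int(np.sum(s & t)),
        fp=int(np.sum(s & ~t)),
        fn=int(np.sum(~s & t)),
        tn=int(np.sum(~s & ~t)),
    )


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float | None, float | None]:
    """LR+ = sens/(1-spec), LR- = (1-sens)/spec, with degenerate cases flagged.

    Returns ``math.inf`` for LR+ at perfect specificity with nonzero
    sensitivity, and ``None`` where a ratio is 0/0 or has a zero denominator
    with zero numerator ambiguity (undefined).
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if specificity < 1.0:
        lr_pos: float | None = sensitivity / (1.0 - specificity)
    else:
        lr_pos = math.inf if sensitivity > 0 else None
    if specificity > 0.0:
        lr_neg: float | None = (1.0 - sensitivity) / specificity
    else:
        lr_neg = None
    return lr_pos, lr_neg


def youden(sensitivity: float, specificity: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sensitivity + specificity - 1.0


def accuracy_metrics(ct: ContingencyTable) -> AccuracyMetrics:
    """All accuracy metrics from a 2x2 table.

    Requires both reference margins nonempty (sensitivity and specificity
    must be defined); PPV/NPV are None when no subject screened
    positive/negative.
    """
    if ct.n_pos == 0:
        raise ValueError("no reference-positive subjects: sensitivity undefined")
    if ct.n_neg == 0:
        raise ValueError("no reference-negative subjects: specificity undefined")
    sens = ct.tp / ct.n_pos
    spec = ct.tn / ct.n_neg
    ppv = ct.tp / (ct.tp + ct.fp) if (ct.tp + ct.fp) > 0 else None
    npv = ct.tn / (ct.tn + ct.fn) if (ct.tn + ct.fn) > 0 else None
    lr_pos, lr_neg = likelihood_ratios(sens, spec)
    return AccuracyMetrics(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        lr_pos=lr_pos, lr_neg=lr_neg, youden_j=youden(sens, spec),
    )


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` places (display convention)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def reconstruct_counts(
    sens_pct: float,
    spec_pct: float,
    n_pos: int,
    n_neg: int,
    decimals: int = 2,
) -> list[ContingencyTable]:
    """Recover integer 2x2 tables from printed sensitivity/specificity.

    Exhaustively enumerates tp in 0..n_pos and tn in 0..n_neg and keeps every
    table whose sensitivity and specificity, rounded half-up to ``decimals``
    decimal places on the percent scale, equal the printed values. Returns
    all consistent tables (possibly none — an inconsistent published row —
    or several — an under-determined one); never forces a fit.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both class margins must be positive")
    if decimals < 0:
        raise ValueError("decimals must be nonnegative")
    tps = [tp for tp in range(n_pos + 1)
           if round_half_up(100.0 * tp / n_pos, decimals) == round_half_up(sens_pct, decimals)]
    tns = [tn for tn in range(n_neg + 1)
           if round_half_up(100.0 * tn / n_neg, decimals) == round_half_up(spec_pct, decimals)]
    return [
        ContingencyTable(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)
        for tp in tps for tn in tns
    ]


# ---------------------------------------------------------------------------
# report formatting (mixed precision: sens/spec 2 dp %, PPV/NPV integer %,
# LRs 2 dp)
# ---------------------------------------------------------------------------

def _fmt_pct(x: float | None, decimals: int) -> str:
    if x is None:
        return "NA"
    s = f"{round_half_up(100.0 * x, decimals):.{decimals}f}"
    if decimals:  # trim trailing zeros, published-table style (79.90 -> 79.9)
        s = s.rstrip("0").rstrip(".")
    return f"{s} %"


def _fmt_lr(x: float | None) -> str:
    if x is None:
        return "NA"
    if math.isinf(x):
        return "∞"
    return f"{round_half_up(x, 2):.2f}"


def accuracy_report_frame(rows: Iterable[tuple[str, AccuracyMetrics]]) -> pd.DataFrame:
    """Tabular accuracy report, one labelled row per screen/cut-off."""
    out = []
    for label, m in rows:
        out.append({
            "model": label,
            "sensitivity": _fmt_pct(m.sensitivity, 2),
            "specificity": _fmt_pct(m.specificity, 2),
            "ppv": _fmt_pct(m.ppv, 0),
            "npv": _fmt_pct(m.npv, 0),
            "lr_pos": _fmt_lr(m.lr_pos),
            "lr_neg": _fmt_lr(m.lr_neg),
        })
    if not out:
        raise ValueError("report requires at least one row")
    return pd.DataFrame(out)


def format_accuracy_report(rows: Iterable[tuple[str, AccuracyMetrics]]) -> str:
    """Aligned plain-text accuracy report."""
    return accuracy_report_frame(rows).to_string(index=False)
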