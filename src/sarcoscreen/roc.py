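"""Empirical ROC analysis from first principles.

The ROC curve is traced over candidate thresholds taken at the distinct
observed score values (plus sentinels), with positivity defined as
score >= threshold. The AUC is the trapezoidal area under the empirical
curve, which equals the Mann-Whitney two-sample statistic (ties counted
half); both are implemented and the equivalence is a tested invariant.

Confidence intervals: DeLong's asymptotic method via placement values
(default; deterministic), or a class-stratified percentile bootstrap.
The Youden-optimal cut-off maximizes J = sensitivity + specificity - 1
over the candidate thresholds; ties go to the smallest threshold (the
most sensitive of the tied cut-offs) and are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RocCurve",
    "YoudenResult",
    "roc_curve",
    "auc_mannwhitney",
    "auc_ci",
    "optimal_cutoff_youden",
]

CiMethod = Literal["delong", "bootstrap"]


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve with AUC and a confidence interval."""

    thresholds: np.ndarray          # descending; aligned with points[1:] onset
    fpr: np.ndarray                 # nondecreasing, starts 0 ends 1
    tpr: np.ndarray                 # nondecreasing, starts 0 ends 1
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_method: CiMethod | None = None

    @property
    def points(self) -> np.ndarray:
        """(fpr, tpr) pairs as an (n, 2) array."""
        return np.column_stack([self.fpr, self.tpr])


def _check_classes(scores, truth) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be 1-d sequences of equal length")
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present; AUC is undefined otherwise")
    return scores, truth


def roc_curve(scores: Sequence[float], truth: Sequence[bool]) -> RocCurve:
    """Empirical ROC curve with trapezoidal AUC (no confidence interval).

    Candidate thresholds are the distinct observed scores in descending
    order; a subject is screen-positive when score >= threshold. The curve
    starts at (0,0) (threshold above every score) and ends at (1,1).
    """
    scores, truth = _check_classes(scores, truth)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())

    thresholds = np.unique(scores)[::-1]  # descending
    # cumulative positives/negatives at score >= t, via sorted order
    order = np.argsort(scores)[::-1]
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    cum_tp = np.cumsum(sorted_truth)
    cum_fp = np.cumsum(~sorted_truth)
    # index of the last subject with score >= t for each distinct threshold
    last_idx = np.searchsorted(-sorted_scores, -thresholds, side="right") - 1
    tpr = np.concatenate([[0.0], cum_tp[last_idx] / n_pos])
    fpr = np.concatenate([[0.0], cum_fp[last_idx] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def auc_mannwhitney(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """AUC as the Mann-Whitney statistic: P(pos > neg) + P(pos == neg)/2.

    Independent of the ROC construction; serves as its oracle.
    """
    scores, truth = _check_classes(scores, truth)
    pos = scores[truth]
    neg = scores[~truth]
    # rank-based O(n log n) evaluation of the pairwise comparison mean
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def _delong_ci(scores: np.ndarray, truth: np.ndarray, level: float) -> tuple[float, float]:
    pos = scores[truth]
    neg = scores[~truth]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("DeLong interval requires at least 2 subjects per class")
    # placement values: V10[i] = fraction of negatives below pos[i] (ties 1/2)
    neg_sorted = np.sort(neg)
    v10 = (np.searchsorted(neg_sorted, pos, side="left")
           + np.searchsorted(neg_sorted, pos, side="right")) / (2.0 * n)
    pos_sorted = np.sort(pos)
    v01 = 1.0 - (np.searchsorted(pos_sorted, neg, side="left")
                 + np.searchsorted(pos_sorted, neg, side="right")) / (2.0 * m)
    auc = float(v10.mean())
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def _bootstrap_ci(
    scores: np.ndarray, truth: np.ndarray, level: float,
    n_boot: int, seed: int,
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    pos = scores[truth]
    neg = scores[~truth]
    m, n = len(pos), len(neg)
    aucs = np.empty(n_boot)
    truth_b = np.concatenate([np.ones(m, bool), np.zeros(n, bool)])
    for b in range(n_boot):
        sample = np.concatenate([rng.choice(pos, m, replace=True),
                                 rng.choice(neg, n, replace=True)])
        aucs[b] = auc_mannwhitney(sample, truth_b)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(max(0.0, lo)), float(min(1.0, hi))


def auc_ci(
    scores: Sequence[float],
    truth: Sequence[bool],
    level: float = 0.95,
    method: CiMethod = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC, truncated to [0, 1].

    ``delong`` (default): asymptotic normal interval from the DeLong
    placement-value variance. ``bootstrap``: class-stratified resampling
    with a percentile interval, ``n_boot`` resamples, reproducible via
    ``seed``.
    """
    scores, truth = _check_classes(scores, truth)
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    if method == "delong":
        return _delong_ci(scores, truth, level)
    if method == "bootstrap":
        return _bootstrap_ci(scores, truth, level, n_boot, seed)
    raise ValueError(f"unknown CI method: {method!r}")


@dataclass(frozen=True)
class YoudenResult:
    """Youden-optimal cut-off and its operating point."""

    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    tie: bool  # True when several thresholds attain the maximal J


def optimal_cutoff_youden(
    scores: Sequence[float],
    truth: Sequence[bool],
    grid: Sequence[float] | None = None,
) -> YoudenResult:
    """Cut-off maximizing J = sensitivity + specificity - 1.

    Evaluates J at every candidate threshold (positivity score >= t), by
    default the distinct observed scores; ``grid`` substitutes an explicit
    candidate list (e.g. integers). Ties on J are broken toward the smallest
    threshold, which maximizes sensitivity among the tied candidates, and
    flagged in the result.
    """
    scores, truth = _check_classes(scores, truth)
    curve = roc_curve(scores, truth)
    if grid is None:
        # include the "screen nobody" sentinel so a degenerate input where
        # every threshold has J = 0 is reported as a tie
        thresholds = np.concatenate([[np.inf], curve.thresholds])
        tpr, fpr = curve.tpr, curve.fpr
    else:
        thresholds = np.asarray(sorted(set(map(float, grid)), reverse=True))
        if thresholds.size == 0:
            raise ValueError("empty threshold grid")
        n_pos = truth.sum()
        n_neg = (~truth).sum()
        tpr = np.array([(scores[truth] >= t).sum() / n_pos for t in thresholds])
        fpr = np.array([(scores[~truth] >= t).sum() / n_neg for t in thresholds])
    j = tpr - fpr
    j_max = j.max()
    at_max = np.flatnonzero(np.isclose(j, j_max))
    best = at_max[np.argmin(thresholds[at_max])]
    return YoudenResult(
        threshold=float(thresholds[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        youden_j=float(j_max),
        tie=len(at_max) > 1,
    )
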