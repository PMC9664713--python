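"""Diagnostic accuracy of adherence measures against detectable viral load.

Orientation is fixed throughout: the *condition* is a detectable viral load
and the *positive test* is non-adherence, so sensitivity is the percentage of
participants with detectable viral load classified non-adherent, and
specificity the percentage with suppressed viral load classified adherent.

The empirical ROC curve treats low adherence as high risk: each distinct
observed adherence value serves as a cut-off (non-adherent iff score < c),
tied scores collapse to one vertex, and the curve is closed at (0,0)
(cut-off at the minimum score: nobody flagged) and (1,1) (cut-off above the
maximum: everybody flagged).  The trapezoidal area equals the Mann-Whitney
probability that a randomly chosen case scores below a randomly chosen
control, with half credit for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import COMPOSITES, CutoffGrid, DEFAULT_CUTOFFS, add_composites, measure_column

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metrics",
    "diagnostic_table",
    "RocCurve",
    "roc_curve",
    "auc",
    "optimal_cutoff",
    "DEFAULT_MEASURES",
]

#: the five comparisons: three single measures, the SR+PR pair, the triple
DEFAULT_MEASURES = ("self_report", "pharmacy_refill", "rtmm", "sr_pr", "all_three")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 cross-tabulation of non-adherence flags against viral-load status."""

    tp: int  # non-adherent, detectable
    fp: int  # non-adherent, suppressed
    fn: int  # adherent, detectable
    tn: int  # adherent, suppressed

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    flags: Sequence[bool], outcomes: Sequence[bool]
) -> ConfusionCounts:
    """Cross-tabulate non-adherence flags against detectable-viral-load outcomes."""
    flags = np.asarray(flags)
    outcomes = np.asarray(outcomes)
    if flags.shape != outcomes.shape or flags.ndim != 1:
        raise ValueError(
            f"flags and outcomes must be aligned 1-d sequences, got shapes "
            f"{flags.shape} and {outcomes.shape}"
        )
    if pd.isna(flags).any() or pd.isna(outcomes).any():
        raise ValueError("flags and outcomes must not contain missing values")
    flags = flags.astype(bool)
    outcomes = outcomes.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(flags & outcomes)),
        fp=int(np.sum(flags & ~outcomes)),
        fn=int(np.sum(~flags & outcomes)),
        tn=int(np.sum(~flags & ~outcomes)),
    )


def _ratio_pct(num: int, den: int) -> float:
    """100*num/den, NaN when the denominator is zero (undefined, never an error)."""
    return 100.0 * num / den if den else math.nan


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV as percents (NaN where undefined)."""
    return {
        "sensitivity": _ratio_pct(c.tp, c.tp + c.fn),
        "specificity": _ratio_pct(c.tn, c.tn + c.fp),
        "ppv": _ratio_pct(c.tp, c.tp + c.fp),
        "npv": _ratio_pct(c.tn, c.tn + c.fn),
    }


def diagnostic_table(
    panel: pd.DataFrame,
    measures: Sequence[str] = DEFAULT_MEASURES,
    grid: CutoffGrid | Sequence[float] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Accuracy metrics for every (measure, cutoff) cell of the grid.

    Each measure (or composite) is evaluated on the participants for whom it
    is defined — analyses involving electronic monitoring are restricted to
    the monitored arm.  Undefined metrics (zero denominator) are NaN.
    """
    if panel.empty:
        raise ValueError("panel is empty")
    grid = grid if isinstance(grid, CutoffGrid) else CutoffGrid(tuple(grid))
    panel = add_composites(panel)
    rows = []
    for measure in measures:
        col = measure_column(measure)
        sub = panel.loc[panel[col].notna()]
        if sub.empty:
            raise ValueError(f"measure {measure!r} is absent for all participants")
        scores = sub[col].to_numpy(dtype=float)
        outcomes = sub["vl_detectable"].to_numpy(dtype=bool)
        for cutoff in grid:
            c = confusion(scores < cutoff, outcomes)
            row = {"measure": measure, "cutoff": cutoff, "n": c.total,
                   "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn}
            row.update(metrics(c))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve with the adherence cut-off at each vertex.

    ``thresholds[i]`` is the cut-off c (non-adherent iff score < c) producing
    vertex ``(fpr[i], tpr[i])``; the terminal all-positive vertex carries an
    infinite threshold.  Starts at (0,0), ends at (1,1); both coordinates are
    non-decreasing.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        for name in ("thresholds", "fpr", "tpr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            self.fpr[0] == 0.0
            and self.tpr[0] == 0.0
            and self.fpr[-1] == 1.0
            and self.tpr[-1] == 1.0
        ):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_curve(
    adherence_scores: Sequence[float], outcomes: Sequence[bool]
) -> RocCurve:
    """Empirical ROC of an adherence score for detectable viral load.

    Low adherence is the risk direction.  Sweeps every distinct observed
    score as a cut-off plus a terminal cut-off above the maximum.
    """
    scores = np.asarray(adherence_scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    if scores.shape != outcomes.shape or scores.ndim != 1:
        raise ValueError("scores and outcomes must be aligned 1-d sequences")
    if np.isnan(scores).any():
        raise ValueError("scores must not contain missing values")
    n_pos = int(outcomes.sum())
    n_neg = int((~outcomes).sum())
    if n_pos == 0:
        raise ValueError("no participants with detectable viral load (no cases)")
    if n_neg == 0:
        raise ValueError("no participants with suppressed viral load (no controls)")

    distinct = np.unique(scores)  # ascending
    thresholds = np.append(distinct, np.inf)
    tpr = np.empty_like(thresholds)
    fpr = np.empty_like(thresholds)
    for i, c in enumerate(thresholds):
        flagged = scores < c
        tpr[i] = np.sum(flagged & outcomes) / n_pos
        fpr[i] = np.sum(flagged & ~outcomes) / n_neg
    area = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=area)


def auc(adherence_scores: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Area under the empirical ROC curve (trapezoidal).

    Equals the Mann-Whitney probability that a case scores strictly below a
    control plus half the tie probability, over all case-control pairs.
    """
    return roc_curve(adherence_scores, outcomes).auc


def optimal_cutoff(curve: RocCurve) -> float:
    """Adherence cut-off of the ROC vertex closest to the top-left corner.

    Minimizes Euclidean distance to (fpr=0, tpr=1) over interior vertices;
    ties break toward the higher-sensitivity vertex, then the lower cut-off.
    Returns NaN for a degenerate two-point curve (no interior vertex).
    """
    interior = ~(
        ((curve.fpr == 0.0) & (curve.tpr == 0.0))
        | ((curve.fpr == 1.0) & (curve.tpr == 1.0))
    )
    if not interior.any():
        return math.nan
    idx = np.flatnonzero(interior)
    dist = np.hypot(curve.fpr[idx], 1.0 - curve.tpr[idx])
    # lexicographic: distance asc, tpr desc, threshold asc
    order = sorted(
        range(len(idx)),
        key=lambda k: (dist[k], -curve.tpr[idx[k]], curve.thresholds[idx[k]]),
    )
    return float(curve.thresholds[idx[order[0]]])
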