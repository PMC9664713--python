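"""Dichotomization at adherence cut-offs and composite (any-measure) rules.

A participant is *non-adherent* at cut-off ``c`` when their adherence percent
is strictly below ``c``; exactly-at-cut-off counts as adherent, so a 100%
cut-off flags only imperfect adherence.  Composite measures follow the
any-measure union rule: non-adherent on the composite iff non-adherent on any
component.  The continuous analog of that rule is the per-participant
minimum, the unique scalar whose thresholding reproduces the union rule at
every cut-off simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scores import MEASURE_COLUMNS

__all__ = [
    "DEFAULT_CUTOFFS",
    "CutoffGrid",
    "dichotomize",
    "combine_flags",
    "composite_score",
    "COMPOSITES",
    "add_composites",
    "classification_long",
]

DEFAULT_CUTOFFS = (80.0, 85.0, 90.0, 95.0, 100.0)

#: composite name -> component single measures
COMPOSITES = {
    "sr_pr": ("self_report", "pharmacy_refill"),
    "all_three": ("self_report", "pharmacy_refill", "rtmm"),
}


@dataclass(frozen=True)
class CutoffGrid:
    """Strictly increasing adherence cut-offs in (0, 100]."""

    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        object.__setattr__(self, "cutoffs", tuple(float(c) for c in self.cutoffs))
        if not self.cutoffs:
            raise ValueError("cutoff grid must be nonempty")
        for c in self.cutoffs:
            if not (0.0 < c <= 100.0):
                raise ValueError(f"cutoff {c!r} outside (0, 100]")
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError(f"cutoffs must be strictly increasing: {self.cutoffs}")

    def __iter__(self):
        return iter(self.cutoffs)

    def __len__(self) -> int:
        return len(self.cutoffs)


def dichotomize(adherence: float, cutoff: float) -> bool:
    """True (non-adherent) iff ``adherence`` is strictly below ``cutoff``."""
    if not (0.0 <= adherence <= 100.0):
        raise ValueError(f"adherence {adherence!r} outside [0, 100]")
    if not (0.0 < cutoff <= 100.0):
        raise ValueError(f"cutoff {cutoff!r} outside (0, 100]")
    return adherence < cutoff


def combine_flags(flags: Iterable[bool]) -> bool:
    """Union rule: non-adherent iff non-adherent on any component."""
    flags = list(flags)
    if not flags:
        raise ValueError("combine_flags requires at least one flag")
    return any(flags)


def composite_score(scores: Iterable[float]) -> float:
    """Continuous composite: the per-participant minimum of the components.

    Thresholding this value at any cut-off equals combining the per-component
    flags with the union rule at that cut-off.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("composite_score requires at least one score")
    return min(scores)


def add_composites(panel: pd.DataFrame) -> pd.DataFrame:
    """Append composite adherence columns to a measure panel.

    A composite is defined only for participants with every component present
    (e.g. the three-measure composite only within the monitored arm).
    """
    out = panel.copy()
    for name, components in COMPOSITES.items():
        cols = [MEASURE_COLUMNS[m] for m in components]
        values = out[cols].min(axis=1)
        values[out[cols].isna().any(axis=1)] = np.nan
        out[f"{name}_adherence"] = values
    return out


def measure_column(measure: str) -> str:
    """Panel column for a single measure or composite name."""
    if measure in MEASURE_COLUMNS:
        return MEASURE_COLUMNS[measure]
    if measure in COMPOSITES:
        return f"{measure}_adherence"
    raise KeyError(
        f"unknown measure {measure!r}; expected one of "
        f"{sorted(MEASURE_COLUMNS) + sorted(COMPOSITES)}"
    )


def classification_long(
    panel: pd.DataFrame,
    measures: Sequence[str],
    grid: CutoffGrid | Sequence[float] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Long-format flag table: participant x measure x cutoff -> non-adherent.

    Rows with a missing measure are omitted for that measure.
    """
    grid = grid if isinstance(grid, CutoffGrid) else CutoffGrid(tuple(grid))
    panel = add_composites(panel)
    rows = []
    for measure in measures:
        col = measure_column(measure)
        sub = panel.loc[panel[col].notna(), ["participant_id", col]]
        for cutoff in grid:
            for pid, score in zip(sub["participant_id"], sub[col]):
                rows.append(
                    {
                        "participant_id": pid,
                        "measure": measure,
                        "cutoff": cutoff,
                        "nonadherent": bool(score < cutoff),
                    }
                )
    return pd.DataFrame(rows, columns=["participant_id", "measure", "cutoff", "nonadherent"])
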