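"""Continuous adherence percentages from raw observables.

Three standard adherence measures, each expressed as percent of prescribed
doses taken over the inter-visit window and truncated to [0, 100]:

* self-report: (prescribed − reported missed) / prescribed
* pharmacy refill: (dispensed + returned previously − returned now) / prescribed
* electronic monitoring: box openings / expected openings

Truncation at 100% is applied to all three measures uniformly (a surplus
ledger or double opening can push the raw ratio above 100); each truncation
is counted and reported through the module logger.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import ParticipantRecord

__all__ = [
    "self_report_adherence",
    "pharmacy_refill_adherence",
    "rtmm_adherence",
    "build_panel",
    "MEASURE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: panel column per single adherence measure
MEASURE_COLUMNS = {
    "self_report": "sr_adherence",
    "pharmacy_refill": "pr_adherence",
    "rtmm": "rtmm_adherence",
}

# fallback window length when the visit interval is unrecorded: the
# questionnaire asks about "the past month"
DEFAULT_RECALL_DAYS = 30


def self_report_adherence(
    days_in_window: int, pills_per_day: int, missed_pills: int
) -> float:
    """Percent adherence implied by a reported missed-pill count.

    Exact rational arithmetic before the percent conversion, so e.g.
    (30 days, 1 pill, 3 missed) is exactly 90.0.
    """
    if days_in_window <= 0 or pills_per_day <= 0:
        raise ValueError(
            "days_in_window and pills_per_day must be positive, got "
            f"{days_in_window!r}, {pills_per_day!r}"
        )
    prescribed = days_in_window * pills_per_day
    if not (0 <= missed_pills <= prescribed):
        raise ValueError(
            f"missed_pills={missed_pills!r} outside [0, {prescribed}]"
        )
    value = float(Fraction(prescribed - missed_pills, prescribed) * 100)
    return min(value, 100.0)


def pharmacy_refill_adherence(
    dispensed_prev: int,
    returned_prev: int,
    returned_current: int | None,
    days_between_visits: int,
    pills_per_day: int,
) -> float:
    """Percent adherence from the pharmacy pill ledger, truncated at 100.

    When the current leftover count is unknown the convention is that all
    dispensed pills were taken as prescribed, i.e. 100%.
    """
    if days_between_visits <= 0 or pills_per_day <= 0:
        raise ValueError("days_between_visits and pills_per_day must be positive")
    if min(dispensed_prev, returned_prev) < 0:
        raise ValueError("pill counts must be non-negative")
    if returned_current is None:
        return 100.0
    if returned_current < 0:
        raise ValueError("pill counts must be non-negative")
    consumed = dispensed_prev + returned_prev - returned_current
    if consumed < 0:
        raise ValueError(
            f"more pills returned ({returned_current}) than available "
            f"({dispensed_prev + returned_prev})"
        )
    prescribed = days_between_visits * pills_per_day
    raw = float(Fraction(consumed, prescribed) * 100)
    if raw > 100.0:
        logger.debug("pharmacy refill adherence %.1f%% truncated to 100%%", raw)
    return min(raw, 100.0)


def rtmm_adherence(
    openings: int, days_in_window: int, dosing_moments_per_day: int
) -> float:
    """Percent adherence from electronic-monitoring opening counts, capped at 100."""
    expected = days_in_window * dosing_moments_per_day
    if expected <= 0:
        raise ValueError("expected openings must be positive")
    if openings < 0:
        raise ValueError("openings must be non-negative")
    raw = float(Fraction(openings, expected) * 100)
    if raw > 100.0:
        logger.debug("RTMM adherence %.1f%% truncated to 100%%", raw)
    return min(raw, 100.0)


def build_panel(cohort: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Apply all three measures row-wise to a cohort.

    Returns one row per participant with continuous adherence percentages
    (``rtmm_adherence`` NaN where the participant has no monitoring data),
    the binary outcome and the covariates needed downstream.  Domain errors
    are re-raised with the participant identifier attached.
    """
    rows = []
    n_truncated = 0
    for rec in cohort:
        try:
            days = rec.days_in_window if rec.days_in_window else DEFAULT_RECALL_DAYS
            sr = self_report_adherence(days, rec.pills_per_day, rec.sr_missed_pills)
            pr = pharmacy_refill_adherence(
                rec.pr_dispensed_prev,
                rec.pr_returned_prev,
                rec.pr_returned_current,
                days,
                rec.pills_per_day,
            )
            if rec.rtmm_openings is None:
                rtmm = np.nan
            else:
                moments_per_day = rec.rtmm_expected_openings // days
                rtmm = rtmm_adherence(rec.rtmm_openings, days, max(moments_per_day, 1))
                if rec.rtmm_openings > rec.rtmm_expected_openings:
                    n_truncated += 1
        except ValueError as exc:
            raise ValueError(f"participant {rec.participant_id}: {exc}") from exc
        rows.append(
            {
                "participant_id": rec.participant_id,
                "sr_adherence": sr,
                "pr_adherence": pr,
                "rtmm_adherence": rtmm,
                "vl_detectable": rec.vl_detectable,
                "sex": rec.sex,
                "regimen_class": rec.regimen_class,
                "true_adherence": rec.true_adherence,
            }
        )
    if n_truncated:
        logger.info("capped %d RTMM adherence values above 100%%", n_truncated)
    panel = pd.DataFrame(rows)
    assert len(panel) == len(cohort)
    return panel
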