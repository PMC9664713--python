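"""Small reporting helpers."""

from __future__ import annotations

__all__ = ["percent"]


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Proportion as a percent rounded to ``ndigits`` decimals.

    The convention used for disposition reporting, e.g. study-completion and
    viral-suppression percentages from enrolment counts.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must be between 0 and denominator")
    return round(100.0 * numerator / denominator, ndigits)
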