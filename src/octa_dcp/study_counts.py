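"""Reported eye-flow counts of the study population this package models.

These integers are inputs (a published quality-control ledger), kept here
so that the exclusion-flow arithmetic — totals, percentages, severity
breakdown — is computed, not transcribed.
"""

from __future__ import annotations

__all__ = [
    "ELIGIBLE_EYES",
    "INCLUDED_EYES",
    "EXCLUSION_REASONS",
    "INCLUDED_DR_COUNTS",
    "total_excluded",
    "exclusion_percentage",
    "included_dr_percentages",
]

ELIGIBLE_EYES = 563
INCLUDED_EYES = 397

# eyes excluded during quality control, by primary reason
EXCLUSION_REASONS = {
    "projection": 53,
    "blur": 67,
    "motion": 27,
    "signal_loss": 10,
    "low_quality": 8,
    "off_center": 1,  # fovea poorly concentrated
}

# included eyes by diabetic-retinopathy severity
INCLUDED_DR_COUNTS = {"none": 170, "mild": 101, "moderate": 90, "severe": 36}


def total_excluded() -> int:
    """Eyes excluded by quality control (sum over reasons)."""
    return sum(EXCLUSION_REASONS.values())


def exclusion_percentage() -> float:
    """Excluded share of eligible eyes, in percent."""
    return 100.0 * total_excluded() / ELIGIBLE_EYES


def included_dr_percentages() -> dict[str, float]:
    """DR-severity shares of the included eyes, in percent."""
    return {
        level: 100.0 * n / INCLUDED_EYES for level, n in INCLUDED_DR_COUNTS.items()
    }
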