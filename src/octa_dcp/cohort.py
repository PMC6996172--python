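"""Synthetic clinical cohorts for the association workflow.

Generates eye-level rows (up to two fellow eyes per subject) with the
covariate structure of a hospital-based diabetic cohort: diabetic
retinopathy (DR) severity on the four-level clinical scale, diabetic
macular edema (DME), visual acuity (logMAR), biometry and OCT thicknesses
at eye level, and demographics / vitals / labs at subject level.  Marginal
means and SDs default to the included-eye characteristics of the study
population this package models (age 60.7 +/- 13.2 y, HbA1c 7.48 +/- 1.33%,
axial length 23.88 +/- 1.34 mm, ...), and are configurable.

Outcomes (FAZ area, vessel density, fractal dimension) are linear in the
*standardized* covariates — coefficients are interpreted per SD of each
continuous predictor, and as offsets versus the no-DR reference for the DR
dummies — plus a shared subject-level random effect that induces a chosen
correlation between fellow eyes, plus independent noise.  This matches the
estimand of the downstream GEE models, so injected coefficients are
directly comparable with fitted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EffectSpec",
    "COVARIATE_MARGINALS",
    "DR_LEVELS",
    "DR_PREVALENCE",
    "generate_cohort",
    "simulate_repeated_measures",
]

DR_LEVELS = ("none", "mild", "moderate", "severe")
# included-eye distribution: 170/101/90/36 of 397
DR_PREVALENCE = (170 / 397, 101 / 397, 90 / 397, 36 / 397)
DME_PREVALENCE = 57 / 397

# (mean, sd, level): level "eye" varies between fellow eyes, "subject" is shared
COVARIATE_MARGINALS: dict[str, tuple[float, float, str]] = {
    "logmar": (0.14, 0.15, "eye"),
    "axial_length_mm": (23.88, 1.34, "eye"),
    "cst_um": (258.2, 47.4, "eye"),
    "choroid_um": (208.58, 78.13, "eye"),
    "gcipl_um": (80.2, 10.9, "eye"),
    "age_y": (60.7, 13.2, "subject"),
    "dm_duration_y": (12.9, 9.07, "subject"),
    "bmi": (26.2, 4.19, "subject"),
    "sbp": (137.8, 20.4, "subject"),
    "dbp": (78.1, 10.5, "subject"),
    "hba1c_pct": (7.48, 1.33, "subject"),
    "total_chol": (4.34, 0.95, "subject"),
    "ldl": (2.31, 0.77, "subject"),
}

OUTCOME_BASELINES = {"faz_area_mm2": 0.35, "vd_pct": 92.0, "fd": 1.45}

# dummy predictors recognised in effect maps besides the continuous covariates
_DUMMIES = ("dr_mild", "dr_moderate", "dr_severe", "dme")


def _default_effects() -> dict[str, dict[str, float]]:
    """Effect magnitudes of the scale reported for this study population
    (multivariable models of the three deep-plexus metrics)."""
    return {
        "faz_area_mm2": {
            "dr_severe": 0.687, "dr_moderate": 0.103, "dr_mild": 0.221,
            "dme": 0.138, "logmar": 0.102, "axial_length_mm": -0.171,
            "choroid_um": -0.122, "bmi": -0.090, "sbp": 0.077, "age_y": 0.051,
        },
        "vd_pct": {
            "dr_severe": -0.842, "dr_moderate": -0.249, "dr_mild": -0.345,
            "dme": -0.160, "axial_length_mm": 0.107, "logmar": -0.133,
            "choroid_um": 0.104, "bmi": 0.073, "sbp": -0.030, "age_y": -0.078,
        },
        "fd": {
            "dr_severe": -0.891, "dr_moderate": -0.357, "dr_mild": -0.307,
            "logmar": -0.074, "gcipl_um": 0.113, "bmi": 0.077,
            "sbp": 0.062, "age_y": -0.142,
        },
    }


@dataclass
class EffectSpec:
    """Linear data-generating model for the three outcomes.

    ``effects[outcome][predictor]`` is the coefficient on the standardized
    scale (per population SD for continuous predictors; versus the no-DR /
    no-DME reference for dummies).  ``residual_sd[outcome]`` is the total
    residual SD around the linear predictor, of which a fraction
    ``inter_eye_correlation`` of the variance is shared between fellow
    eyes of a subject.
    """

    effects: dict[str, dict[str, float]] = field(default_factory=_default_effects)
    residual_sd: dict[str, float] = field(
        default_factory=lambda: {"faz_area_mm2": 0.8, "vd_pct": 1.0, "fd": 0.9}
    )
    inter_eye_correlation: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.inter_eye_correlation < 1:
            raise ValueError("inter_eye_correlation must lie in [0, 1)")
        for outcome, sd in self.residual_sd.items():
            if sd <= 0:
                raise ValueError(f"residual_sd[{outcome!r}] must be positive")
        valid = set(COVARIATE_MARGINALS) | set(_DUMMIES)
        for outcome, terms in self.effects.items():
            unknown = set(terms) - valid
            if unknown:
                raise ValueError(f"unknown predictors for {outcome}: {sorted(unknown)}")

    @classmethod
    def null(cls, inter_eye_correlation: float = 0.4) -> "EffectSpec":
        """All coefficients zero (for type-I-error and coverage studies)."""
        return cls(
            effects={k: {} for k in OUTCOME_BASELINES},
            inter_eye_correlation=inter_eye_correlation,
        )


def generate_cohort(
    n_subjects: int,
    both_eyes_fraction: float = 0.59,
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an eye-level cohort table.

    Each subject contributes both eyes with probability
    ``both_eyes_fraction`` (the study's 397 eyes / 250 subjects implies
    ~0.59), otherwise one.  Returns one row per eye with all covariates,
    the three outcomes, and subject/eye identifiers.  Deterministic given
    the seed.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not 0 <= both_eyes_fraction <= 1:
        raise ValueError("both_eyes_fraction must lie in [0, 1]")
    effects = effects or EffectSpec()
    rng = np.random.default_rng(seed)

    subj_values = {
        name: rng.normal(mean, sd, n_subjects)
        for name, (mean, sd, level) in COVARIATE_MARGINALS.items()
        if level == "subject"
    }
    n_eyes_per_subject = 1 + (rng.random(n_subjects) < both_eyes_fraction)

    rows: list[dict] = []
    for i in range(n_subjects):
        for e in range(n_eyes_per_subject[i]):
            row = {
                "subject_id": f"S{i:05d}",
                "eye_id": f"S{i:05d}_{'OD' if e == 0 else 'OS'}",
            }
            for name, vals in subj_values.items():
                row[name] = vals[i]
            for name, (mean, sd, level) in COVARIATE_MARGINALS.items():
                if level == "eye":
                    row[name] = rng.normal(mean, sd)
            row["dr_severity"] = DR_LEVELS[rng.choice(4, p=DR_PREVALENCE)]
            row["dme"] = bool(rng.random() < DME_PREVALENCE)
            rows.append(row)
    df = pd.DataFrame(rows)

    # standardized design columns for the linear predictor
    z = {
        name: (df[name] - mean) / sd
        for name, (mean, sd, _lvl) in COVARIATE_MARGINALS.items()
    }
    z["dr_mild"] = (df["dr_severity"] == "mild").astype(float)
    z["dr_moderate"] = (df["dr_severity"] == "moderate").astype(float)
    z["dr_severe"] = (df["dr_severity"] == "severe").astype(float)
    z["dme"] = df["dme"].astype(float)

    subj_index = df["subject_id"].factorize()[0]
    rho = effects.inter_eye_correlation
    for outcome, base in OUTCOME_BASELINES.items():
        sd_tot = effects.residual_sd.get(outcome, 1.0)
        lin = np.full(len(df), base)
        for predictor, beta in effects.effects.get(outcome, {}).items():
            lin = lin + beta * z[predictor].to_numpy()
        b = rng.normal(0.0, sd_tot * np.sqrt(rho), n_subjects)[subj_index]
        e = rng.normal(0.0, sd_tot * np.sqrt(1 - rho), len(df))
        df[outcome] = lin + b + e

    return df


def simulate_repeated_measures(
    n_eyes: int,
    subject_sd: float,
    error_sd: float,
    metric_name: str = "fd",
    sessions: tuple[str, ...] = ("visit1_scan1", "visit1_scan2", "visit2_scan1"),
    mean: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format repeated scans of one eye per subject, for reliability
    studies: value = mean + eye effect (SD ``subject_sd``) + scan error
    (SD ``error_sd``).  The population intraclass correlation is
    ``subject_sd**2 / (subject_sd**2 + error_sd**2)``.
    """
    rng = np.random.default_rng(seed)
    eye_effect = rng.normal(0.0, subject_sd, n_eyes)
    rows = []
    for i in range(n_eyes):
        for session in sessions:
            rows.append(
                {
                    "eye_id": f"E{i:05d}",
                    "session_label": session,
                    "metric_name": metric_name,
                    "value": mean + eye_effect[i] + rng.normal(0.0, error_sd),
                }
            )
    return pd.DataFrame(rows)
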