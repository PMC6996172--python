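"""Clustered association analysis of deep-plexus metrics.

The workflow mirrors the clinical analysis this package models: for each
outcome (FAZ area, vessel density, fractal dimension),

1. standardize the continuous predictors on the analysed rows, so
   coefficients read "per SD increase";
2. screen every candidate factor in a univariate marginal model;
3. fit a multivariable model on the factors that screened significant
   (p < 0.05 two-sided by default);
4. repeat everything on the subset without diabetic macular edema, whose
   cystic fluid can mimic non-perfusion in the deep slab.

All models are generalized estimating equations (GEE) with identity link,
Gaussian errors, subjects as clusters (fellow eyes are correlated), an
exchangeable working correlation, and robust (sandwich) standard errors.
DR severity enters as three dummies against the no-DR reference and is
screened as a block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "snellen_to_logmar",
    "standardize",
    "fit_gee",
    "univariate_screen",
    "run_full_analysis",
    "OUTCOMES",
    "CANDIDATE_FACTORS",
    "CONTINUOUS_FACTORS",
    "DegenerateCovariateError",
    "CollinearityError",
]

OUTCOMES = ("faz_area_mm2", "vd_pct", "fd")

CONTINUOUS_FACTORS = (
    "logmar",
    "axial_length_mm",
    "cst_um",
    "gcipl_um",
    "choroid_um",
    "age_y",
    "dm_duration_y",
    "bmi",
    "sbp",
    "dbp",
    "hba1c_pct",
    "total_chol",
    "ldl",
)

# dr_severity expands to three dummies vs the no-DR reference
CANDIDATE_FACTORS = ("dr_severity", "dme") + CONTINUOUS_FACTORS

_DR_DUMMIES = {"dr_mild": "mild", "dr_moderate": "moderate", "dr_severe": "severe"}


class DegenerateCovariateError(ValueError):
    """A column to standardize has zero variance."""


class CollinearityError(ValueError):
    """The model design matrix is singular."""


@dataclass(frozen=True)
class AssociationResult:
    """One predictor's row of one fitted model (per-SD scale for
    continuous predictors, dummy-vs-reference for categorical ones)."""

    outcome: str
    predictor: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    model_stage: str  # univariate | multivariable
    cohort_variant: str = "all"  # all | no_dme

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("CI must bracket beta")
        if self.se <= 0:
            raise ValueError("SE must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")


def snellen_to_logmar(numerator: float, denominator: float) -> float:
    """Convert a Snellen fraction to logMAR: log10(denominator/numerator).

    20/20 -> 0.0; 20/200 -> 1.0; 6/12 -> 0.301.
    """
    if numerator <= 0 or denominator <= 0:
        raise ValueError("Snellen numerator and denominator must be positive")
    return math.log10(denominator / numerator)


def standardize(cohort: pd.DataFrame, continuous_vars: list[str]) -> pd.DataFrame:
    """Z-score the named columns on the given rows (ddof=1); other columns
    untouched.  Coefficients of the standardized columns read per-SD."""
    out = cohort.copy()
    for name in continuous_vars:
        col = pd.to_numeric(out[name])
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise DegenerateCovariateError(f"column {name!r} has zero or undefined SD")
        out[name] = (col - col.mean()) / sd
    return out


def _design(cohort: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """Expand predictors into numeric design columns (DR -> three dummies)."""
    cols: dict[str, np.ndarray] = {}
    for name in predictors:
        if name == "dr_severity":
            for dummy, level in _DR_DUMMIES.items():
                cols[dummy] = (cohort["dr_severity"] == level).to_numpy(float)
        elif name == "dme":
            cols["dme"] = cohort["dme"].to_numpy(float)
        else:
            cols[name] = pd.to_numeric(cohort[name]).to_numpy(float)
    return pd.DataFrame(cols, index=cohort.index)


def fit_gee(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    model_stage: str = "multivariable",
    cohort_variant: str = "all",
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Marginal linear model of one outcome, clustered by subject.

    Identity link, exchangeable working correlation, robust sandwich SEs;
    Wald CIs and p-values per predictor.  With one eye per subject and no
    residual correlation this degenerates to OLS.
    """
    data = cohort.dropna(subset=[outcome]).copy()
    if data["subject_id"].nunique() < 2:
        raise ValueError("need >= 2 subject clusters")
    X = _design(data, predictors)
    complete = X.notna().all(axis=1)
    data, X = data[complete], X[complete]
    # a dummy for an absent level (or an absent exposure) carries no
    # information: drop it instead of failing on a singular design
    X = X.loc[:, X.nunique() > 1]
    if X.shape[1] == 0:
        return []
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        # name the aliased columns for the caller
        u, s, vt = np.linalg.svd(exog.to_numpy())
        aliased = [
            exog.columns[i]
            for i in np.nonzero(np.abs(vt[s.size - 1]) > 1e-6)[0]
        ]
        raise CollinearityError(f"singular design; aliased terms: {aliased}")

    model = sm.GEE(
        data[outcome].to_numpy(float),
        exog,
        groups=data["subject_id"],
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    fit = model.fit()  # robust covariance is the statsmodels GEE default
    zcrit = stats.norm.ppf(1 - alpha / 2)
    results = []
    for name in X.columns:
        beta = float(fit.params[name])
        se = float(fit.bse[name])
        p = float(fit.pvalues[name])
        results.append(
            AssociationResult(
                outcome=outcome,
                predictor=name,
                beta=beta,
                se=se,
                ci_low=beta - zcrit * se,
                ci_high=beta + zcrit * se,
                p=max(p, np.finfo(float).tiny),
                model_stage=model_stage,
                cohort_variant=cohort_variant,
            )
        )
    return results


def univariate_screen(
    cohort: pd.DataFrame,
    outcome: str,
    candidate_factors: list[str],
    alpha: float = 0.05,
    cohort_variant: str = "all",
) -> tuple[list[str], list[AssociationResult]]:
    """Fit one single-factor GEE per candidate; keep factors with p < alpha.

    DR severity is screened as a block: selected if any of its three
    dummies is significant.  Returns (selected factors, all univariate
    rows).
    """
    if not candidate_factors:
        raise ValueError("candidate_factors must be non-empty")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    selected, rows = [], []
    for factor in candidate_factors:
        res = fit_gee(
            cohort, outcome, [factor],
            model_stage="univariate", cohort_variant=cohort_variant, alpha=alpha,
        )
        rows.extend(res)
        if any(r.p < alpha for r in res):
            selected.append(factor)
    return selected, rows


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "predictor": r.predictor,
                "stage": r.model_stage,
                "variant": r.cohort_variant,
                "beta": r.beta,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
            }
            for r in results
        ]
    )


def run_full_analysis(
    cohort: pd.DataFrame,
    candidate_factors: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """The complete workflow over both cohort variants.

    For each outcome: standardize continuous candidates (on the variant's
    rows, so per-SD effects are relative to that analysis set), screen
    univariately, fit the multivariable model on the selected factors.
    The ``no_dme`` variant repeats everything on eyes without DME.
    Returns a long-format table of all univariate and multivariable rows.
    """
    candidates = list(candidate_factors or CANDIDATE_FACTORS)
    continuous = [c for c in candidates if c in CONTINUOUS_FACTORS]
    all_rows: list[AssociationResult] = []
    for variant in ("all", "no_dme"):
        subset = cohort if variant == "all" else cohort[~cohort["dme"].astype(bool)]
        subset = standardize(subset, continuous)
        variant_candidates = (
            candidates if variant == "all" else [c for c in candidates if c != "dme"]
        )
        for outcome in OUTCOMES:
            selected, uni_rows = univariate_screen(
                subset, outcome, variant_candidates, alpha=alpha, cohort_variant=variant
            )
            all_rows.extend(uni_rows)
            if selected:
                all_rows.extend(
                    fit_gee(
                        subset, outcome, selected,
                        model_stage="multivariable", cohort_variant=variant, alpha=alpha,
                    )
                )
    return results_to_frame(all_rows)
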