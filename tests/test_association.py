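"""Clustered association workflow: acuity conversion, standardization,
GEE estimation, screening, and the full two-variant analysis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from octa_dcp.association import (
    CANDIDATE_FACTORS,
    CollinearityError,
    DegenerateCovariateError,
    fit_gee,
    run_full_analysis,
    snellen_to_logmar,
    standardize,
    univariate_screen,
)
from octa_dcp.cohort import EffectSpec, generate_cohort


class TestSnellenToLogmar:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(20, 20, 0.0), (20, 200, 1.0), (6, 12, 0.301), (6, 6, 0.0)],
    )
    def test_known_conversions(self, num, den, expected):
        assert snellen_to_logmar(num, den) == pytest.approx(expected, abs=5e-4)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            snellen_to_logmar(0, 20)
        with pytest.raises(ValueError):
            snellen_to_logmar(20, -5)


class TestStandardize:
    def test_mean_zero_sd_one(self):
        coh = generate_cohort(100, seed=0)
        std = standardize(coh, ["age_y", "bmi"])
        for col in ("age_y", "bmi"):
            assert std[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert std[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        # untouched columns
        pd.testing.assert_series_equal(std["sbp"], coh["sbp"])

    def test_constant_column_rejected(self):
        coh = generate_cohort(50, seed=0)
        coh["age_y"] = 60.0
        with pytest.raises(DegenerateCovariateError, match="age_y"):
            standardize(coh, ["age_y"])

    def test_scale_invariance(self):
        coh = generate_cohort(80, seed=1)
        doubled = coh.copy()
        doubled["bmi"] = 2.0 * doubled["bmi"]
        a = standardize(coh, ["bmi"])["bmi"]
        b = standardize(doubled, ["bmi"])["bmi"]
        assert np.allclose(a, b)


class TestFitGee:
    def test_single_eye_independent_matches_ols(self):
        coh = generate_cohort(
            300, both_eyes_fraction=0.0,
            effects=EffectSpec(inter_eye_correlation=0.0), seed=2,
        )
        res = fit_gee(coh, "fd", ["age_y", "bmi"])
        X = sm.add_constant(coh[["age_y", "bmi"]])
        ols = sm.OLS(coh["fd"], X).fit()
        for r in res:
            assert r.beta == pytest.approx(ols.params[r.predictor], abs=1e-6)

    def test_recovers_injected_effects_within_2se(self):
        coh = generate_cohort(400, both_eyes_fraction=1.0, seed=3)
        std = standardize(coh, ["logmar", "gcipl_um", "bmi", "sbp", "age_y"])
        res = fit_gee(std, "fd", ["dr_severity", "logmar", "gcipl_um", "bmi", "sbp", "age_y"])
        spec = EffectSpec()
        injected = {
            "dr_mild": -0.307, "dr_moderate": -0.357, "dr_severe": -0.891,
            "logmar": -0.074, "gcipl_um": 0.113, "bmi": 0.077,
            "sbp": 0.062, "age_y": -0.142,
        }
        assert injected == {
            k: v for k, v in {**spec.effects["fd"]}.items()
        }  # generator defaults are what we think they are
        for r in res:
            assert abs(r.beta - injected[r.predictor]) < 2 * r.se, r.predictor

    def test_robust_se_at_least_naive_on_correlated_eyes(self):
        coh = generate_cohort(
            250, both_eyes_fraction=1.0,
            effects=EffectSpec.null(inter_eye_correlation=0.7), seed=4,
        )
        X = sm.add_constant(coh[["age_y"]].to_numpy())
        model = sm.GEE(
            coh["fd"].to_numpy(), X, groups=coh["subject_id"],
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Independence(),
        )
        robust = model.fit().bse[1]
        naive = model.fit(cov_type="naive").bse[1]
        assert robust >= naive

    def test_null_coverage_calibrated(self):
        """95% Wald CIs cover zero ~95% of the time under the null
        (clustered data, subject-level predictor)."""
        cover = 0
        n_rep = 200
        for rep in range(n_rep):
            coh = generate_cohort(
                80, both_eyes_fraction=1.0,
                effects=EffectSpec.null(), seed=10_000 + rep,
            )
            r = fit_gee(coh, "vd_pct", ["age_y"])[0]
            cover += r.ci_low <= 0.0 <= r.ci_high
        assert cover / n_rep == pytest.approx(0.95, abs=0.04)

    def test_collinear_design_rejected(self):
        coh = generate_cohort(50, seed=5)
        coh["age_copy"] = coh["age_y"]
        with pytest.raises(CollinearityError):
            fit_gee(coh, "fd", ["age_y", "age_copy"])


class TestUnivariateScreen:
    def test_strong_effect_selected(self):
        coh = generate_cohort(400, seed=6)
        std = standardize(coh, ["age_y"])
        selected, rows = univariate_screen(std, "fd", ["age_y", "dm_duration_y"])
        assert "age_y" in selected  # injected -0.142 per SD at n=400
        assert {r.model_stage for r in rows} == {"univariate"}

    def test_dr_enters_as_block(self):
        coh = generate_cohort(400, seed=7)
        selected, rows = univariate_screen(coh, "fd", ["dr_severity"])
        assert selected == ["dr_severity"]
        assert {r.predictor for r in rows} == {"dr_mild", "dr_moderate", "dr_severe"}

    def test_null_factor_selection_rate_near_alpha(self):
        hits = 0
        n_rep = 120
        for rep in range(n_rep):
            coh = generate_cohort(
                60, effects=EffectSpec.null(), seed=20_000 + rep
            )
            selected, _ = univariate_screen(coh, "faz_area_mm2", ["total_chol"])
            hits += bool(selected)
        assert hits / n_rep < 0.12  # ~5% nominal, binomial noise allowed

    def test_empty_inputs_rejected(self):
        coh = generate_cohort(50, seed=8)
        with pytest.raises(ValueError):
            univariate_screen(coh, "fd", [])
        with pytest.raises(ValueError):
            univariate_screen(coh.iloc[:0], "fd", ["age_y"])


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(250, seed=9)


class TestRunFullAnalysis:

    def test_zero_dme_variants_identical(self):
        coh = generate_cohort(150, seed=10)
        coh["dme"] = False
        res = run_full_analysis(coh)
        a = res[res.variant == "all"].drop(columns="variant").reset_index(drop=True)
        b = res[res.variant == "no_dme"].drop(columns="variant").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_no_dme_variant_row_arithmetic(self, cohort):
        n_dme = int(cohort["dme"].sum())
        assert n_dme > 0
        sub = cohort[~cohort["dme"]]
        assert len(sub) == len(cohort) - n_dme

    def test_recovered_multivariable_signs_match_injected(self):
        """With the default effect magnitudes at n=400 subjects, every
        multivariable coefficient keeps its injected sign."""
        coh = generate_cohort(400, both_eyes_fraction=1.0, seed=11)
        res = run_full_analysis(coh)
        spec = EffectSpec()
        multi = res[(res.stage == "multivariable") & (res.variant == "all")]
        for _, row in multi.iterrows():
            injected = spec.effects[row.outcome].get(row.predictor)
            if injected is None or abs(injected) < 0.1:
                continue  # tiny effects may not be screened/estimated stably
            assert np.sign(row.beta) == np.sign(injected), (row.outcome, row.predictor)

    def test_output_is_long_format_with_both_stages(self, cohort):
        res = run_full_analysis(cohort)
        assert set(res.columns) == {
            "outcome", "predictor", "stage", "variant",
            "beta", "se", "ci_low", "ci_high", "p",
        }
        assert set(res.stage) == {"univariate", "multivariable"}
        assert set(res.variant) == {"all", "no_dme"}
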