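"""Risk model: selection criteria, fit, scoring, calibration, Z-scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from bctrisk.synthetic_data import (
    CohortSpec,
    generate_cohort,
    split_development_validation,
    MODEL_COVARIATES,
    TRAIT_NAMES,
    RISK_DIRECTIONS,
)
from bctrisk.evaluation import recode_outcomes, auc
from bctrisk.risk_model import (
    RiskModel,
    select_traits,
    fit_logistic,
    compute_logit,
    score,
    display_score,
    calibrate_sex_offsets,
    fit_zscore_reference,
    zscore,
    adverse_flag,
    impute_missing_traits,
    round_half_up,
)


# ---------------------------------------------------------------------------
# Scoring arithmetic
# ---------------------------------------------------------------------------

def _unit_model(**coef):
    coefs = {c: coef.get(c, 0.0) for c in MODEL_COVARIATES}
    return RiskModel(intercept=coef.get("intercept", 0.0), coefficients=coefs)


def _row(**kv):
    base = {c: 0.0 for c in MODEL_COVARIATES}
    base.update(kv)
    return pd.DataFrame([base])


class TestScore:
    def test_logit_zero_maps_to_fifty(self):
        assert score(_unit_model(), _row())[0] == pytest.approx(50.0)

    def test_logit_ln3_maps_to_seventyfive(self):
        m = _unit_model(intercept=np.log(3.0))
        assert score(m, _row())[0] == pytest.approx(75.0)

    def test_saturation(self):
        assert score(_unit_model(intercept=80.0), _row())[0] == pytest.approx(100.0)
        assert score(_unit_model(intercept=-80.0), _row())[0] == pytest.approx(0.0)

    def test_sex_offset_is_additive(self):
        m = _unit_model(intercept=0.3, age=0.1)
        x = _row(age=2.0, sex="F")
        base = compute_logit(m, x)[0]
        m.sex_offsets["F"] = 0.7
        assert compute_logit(m, x)[0] == pytest.approx(base + 0.7)

    def test_hand_computed_dot_product(self):
        m = _unit_model(intercept=-1.0, age=0.02, femoral_strength=-0.001,
                        hip_width=0.05)
        x = _row(age=80.0, femoral_strength=3000.0, hip_width=180.0, sex="M")
        m.sex_offsets["M"] = 0.25
        expected = -1.0 + 0.02 * 80 - 0.001 * 3000 + 0.05 * 180 + 0.25
        assert compute_logit(m, x)[0] == pytest.approx(expected)
        assert score(m, x)[0] == pytest.approx(100 * expit(expected))

    def test_missing_covariate_errors(self):
        with pytest.raises(ValueError, match="missing"):
            compute_logit(_unit_model(), pd.DataFrame([{"age": 70.0}]))

    def test_nan_covariate_errors(self):
        with pytest.raises(ValueError, match="impute"):
            compute_logit(_unit_model(), _row(age=np.nan))

    def test_display_rounding_half_up(self):
        assert display_score(90.5) == 91
        assert display_score(90.4999) == 90
        assert round_half_up(12.65, 1) == pytest.approx(12.7)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class TestFit:
    def test_parameter_recovery_large_n(self, rng):
        """With covariates drawn iid and outcomes from a known logistic
        model at n = 20000, the fit recovers each coefficient within 10%."""
        n = 20000
        true = {"age": 0.4, "femoral_strength": -0.8, "trab_cort_ratio": -0.3,
                "fat_thickness": -0.2, "muscle_area": -0.35,
                "intramuscular_fat": 0.45, "fn_volume": 0.5, "hip_width": 0.15}
        X = pd.DataFrame(rng.standard_normal((n, 8)), columns=MODEL_COVARIATES)
        eta = -1.0 + sum(true[c] * X[c] for c in MODEL_COVARIATES)
        X["case"] = rng.uniform(size=n) < expit(eta)
        model = fit_logistic(X)
        assert model.intercept == pytest.approx(-1.0, rel=0.1)
        for c in MODEL_COVARIATES:
            # absolute floor at ~3 sampling SEs for the small coefficients,
            # where 10% relative would be below the estimator's own noise
            tol = max(0.10 * abs(true[c]), 0.05)
            assert abs(model.coefficients[c] - true[c]) <= tol, c

    def test_single_class_errors(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 8)), columns=MODEL_COVARIATES)
        X["case"] = False
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(X)

    def test_duplicated_data_same_fit(self, rng):
        n = 400
        X = pd.DataFrame(rng.standard_normal((n, 8)), columns=MODEL_COVARIATES)
        X["case"] = rng.uniform(size=n) < expit(X["age"] - 0.2)
        m1 = fit_logistic(X)
        m2 = fit_logistic(pd.concat([X, X], ignore_index=True))
        for c in MODEL_COVARIATES:
            assert m1.coefficients[c] == pytest.approx(m2.coefficients[c], abs=1e-6)

    def test_perfect_separation_errors(self):
        X = pd.DataFrame({c: np.linspace(-1, 1, 40) for c in MODEL_COVARIATES})
        X["case"] = X["age"] > 0
        with pytest.raises(ValueError):
            fit_logistic(X)

    def test_serialization_round_trip(self, tmp_path, rng):
        n = 500
        X = pd.DataFrame(rng.standard_normal((n, 8)), columns=MODEL_COVARIATES)
        X["case"] = rng.uniform(size=n) < expit(X["age"])
        model = fit_logistic(X)
        model.sex_offsets = {"F": 0.5, "M": -0.25}
        path = tmp_path / "model.json"
        model.to_json(str(path))
        back = RiskModel.from_json(str(path))
        assert back.coefficients == model.coefficients
        assert back.sex_offsets == model.sex_offsets


# ---------------------------------------------------------------------------
# Trait selection
# ---------------------------------------------------------------------------

class TestSelectTraits:
    def test_high_r2_candidate_rejected(self, big_cohort):
        """A trait engineered with R^2 vs strength of 0.36 in the random
        sample fails the weak-correlation criterion."""
        spec = CohortSpec(n_per_sex={"F": 8000, "M": 4000}, seed=3)
        spec.trait_params["fat_thickness"]["r2_strength"] = {"F": 0.36, "M": 0.36}
        # equalize sex means so the pooled correlation reflects the
        # within-sex structure rather than between-sex mean offsets
        spec.trait_params["fat_thickness"]["mean"] = {"F": 20.0, "M": 20.0}
        spec.trait_params["femoral_strength"]["mean"] = {"F": 4000.0, "M": 4000.0}
        spec.trait_params["femoral_strength"]["sd"] = {"F": 1000.0, "M": 1000.0}
        table, _ = generate_cohort(spec)
        analysis, _ = recode_outcomes(table, 5)
        _, audit = select_traits(analysis)
        row = audit.set_index("trait").loc["fat_thickness"]
        assert row["r2_strength"] > 0.25
        assert not row["pass_r2"]
        assert not row["selected"]

    def test_noise_candidate_rejected(self):
        """A pure-noise trait is rejected by the univariate p < 1e-4
        criterion in every replicate."""
        for seed in range(8):
            spec = CohortSpec(n_per_sex={"F": 8000, "M": 3500}, seed=100 + seed)
            table, _ = generate_cohort(spec)
            analysis, _ = recode_outcomes(table, 5)
            rng = np.random.default_rng(seed)
            analysis = analysis.copy()
            analysis["noise_trait"] = rng.standard_normal(len(analysis))
            _, audit = select_traits(
                analysis, candidates=list(TRAIT_NAMES) + ["noise_trait"]
            )
            row = audit.set_index("trait").loc["noise_trait"]
            assert not row["pass_univariate"], seed
            assert not row["selected"], seed

    def test_true_effect_traits_retained(self):
        """Every generated trait carries a real effect, so all six are
        retained once the sample is large enough for the p < 1e-4
        criteria to resolve the weakest coefficients."""
        spec = CohortSpec(n_per_sex={"F": 90000, "M": 40000}, seed=17)
        table, _ = generate_cohort(spec)
        analysis, _ = recode_outcomes(table, 5)
        selected, audit = select_traits(analysis)
        assert set(selected) == set(TRAIT_NAMES), audit.to_string()


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted(big_cohort):
    table, _ = big_cohort
    dev, val = split_development_validation(table)
    analysis, _ = recode_outcomes(dev, 5)
    model = fit_logistic(analysis)
    return table, dev, val, model


class TestCalibration:
    def test_positive_rate_matches_reference(self, fitted):
        table, _, _, model = fitted
        rs = table[table["random_sample"]]
        cal = calibrate_sex_offsets(model, rs)
        for sex, sub in rs.groupby("sex"):
            bct_rate = (score(cal, sub) >= 75.0).mean()
            frax_rate = (sub["frax_hip_risk"] >= 3.0).mean()
            assert abs(bct_rate - frax_rate) <= 1.0 / len(sub) + 1e-12, sex

    def test_fixed_point_offset_near_zero(self, fitted):
        """If the reference rate already equals the uncalibrated positive
        rate, the calibrated offset is (numerically) zero."""
        table, _, _, model = fitted
        rs = table[table["random_sample"]].copy()
        rs["frax_hip_risk"] = score(model, rs)  # reference = own score
        cal = calibrate_sex_offsets(model, rs, frax_threshold=75.0)
        for sex, sub in rs.groupby("sex"):
            # offset sits within the zero-width plateau of the empirical
            # rate step function: numerically near zero, same positives
            assert abs(cal.sex_offsets[sex]) < 0.05
            assert np.array_equal(
                score(model, sub) >= 75.0, score(cal, sub) >= 75.0
            )

    def test_auc_sens_spec_unchanged(self, fitted):
        """Per-sex discrimination is invariant under the calibration
        constant (thresholds transformed accordingly)."""
        table, _, val, model = fitted
        rs = table[table["random_sample"]]
        cal = calibrate_sex_offsets(model, rs)
        analysis, _ = recode_outcomes(val, 5)
        thr_logit = np.log(3.0)
        for sex, sub in analysis.groupby("sex"):
            y = sub["case"].to_numpy(bool)
            pre = compute_logit(model, sub)
            post = pre + cal.sex_offsets[sex]
            assert auc(pre, y).auc == pytest.approx(auc(post, y).auc, abs=1e-12)
            pre_pos = pre >= thr_logit - cal.sex_offsets[sex]
            post_pos = post >= thr_logit
            assert np.array_equal(pre_pos, post_pos)

    def test_rank_order_preserved(self, fitted):
        table, _, _, model = fitted
        rs = table[table["random_sample"]]
        cal = calibrate_sex_offsets(model, rs)
        for sex, sub in rs.groupby("sex"):
            a = np.argsort(score(model, sub), kind="stable")
            b = np.argsort(score(cal, sub), kind="stable")
            assert np.array_equal(a, b)

    def test_degenerate_target_warns_and_pins(self, fitted):
        table, _, _, model = fitted
        rs = table[table["random_sample"]].copy()
        rs["frax_hip_risk"] = 100.0  # everyone positive
        with pytest.warns(UserWarning, match="pinned"):
            cal = calibrate_sex_offsets(model, rs)
        assert all(off == 50.0 for off in cal.sex_offsets.values())

    def test_monotone_directions_of_fitted_model(self, fitted):
        """With sign-correct coefficients, raising a risk-increasing trait
        never lowers the score and vice versa."""
        _, _, _, model = fitted
        base = {c: 0.0 for c in MODEL_COVARIATES}
        base.update(age=75.0, femoral_strength=4000.0, trab_cort_ratio=0.5,
                    fat_thickness=20.0, muscle_area=30.0, intramuscular_fat=25.0,
                    fn_volume=10.0, hip_width=180.0)
        s0 = score(model, pd.DataFrame([base]))[0]
        for trait, direction in RISK_DIRECTIONS.items():
            bumped = dict(base)
            bumped[trait] = base[trait] * 1.05 + 1.0
            s1 = score(model, pd.DataFrame([bumped]))[0]
            if direction > 0:
                assert s1 >= s0, trait
            else:
                assert s1 <= s0, trait


# ---------------------------------------------------------------------------
# Z-scores and imputation
# ---------------------------------------------------------------------------

def _reference_table(rng, n=5000):
    age = rng.uniform(65, 89, n)
    df = pd.DataFrame({
        "sex": np.repeat(["F", "M"], n // 2)[:n],
        "age": age,
        "muscle_area": 60 - 0.4 * age + rng.normal(0, 5, n),
        "hip_width": 180 + rng.normal(0, 9, n),  # age-independent
    })
    return df


class TestZScores:
    def test_definition_and_antisymmetry(self, rng):
        df = _reference_table(rng)
        ref = fit_zscore_reference(df, traits=("muscle_area", "hip_width"))
        p = ref.params[("F", "muscle_area")]
        mean80 = p["intercept"] + p["slope"] * 80.0
        assert zscore(ref, "F", "muscle_area", 80.0, mean80) == pytest.approx(0.0)
        z2 = zscore(ref, "F", "muscle_area", 80.0, mean80 + 2 * p["se"])
        assert z2 == pytest.approx(2.0)
        zneg = zscore(ref, "F", "muscle_area", 80.0, mean80 - 2 * p["se"])
        assert zneg == pytest.approx(-2.0)
        # low muscle area is the adverse direction
        assert adverse_flag("muscle_area", zneg)
        assert not adverse_flag("muscle_area", z2)

    def test_age_independent_trait(self, rng):
        """For a trait independent of age the slope vanishes and the
        residual SE approaches the marginal SD."""
        df = _reference_table(rng)
        ref = fit_zscore_reference(df, traits=("hip_width",))
        for sex in ("F", "M"):
            p = ref.params[(sex, "hip_width")]
            assert abs(p["slope"]) < 0.05
            assert p["se"] == pytest.approx(9.0, rel=0.05)

    def test_exact_linear_trait_flagged_degenerate(self, rng):
        df = _reference_table(rng)
        df["muscle_area"] = 60 - 0.4 * df["age"]  # exact linear function
        ref = fit_zscore_reference(df, traits=("muscle_area",))
        assert ref.params[("F", "muscle_area")]["degenerate"]
        with pytest.raises(ValueError, match="degenerate"):
            zscore(ref, "F", "muscle_area", 70.0, 30.0)

    def test_exclusion_rules(self, rng):
        df = _reference_table(rng, n=200)
        df.loc[df.index[:20], "age"] = 90.0          # age-coded records
        df["imputed_muscle_area"] = False
        df.loc[df.index[20:30], "imputed_muscle_area"] = True
        ref = fit_zscore_reference(df, traits=("muscle_area",))
        n_used = sum(ref.params[(s, "muscle_area")]["n"] for s in ("F", "M"))
        assert n_used == 170

    def test_insufficient_records(self, rng):
        df = _reference_table(rng, n=10)
        with pytest.raises(ValueError, match="fewer"):
            fit_zscore_reference(df, traits=("muscle_area",))


class TestImputation:
    def test_complete_record_unchanged(self, rng):
        df = _reference_table(rng, n=400)
        out = impute_missing_traits(df, df, traits=("muscle_area",))
        pd.testing.assert_series_equal(out["muscle_area"], df["muscle_area"])
        assert not out["imputed_muscle_area"].any()

    def test_prediction_is_age_regression(self, rng):
        rs = _reference_table(rng, n=2000)
        ref = fit_zscore_reference(rs, traits=("muscle_area",), apply_exclusions=False)
        target = _reference_table(rng, n=10)
        target.loc[target.index[0], "muscle_area"] = np.nan
        target.loc[target.index[0], "age"] = 80.0
        out = impute_missing_traits(target, rs, traits=("muscle_area",))
        sex = target.iloc[0]["sex"]
        p = ref.params[(sex, "muscle_area")]
        assert out.iloc[0]["muscle_area"] == pytest.approx(p["intercept"] + p["slope"] * 80.0)
        assert out.iloc[0]["imputed_muscle_area"]

    def test_masked_value_returns_regression_prediction(self, rng):
        """Round trip: masking a known value recovers the regression
        prediction, not the original value (imputation is a conditional
        mean, not a reconstruction)."""
        rs = _reference_table(rng, n=3000)
        victim = rs.iloc[[10]].copy()
        true_value = victim.iloc[0]["muscle_area"]
        victim.loc[victim.index, "muscle_area"] = np.nan
        out = impute_missing_traits(victim, rs, traits=("muscle_area",))
        imputed = out.iloc[0]["muscle_area"]
        ref = fit_zscore_reference(rs, traits=("muscle_area",), apply_exclusions=False)
        p = ref.params[(victim.iloc[0]["sex"], "muscle_area")]
        pred = p["intercept"] + p["slope"] * victim.iloc[0]["age"]
        assert imputed == pytest.approx(pred)
        assert imputed != pytest.approx(true_value, abs=1e-6)

    def test_all_missing_for_sex_errors(self, rng):
        rs = _reference_table(rng, n=100)
        rs.loc[rs["sex"] == "F", "muscle_area"] = np.nan
        target = _reference_table(rng, n=4)
        target.loc[target["sex"] == "F", "muscle_area"] = np.nan
        with pytest.raises(ValueError):
            impute_missing_traits(target, rs, traits=("muscle_area",))
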