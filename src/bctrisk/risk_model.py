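"""The 0-100 hip-fracture risk score: trait selection, logistic fit,
sex-specific logit calibration, and age-referenced trait Z-scores.

The score is ``100 * logistic(logit)`` where the logit is a linear
function of eight covariates (age, femoral strength, and six image
traits; no sex term) plus a per-sex calibration constant.  The constant
is chosen so that, in a random population sample, the fraction of each
sex scoring at or above the high-risk threshold (75) equals the fraction
at or above a reference absolute-risk threshold (10-yr hip risk >= 3.0%).
Adding a per-sex constant leaves within-sex rank order, and hence AUC,
sensitivity and specificity, unchanged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .synthetic_data import MODEL_COVARIATES, TRAIT_NAMES, RISK_DIRECTIONS

__all__ = [
    "RiskModel",
    "ZScoreReference",
    "select_traits",
    "fit_logistic",
    "compute_logit",
    "score",
    "display_score",
    "calibrate_sex_offsets",
    "fit_zscore_reference",
    "zscore",
    "impute_missing_traits",
    "round_half_up",
]

SCORE_THRESHOLD_DEFAULT = 75.0
FRAX_THRESHOLD_DEFAULT = 3.0  # percent 10-yr hip risk
P_SELECT = 1e-4
R2_MAX = 0.25


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` (display convention)."""
    factor = 10.0**decimals
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)


@dataclass
class RiskModel:
    """Fitted logistic risk model with per-sex calibration offsets."""

    intercept: float
    coefficients: dict
    sex_offsets: dict = field(default_factory=lambda: {"F": 0.0, "M": 0.0})
    high_risk_threshold: float = SCORE_THRESHOLD_DEFAULT

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RiskModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class ZScoreReference:
    """Per-sex, per-trait linear age regressions of the physical traits.

    Each entry holds (slope, intercept, residual standard error, n,
    degenerate flag).  Fitted on random-sample records only, excluding
    age-coded-90 records and records with any imputed trait.
    """

    params: dict = field(default_factory=dict)  # (sex, trait) -> dict

    def predict(self, sex: str, trait: str, age: float) -> float:
        p = self.params[(sex, trait)]
        return p["intercept"] + p["slope"] * age


# ---------------------------------------------------------------------------
# Trait selection
# ---------------------------------------------------------------------------

def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10, maxiter=200)


def select_traits(
    table: pd.DataFrame,
    candidates: Sequence[str] = TRAIT_NAMES,
    outcome: str = "case",
) -> tuple[list[str], pd.DataFrame]:
    """Screen candidate traits by correlation and predictive criteria.

    A candidate is retained when (iii) its R^2 against both age and
    femoral strength in the random sample is <= 0.25, (iv) it predicts
    the outcome alone at p < 1e-4, and (v) it predicts the outcome at
    p < 1e-4 in the model containing all candidates plus age and
    strength.  (The two curation criteria - biomechanical plausibility
    and measurement reliability - are recorded upstream, not here.)
    Returns the selected list and an audit table.
    """
    if outcome not in table:
        raise ValueError(f"table lacks outcome column {outcome!r}")
    rs = table[table["random_sample"]] if "random_sample" in table else table
    y = table[outcome].to_numpy(dtype=float)
    rows = []
    # full model for criterion (v): age + strength + all candidates
    full_cols = ["age", "femoral_strength"] + list(candidates)
    Xf = sm.add_constant(table[full_cols].to_numpy(dtype=float))
    full_fit = _fit_logit(y, Xf)
    full_p = dict(zip(full_cols, full_fit.pvalues[1:]))
    for trait in candidates:
        r2_age = _univariate_r2(rs["age"], rs[trait])
        r2_str = _univariate_r2(rs["femoral_strength"], rs[trait])
        uni_fit = _fit_logit(y, sm.add_constant(table[[trait]].to_numpy(dtype=float)))
        p_uni = float(uni_fit.pvalues[1])
        p_full = float(full_p[trait])
        ok_r2 = (r2_age <= R2_MAX) and (r2_str <= R2_MAX)
        ok_uni = p_uni < P_SELECT
        ok_full = p_full < P_SELECT
        rows.append(
            {
                "trait": trait,
                "r2_age": r2_age,
                "r2_strength": r2_str,
                "p_univariate": p_uni,
                "p_full_model": p_full,
                "pass_r2": ok_r2,
                "pass_univariate": ok_uni,
                "pass_full_model": ok_full,
                "selected": ok_r2 and ok_uni and ok_full,
            }
        )
    audit = pd.DataFrame(rows)
    selected = audit.loc[audit["selected"], "trait"].tolist()
    return selected, audit


def _univariate_r2(x: pd.Series, y: pd.Series) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# Model fit and scoring
# ---------------------------------------------------------------------------

def fit_logistic(
    table: pd.DataFrame,
    covariates: Sequence[str] = MODEL_COVARIATES,
    outcome: str = "case",
    high_risk_threshold: float = SCORE_THRESHOLD_DEFAULT,
) -> RiskModel:
    """Maximum-likelihood logistic fit of the outcome on the covariates.

    The problem is convex, so the fit is deterministic given the data;
    Newton iterations stop at relative log-likelihood change < 1e-10.
    Raises on a one-class outcome or on perfect separation.
    """
    y = table[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; cannot fit")
    X = sm.add_constant(table[list(covariates)].to_numpy(dtype=float))
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        fit = _fit_logit(y, X)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "logistic fit failed (perfect separation or singular design); "
            "reduce covariates or add data"
        ) from exc
    if not fit.mle_retvals.get("converged", True) or np.any(~np.isfinite(fit.params)):
        raise ValueError("logistic fit did not converge")
    params = fit.params
    return RiskModel(
        intercept=float(params[0]),
        coefficients={c: float(b) for c, b in zip(covariates, params[1:])},
        high_risk_threshold=high_risk_threshold,
    )


def compute_logit(model: RiskModel, x: pd.DataFrame | dict) -> np.ndarray:
    """Linear predictor: intercept + sum(coef * covariate) + sex offset."""
    if isinstance(x, dict):
        x = pd.DataFrame([x])
    missing = [c for c in model.coefficients if c not in x.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    logit = np.full(len(x), model.intercept, dtype=float)
    for cov, beta in model.coefficients.items():
        vals = x[cov].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"covariate {cov} has missing values; impute first")
        logit += beta * vals
    if "sex" in x.columns:
        offs = x["sex"].map(model.sex_offsets).to_numpy(dtype=float)
        logit += offs
    return logit


def score(model: RiskModel, x: pd.DataFrame | dict) -> np.ndarray:
    """Continuous risk score in [0, 100]: 100 * logistic(logit)."""
    return 100.0 * expit(compute_logit(model, x))


def display_score(value: float | np.ndarray) -> np.ndarray:
    """Integer display rounding (half up) of the continuous score."""
    return np.vectorize(lambda v: int(round_half_up(v, 0)))(value)


# ---------------------------------------------------------------------------
# Sex-specific calibration
# ---------------------------------------------------------------------------

def calibrate_sex_offsets(
    model: RiskModel,
    random_sample: pd.DataFrame,
    frax_threshold: float = FRAX_THRESHOLD_DEFAULT,
    score_threshold: float = SCORE_THRESHOLD_DEFAULT,
    frax_column: str = "frax_hip_risk",
) -> RiskModel:
    """Set per-sex logit offsets so the positive-test rate at
    ``score >= score_threshold`` matches the reference positive rate at
    ``frax >= frax_threshold`` in the random sample, per sex.

    Solved by bisection on the offset in [-50, 50] logit units (the
    positive rate is monotone non-decreasing in the offset); the achieved
    rate difference is at most 1/n_sex up to ties in the empirical score
    distribution.  A target prevalence of exactly 0 or 1 pins the offset
    at the bracket bound with a warning.
    """
    out = RiskModel(
        intercept=model.intercept,
        coefficients=dict(model.coefficients),
        sex_offsets=dict(model.sex_offsets),
        high_risk_threshold=score_threshold,
    )
    thr_logit = np.log(score_threshold / (100.0 - score_threshold))
    for sex, sub in random_sample.groupby("sex"):
        target = float((sub[frax_column] >= frax_threshold).mean())
        base = compute_logit(
            RiskModel(model.intercept, model.coefficients), sub
        )
        n = len(sub)

        def rate(offset: float) -> float:
            return float((base + offset >= thr_logit).mean())

        lo, hi = -50.0, 50.0
        if target <= 0.0 or target >= 1.0:
            offset = hi if target >= 1.0 else lo
            warnings.warn(
                f"target prevalence for sex {sex} is {target}; offset pinned "
                f"to bracket bound {offset}"
            )
        else:
            while hi - lo > 1e-8:
                mid = 0.5 * (lo + hi)
                if rate(mid) < target:
                    lo = mid
                else:
                    hi = mid
            offset = hi if abs(rate(hi) - target) <= abs(rate(lo) - target) else lo
        out.sex_offsets[sex] = float(offset)
    return out


# ---------------------------------------------------------------------------
# Z-scores and imputation
# ---------------------------------------------------------------------------

def fit_zscore_reference(
    random_sample: pd.DataFrame,
    traits: Sequence[str] = MODEL_COVARIATES[1:],
    min_per_sex: int = 10,
    apply_exclusions: bool = True,
) -> ZScoreReference:
    """Per-sex ordinary least-squares age regressions of each trait.

    With ``apply_exclusions`` (the default, used for Z-score references)
    records with age coded 90 or any imputed trait are omitted; the
    imputation path reuses this fit without exclusions.
    """
    ref = ZScoreReference()
    df = random_sample
    if apply_exclusions:
        keep = df["age"] < 90.0
        imput_cols = [c for c in df.columns if c.startswith("imputed_")]
        for c in imput_cols:
            keep &= ~df[c].fillna(False).astype(bool)
        df = df[keep]
    for sex, sub in df.groupby("sex"):
        if len(sub) < min_per_sex:
            raise ValueError(f"fewer than {min_per_sex} usable records for sex {sex}")
        age = sub["age"].to_numpy(dtype=float)
        A = np.column_stack([np.ones_like(age), age])
        for trait in traits:
            yv = sub[trait].to_numpy(dtype=float)
            ok = ~np.isnan(yv)
            if ok.sum() < min_per_sex:
                raise ValueError(
                    f"fewer than {min_per_sex} non-missing {trait} records for sex {sex}"
                )
            coef, *_ = np.linalg.lstsq(A[ok], yv[ok], rcond=None)
            resid = yv[ok] - A[ok] @ coef
            dof = ok.sum() - 2
            se = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else 0.0
            degenerate = se < 1e-8 * max(1.0, float(np.std(yv[ok])), 1e-8) or se == 0.0
            ref.params[(sex, trait)] = {
                "intercept": float(coef[0]),
                "slope": float(coef[1]),
                "se": se,
                "n": int(ok.sum()),
                "degenerate": bool(degenerate),
            }
    return ref


def zscore(ref: ZScoreReference, sex: str, trait: str, age: float, value: float) -> float:
    """Age-referenced trait Z-score: (value - age-predicted mean) / SE.

    The raw signed Z is returned; pair it with ``RISK_DIRECTIONS`` to
    flag deviations in the risk-increasing direction for display.
    """
    if (sex, trait) not in ref.params:
        raise KeyError(f"no reference for sex={sex}, trait={trait}")
    p = ref.params[(sex, trait)]
    if p["degenerate"]:
        raise ValueError(f"degenerate age-regression reference for {trait} ({sex})")
    return (value - ref.predict(sex, trait, age)) / p["se"]


def adverse_flag(trait: str, z: float) -> bool:
    """Whether a Z-score deviates in the risk-increasing direction."""
    return bool(np.sign(z) == RISK_DIRECTIONS[trait]) and z != 0.0


def impute_missing_traits(
    table: pd.DataFrame,
    random_sample: pd.DataFrame,
    traits: Sequence[str] = TRAIT_NAMES,
) -> pd.DataFrame:
    """Replace missing trait values by sex- and age-based regression
    predictions from the random sample, retaining per-trait imputed
    flags."""
    ref = fit_zscore_reference(random_sample, traits=traits, apply_exclusions=False)
    out = table.copy()
    for trait in traits:
        flag = f"imputed_{trait}"
        if flag not in out:
            out[flag] = False
        missing = out[trait].isna()
        if not missing.any():
            continue
        for sex in out.loc[missing, "sex"].unique():
            if (sex, trait) not in ref.params:
                raise ValueError(
                    f"trait {trait} missing for all random-sample records of sex {sex}"
                )
            sel = missing & (out["sex"] == sex)
            ages = out.loc[sel, "age"].to_numpy(dtype=float)
            p = ref.params[(sex, trait)]
            out.loc[sel, trait] = p["intercept"] + p["slope"] * ages
            out.loc[sel, flag] = True
    return out
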