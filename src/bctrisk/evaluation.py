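"""Case-cohort outcome recoding and comparative test statistics.

Implements the study's evaluation toolkit: horizon recoding of the
case-cohort table with an exclusion ledger, AUC by the rank
(Mann-Whitney) formulation with a DeLong variance, DeLong's paired test
for correlated ROC curves, sensitivity/specificity with binomial
normal-approximation confidence intervals at clinical binary thresholds,
the diagnostic odds ratio, and the net sensitivity-vs-specificity gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "recode_outcomes",
    "auc",
    "delong_test",
    "sensitivity_specificity",
    "diagnostic_odds_ratio",
    "net_gain",
    "AUCResult",
    "AUCComparison",
    "ClassificationMetrics",
]

TREATMENT_EXCLUSION_DAYS = 180


# ---------------------------------------------------------------------------
# Outcome recoding
# ---------------------------------------------------------------------------

def recode_outcomes(table: pd.DataFrame, horizon: float = 5.0) -> tuple[pd.DataFrame, dict]:
    """Recode a case-cohort table to a binary fracture-within-horizon
    analysis table, with an exclusion ledger.

    Rules: patients treated >= 180 days are excluded; a fracture within
    the horizon is a case; a fracture beyond the horizon is recoded to a
    no-fracture control if the patient is in the random sample, excluded
    otherwise; a non-fracturing patient without follow-up to the horizon
    is dropped.  The ledger counts form a partition of the input rows.
    """
    if horizon not in (2.0, 5.0, 2, 5):
        raise ValueError("analysis horizon must be 2 or 5 years")
    df = table.copy()
    n_in = len(df)
    ledger = {"input": n_in}

    treated = df["treated_days"].to_numpy(dtype=float) >= TREATMENT_EXCLUSION_DAYS
    ledger["excluded_treated"] = int(treated.sum())
    df = df[~treated]

    ft = df["fracture_time"].to_numpy(dtype=float)
    has_fx = ~np.isnan(ft)
    case = has_fx & (ft <= horizon)
    late = has_fx & (ft > horizon)
    in_rs = df["random_sample"].to_numpy(dtype=bool)

    excl_late = late & ~in_rs
    recoded = late & in_rs
    ledger["excluded_late_fracture"] = int(excl_late.sum())
    ledger["recoded_to_control"] = int(recoded.sum())

    fu = df["followup_time"].to_numpy(dtype=float)
    no_fx = ~has_fx
    if np.isnan(fu[no_fx]).any():
        raise ValueError("non-fracture record with missing follow-up time")
    dropped = no_fx & (fu < horizon)
    ledger["dropped"] = int(dropped.sum())

    keep = ~(excl_late | dropped)
    out = df[keep].copy()
    out["case"] = case[keep]
    ledger["analyzed"] = len(out)
    ledger["cases"] = int(out["case"].sum())
    ledger["controls"] = int((~out["case"]).sum())
    assert (
        ledger["excluded_treated"]
        + ledger["excluded_late_fracture"]
        + ledger["dropped"]
        + ledger["analyzed"]
        == n_in
    )
    return out, ledger


# ---------------------------------------------------------------------------
# AUC and DeLong machinery
# ---------------------------------------------------------------------------

@dataclass
class AUCResult:
    auc: float
    ci: tuple[float, float]
    se: float
    n_cases: int
    n_controls: int


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    difference: float
    z: float
    p_value: float


def _split(scores: np.ndarray, outcomes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    if len(scores) != len(outcomes):
        raise ValueError("scores and outcomes differ in length")
    cases = scores[outcomes]
    controls = scores[~outcomes]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both outcome classes must be present")
    return cases, controls


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values.

    ``V10[i]`` is the fraction of controls scoring below case i (ties
    half-weighted); ``V01[j]`` the fraction of cases scoring above
    control j.  Their means equal the tie-corrected Mann-Whitney AUC.
    """
    cs = np.sort(controls)
    below = np.searchsorted(cs, cases, side="left")
    ties = np.searchsorted(cs, cases, side="right") - below
    v10 = (below + 0.5 * ties) / len(controls)
    ks = np.sort(cases)
    above = len(cases) - np.searchsorted(ks, controls, side="right")
    ties_c = np.searchsorted(ks, controls, side="right") - np.searchsorted(
        ks, controls, side="left"
    )
    v01 = (above + 0.5 * ties_c) / len(cases)
    return v10, v01


def auc(scores, outcomes, alpha: float = 0.05) -> AUCResult:
    """AUC by the tie-corrected rank formulation with a DeLong variance CI.

    Identical to the ROC area of a univariate logistic model of the same
    predictor, since the fitted probability is monotone in it.
    """
    cases, controls = _split(scores, outcomes)
    v10, v01 = _placements(cases, controls)
    a = float(v10.mean())
    var = (
        (np.var(v10, ddof=1) / len(cases) if len(cases) > 1 else 0.0)
        + (np.var(v01, ddof=1) / len(controls) if len(controls) > 1 else 0.0)
    )
    se = float(np.sqrt(var))
    zq = stats.norm.ppf(1 - alpha / 2)
    ci = (max(0.0, a - zq * se), min(1.0, a + zq * se))
    return AUCResult(a, ci, se, len(cases), len(controls))


def delong_test(scores_a, scores_b, outcomes) -> AUCComparison:
    """DeLong's paired test comparing two correlated AUCs on the same
    patients, via the covariance of the placement values."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have identical shape")
    outcomes = np.asarray(outcomes, dtype=bool)
    ca, na = _split(scores_a, outcomes)
    cb, nb = _split(scores_b, outcomes)
    v10a, v01a = _placements(ca, na)
    v10b, v01b = _placements(cb, nb)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    n1, n0 = len(ca), len(na)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n0 > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    )
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    ra = auc(scores_a, outcomes)
    rb = auc(scores_b, outcomes)
    return AUCComparison(auc_a, auc_b, ra.ci, rb.ci, diff, float(z), p)


# ---------------------------------------------------------------------------
# Binary-threshold metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassificationMetrics:
    sensitivity: float  # percent
    specificity: float  # percent
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    dor: float
    dor_ci: tuple[float, float]
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    direction: str
    undefined: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _binomial_ci(p: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Normal approximation to the binomial, truncated to [0, 1]."""
    if n == 0:
        return (np.nan, np.nan)
    zq = stats.norm.ppf(1 - alpha / 2)
    half = zq * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def diagnostic_odds_ratio(sensitivity_pct: float, specificity_pct: float) -> float:
    """DOR from percent sensitivity/specificity: odds of fracture if test
    positive over odds if test negative."""
    s = sensitivity_pct / 100.0
    c = specificity_pct / 100.0
    return (s / (1 - s)) * (c / (1 - c))


def sensitivity_specificity(
    values,
    outcomes,
    threshold: float,
    direction: str = ">=",
    alpha: float = 0.05,
) -> ClassificationMetrics:
    """Sensitivity and specificity (percent) at a binary threshold, with
    binomial normal-approximation CIs and the diagnostic odds ratio.

    ``direction`` is ``">="`` (value at or above the threshold is
    positive, as for risk scores) or ``"<="`` (as for T-scores).  Ties at
    the threshold are positive.  An empty class leaves the affected
    metric undefined (NaN, listed in ``undefined``) rather than silently
    zero.  The DOR confidence interval uses a log-odds Wald interval with
    a Haldane-Anscombe 0.5 correction when any cell is zero.
    """
    values = np.asarray(values, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    if direction == ">=":
        positive = values >= threshold
    elif direction == "<=":
        positive = values <= threshold
    else:
        raise ValueError("direction must be '>=' or '<='")
    tp = int((positive & outcomes).sum())
    fn = int((~positive & outcomes).sum())
    fp = int((positive & ~outcomes).sum())
    tn = int((~positive & ~outcomes).sum())

    undefined = []
    if tp + fn > 0:
        sens = 100.0 * tp / (tp + fn)
        sens_ci = tuple(100 * v for v in _binomial_ci(tp / (tp + fn), tp + fn, alpha))
    else:
        sens, sens_ci = np.nan, (np.nan, np.nan)
        undefined.append("sensitivity")
    if fp + tn > 0:
        spec = 100.0 * tn / (fp + tn)
        spec_ci = tuple(100 * v for v in _binomial_ci(tn / (fp + tn), fp + tn, alpha))
    else:
        spec, spec_ci = np.nan, (np.nan, np.nan)
        undefined.append("specificity")

    if undefined:
        dor, dor_ci = np.nan, (np.nan, np.nan)
        undefined.append("dor")
    else:
        cells = np.array([tp, fn, fp, tn], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        a, b, c, d = cells
        dor = float((a / b) / (c / d))
        se_log = float(np.sqrt((1 / cells).sum()))
        zq = stats.norm.ppf(1 - alpha / 2)
        dor_ci = (
            float(np.exp(np.log(dor) - zq * se_log)),
            float(np.exp(np.log(dor) + zq * se_log)),
        )

    return ClassificationMetrics(
        sensitivity=sens,
        specificity=spec,
        sens_ci=sens_ci,
        spec_ci=spec_ci,
        dor=dor,
        dor_ci=dor_ci,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        threshold=threshold,
        direction=direction,
        undefined=undefined,
    )


def net_gain(sens_a: float, spec_a: float, sens_b: float, spec_b: float) -> float:
    """Net sensitivity-vs-specificity gain of test A over test B, in
    percentage points: (sens_a - sens_b) - (spec_b - spec_a)."""
    return (sens_a - sens_b) - (spec_b - spec_a)
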