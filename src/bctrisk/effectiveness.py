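"""Clinical-effectiveness arithmetic for hip-fracture screening tests.

For a binary screening test with sensitivity S, population 5-yr fracture
risk PopFR, baseline positive-test rate TestPR, and drug treatment
efficacy E (risk-reduction fraction, default 0.53 for alendronate):

    PPV = S * PopFR / TestPR
    preventable hip fractures per 1000 tested = S * PopFR * E * 1000

The preventable count assumes all high-risk (positive-testing) patients
are treated and their risk is reduced by E on average.  PopFR is
measured from the untreated random sample excluding dropouts; TestPR
from the full random sample at baseline (future dropouts included, since
future status is unknown at testing time); S from the validation set.
Display values round half-up: one decimal for percentages, integer for
counts; internal arithmetic is unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import recode_outcomes, sensitivity_specificity
from .risk_model import round_half_up

__all__ = [
    "EffectivenessInputs",
    "ppv",
    "preventable_per_1000",
    "estimate_inputs",
    "threshold_sweep",
    "classify_risk",
    "relative_improvement",
    "DEFAULT_EFFICACY",
    "BCT_THRESHOLDS",
]

DEFAULT_EFFICACY = 0.53
BCT_THRESHOLDS = (75.0, 80.0, 85.0, 90.0, 95.0)


@dataclass
class EffectivenessInputs:
    """Fractions in [0, 1]: sensitivity, population fracture risk,
    positive-test rate, and treatment efficacy."""

    s: float
    pop_fr: float
    test_pr: float
    efficacy: float = DEFAULT_EFFICACY

    def __post_init__(self) -> None:
        for name in ("s", "pop_fr", "test_pr", "efficacy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")


def ppv(inputs: EffectivenessInputs, rounded: bool = True) -> float:
    """Positive predictive value in percent: 100 * S * PopFR / TestPR."""
    if inputs.test_pr == 0:
        raise ValueError("TestPR must be positive to compute PPV")
    value = 100.0 * inputs.s * inputs.pop_fr / inputs.test_pr
    return round_half_up(value, 1) if rounded else value


def preventable_per_1000(inputs: EffectivenessInputs, rounded: bool = True) -> float:
    """Preventable hip fractures per 1000 tested: S * PopFR * E * 1000."""
    value = inputs.s * inputs.pop_fr * inputs.efficacy * 1000.0
    return round_half_up(value, 0) if rounded else value


def estimate_inputs(
    random_sample: pd.DataFrame,
    validation: pd.DataFrame,
    test_column: str,
    threshold: float,
    direction: str = ">=",
    horizon: float = 5.0,
    efficacy: float = DEFAULT_EFFICACY,
) -> EffectivenessInputs:
    """Estimate S, PopFR and TestPR from cohort tables.

    PopFR: fracture-within-horizon rate among untreated random-sample
    patients, excluding dropouts (via outcome recoding).  TestPR:
    positive fraction of the whole random sample at baseline, dropouts
    and treated included.  S: sensitivity on the recoded validation set.
    """
    for col in ("random_sample", "treated_days", "followup_time"):
        if col not in random_sample:
            raise ValueError(f"random-sample table lacks required column {col!r}")
    rs = random_sample[random_sample["random_sample"]]
    if len(rs) == 0:
        raise ValueError("no random-sample rows present")
    vals = rs[test_column].to_numpy(dtype=float)
    test_pr = float((vals >= threshold).mean() if direction == ">=" else (vals <= threshold).mean())

    recoded_rs, _ = recode_outcomes(rs, horizon)
    pop_fr = float(recoded_rs["case"].mean())

    recoded_val, _ = recode_outcomes(validation, horizon)
    m = sensitivity_specificity(
        recoded_val[test_column].to_numpy(dtype=float),
        recoded_val["case"].to_numpy(dtype=bool),
        threshold,
        direction,
    )
    return EffectivenessInputs(m.sensitivity / 100.0, pop_fr, test_pr, efficacy)


def classify_risk(
    ppv_value: float, frax_high_ppv: float, frax_veryhigh_ppv: float
) -> str:
    """Risk class of a test/threshold by comparing its PPV to the FRAX
    reference PPVs of the same stratum, on 1-decimal rounded values:
    very-high if >= the FRAX-4.5% PPV, else high if >= the FRAX-3.0% PPV,
    else below-high."""
    if frax_high_ppv is None or frax_veryhigh_ppv is None:
        raise ValueError("reference PPVs are required")
    p = round_half_up(ppv_value, 1)
    if p >= round_half_up(frax_veryhigh_ppv, 1):
        return "very-high"
    if p >= round_half_up(frax_high_ppv, 1):
        return "high"
    return "below-high"


def threshold_sweep(
    random_sample: pd.DataFrame,
    validation: pd.DataFrame,
    test_column: str = "bct_score",
    thresholds: Sequence[float] = BCT_THRESHOLDS,
    direction: str = ">=",
    horizon: float = 5.0,
    efficacy: float = DEFAULT_EFFICACY,
    frax_reference: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """One effectiveness report row per threshold.

    Positive rate and sensitivity are non-increasing in the threshold
    (nested positives).  If ``frax_reference`` is given as the
    (high, very-high) reference PPVs of the stratum, each row carries a
    risk classification.
    """
    rows = []
    for thr in thresholds:
        inputs = estimate_inputs(
            random_sample, validation, test_column, thr, direction, horizon, efficacy
        )
        row = {
            "test": test_column,
            "threshold": thr,
            "positive_rate_pct": round_half_up(100.0 * inputs.test_pr, 1),
            "sensitivity_pct": round_half_up(100.0 * inputs.s, 1),
            "ppv_pct": ppv(inputs),
            "preventable_per_1000": int(preventable_per_1000(inputs)),
            "pop_fr_pct": round_half_up(100.0 * inputs.pop_fr, 1),
        }
        if frax_reference is not None:
            row["risk_class"] = classify_risk(ppv(inputs, rounded=False), *frax_reference)
        rows.append(row)
    return pd.DataFrame(rows)


def relative_improvement(a_per_1000: float, b_per_1000: float) -> float:
    """Percent improvement of A over B: 100 * (A - B) / B, rounded
    half-up to an integer.  Not symmetric in its arguments."""
    if b_per_1000 == 0:
        raise ValueError("reference count must be positive")
    return round_half_up(100.0 * (a_per_1000 - b_per_1000) / b_per_1000, 0)
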