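"""Closed-form worked examples of the effectiveness and DOR arithmetic.

A fixture deck of published clinical-performance figures for CT-based
hip-fracture screening in adults aged 65+ (four strata: women/men, ages
>=65 / >=70; three tests: FRAX hip risk, hip BMD T-score, and the CT
risk score at thresholds 75-95).  Each row carries the printed inputs
(sensitivity, population fracture risk, baseline positive-test rate) and
the printed outputs (PPV, preventable fractures per 1000 tested).

Recomputing the outputs from the printed inputs reproduces most rows
exactly under half-up display rounding; rows whose printed outputs were
derived from unrounded internal sensitivities differ by one display unit
and are flagged ``exact=False``.  These flags were frozen from an
independent recomputation of the formulas and are regression-checked,
never adjusted to the code.
"""

from __future__ import annotations

import pandas as pd

from .effectiveness import (
    EffectivenessInputs,
    ppv,
    preventable_per_1000,
    DEFAULT_EFFICACY,
)
from .evaluation import diagnostic_odds_ratio, net_gain
from .risk_model import round_half_up

__all__ = [
    "EFFECTIVENESS_DECK",
    "DOR_DECK",
    "NET_GAIN_DECK",
    "run_effectiveness_examples",
    "run_dor_examples",
    "run_net_gain_examples",
]

# stratum, test, pop_fr, test_pr, sensitivity (fractions),
# printed PPV %, PPV exact?, printed preventable/1000, preventable exact?
EFFECTIVENESS_DECK = [
    ("women_65", "frax_3.0", 0.058, 0.346, 0.759, 12.7, True, 23, True),
    ("women_65", "frax_4.5", 0.058, 0.235, 0.627, 15.4, False, 19, True),
    ("women_65", "bmd_-2.5", 0.058, 0.180, 0.478, 15.3, False, 15, True),
    ("women_65", "bct_75", 0.058, 0.345, 0.814, 13.6, False, 25, True),
    ("women_65", "bct_80", 0.058, 0.298, 0.763, 14.8, False, 23, True),
    ("women_65", "bct_85", 0.058, 0.244, 0.704, 16.6, False, 22, True),
    ("women_65", "bct_90", 0.058, 0.185, 0.621, 19.4, False, 19, True),
    ("women_65", "bct_95", 0.058, 0.124, 0.482, 22.4, False, 15, True),
    ("women_70", "frax_3.0", 0.083, 0.489, 0.828, 14.1, True, 36, True),
    ("women_70", "frax_4.5", 0.083, 0.343, 0.696, 16.9, False, 31, True),
    ("women_70", "bmd_-2.5", 0.083, 0.242, 0.517, 17.8, False, 23, True),
    ("women_70", "bct_75", 0.083, 0.488, 0.864, 14.7, True, 38, True),
    ("women_70", "bct_80", 0.083, 0.430, 0.817, 15.8, True, 36, True),
    ("women_70", "bct_85", 0.083, 0.360, 0.768, 17.7, True, 34, True),
    ("women_70", "bct_90", 0.083, 0.278, 0.682, 20.4, True, 30, True),
    ("women_70", "bct_95", 0.083, 0.189, 0.534, 23.5, True, 24, False),
    ("men_65", "frax_3.0", 0.034, 0.200, 0.581, 9.8, False, 10, True),
    ("men_65", "frax_4.5", 0.034, 0.097, 0.388, 13.4, False, 7, True),
    ("men_65", "bmd_-2.5", 0.034, 0.062, 0.268, 14.5, False, 5, True),
    ("men_65", "bct_75", 0.034, 0.199, 0.669, 11.3, False, 12, True),
    ("men_65", "bct_80", 0.034, 0.169, 0.616, 12.2, False, 11, True),
    ("men_65", "bct_85", 0.034, 0.138, 0.513, 12.5, False, 9, True),
    ("men_65", "bct_90", 0.034, 0.103, 0.425, 13.9, False, 8, True),
    ("men_65", "bct_95", 0.034, 0.057, 0.265, 15.6, False, 5, True),
    ("men_70", "frax_3.0", 0.045, 0.300, 0.650, 9.8, True, 16, True),
    ("men_70", "frax_4.5", 0.045, 0.146, 0.435, 13.5, False, 10, True),
    ("men_70", "bmd_-2.5", 0.045, 0.088, 0.285, 14.8, False, 7, True),
    ("men_70", "bct_75", 0.045, 0.297, 0.731, 11.2, False, 18, False),
    ("men_70", "bct_80", 0.045, 0.254, 0.682, 12.2, False, 16, True),
    ("men_70", "bct_85", 0.045, 0.211, 0.579, 12.5, False, 14, True),
    ("men_70", "bct_90", 0.045, 0.161, 0.486, 13.7, False, 12, True),
    ("men_70", "bct_95", 0.045, 0.088, 0.384, 19.7, False, 9, True),
]

# sex_horizon, test, sensitivity %, specificity %, printed DOR, exact?
DOR_DECK = [
    ("women_5yr", "bmd", 47.8, 92.9, 12.0, True),
    ("women_5yr", "frax", 75.9, 79.1, 11.9, True),
    ("women_5yr", "bct", 81.4, 80.0, 17.4, False),
    ("men_5yr", "bmd", 26.8, 98.6, 25.4, False),
    ("men_5yr", "frax", 58.1, 89.4, 11.7, True),
    ("men_5yr", "bct", 66.9, 92.2, 23.9, True),
    ("women_2yr", "bmd", 52.2, 88.3, 8.2, True),
    ("women_2yr", "frax", 79.6, 72.1, 10.1, True),
    ("women_2yr", "bct", 85.3, 73.0, 15.7, True),
    ("men_2yr", "bmd", 30.6, 97.1, 14.5, False),
    ("men_2yr", "frax", 59.2, 84.7, 8.0, True),
    ("men_2yr", "bct", 73.2, 87.3, 18.7, False),
]

# label, (sens_a, spec_a), (sens_b, spec_b), printed net gain (points)
NET_GAIN_DECK = [
    ("women_bct_vs_bmd", (81.4, 80.0), (47.8, 92.9), 20.7),
    ("men_bct_vs_bmd", (66.9, 92.2), (26.8, 98.6), 33.7),
]


def run_effectiveness_examples(efficacy: float = DEFAULT_EFFICACY) -> pd.DataFrame:
    """Recompute every deck row from its printed inputs."""
    rows = []
    for (stratum, test, pop_fr, test_pr, s, ppv_printed, ppv_exact,
         prev_printed, prev_exact) in EFFECTIVENESS_DECK:
        inputs = EffectivenessInputs(s, pop_fr, test_pr, efficacy)
        rows.append(
            {
                "stratum": stratum,
                "test": test,
                "ppv_printed": ppv_printed,
                "ppv_recomputed": ppv(inputs),
                "ppv_exact": ppv_exact,
                "preventable_printed": prev_printed,
                "preventable_recomputed": int(preventable_per_1000(inputs)),
                "preventable_exact": prev_exact,
            }
        )
    df = pd.DataFrame(rows)
    df["ppv_match"] = df["ppv_printed"] == df["ppv_recomputed"]
    df["preventable_match"] = df["preventable_printed"] == df["preventable_recomputed"]
    return df


def run_dor_examples() -> pd.DataFrame:
    rows = []
    for label, test, sens, spec, printed, exact in DOR_DECK:
        recomputed = round_half_up(diagnostic_odds_ratio(sens, spec), 1)
        rows.append(
            {
                "group": label,
                "test": test,
                "dor_printed": printed,
                "dor_recomputed": recomputed,
                "exact": exact,
                "match": recomputed == printed,
            }
        )
    return pd.DataFrame(rows)


def run_net_gain_examples() -> pd.DataFrame:
    rows = []
    for label, (sa, ca), (sb, cb), printed in NET_GAIN_DECK:
        recomputed = round_half_up(net_gain(sa, ca, sb, cb), 1)
        rows.append(
            {
                "comparison": label,
                "net_gain_printed": printed,
                "net_gain_recomputed": recomputed,
                "match": recomputed == printed,
            }
        )
    return pd.DataFrame(rows)
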