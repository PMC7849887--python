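"""Standardized differences, their classification, and score reweighting.

The standardized difference (STD) is the scale-free two-group contrast
used throughout as the balance diagnostic and as the effect-size measure
that drives the reweighting. The pooled two-group forms are used:

* binary:      ``(p_a - p_b) / sqrt((p_a(1-p_a) + p_b(1-p_b)) / 2)``
* continuous:  ``(m_a - m_b) / sqrt((s_a^2 + s_b^2) / 2)``

with the magnitude classified as *negligible* (|STD| < 0.1), *moderate*
(0.1 <= |STD| <= 0.2) or *substantial* (|STD| > 0.2).

The reweighting rule maps the classification of each comorbidity
component's *incident* (delta) contrast between the solitary-AFL and
AFL-then-AF groups to an integer weight — substantial -> 2, moderate
-> 1, negligible -> 0 — while the demographic weights (sex, age bands)
are inherited from the base scoring system. Applied to a cohort with the
study's incident-rate structure this yields the A2C2S2-VASc weight set:
heart failure 2, stroke/TIA 2, vascular disease 1, hypertension and
diabetes 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from dynascore.cohort import COMPONENT_COLUMNS, COMPONENTS, DAYS_PER_YEAR, PatientRecord, to_frame
from dynascore.scoring import ScoreWeights, builtin_weights, score_frame

CATEGORIES = ("negligible", "moderate", "substantial")

#: Comorbidity components entering the reweighting rule.
REWEIGHTED_COMPONENTS = (
    "heart_failure",
    "hypertension",
    "diabetes",
    "stroke_tia",
    "vascular_disease",
)

TIMEPOINTS = ("baseline", "follow_up", "delta")

#: Default balance-table variables: the scored comorbidities, demographics
#: and the two aggregate scores.
DEFAULT_VARIABLES = (
    "female",
    "age",
    "age_lt65",
    "age_65_74",
    "age_ge75",
    *REWEIGHTED_COMPONENTS,
    "copd",
    "score:chads_vasc",
    "score:a2c2s2_vasc",
)


@dataclass(frozen=True)
class BalanceRow:
    """Two-group summary of one variable at one timepoint."""

    variable: str
    timepoint: str
    group_a_summary: dict
    group_b_summary: dict
    std: float
    category: str


def std_binary(x_a: int, n_a: int, x_b: int, n_b: int) -> float:
    """Pooled-proportion standardized difference of two binary variables.

    Signed as group A minus group B. When both variances vanish the
    result is 0 for equal proportions and a signed infinity otherwise
    (classified substantial downstream).
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be at least 1")
    if not (0 <= x_a <= n_a and 0 <= x_b <= n_b):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p_a, p_b = x_a / n_a, x_b / n_b
    pooled = (p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0
    if pooled == 0.0:
        return 0.0 if p_a == p_b else math.copysign(math.inf, p_a - p_b)
    return (p_a - p_b) / math.sqrt(pooled)


def std_continuous(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Pooled-SD standardized difference of two continuous summaries."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = (sd_a**2 + sd_b**2) / 2.0
    if pooled == 0.0:
        return 0.0 if mean_a == mean_b else math.copysign(math.inf, mean_a - mean_b)
    return (mean_a - mean_b) / math.sqrt(pooled)


def classify_std(std: float) -> str:
    """Classify |STD|: < 0.1 negligible, 0.1..0.2 moderate, > 0.2 substantial."""
    a = abs(std)
    if a < 0.1:
        return "negligible"
    if a <= 0.2:
        return "moderate"
    return "substantial"


def _component_presence(frame: pd.DataFrame, component: str, timepoint: str) -> np.ndarray:
    onset = frame[COMPONENT_COLUMNS[component]].to_numpy(dtype=np.float64, na_value=np.nan)
    end = frame["followup_end"].to_numpy(dtype=np.int64)
    known = ~np.isnan(onset)
    at_baseline = known & (onset <= 0)
    at_followup = known & (onset <= end)
    if timepoint == "baseline":
        return at_baseline
    if timepoint == "follow_up":
        return at_followup
    if timepoint == "delta":
        return at_followup & ~at_baseline
    raise ValueError(f"unknown timepoint {timepoint!r}")


def _variable_values(frame: pd.DataFrame, variable: str, timepoint: str):
    """Return ("binary", bool array) or ("continuous", float array) or None.

    None means the (variable, timepoint) combination is undefined (e.g.
    a delta of sex), and no row is emitted for it.
    """
    age_b = frame["age_at_index"].to_numpy(dtype=np.int64)
    end = frame["followup_end"].to_numpy(dtype=np.int64)
    age_f = age_b + np.floor(end / DAYS_PER_YEAR).astype(np.int64)
    age = {"baseline": age_b, "follow_up": age_f}
    if variable == "female":
        if timepoint != "baseline":
            return None
        return "binary", (frame["sex"] == "female").to_numpy()
    if variable == "age":
        if timepoint == "delta":
            return "continuous", (age_f - age_b).astype(float)
        return "continuous", age[timepoint].astype(float)
    if variable in ("age_lt65", "age_65_74", "age_ge75"):
        if timepoint == "delta":
            return None
        a = age[timepoint]
        if variable == "age_lt65":
            return "binary", a < 65
        if variable == "age_65_74":
            return "binary", (a >= 65) & (a < 75)
        return "binary", a >= 75
    if variable in COMPONENTS:
        return "binary", _component_presence(frame, variable, timepoint)
    if variable.startswith("score:"):
        name = variable.split(":", 1)[1]
        scores = score_frame(frame, builtin_weights(name))
        return "continuous", scores[timepoint].to_numpy(dtype=float)
    raise ValueError(f"unknown balance variable {variable!r}")


def balance_table(
    cohort: pd.DataFrame | list[PatientRecord],
    variables: Sequence[str] = DEFAULT_VARIABLES,
    timepoints: Sequence[str] = TIMEPOINTS,
    group_order: tuple[str, str] = ("solitary_afl", "afl_daf"),
) -> list[BalanceRow]:
    """Per-variable two-group balance diagnostics.

    One row per defined (variable, timepoint) pair. Binary variables are
    summarised as count + proportion, continuous ones as mean + sd; the
    delta indicator of a component means *newly acquired during
    follow-up* (present at follow-up and absent at baseline). Group A is
    ``group_order[0]`` (solitary AFL by default), so the sign convention
    matches a (solitary - AFL-then-AF) contrast.
    """
    frame = to_frame(cohort) if isinstance(cohort, list) else cohort
    mask_a = (frame["group"] == group_order[0]).to_numpy()
    mask_b = (frame["group"] == group_order[1]).to_numpy()
    rows: list[BalanceRow] = []
    for variable in variables:
        for timepoint in timepoints:
            got = _variable_values(frame, variable, timepoint)
            if got is None:
                continue
            kind, values = got
            if kind == "binary":
                x_a, n_a = int(values[mask_a].sum()), int(mask_a.sum())
                x_b, n_b = int(values[mask_b].sum()), int(mask_b.sum())
                std = std_binary(x_a, n_a, x_b, n_b)
                summ_a = {"n": n_a, "count": x_a, "proportion": x_a / n_a}
                summ_b = {"n": n_b, "count": x_b, "proportion": x_b / n_b}
            else:
                v_a, v_b = values[mask_a], values[mask_b]
                m_a, s_a = float(v_a.mean()), float(v_a.std(ddof=1))
                m_b, s_b = float(v_b.mean()), float(v_b.std(ddof=1))
                std = std_continuous(m_a, s_a, m_b, s_b)
                summ_a = {"n": int(mask_a.sum()), "mean": m_a, "sd": s_a}
                summ_b = {"n": int(mask_b.sum()), "mean": m_b, "sd": s_b}
            rows.append(
                BalanceRow(
                    variable=variable,
                    timepoint=timepoint,
                    group_a_summary=summ_a,
                    group_b_summary=summ_b,
                    std=float(std),
                    category=classify_std(std),
                )
            )
    return rows


def derive_weights(balance: Iterable[BalanceRow], base: ScoreWeights) -> ScoreWeights:
    """Reweight comorbidity components from their incident-contrast category.

    Uses the *delta*-timepoint rows of the five scored comorbidities:
    substantial -> 2, moderate -> 1, negligible -> 0. Sex and age-band
    weights are inherited from ``base`` unchanged; COPD gets weight 0.
    Deterministic in its inputs, hence idempotent under recomputation.

    Raises
    ------
    ValueError
        If a required component's delta row is missing.
    """
    delta_rows = {row.variable: row for row in balance if row.timepoint == "delta"}
    missing = [c for c in REWEIGHTED_COMPONENTS if c not in delta_rows]
    if missing:
        raise ValueError(f"balance table lacks delta rows for: {missing}")
    mapping = {"substantial": 2, "moderate": 1, "negligible": 0}
    weights = {
        "female": base.weight("female"),
        "age_65_74": base.weight("age_65_74"),
        "age_ge75": base.weight("age_ge75"),
        "copd": 0,
    }
    for comp in REWEIGHTED_COMPONENTS:
        weights[comp] = mapping[delta_rows[comp].category]
    return ScoreWeights(name=f"derived({base.name})", weights=weights)


def balance_frame(rows: Sequence[BalanceRow]) -> pd.DataFrame:
    """Flatten balance rows to the report CSV layout (std rounded to 2 dp)."""
    records = []
    for row in rows:
        stat_a = row.group_a_summary.get("proportion", row.group_a_summary.get("mean"))
        stat_b = row.group_b_summary.get("proportion", row.group_b_summary.get("mean"))
        records.append(
            {
                "variable": row.variable,
                "timepoint": row.timepoint,
                "n_a": row.group_a_summary["n"],
                "stat_a": stat_a,
                "n_b": row.group_b_summary["n"],
                "stat_b": stat_b,
                "std": round(row.std, 2),
                "category": row.category,
            }
        )
    return pd.DataFrame(records)
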