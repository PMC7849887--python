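"""Risk-score weight sets and baseline/follow-up/delta score computation.

Three built-in scoring systems are provided:

* ``chads_vasc`` — CHA2DS2-VASc: CHF 1, hypertension 1, age >=75 2,
  diabetes 1, stroke/TIA 2, vascular disease 1, age 65-74 1, female 1
  (maximum 9);
* ``a2c2s2_vasc`` — the reweighted A2C2S2-VASc: age >=75 2, CHF 2,
  stroke/TIA 2, vascular disease 1, age 65-74 1, female 1; hypertension
  and diabetes carry no weight (maximum 8);
* ``hatch`` — HATCH: CHF 2, hypertension 1, age >=75 1, stroke/TIA 2,
  COPD 1 (maximum 7).

A patient's score at a given day is the sum of weights over components
present at that day, plus the weight of the attained age band and, if
female, the sex weight. The *follow-up* score is taken at the end of the
follow-up window, and the *delta* score is follow-up minus baseline; with
permanent comorbidities and monotone ageing the delta is never negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from dynascore.cohort import COMPONENT_COLUMNS, COMPONENTS, DAYS_PER_YEAR, PatientRecord

#: Components a weight set may assign a weight to.
SCORE_COMPONENTS = ("female", "age_65_74", "age_ge75", *COMPONENTS)

#: Comorbidity (non-demographic) score components.
COMORBIDITY_COMPONENTS = COMPONENTS

BUILTIN_NAMES = ("chads_vasc", "a2c2s2_vasc", "hatch")


@dataclass(frozen=True)
class ScoreWeights:
    """A named map component -> non-negative integer weight."""

    name: str
    weights: Mapping[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(SCORE_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown score components: {sorted(unknown)}")
        if any(w < 0 or int(w) != w for w in self.weights.values()):
            raise ValueError("weights must be non-negative integers")

    def weight(self, component: str) -> int:
        return int(self.weights.get(component, 0))

    @property
    def max_score(self) -> int:
        """Largest attainable score: female + age>=75 band + all comorbidities."""
        total = self.weight("female") + self.weight("age_ge75")
        total += sum(self.weight(c) for c in COMORBIDITY_COMPONENTS)
        return total


@dataclass(frozen=True)
class ScoreTriple:
    """Baseline, follow-up and delta score for one patient."""

    baseline: int
    follow_up: int
    delta: int

    def __post_init__(self) -> None:
        if self.follow_up != self.baseline + self.delta:
            raise ValueError("follow_up must equal baseline + delta")
        if self.delta < 0:
            raise ValueError("delta score cannot be negative")


_BUILTINS = {
    "chads_vasc": {
        "female": 1,
        "age_65_74": 1,
        "age_ge75": 2,
        "heart_failure": 1,
        "hypertension": 1,
        "diabetes": 1,
        "stroke_tia": 2,
        "vascular_disease": 1,
        "copd": 0,
    },
    "a2c2s2_vasc": {
        "female": 1,
        "age_65_74": 1,
        "age_ge75": 2,
        "heart_failure": 2,
        "hypertension": 0,
        "diabetes": 0,
        "stroke_tia": 2,
        "vascular_disease": 1,
        "copd": 0,
    },
    "hatch": {
        "female": 0,
        "age_65_74": 0,
        "age_ge75": 1,
        "heart_failure": 2,
        "hypertension": 1,
        "diabetes": 0,
        "stroke_tia": 2,
        "vascular_disease": 0,
        "copd": 1,
    },
}


def builtin_weights(name: str) -> ScoreWeights:
    """Return a built-in weight set by name.

    Raises
    ------
    ValueError
        For unknown names; the message lists the valid ones.
    """
    if name not in _BUILTINS:
        raise ValueError(f"unknown score name {name!r}; valid names: {', '.join(BUILTIN_NAMES)}")
    return ScoreWeights(name=name, weights=dict(_BUILTINS[name]))


def _age_band(age: int) -> str | None:
    if age >= 75:
        return "age_ge75"
    if age >= 65:
        return "age_65_74"
    return None


def snapshot(record: PatientRecord, day: int) -> dict[str, bool]:
    """Component-presence map (plus sex and age band) at ``day``.

    A comorbidity is present iff its onset day is ``<= day``; the age band
    is derived from the attained age ``age_at_index + floor(day/365.25)``.
    ``day`` must lie within ``[0, followup_end_day]``.
    """
    if day < 0 or day > record.followup_end_day:
        raise ValueError(f"day {day} outside follow-up window [0, {record.followup_end_day}]")
    snap = {comp: record.has_component(comp, day) for comp in COMPONENTS}
    band = _age_band(record.age_at(day))
    snap["age_65_74"] = band == "age_65_74"
    snap["age_ge75"] = band == "age_ge75"
    snap["female"] = record.sex == "female"
    return snap


def score(snap: Mapping[str, bool], weights: ScoreWeights) -> int:
    """Sum of weights over present components in a snapshot."""
    return sum(weights.weight(comp) for comp, present in snap.items() if present)


def score_trajectory(record: PatientRecord, weights: ScoreWeights) -> ScoreTriple:
    """Baseline, follow-up and delta score of one patient under one weight set."""
    baseline = score(snapshot(record, 0), weights)
    follow_up = score(snapshot(record, record.followup_end_day), weights)
    return ScoreTriple(baseline=baseline, follow_up=follow_up, delta=follow_up - baseline)


def score_frame(frame: pd.DataFrame, weights: ScoreWeights) -> pd.DataFrame:
    """Vectorised :func:`score_trajectory` over a cohort DataFrame.

    Returns a DataFrame with columns ``patient_id``, ``score_name``,
    ``baseline``, ``follow_up``, ``delta`` aligned with the input rows.
    """
    end = frame["followup_end"].to_numpy(dtype=np.int64)
    age_b = frame["age_at_index"].to_numpy(dtype=np.int64)
    age_f = age_b + np.floor(end / DAYS_PER_YEAR).astype(np.int64)

    def band_points(age: np.ndarray) -> np.ndarray:
        return np.where(
            age >= 75, weights.weight("age_ge75"), np.where(age >= 65, weights.weight("age_65_74"), 0)
        )

    female = (frame["sex"] == "female").to_numpy()
    baseline = band_points(age_b) + female * weights.weight("female")
    follow_up = band_points(age_f) + female * weights.weight("female")
    for comp, col in COMPONENT_COLUMNS.items():
        w = weights.weight(comp)
        if w == 0:
            continue
        onset = frame[col].to_numpy(dtype=np.float64, na_value=np.nan)
        known = ~np.isnan(onset)
        baseline = baseline + w * (known & (onset <= 0))
        follow_up = follow_up + w * (known & (onset <= end))
    return pd.DataFrame(
        {
            "patient_id": frame["patient_id"].to_numpy(),
            "score_name": weights.name,
            "baseline": baseline.astype(np.int64),
            "follow_up": follow_up.astype(np.int64),
            "delta": (follow_up - baseline).astype(np.int64),
        }
    )
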