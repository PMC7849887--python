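"""Seeded synthetic claims-style cohort generator.

Real administrative-claims cohorts of atrial-flutter patients are not
publicly distributable, so every downstream stage in this package is
exercised on synthetic cohorts with the same statistical skeleton: two
groups (solitary AFL, and AFL that develops AF) that are balanced at
baseline on the CHA2DS2-VASc components but diverge during follow-up in
their incident comorbidity rates, a capped 3-year follow-up window whose
duration distribution matches the reported summaries (median ~0.47 years,
mean ~0.81 years), and a post-index ischaemic-stroke outcome whose
probability rises with the patient's delta score.

What the generator emulates, and what it does not: components are drawn
independently per patient (no comorbidity correlation structure), incident
onsets are placed uniformly over the follow-up window (only end-of-window
presence matters downstream), and the stroke outcome depends on the delta
CHA2DS2-VASc score alone. Incident probabilities are *marginal* over the
whole group — internally the per-patient conditional probability is
inflated by 1/(1 - baseline prevalence) so the expected incident (delta)
proportion equals the configured value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from dynascore.cohort import (
    COMPONENT_COLUMNS,
    COMPONENTS,
    CSV_COLUMNS,
    DAYS_PER_YEAR,
    FOLLOWUP_CAP_DAYS,
    GROUPS,
    PatientRecord,
    from_frame,
    to_frame,
)
from dynascore.scoring import builtin_weights, score_frame

# Baseline prevalence per group: matched-cohort values (counts / 4101).
DEFAULT_BASELINE_PREVALENCE: dict[str, dict[str, float]] = {
    "solitary_afl": {
        "heart_failure": 0.120,
        "hypertension": 0.581,
        "diabetes": 0.188,
        "stroke_tia": 0.129,
        "vascular_disease": 0.404,
        "copd": 0.174,
    },
    "afl_daf": {
        "heart_failure": 0.127,
        "hypertension": 0.581,
        "diabetes": 0.165,
        "stroke_tia": 0.133,
        "vascular_disease": 0.412,
        "copd": 0.194,
    },
}

# Marginal probability of gaining each component during follow-up.
DEFAULT_INCIDENT_PROB: dict[str, dict[str, float]] = {
    "solitary_afl": {
        "heart_failure": 0.093,
        "hypertension": 0.092,
        "diabetes": 0.026,
        "stroke_tia": 0.049,
        "vascular_disease": 0.117,
        "copd": 0.0,
    },
    "afl_daf": {
        "heart_failure": 0.221,
        "hypertension": 0.108,
        "diabetes": 0.024,
        "stroke_tia": 0.127,
        "vascular_disease": 0.175,
        "copd": 0.0,
    },
}

# Age-band probabilities <65 / 65-74 / >=75, as matched-cohort fractions.
DEFAULT_AGE_BAND_PROBS = (1212 / 4101, 1201 / 4101, 1688 / 4101)

DEFAULT_FEMALE_PROB = 0.383


@dataclass(frozen=True)
class FollowupShape:
    """Log-normal follow-up duration, capped at the 3-year horizon.

    The log-normal is the conventional skewed-duration model; its two free
    parameters are solved so that the *capped* variable ``min(X, cap)``
    has the target median and mean.
    """

    median_years: float = 0.47
    mean_years: float = 0.81
    cap_days: int = FOLLOWUP_CAP_DAYS


@dataclass(frozen=True)
class StrokeModel:
    """Logistic link from delta score to post-index stroke probability.

    ``P(stroke) = expit(intercept + per_point * delta)`` with delta the
    CHA2DS2-VASc delta score. Defaults give an overall event rate near
    10% over the window — a realistic 3-year ischaemic-stroke risk for an
    elderly arrhythmia cohort — with a per-point log-odds increment of
    0.55.
    """

    intercept: float = -2.6
    per_point: float = 0.55


@dataclass(frozen=True)
class CohortGenParams:
    """All knobs of the synthetic cohort generator (seeded, deterministic)."""

    n_per_group: int = 4101
    baseline_prevalence: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_BASELINE_PREVALENCE.items()}
    )
    incident_prob: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_INCIDENT_PROB.items()}
    )
    female_prob: float = DEFAULT_FEMALE_PROB
    age_band_probs: tuple[float, float, float] = DEFAULT_AGE_BAND_PROBS
    followup_shape: FollowupShape = field(default_factory=FollowupShape)
    stroke_model: StrokeModel = field(default_factory=StrokeModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 0:
            raise ValueError("n_per_group must be non-negative")
        for name, table in (
            ("baseline_prevalence", self.baseline_prevalence),
            ("incident_prob", self.incident_prob),
        ):
            for group in GROUPS:
                if group not in table:
                    raise ValueError(f"{name} missing group {group!r}")
                for comp in COMPONENTS:
                    p = table[group].get(comp, 0.0)
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"{name}[{group}][{comp}] = {p} not in [0, 1]")
        if not 0.0 <= self.female_prob <= 1.0:
            raise ValueError("female_prob must be in [0, 1]")
        if len(self.age_band_probs) != 3 or any(p < 0 for p in self.age_band_probs):
            raise ValueError("age_band_probs must be three non-negative probabilities")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        shape = self.followup_shape
        if not 0 < shape.median_years * DAYS_PER_YEAR < shape.cap_days:
            raise ValueError("follow-up median must lie in (0, cap)")
        if shape.mean_years <= 0:
            raise ValueError("follow-up mean must be positive")


def _solve_lognormal_sigma(shape: FollowupShape) -> tuple[float, float]:
    """Solve (mu, sigma) so min(LogNormal, cap) hits the target median/mean.

    The median of the capped variable equals the uncapped median whenever
    it lies below the cap, which pins ``mu = log(median)``; sigma is then
    found by root-finding on the capped-mean identity
    ``E[min(X, c)] = exp(mu + s^2/2) * Phi((log c - mu - s^2)/s)
    + c * (1 - Phi((log c - mu)/s))``.
    """
    mu = np.log(shape.median_years * DAYS_PER_YEAR)
    cap = float(shape.cap_days)
    target = shape.mean_years * DAYS_PER_YEAR

    def capped_mean(s: float) -> float:
        return np.exp(mu + s * s / 2.0) * norm.cdf((np.log(cap) - mu - s * s) / s) + cap * (
            1.0 - norm.cdf((np.log(cap) - mu) / s)
        )

    lo, hi = 1e-6, 10.0
    if not capped_mean(lo) < target < capped_mean(hi):
        raise ValueError("follow-up mean/median targets are not attainable under the cap")
    sigma = brentq(lambda s: capped_mean(s) - target, lo, hi, xtol=1e-10)
    return float(mu), float(sigma)


def _draw_ages(rng: np.random.Generator, n: int, band_probs: Sequence[float]) -> np.ndarray:
    """Integer ages: band by configured probabilities, uniform within band."""
    band = rng.choice(3, size=n, p=np.asarray(band_probs, dtype=float))
    age = np.empty(n, dtype=np.int64)
    age[band == 0] = rng.integers(20, 65, size=int((band == 0).sum()))
    age[band == 1] = rng.integers(65, 75, size=int((band == 1).sum()))
    age[band == 2] = rng.integers(75, 95, size=int((band == 2).sum()))
    return age


def generate_cohort(params: CohortGenParams) -> list[PatientRecord]:
    """Generate a paired two-group cohort (2 * n_per_group records).

    AFL-then-AF patients get ``af_day == followup_end_day`` drawn from the
    capped log-normal; each solitary patient is the 1:1 counterpart of one
    AFL-then-AF patient and inherits that patient's follow-up end day
    (counterpart follow-up assignment). Identical parameters and seed give
    bit-identical output.
    """
    params.validate()
    n = params.n_per_group
    if n == 0:
        return []
    rng = np.random.default_rng(params.seed)
    mu, sigma = _solve_lognormal_sigma(params.followup_shape)
    durations = np.exp(rng.normal(mu, sigma, size=n))
    durations = np.clip(np.rint(durations), 1, params.followup_shape.cap_days).astype(np.int64)

    frames = []
    for group, prefix in (("afl_daf", "daf"), ("solitary_afl", "sol")):
        data: dict[str, object] = {
            "patient_id": [f"{prefix}-{i:06d}" for i in range(n)],
            "sex": np.where(rng.random(n) < params.female_prob, "female", "male"),
            "age_at_index": _draw_ages(rng, n, params.age_band_probs),
            "group": group,
            "followup_end": durations,
        }
        end = durations
        for comp, col in COMPONENT_COLUMNS.items():
            p_base = float(params.baseline_prevalence[group].get(comp, 0.0))
            p_inc = float(params.incident_prob[group].get(comp, 0.0))
            at_baseline = rng.random(n) < p_base
            # conditional probability among the baseline-free, so the
            # marginal incident proportion equals p_inc
            p_cond = 0.0 if p_base >= 1.0 else min(1.0, p_inc / (1.0 - p_base))
            incident = ~at_baseline & (rng.random(n) < p_cond)
            onset = np.full(n, np.nan)
            onset[at_baseline] = 0
            n_inc = int(incident.sum())
            if n_inc:
                onset[incident] = rng.integers(1, end[incident] + 1, size=n_inc)
            data[col] = onset
        data["af_day"] = durations if group == "afl_daf" else np.full(n, np.nan)
        frames.append(pd.DataFrame(data))

    frame = pd.concat(frames, ignore_index=True)
    for col in COMPONENT_COLUMNS.values():
        frame[col] = frame[col].astype("Int64")
    frame["af_day"] = frame["af_day"].astype("Int64")

    # stroke outcome driven by the delta CHA2DS2-VASc score
    delta = score_frame(frame, builtin_weights("chads_vasc"))["delta"].to_numpy()
    p_stroke = expit(params.stroke_model.intercept + params.stroke_model.per_point * delta)
    has_stroke = rng.random(2 * n) < p_stroke
    end_all = frame["followup_end"].to_numpy(dtype=np.int64)
    stroke_day = np.full(2 * n, np.nan)
    k = int(has_stroke.sum())
    if k:
        stroke_day[has_stroke] = rng.integers(1, end_all[has_stroke] + 1, size=k)
    frame["stroke_day"] = pd.array(stroke_day, dtype="Int64")
    frame["prior_af"] = 0
    frame["ablation"] = 0
    frame["died"] = 0
    frame = frame[list(CSV_COLUMNS)]
    frame["age_at_index"] = frame["age_at_index"].astype("Int64")
    frame["followup_end"] = frame["followup_end"].astype("Int64")
    return from_frame(frame)


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write a cohort to CSV (header mandatory, empty cell = absent)."""
    to_frame(records).to_csv(path, index=False)


def _parse_int_column(frame: pd.DataFrame, col: str, required: bool) -> pd.Series:
    raw = frame[col]
    parsed = pd.to_numeric(raw, errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(f"column {col!r}: unparsable integer at line {row}")
    if required and parsed.isna().any():
        # permitted: eligibility handles missing mandatory fields
        pass
    frac = parsed.dropna() % 1
    if (frac != 0).any():
        row = int((parsed % 1 != 0).idxmax()) + 2
        raise ValueError(f"column {col!r}: non-integer value at line {row}")
    return parsed.astype("Int64")


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV; malformed rows raise errors naming the line.

    Round-trip contract: ``read_cohort(write_cohort(x)) == x``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    out = pd.DataFrame()
    out["patient_id"] = frame["patient_id"]
    out["sex"] = frame["sex"]
    out["group"] = frame["group"]
    bad_group = frame["group"].notna() & ~frame["group"].isin(GROUPS)
    if bad_group.any():
        row = int(bad_group.idxmax()) + 2
        raise ValueError(f"column 'group': unknown group label at line {row}")
    for col in ("age_at_index", *COMPONENT_COLUMNS.values(), "followup_end", "af_day", "stroke_day"):
        out[col] = _parse_int_column(frame, col, required=False)
    for col in ("prior_af", "ablation", "died"):
        parsed = _parse_int_column(frame, col, required=True)
        bad = parsed.isna() | ~parsed.isin([0, 1])
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise ValueError(f"column {col!r}: boolean cell must be 0 or 1 at line {row}")
        out[col] = parsed.astype("int64")
    return from_frame(out[list(CSV_COLUMNS)])
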