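"""Domain types for longitudinal atrial-flutter patient records.

A cohort is a list of :class:`PatientRecord` objects (or the equivalent
:func:`to_frame` DataFrame). Days are integers relative to the index date
(the AFL diagnosis); day 0 is the index day, onset days ``<= 0`` mean the
comorbidity was already present at baseline. Comorbidity onsets are
permanent: a component is present at day ``t`` iff its onset day is
``<= t``, so presence as a function of time never reverts.

Two study-design rules live here:

* eligibility filtering (adults with complete records, no atrial
  fibrillation at or before the index date, no AFL catheter ablation
  during follow-up), applied in a fixed precedence so every excluded
  record is tallied exactly once; and
* counterpart follow-up assignment: each patient with solitary AFL
  inherits the follow-up end day of a matched AFL-then-AF counterpart,
  which makes the follow-up duration distribution identical between the
  two groups by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

#: Comorbidity components tracked per patient (score components plus COPD).
COMPONENTS = (
    "heart_failure",
    "hypertension",
    "diabetes",
    "stroke_tia",
    "vascular_disease",
    "copd",
)

GROUPS = ("solitary_afl", "afl_daf")
SEXES = ("female", "male")

#: Follow-up horizon in days (3 years).
FOLLOWUP_CAP_DAYS = 1095

#: Calendar-year length used for ageing arithmetic.
DAYS_PER_YEAR = 365.25

#: Mapping component name -> cohort CSV column holding its onset day.
COMPONENT_COLUMNS = {
    "heart_failure": "hf_onset",
    "hypertension": "htn_onset",
    "diabetes": "dm_onset",
    "stroke_tia": "stroke_onset",
    "vascular_disease": "vasc_onset",
    "copd": "copd_onset",
}

#: Canonical cohort CSV column order.
CSV_COLUMNS = (
    "patient_id",
    "sex",
    "age_at_index",
    "group",
    "hf_onset",
    "htn_onset",
    "dm_onset",
    "stroke_onset",
    "vasc_onset",
    "copd_onset",
    "followup_end",
    "af_day",
    "stroke_day",
    "prior_af",
    "ablation",
    "died",
)


@dataclass
class PatientRecord:
    """One subject's index-date covariates, timed onsets, window and outcomes.

    ``onset_day`` maps component names (see :data:`COMPONENTS`) to integer
    onset days relative to the index date; a missing key means the
    comorbidity never appears. ``af_day`` is the atrial-fibrillation
    diagnosis day (present exactly for the ``afl_daf`` group, where it
    equals ``followup_end_day``); ``stroke_day`` is the first post-index
    ischaemic-stroke hospitalisation day.
    """

    patient_id: str
    sex: str | None
    age_at_index: int | None
    group: str
    followup_end_day: int | None
    onset_day: dict[str, int] = field(default_factory=dict)
    af_day: int | None = None
    stroke_day: int | None = None
    prior_af: bool = False
    ablation_during_followup: bool = False
    died_during_followup: bool = False

    def has_component(self, component: str, day: int) -> bool:
        """True iff ``component`` is present at ``day`` (onset <= day)."""
        onset = self.onset_day.get(component)
        return onset is not None and onset <= day

    def age_at(self, day: int) -> int:
        """Attained age in whole years at ``day`` (365.25-day years)."""
        return self.age_at_index + math.floor(day / DAYS_PER_YEAR)


@dataclass
class EligibilityReport:
    """Flow-chart style tally of the eligibility filter."""

    n_input: int = 0
    n_excluded_missing_or_young: int = 0
    n_excluded_prior_af: int = 0
    n_excluded_ablation: int = 0
    n_eligible: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_input,
            self.n_excluded_missing_or_young,
            self.n_excluded_prior_af,
            self.n_excluded_ablation,
            self.n_eligible,
        )
        if any(c < 0 for c in counts):
            raise ValueError("eligibility counts must be non-negative")
        excluded = (
            self.n_excluded_missing_or_young + self.n_excluded_prior_af + self.n_excluded_ablation
        )
        if self.n_input - excluded != self.n_eligible:
            raise ValueError("eligibility counts do not add up")


def _is_missing_mandatory(rec: PatientRecord) -> bool:
    if rec.sex not in SEXES:
        return True
    if rec.age_at_index is None:
        return True
    if rec.group not in GROUPS:
        return True
    if rec.followup_end_day is None:
        return True
    return False


def apply_eligibility(
    records: Sequence[PatientRecord], missing_policy: str = "exclude"
) -> tuple[list[PatientRecord], EligibilityReport]:
    """Filter a cohort by the study's eligibility rules.

    Exclusion precedence is fixed: (1) missing mandatory fields or age
    below 20, (2) atrial fibrillation at or before the index date
    (``prior_af`` or an ``af_day <= 0``), (3) AFL catheter ablation during
    follow-up. Each record is counted once, under the first rule it
    violates. The operation is idempotent.

    Parameters
    ----------
    records
        Input cohort; may contain incomplete records.
    missing_policy
        ``"exclude"`` (default) drops records with missing mandatory
        fields; ``"error"`` raises on the first such record.

    Returns
    -------
    (eligible, report)
        The surviving records (input order preserved) and the tally.
    """
    if missing_policy not in ("exclude", "error"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    eligible: list[PatientRecord] = []
    n_missing_or_young = n_prior_af = n_ablation = 0
    for rec in records:
        if _is_missing_mandatory(rec):
            if missing_policy == "error":
                raise ValueError(f"record {rec.patient_id!r} has missing mandatory fields")
            n_missing_or_young += 1
        elif rec.age_at_index < 20:
            n_missing_or_young += 1
        elif rec.prior_af or (rec.af_day is not None and rec.af_day <= 0):
            n_prior_af += 1
        elif rec.ablation_during_followup:
            n_ablation += 1
        else:
            eligible.append(rec)
    report = EligibilityReport(
        n_input=len(records),
        n_excluded_missing_or_young=n_missing_or_young,
        n_excluded_prior_af=n_prior_af,
        n_excluded_ablation=n_ablation,
        n_eligible=len(eligible),
    )
    return eligible, report


def assign_counterpart_followup(
    pairs: Iterable[tuple[PatientRecord, PatientRecord]],
) -> list[PatientRecord]:
    """Assign each solitary-AFL patient the follow-up end of its counterpart.

    Every pair is ``(solitary, afl_daf)``; the solitary member's
    ``followup_end_day`` is set to the counterpart's AF diagnosis day, the
    AFL-then-AF member is returned unchanged. Output preserves pair order,
    flattened as ``[solitary_1, afl_daf_1, solitary_2, ...]``.

    Raises
    ------
    ValueError
        If a pair's groups are wrong or the counterpart lacks ``af_day``.
    """
    out: list[PatientRecord] = []
    for i, (sol, daf) in enumerate(pairs):
        if sol.group != "solitary_afl" or daf.group != "afl_daf":
            raise ValueError(f"pair {i}: expected (solitary_afl, afl_daf), got ({sol.group}, {daf.group})")
        if daf.af_day is None:
            raise ValueError(f"pair {i}: counterpart {daf.patient_id!r} has no af_day")
        out.append(replace(sol, followup_end_day=daf.af_day))
        out.append(daf)
    return out


def to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Convert records to the canonical cohort DataFrame (CSV layout).

    Day columns use the pandas nullable ``Int64`` dtype so absent values
    survive a CSV round trip as empty cells.
    """
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.patient_id,
            "sex": rec.sex,
            "age_at_index": rec.age_at_index,
            "group": rec.group,
            "followup_end": rec.followup_end_day,
            "af_day": rec.af_day,
            "stroke_day": rec.stroke_day,
            "prior_af": int(rec.prior_af),
            "ablation": int(rec.ablation_during_followup),
            "died": int(rec.died_during_followup),
        }
        for comp, col in COMPONENT_COLUMNS.items():
            row[col] = rec.onset_day.get(comp)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    for col in ("age_at_index", *COMPONENT_COLUMNS.values(), "followup_end", "af_day", "stroke_day"):
        frame[col] = frame[col].astype("Int64")
    for col in ("prior_af", "ablation", "died"):
        frame[col] = frame[col].astype("int64")
    return frame


def _opt_int(value) -> int | None:
    return None if pd.isna(value) else int(value)


def from_frame(frame: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`to_frame`."""
    records = []
    for row in frame.itertuples(index=False):
        onset = {}
        for comp, col in COMPONENT_COLUMNS.items():
            day = _opt_int(getattr(row, col))
            if day is not None:
                onset[comp] = day
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                sex=None if pd.isna(row.sex) else str(row.sex),
                age_at_index=_opt_int(row.age_at_index),
                group=str(row.group),
                followup_end_day=_opt_int(row.followup_end),
                onset_day=onset,
                af_day=_opt_int(row.af_day),
                stroke_day=_opt_int(row.stroke_day),
                prior_af=bool(row.prior_af),
                ablation_during_followup=bool(row.ablation),
                died_during_followup=bool(row.died),
            )
        )
    return records
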