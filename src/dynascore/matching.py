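"""Propensity-score estimation and 1:1 greedy nearest-neighbour matching.

The propensity score is the predicted probability of belonging to the
AFL-then-AF group given baseline covariates, from a main-effects logistic
regression (no interaction terms). Matching is greedy 1:1 nearest
neighbour on the *logit* of the propensity score, without replacement,
with a caliper of ``caliper_multiplier`` (default 0.2) times the pooled
standard deviation of the logit, and a seeded random traversal order over
treated patients. Ties in distance are broken toward the lowest control
patient id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from dynascore.cohort import COMPONENT_COLUMNS, PatientRecord, to_frame
from dynascore.scoring import builtin_weights, score_frame


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


#: Default propensity covariates: the baseline CHA2DS2-VASc score and its
#: components, COPD, and the baseline HATCH score.
DEFAULT_COVARIATES = (
    "chads_vasc_baseline",
    "female",
    "age_65_74",
    "age_ge75",
    "heart_failure",
    "hypertension",
    "diabetes",
    "stroke_tia",
    "vascular_disease",
    "copd",
    "hatch_baseline",
)


@dataclass
class PropensityFit:
    """A fitted propensity model plus per-patient scores."""

    coefficients: dict[str, float]
    patient_id: np.ndarray
    group: np.ndarray
    logit: np.ndarray
    probability: np.ndarray
    converged: bool
    n_iterations: int
    dropped: list[str] = field(default_factory=list)


@dataclass
class MatchResult:
    """1:1 matched pairs (treated = afl_daf, control = solitary)."""

    pairs: list[tuple[str, str]]
    distances: list[float]
    caliper_value: float
    n_unmatched_treated: int
    order_seed: int


def covariate_frame(cohort: pd.DataFrame | list[PatientRecord]) -> pd.DataFrame:
    """Derive the standard covariate columns from a cohort.

    Adds baseline component indicators, sex and age-band indicators, and
    the baseline CHA2DS2-VASc and HATCH scores. Extra columns already in
    the cohort frame are carried through, so user-supplied covariates
    (e.g. additional comorbidities) can be referenced by name.
    """
    frame = to_frame(cohort) if isinstance(cohort, list) else cohort.copy()
    out = frame.copy()
    out["female"] = (frame["sex"] == "female").astype(float)
    age = frame["age_at_index"].astype("int64")
    out["age_65_74"] = ((age >= 65) & (age < 75)).astype(float)
    out["age_ge75"] = (age >= 75).astype(float)
    for comp, col in COMPONENT_COLUMNS.items():
        onset = frame[col].astype("Float64")
        out[comp] = (onset.notna() & (onset <= 0)).astype(float)
    for name in ("chads_vasc", "hatch"):
        out[f"{name}_baseline"] = score_frame(frame, builtin_weights(name))["baseline"].to_numpy(
            dtype=float
        )
    return out


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for col in X.columns:
        x = X[col].to_numpy()
        levels = np.unique(x)
        if len(levels) != 2:
            continue
        means = [y[x == lv].mean() for lv in levels]
        if all(m in (0.0, 1.0) for m in means) and means[0] != means[1]:
            raise SeparationError(f"covariate {col!r} perfectly separates the groups")


def fit_propensity(
    cohort: pd.DataFrame | list[PatientRecord],
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
) -> PropensityFit:
    """Fit the propensity model (group == afl_daf on main effects).

    Constant covariates are dropped with a warning; collinear covariates
    are dropped (keeping the earliest listed) with a warning, so the
    default covariate menu — which includes both the aggregate score and
    its components — fits cleanly. Fitting is iteratively reweighted
    least squares to relative tolerance 1e-8 (at most 100 iterations),
    hence deterministic given the data.

    Raises
    ------
    SeparationError
        If a covariate perfectly separates the two groups.
    """
    design = covariate_frame(cohort)
    missing = [c for c in covariates if c not in design.columns]
    if missing:
        raise ValueError(f"covariates not found in cohort: {missing}")
    y = (design["group"] == "afl_daf").to_numpy(dtype=float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 patients per group to fit a propensity model")
    X = design[list(covariates)].astype(float)

    dropped: list[str] = []
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariates: {constant}", stacklevel=2)
        dropped += constant
        X = X.drop(columns=constant)
    # forward pass on rank contribution: drop columns in the span of the
    # intercept plus earlier-listed covariates
    keep_mask = np.ones(X.shape[1], dtype=bool)
    basis = np.ones((len(X), 1))
    for j, col in enumerate(X.columns):
        v = X[col].to_numpy()[:, None]
        proj, *_ = np.linalg.lstsq(basis, v, rcond=None)
        resid = v - basis @ proj
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(v)):
            keep_mask[j] = False
        else:
            basis = np.hstack([basis, v])
    collinear = [c for c, k in zip(X.columns, keep_mask) if not k]
    if collinear:
        warnings.warn(f"dropping collinear covariates: {collinear}", stacklevel=2)
        dropped += collinear
        X = X.drop(columns=collinear)

    _check_separation(X, y)
    exog = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, exog, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        if "separation" in str(exc).lower() or type(exc).__name__ == "PerfectSeparationError":
            raise SeparationError(str(exc)) from exc
        raise
    linpred = np.asarray(exog.to_numpy() @ res.params.to_numpy(), dtype=float)
    prob = 1.0 / (1.0 + np.exp(-linpred))
    eps = np.finfo(float).tiny
    prob = np.clip(prob, eps, 1 - eps)
    return PropensityFit(
        coefficients={k: float(v) for k, v in res.params.items()},
        patient_id=design["patient_id"].to_numpy(),
        group=design["group"].to_numpy(),
        logit=linpred,
        probability=prob,
        converged=bool(res.converged),
        n_iterations=int(res.fit_history.get("iteration", 0)) if isinstance(res.fit_history, dict) else 0,
        dropped=dropped,
    )


def greedy_match(
    fit: PropensityFit, caliper_multiplier: float = 0.2, order_seed: int = 0
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the propensity logit.

    Treated (afl_daf) patients are visited in a seeded random permutation;
    each takes the unused control with the smallest absolute logit
    difference, or stays unmatched if that minimum exceeds the caliper
    (``caliper_multiplier`` x the pooled-sample SD of the logit).
    """
    if caliper_multiplier <= 0:
        raise ValueError("caliper_multiplier must be positive")
    caliper_value = float(caliper_multiplier * np.std(fit.logit, ddof=1))
    treated = fit.group == "afl_daf"
    t_idx = np.flatnonzero(treated)
    c_idx = np.flatnonzero(~treated)
    # sort controls by patient id so argmin tie-break lands on the lowest id
    c_order = np.argsort(fit.patient_id[c_idx].astype(str), kind="stable")
    c_idx = c_idx[c_order]
    c_logit = fit.logit[c_idx]
    available = np.ones(len(c_idx), dtype=bool)

    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(t_idx))

    pairs: list[tuple[str, str]] = []
    distances: list[float] = []
    n_unmatched = 0
    for k in order:
        ti = t_idx[k]
        if not available.any():
            n_unmatched += 1
            continue
        dist = np.abs(c_logit - fit.logit[ti])
        dist[~available] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= caliper_value:
            available[j] = False
            pairs.append((str(fit.patient_id[ti]), str(fit.patient_id[c_idx[j]])))
            distances.append(float(dist[j]))
        else:
            n_unmatched += 1
    return MatchResult(
        pairs=pairs,
        distances=distances,
        caliper_value=caliper_value,
        n_unmatched_treated=n_unmatched,
        order_seed=order_seed,
    )


def match_summary(
    result: MatchResult, cohort: pd.DataFrame | list[PatientRecord]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Extract the matched sub-cohort and per-group counts.

    Returns the cohort rows belonging to any matched pair (both members)
    and a summary dict; matched group sizes are equal by construction.
    """
    frame = to_frame(cohort) if isinstance(cohort, list) else cohort
    ids = {pid for pair in result.pairs for pid in pair}
    known = set(frame["patient_id"].astype(str))
    unknown = ids - known
    if unknown:
        raise ValueError(f"match result references unknown patient ids: {sorted(unknown)[:5]}")
    matched = frame[frame["patient_id"].astype(str).isin(ids)].reset_index(drop=True)
    counts = matched["group"].value_counts().to_dict()
    summary = {
        "n_pairs": len(result.pairs),
        "n_matched_total": int(len(matched)),
        "n_afl_daf": int(counts.get("afl_daf", 0)),
        "n_solitary_afl": int(counts.get("solitary_afl", 0)),
        "n_unmatched_treated": result.n_unmatched_treated,
    }
    return matched, summary
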