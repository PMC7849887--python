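"""Outcome analysis: score-stratified relative risks and discrimination.

Two kinds of evaluation are provided:

* **Relative risk by score stratum** for a binary outcome (here: AF
  development in a 1:1 matched cohort). The 0-score stratum is the
  reference; risk ratios get Katz log-method 95% intervals, with a 0.5
  continuity correction when any contingency cell is empty, and sparse
  upper strata are merged upward into a top-coded band.

* **Discrimination comparison** of two score variants against a binary
  outcome (here: ischaemic stroke): tie-corrected Mann-Whitney AUC with
  DeLong variance, paired DeLong differences, and — after a univariate
  logistic calibration of outcome on score — the integrated
  discrimination improvement (IDI) and the category-free (continuous)
  net reclassification improvement (NRI).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm, rankdata

Z95 = norm.ppf(0.975)


@dataclass(frozen=True)
class RiskRow:
    """One score stratum's event risk relative to the 0-score stratum."""

    score_level: str
    n_total: int
    n_events: int
    relative_risk: float
    ci_low: float | None
    ci_high: float | None
    reference: bool


@dataclass(frozen=True)
class MetricEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class DiscriminationReport:
    """AUC / delta-AUC / IDI / NRI for a pair of score variants.

    All quantities are on the probability scale (AUC in [0, 1]); the
    comparison is antisymmetric: swapping the two models negates
    ``delta_auc``, ``idi`` and ``nri``.
    """

    model_new: str
    model_old: str
    auc_new: MetricEstimate
    auc_old: MetricEstimate
    delta_auc: MetricEstimate
    idi: MetricEstimate
    nri: MetricEstimate

    def to_dict(self) -> dict:
        return asdict(self)


def _as_outcome(outcome) -> np.ndarray:
    y = np.asarray(outcome, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("outcome needs at least one event and one non-event")
    return y


def _delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong structural components (V10 events, V01 non-events)."""
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    allr = rankdata(np.concatenate([pos, neg]))
    pos_r, neg_r = allr[:m], allr[m:]
    auc_hat = (pos_r.sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (pos_r - rankdata(pos)) / n
    v01 = 1.0 - (neg_r - rankdata(neg)) / m
    return float(auc_hat), v10, v01


def auc(scores, outcome) -> tuple[float, tuple[float, float]]:
    """Tie-corrected concordance (Mann-Whitney) AUC with a DeLong 95% CI.

    Ties between an event and a non-event score count 1/2. Requires at
    least one event and one non-event.
    """
    y = _as_outcome(outcome)
    s = np.asarray(scores, dtype=float)
    auc_hat, v10, v01 = _delong_components(s, y)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    half = Z95 * math.sqrt(max(var, 0.0))
    return auc_hat, (max(0.0, auc_hat - half), min(1.0, auc_hat + half))


def delta_auc(scores_a, scores_b, outcome) -> MetricEstimate:
    """Paired DeLong difference AUC(a) - AUC(b) on the same patients.

    Antisymmetric in its score arguments. Identical score vectors give a
    zero estimate with a degenerate interval and p = 1.
    """
    y = _as_outcome(outcome)
    s_a = np.asarray(scores_a, dtype=float)
    s_b = np.asarray(scores_b, dtype=float)
    if s_a.shape != s_b.shape or s_a.shape != y.shape:
        raise ValueError("score vectors and outcome must be aligned")
    auc_a, v10_a, v01_a = _delong_components(s_a, y)
    auc_b, v10_b, v01_b = _delong_components(s_b, y)
    est = auc_a - auc_b
    m, n = len(v10_a), len(v01_a)
    cov10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    cov01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (cov10[0, 0] + cov10[1, 1] - 2 * cov10[0, 1]) / m
    var += (cov01[0, 0] + cov01[1, 1] - 2 * cov01[0, 1]) / n
    var = max(float(var), 0.0)
    se = math.sqrt(var)
    if se == 0.0:
        return MetricEstimate(est, est, est, 1.0 if est == 0 else 0.0)
    z = est / se
    return MetricEstimate(est, est - Z95 * se, est + Z95 * se, 2 * (1 - norm.cdf(abs(z))))


def score_to_risk(scores, outcome) -> np.ndarray:
    """Per-patient event probabilities from a univariate logistic calibration.

    IDI and NRI operate on risks, not raw scores; the calibration is a
    logistic fit of outcome on score (monotone in the score). Degenerate
    cases: a constant score yields the event prevalence everywhere, and
    perfect separation falls back to empirical per-level event rates with
    a 0.5 continuity correction.
    """
    y = _as_outcome(outcome).astype(float)
    s = np.asarray(scores, dtype=float)
    if np.ptp(s) == 0.0:
        return np.full_like(s, y.mean())
    exog = sm.add_constant(s)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=100)
        if not np.all(np.isfinite(res.params)) or not res.mle_retvals.get("converged", False):
            raise RuntimeError("logistic calibration did not converge")
        prob = np.asarray(res.predict(exog), dtype=float)
    except Exception:
        # separation fallback: empirical per-level rates, continuity-corrected
        prob = np.empty_like(s)
        for level in np.unique(s):
            mask = s == level
            prob[mask] = (y[mask].sum() + 0.5) / (mask.sum() + 1.0)
    eps = 1e-12
    return np.clip(prob, eps, 1 - eps)


def idi(prob_new, prob_old, outcome) -> MetricEstimate:
    """Integrated discrimination improvement with an asymptotic 95% CI.

    IDI = (mean new - old risk difference among events) minus the same
    among non-events; equivalently the change in discrimination slope.
    Events and non-events are treated as independent samples.
    """
    y = _as_outcome(outcome)
    d = np.asarray(prob_new, dtype=float) - np.asarray(prob_old, dtype=float)
    d_e, d_n = d[y], d[~y]
    est = float(d_e.mean() - d_n.mean())
    var = d_e.var(ddof=1) / len(d_e) + d_n.var(ddof=1) / len(d_n)
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        return MetricEstimate(est, est, est, 1.0 if est == 0 else 0.0)
    z = est / se
    return MetricEstimate(est, est - Z95 * se, est + Z95 * se, 2 * (1 - norm.cdf(abs(z))))


def category_free_nri(prob_new, prob_old, outcome) -> MetricEstimate:
    """Continuous (category-free) net reclassification improvement.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) -
    P(up|non-event)], where up/down is any increase/decrease of predicted
    risk under the new model; ties count in neither direction. The
    estimate lies in [-2, 2].
    """
    y = _as_outcome(outcome)
    p_new = np.asarray(prob_new, dtype=float)
    p_old = np.asarray(prob_old, dtype=float)
    up, down = p_new > p_old, p_new < p_old
    n_e, n_n = int(y.sum()), int((~y).sum())
    pu_e, pd_e = up[y].mean(), down[y].mean()
    pu_n, pd_n = up[~y].mean(), down[~y].mean()
    nri_e = pu_e - pd_e
    nri_n = pd_n - pu_n
    est = float(nri_e + nri_n)
    var = (pu_e + pd_e - nri_e**2) / n_e + (pu_n + pd_n - nri_n**2) / n_n
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        return MetricEstimate(est, est, est, 1.0 if est == 0 else 0.0)
    z = est / se
    return MetricEstimate(est, est - Z95 * se, est + Z95 * se, 2 * (1 - norm.cdf(abs(z))))


def compare_scores(scores_new, scores_old, outcome, label_new: str, label_old: str) -> DiscriminationReport:
    """Full discrimination comparison of two score variants."""
    y = _as_outcome(outcome)
    a_new, ci_new = auc(scores_new, y)
    a_old, ci_old = auc(scores_old, y)
    p_new = score_to_risk(scores_new, y)
    p_old = score_to_risk(scores_old, y)
    return DiscriminationReport(
        model_new=label_new,
        model_old=label_old,
        auc_new=MetricEstimate(a_new, ci_new[0], ci_new[1], math.nan),
        auc_old=MetricEstimate(a_old, ci_old[0], ci_old[1], math.nan),
        delta_auc=delta_auc(scores_new, scores_old, y),
        idi=idi(p_new, p_old, y),
        nri=category_free_nri(p_new, p_old, y),
    )


def _katz_rr(a: int, n1: int, c: int, n0: int) -> tuple[float, float, float]:
    """Risk ratio with Katz log-method 95% CI; 0.5 correction on empty cells."""
    if min(a, c, n1 - a, n0 - c) == 0:
        a_, c_ = a + 0.5, c + 0.5
        n1_, n0_ = n1 + 1.0, n0 + 1.0
    else:
        a_, c_, n1_, n0_ = float(a), float(c), float(n1), float(n0)
    rr = (a_ / n1_) / (c_ / n0_)
    se = math.sqrt(1.0 / a_ - 1.0 / n1_ + 1.0 / c_ - 1.0 / n0_)
    return rr, rr * math.exp(-Z95 * se), rr * math.exp(Z95 * se)


def risk_table_by_score(scores, outcome, min_stratum: int = 20) -> list[RiskRow]:
    """Event risk per score level relative to the 0-score reference.

    Integer score levels above the reference with fewer than
    ``min_stratum`` patients are merged upward with the next higher
    levels; a sparse remainder at the top joins the band below it, so the
    highest band is labelled ``"k+"`` when merged.

    Raises
    ------
    ValueError
        If the reference (score 0) stratum is empty or the outcome is
        degenerate (single-group / no events).
    """
    y = _as_outcome(outcome)
    s = np.asarray(scores)
    levels = np.unique(s)
    if 0 not in levels:
        raise ValueError("reference stratum (score 0) is empty")
    ref_mask = s == 0
    n0, c = int(ref_mask.sum()), int(y[ref_mask].sum())
    rows = [
        RiskRow(
            score_level="0",
            n_total=n0,
            n_events=c,
            relative_risk=1.0,
            ci_low=None,
            ci_high=None,
            reference=True,
        )
    ]
    upper = [int(v) for v in levels if v > 0]
    bands: list[list[int]] = []
    current: list[int] = []
    for level in upper:
        current.append(level)
        if int((np.isin(s, current)).sum()) >= min_stratum:
            bands.append(current)
            current = []
    if current:
        if bands:
            bands[-1].extend(current)
        else:
            bands.append(current)
    for band in bands:
        mask = np.isin(s, band)
        n1, a = int(mask.sum()), int(y[mask].sum())
        rr, lo, hi = _katz_rr(a, n1, c, n0)
        if len(band) == 1:
            label = str(band[0])
        elif band[-1] == upper[-1]:
            label = f"{band[0]}+"
        else:
            label = f"{band[0]}-{band[-1]}"
        rows.append(
            RiskRow(
                score_level=label,
                n_total=n1,
                n_events=a,
                relative_risk=rr,
                ci_low=lo,
                ci_high=hi,
                reference=False,
            )
        )
    return rows
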