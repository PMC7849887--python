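# Methods

## Cohort model

A patient record carries sex, integer age at the index date (the AFL
diagnosis), group label (`solitary_afl` / `afl_daf`), per-comorbidity
integer onset days relative to index, a follow-up end day in 1..1095, and
outcome days (AF, first post-index ischaemic-stroke hospitalisation).
Conventions:

- Day 0 is the index day; onset ≤ 0 means present at baseline.
- Comorbidities are permanent: present at day *t* iff onset ≤ *t*.
- The follow-up horizon is fixed at 1095 days (3 years); follow-up scores
  are evaluated at the end of the window.
- Attained age is `age_at_index + floor(day / 365.25)`; the 65–74 and ≥75
  bands include the birthday itself.
- AFL-then-AF records have `af_day == followup_end_day`; each solitary-AFL
  record inherits its counterpart's AF day as its own follow-up end
  (counterpart assignment), which equalises the follow-up duration
  distribution across groups by construction.

Eligibility excludes, in fixed precedence with each record tallied once:
(1) missing mandatory fields or age < 20, (2) AF at or before index — a
record with `af_day ≤ 0` is treated as prevalent AF, since day-level data
cannot order "simultaneous" diagnoses, (3) AFL catheter ablation during
follow-up. No imputation is attempted for missing fields.

## Synthetic cohort generator

The generator emulates the structure of a matched claims cohort; all
defaults are the published study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 4101 | matched group size |
| `baseline_prevalence` | e.g. HF 0.120/0.127 | per-group baseline comorbidity probabilities |
| `incident_prob` | e.g. HF 0.093/0.221, stroke 0.049/0.127, vascular 0.117/0.175 | marginal probability of acquiring the component during follow-up |
| `female_prob` | 0.383 | shared by both groups (matched) |
| `age_band_probs` | 1212/4101, 1201/4101, 1688/4101 | <65 / 65–74 / ≥75; ages uniform within band (20–64, 65–74, 75–94) |
| `followup_shape` | median 0.47 y, mean 0.81 y, cap 1095 d | capped log-normal duration |
| `stroke_model` | intercept −2.6, +0.55/point | logistic link from delta score to stroke probability |

Implementation notes:

- Follow-up durations are log-normal capped at 1095 days. The median of
  the capped variable pins `mu = log(median)`; `sigma` is solved by
  Brent root-finding on the closed-form capped mean
  `E[min(X,c)] = exp(mu+s²/2)Φ((log c − mu − s²)/s) + c(1 − Φ((log c − mu)/s))`.
- Incident events: the configured probabilities are *marginal* over the
  group (matching how incident counts are reported, out of the full group
  size). Internally the per-patient conditional probability among the
  baseline-free is `p_inc / (1 − p_base)`, so the expected incident
  proportion equals the configured value exactly. Onset days are uniform
  on (0, follow-up end]; only end-of-window presence matters downstream,
  so the timing convention is inert.
- The stroke outcome is generated from the delta CHA₂DS₂-VASc score, not
  the follow-up score; that the delta score discriminates stroke better is
  therefore a construction property of the generator — tests and reports
  assert the *direction*, never the published magnitudes. The default
  intercept/slope give ≈10% overall event rate and a delta-score AUC near
  0.6, a realistic 3-year ischaemic-stroke profile for an elderly
  arrhythmia cohort.
- Components are drawn independently; real comorbidities are correlated
  (e.g. hypertension with vascular disease), so passing tests say nothing
  about correlation-sensitive behaviour. Ageing during follow-up induces
  small age-band crossings (delta-of-age), as in real cohorts.
- Identical parameters and seed give bit-identical output (single
  `default_rng` stream, fixed draw order).

## Propensity matching

The propensity model is a main-effects logistic regression of group
membership on baseline covariates, fitted by IRLS (statsmodels GLM,
relative tolerance 1e-8, ≤100 iterations — deterministic given data).
Constant covariates are dropped with a warning; collinear covariates are
dropped keeping the earliest listed (the default menu contains the
aggregate score *and* its components, which is rank-deficient by
construction — the fitted logit is invariant to the basis kept). A
covariate that perfectly separates the groups raises an error naming it.

Matching is greedy 1:1 nearest neighbour on the logit, without
replacement: treated patients are visited in a seeded random permutation;
each takes the unused control with minimal |logit difference|, skipped if
that minimum exceeds the caliper = 0.2 × SD of the logit. The SD is taken
over the pooled (both-group) sample, the common convention for this
caliper rule. Exact distance ties break toward the lowest control id, so
results are reproducible given the order seed. An exact-match constraint
(e.g. on diagnosis year) is not applied in synthetic mode, where no
calendar years are generated; additional covariates can be supplied by
adding columns to the cohort frame and naming them in the config.

## Balance and weight derivation

Standardized differences use the pooled two-group forms (binary: pooled
proportion variance; continuous: root-mean pooled variance) — these
reproduce every published STD that is checkable from printed counts to
2 decimals. Classification: |STD| < 0.1 negligible, 0.1–0.2 moderate
(both endpoints inclusive, since "less than 0.1" is negligible and
"exceeding 0.2" is substantial), > 0.2 substantial. Degenerate inputs
(both groups constant but unequal) yield a signed infinity, classified
substantial. Reported tables round STD to 2 decimals; internal
computation keeps full precision. Sign convention: group A is solitary
AFL, so adverse incident contrasts are negative.

`derive_weights` maps the *delta*-timepoint category of each of the five
scored comorbidities (HF, hypertension, diabetes, stroke/TIA, vascular
disease) to a weight: substantial → 2, moderate → 1, negligible → 0.
Sex and age-band weights are inherited from the base weight set, COPD is
0. The rule is deterministic and idempotent. Multi-level variables (age
bands) are reported as per-level binary rows; aggregate scores as
continuous mean ± SD rows.

## Outcome evaluation

- **Relative risk by score stratum** (outcome: AF development, i.e. group
  membership in the matched cohort): the 0-score stratum is the
  reference; RR confidence intervals use the Katz log method
  `exp(ln RR ± 1.96·sqrt(1/a − 1/n_s + 1/c − 1/n_0))`, with a 0.5
  continuity correction on all four cells when any cell is empty. Levels
  above the reference with fewer than 20 patients are merged upward into
  the next band; a sparse remainder at the very top joins the band below
  it (labelled `k+`).
- **AUC** is the tie-corrected Mann–Whitney concordance (ties 0.5 —
  mandatory here, since integer scores tie heavily), with DeLong
  structural-component variance for the CI; paired comparisons use the
  covariance-adjusted DeLong difference, antisymmetric in its arguments.
- **IDI / category-free NRI** operate on risks, obtained by a univariate
  logistic calibration of the outcome on the score (monotone in the
  score). A constant score yields the event prevalence everywhere;
  perfect separation falls back to empirical per-level rates with a 0.5
  continuity correction. IDI is the change in discrimination slope with
  an independent-samples asymptotic SE; continuous NRI counts any risk
  increase/decrease (ties count in neither direction), estimate bounded
  in [−2, 2]. Two-sided normal p-values, no multiplicity adjustment.

## Pipeline

`run_pipeline` executes simulate → eligibility → match → score → balance
→ derive-weights → evaluate, writing plain-text artifacts (CSV/JSON/YAML)
plus a manifest with seeds and per-stage counts. One global seed spawns
per-stage seeds through `numpy.random.SeedSequence`, so stages are
individually re-runnable and the whole run is byte-reproducible. The CLI
(`dynascore`) exposes each stage and `run-all`; exit codes are 0 (ok),
1 (stage/config failure), 2 (usage error).

## Problem sizes used in the test suite

Unit tests run on 300-per-group cohorts; the end-to-end scientific checks
use the study's matched scale (4101 per group) — 100 seeded replicates
for weight recovery, 3 replicates for post-match balance, and a single
seeded cohort for the discrimination-direction checks. Convergence checks
of the generator use 25 000 per group.

## Known limitations

- Independence of comorbidity draws (no correlation structure; a config
  hook would be needed for correlated draws).
- No competing-risk or death modelling beyond the design restriction that
  solitary-AFL patients survive follow-up; no treatment (anticoagulation,
  ablation success) modelling.
- Stroke absolute rates are not calibrated to any national incidence;
  only their dependence on the delta score is modelled.
- At the study's own incident rates the incident-vascular-disease
  contrast (expected STD ≈ −0.16 at n = 4101/group, sampling SD ≈ 0.022)
  lies within 2 SE of the moderate/substantial boundary, so a mid-single-
  digit percentage of seeds classify it substantial and derive a weight
  of 2 instead of 1 — an inherent sampling property of the derivation
  rule near its thresholds, visible in the seeded weight-recovery test.
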