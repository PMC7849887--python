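"""Config-driven end-to-end orchestration of the analysis.

Stage order follows the study design: generate (or load) the cohort,
apply eligibility, propensity-match, score the matched cohort, tabulate
balance, derive the reweighted score, and evaluate outcomes (relative
risk of AF by score stratum; stroke discrimination of delta vs follow-up
scores). Each stage writes a plain-text artifact so it can be re-run in
isolation, and a manifest records seeds and per-stage record counts.
A single global seed deterministically spawns the per-stage seeds, so
identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dynascore import balance as _balance
from dynascore import evaluation as _evaluation
from dynascore import matching as _matching
from dynascore import synthetic as _synthetic
from dynascore.cohort import GROUPS, apply_eligibility, to_frame
from dynascore.scoring import BUILTIN_NAMES, builtin_weights, score_frame

logger = logging.getLogger("dynascore")

_MAX_SEED = 2**31


@dataclass
class PipelineConfig:
    """Typed configuration for the full pipeline run."""

    gen: _synthetic.CohortGenParams = field(default_factory=_synthetic.CohortGenParams)
    caliper_multiplier: float = 0.2
    covariates: tuple[str, ...] = _matching.DEFAULT_COVARIATES
    score_names: tuple[str, ...] = ("chads_vasc", "a2c2s2_vasc")
    min_stratum: int = 20
    seed: int = 0


def _collect_prob_errors(table: dict, key: str, errors: list[str]) -> None:
    for group, comps in table.items():
        if group not in GROUPS:
            errors.append(f"{key}: unknown group {group!r}")
            continue
        for comp, p in comps.items():
            if not isinstance(p, (int, float)) or not 0.0 <= float(p) <= 1.0:
                errors.append(f"{key}.{group}.{comp}: probability {p!r} not in [0, 1]")


def config_from_mapping(raw: dict) -> tuple[PipelineConfig | None, list[str]]:
    """Build a config from a parsed mapping, collecting all violations."""
    errors: list[str] = []
    raw = dict(raw or {})
    gen_kwargs: dict = {}
    if "n_per_group" in raw:
        n = raw["n_per_group"]
        if not isinstance(n, int) or n < 0:
            errors.append(f"n_per_group: {n!r} is not a non-negative integer")
        else:
            gen_kwargs["n_per_group"] = n
    if "seed" in raw and not isinstance(raw["seed"], int):
        errors.append(f"seed: {raw['seed']!r} is not an integer")
    for key in ("baseline_prevalence", "incident_prob"):
        if key in raw:
            _collect_prob_errors(raw[key], key, errors)
            merged = {
                g: {
                    **(
                        _synthetic.DEFAULT_BASELINE_PREVALENCE
                        if key == "baseline_prevalence"
                        else _synthetic.DEFAULT_INCIDENT_PROB
                    )[g],
                    **raw[key].get(g, {}),
                }
                for g in GROUPS
            }
            gen_kwargs[key] = merged
    if "female_prob" in raw:
        p = raw["female_prob"]
        if not isinstance(p, (int, float)) or not 0.0 <= float(p) <= 1.0:
            errors.append(f"female_prob: {p!r} not in [0, 1]")
        else:
            gen_kwargs["female_prob"] = float(p)
    if "age_band_probs" in raw:
        probs = raw["age_band_probs"]
        if not isinstance(probs, (list, tuple)) or len(probs) != 3:
            errors.append("age_band_probs: need exactly three probabilities")
        else:
            gen_kwargs["age_band_probs"] = tuple(float(p) for p in probs)
    if "followup" in raw:
        try:
            gen_kwargs["followup_shape"] = _synthetic.FollowupShape(**raw["followup"])
        except TypeError as exc:
            errors.append(f"followup: {exc}")
    if "stroke_model" in raw:
        try:
            gen_kwargs["stroke_model"] = _synthetic.StrokeModel(**raw["stroke_model"])
        except TypeError as exc:
            errors.append(f"stroke_model: {exc}")

    matching_raw = raw.get("matching", {}) or {}
    caliper = matching_raw.get("caliper_multiplier", 0.2)
    if not isinstance(caliper, (int, float)) or caliper <= 0:
        errors.append(f"matching.caliper_multiplier: {caliper!r} must be positive")
    covariates = tuple(matching_raw.get("covariates", _matching.DEFAULT_COVARIATES))

    eval_raw = raw.get("evaluation", {}) or {}
    score_names = tuple(eval_raw.get("score_names", ("chads_vasc", "a2c2s2_vasc")))
    for name in score_names:
        if name not in BUILTIN_NAMES:
            errors.append(f"evaluation.score_names: unknown score {name!r}; valid: {', '.join(BUILTIN_NAMES)}")
    min_stratum = eval_raw.get("min_stratum", 20)
    if not isinstance(min_stratum, int) or min_stratum < 1:
        errors.append(f"evaluation.min_stratum: {min_stratum!r} must be a positive integer")

    if errors:
        return None, errors
    gen = _synthetic.CohortGenParams(seed=raw.get("seed", 0), **gen_kwargs)
    try:
        gen.validate()
    except ValueError as exc:
        return None, [str(exc)]
    return (
        PipelineConfig(
            gen=gen,
            caliper_multiplier=float(caliper),
            covariates=covariates,
            score_names=score_names,
            min_stratum=min_stratum,
            seed=raw.get("seed", 0),
        ),
        [],
    )


def validate_config(path) -> tuple[PipelineConfig | None, list[str]]:
    """Load and validate a YAML config; returns (config, violations).

    All violations are collected (not fail-fast); the config is None
    whenever the list is non-empty.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        return None, [f"config parse error: {exc}"]
    if raw is not None and not isinstance(raw, dict):
        return None, ["config must be a mapping of keys to values"]
    return config_from_mapping(raw or {})


def _spawn_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(3)
    return {
        "generator": int(state[0] % _MAX_SEED),
        "match_order": int(state[1] % _MAX_SEED),
        "spare": int(state[2] % _MAX_SEED),
    }


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Execute all stages and write artifacts under ``outdir``.

    Returns the manifest dict (also written to ``manifest.json``). Any
    stage failure propagates as an exception naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    global_seed = config.seed if seed is None else seed
    seeds = _spawn_seeds(global_seed)
    manifest: dict = {"seed": global_seed, "stage_seeds": seeds, "stages": {}}

    stage = "simulate"
    try:
        params = dataclasses.replace(config.gen, seed=seeds["generator"])
        records = _synthetic.generate_cohort(params)
        _synthetic.write_cohort(records, outdir / "cohort.csv")
        manifest["stages"]["simulate"] = {"n_records": len(records)}
        logger.info("simulate: %d records", len(records))

        stage = "eligibility"
        eligible, report = apply_eligibility(records)
        manifest["stages"]["eligibility"] = dataclasses.asdict(report)
        logger.info("eligibility: %d of %d eligible", report.n_eligible, report.n_input)
        frame = to_frame(eligible)

        stage = "match"
        fit = _matching.fit_propensity(frame, config.covariates)
        result = _matching.greedy_match(
            fit, caliper_multiplier=config.caliper_multiplier, order_seed=seeds["match_order"]
        )
        matched, summary = _matching.match_summary(result, frame)
        pd.DataFrame(
            {
                "treated_id": [p[0] for p in result.pairs],
                "control_id": [p[1] for p in result.pairs],
                "logit_distance": result.distances,
            }
        ).to_csv(outdir / "matches.csv", index=False)
        manifest["stages"]["match"] = {**summary, "caliper_value": result.caliper_value}
        logger.info("match: %d pairs (caliper %.4f)", summary["n_pairs"], result.caliper_value)

        stage = "score"
        score_tables = []
        for name in config.score_names:
            score_tables.append(score_frame(matched, builtin_weights(name)))
        pd.concat(score_tables, ignore_index=True).to_csv(outdir / "scores.csv", index=False)
        manifest["stages"]["score"] = {"variants": list(config.score_names), "n_patients": len(matched)}

        stage = "balance"
        rows = _balance.balance_table(matched)
        _balance.balance_frame(rows).to_csv(outdir / "balance.csv", index=False)
        (outdir / "balance.json").write_text(
            json.dumps([dataclasses.asdict(r) for r in rows], indent=2, sort_keys=True),
            encoding="utf-8",
        )
        manifest["stages"]["balance"] = {"n_rows": len(rows)}

        stage = "derive_weights"
        derived = _balance.derive_weights(rows, builtin_weights("chads_vasc"))
        with open(outdir / "derived_weights.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump({"name": derived.name, "weights": dict(derived.weights)}, fh, sort_keys=True)
        manifest["stages"]["derive_weights"] = {"name": derived.name, "weights": dict(derived.weights)}
        logger.info("derive_weights: %s", dict(derived.weights))

        stage = "evaluate"
        af_outcome = (matched["group"] == "afl_daf").to_numpy()
        stroke_outcome = matched["stroke_day"].notna().to_numpy()
        scores = {
            name: score_frame(matched, builtin_weights(name)) for name in config.score_names
        }
        for name, table in scores.items():
            for timepoint in ("follow_up", "delta"):
                risk_rows = _evaluation.risk_table_by_score(
                    table[timepoint].to_numpy(), af_outcome, min_stratum=config.min_stratum
                )
                pd.DataFrame([dataclasses.asdict(r) for r in risk_rows]).to_csv(
                    outdir / f"risk_{name}_{timepoint}.csv", index=False
                )
        comparisons = []
        for name, table in scores.items():
            comparisons.append(
                _evaluation.compare_scores(
                    table["delta"].to_numpy(),
                    table["follow_up"].to_numpy(),
                    stroke_outcome,
                    f"{name}:delta",
                    f"{name}:follow_up",
                )
            )
        if {"chads_vasc", "a2c2s2_vasc"} <= set(scores):
            for timepoint in ("follow_up", "delta"):
                comparisons.append(
                    _evaluation.compare_scores(
                        scores["a2c2s2_vasc"][timepoint].to_numpy(),
                        scores["chads_vasc"][timepoint].to_numpy(),
                        stroke_outcome,
                        f"a2c2s2_vasc:{timepoint}",
                        f"chads_vasc:{timepoint}",
                    )
                )
        (outdir / "discrimination.json").write_text(
            json.dumps([c.to_dict() for c in comparisons], indent=2, sort_keys=True),
            encoding="utf-8",
        )
        manifest["stages"]["evaluate"] = {
            "n_stroke_events": int(stroke_outcome.sum()),
            "n_comparisons": len(comparisons),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
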