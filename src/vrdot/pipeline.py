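"""End-to-end screening pipeline.

Orchestrates: simulate/ingest -> score -> (optional) calibrate ->
psychomotor derivation -> per-subject slopes -> correlation matrix ->
per-pair ROC/AUC/cutoffs -> conversion prediction -> report bundle.

Every artifact is stamped with the seed and a hash of the configuration;
reruns with the same seed and config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationConfig, calibrate
from .discrimination import auc_ci, optimal_cutoff, partial_spearman, roc_curve
from .longitudinal import measurement_table, rate_of_change_features
from .prediction import classify, fit_logistic, nagelkerke_r2
from .psychomotor import derive_metrics
from .scoring import score_cohort
from .session_model import CohortDataset, ScoreParams, load_cohort
from .synthetic_data import default_config, generate_cohort, make_pilot

log = logging.getLogger("vrdot.pipeline")

#: screening measures entering the correlation and AUC tables, with the
#: direction in which each indicates impairment.
SCREENING_MEASURES = {
    "mmse": "lower-is-positive",
    "bristol_adl": "higher-is-positive",
    "blessed_adl": "higher-is-positive",
    "ravlt_delayed": "lower-is-positive",
    "fi": "lower-is-positive",
}

GROUP_PAIRS = (("control", "aMCI"), ("aMCI", "mildAD"))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One input source (a cohort file or a simulation), score-parameter
    source (explicit weights or calibrate-on-pilot), and analysis knobs."""

    input_path: str | None = None  # cohort JSON; mutually exclusive with simulate
    simulate: bool = True
    seed: int = 0
    score_params: tuple[float, float, float, float] | None = None
    calibrate_on_pilot: bool = True
    calibration_grid_step: float = 0.1
    rho_mmse_min: float = 0.6
    rho_iadl_max: float = -0.6
    outcome_column: str = "converted_to_ad"
    forced_in: tuple[str, ...] = ()
    n_boot: int = 2000
    out_dir: str = "vrdot_out"

    def __post_init__(self):
        if self.input_path is not None and self.simulate:
            raise ValueError("exactly one input source: set input_path or simulate, not both")
        if self.input_path is None and not self.simulate:
            raise ValueError("exactly one input source: set input_path or simulate")

    def config_hash(self) -> str:
        doc = {k: v for k, v in self.__dict__.items()}
        doc["forced_in"] = list(self.forced_in)
        if doc.get("score_params") is not None:
            doc["score_params"] = list(doc["score_params"])
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stamp(config: PipelineConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash(),
            "vrdot_version": __version__}


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_json(path: Path, doc: dict) -> None:
    path.write_text(json.dumps(_json_safe(doc), indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full battery; write the artifact bundle; return the report."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(config)

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.monotonic() - t0)

    # --- input
    stage("input")
    try:
        if config.simulate:
            cohort = generate_cohort(default_config(), seed=config.seed)
        else:
            cohort = load_cohort(config.input_path, format="json")
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError("input", str(e)) from e

    # --- score parameters
    stage("calibrate")
    try:
        if config.score_params is not None:
            params = ScoreParams(*config.score_params)
            cal_doc = {"source": "explicit", "k": list(params.as_tuple()), **stamp}
        elif config.calibrate_on_pilot:
            pilot = make_pilot(default_config(), seed=config.seed + 1)
            ccfg = CalibrationConfig(
                grid_step=config.calibration_grid_step,
                rho_mmse_min=config.rho_mmse_min,
                rho_iadl_max=config.rho_iadl_max,
            )
            cal = calibrate(pilot, ccfg)
            params = cal.final
            cal_doc = {
                "source": "pilot-calibration",
                "k": list(params.as_tuple()),
                "n_candidates": int(len(cal.diagnostics)),
                "n_accepted": int(len(cal.accepted)),
                **stamp,
            }
        else:
            params = ScoreParams(0.3, 0.2, 0.4, 0.1)
            cal_doc = {"source": "default", "k": list(params.as_tuple()), **stamp}
    except Exception as e:
        raise PipelineError("calibrate", str(e)) from e
    _write_json(out / "params.json", cal_doc)

    # --- scoring
    stage("score")
    try:
        scores = score_cohort(cohort, params)
    except Exception as e:
        raise PipelineError("score", str(e)) from e
    scores.to_csv(out / "scores.csv", index=False)

    # --- psychomotor + features
    stage("features")
    try:
        derived = derive_metrics(cohort, adjust="apply")
        table = measurement_table(cohort, scores=scores, derived=derived)
        groups = {s.subject_id: s.group for s in cohort.subjects}
        feat_measures = [
            "reff", "fi", "mmse", "bristol_adl", "blessed_adl", "ravlt_delayed",
            "gait_speed_adj", "stride_length_adj", "tap_rate_dom",
        ]
        features = rate_of_change_features(table, feat_measures, groups=groups)
        meta = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in cohort.subjects],
                "group": [s.group for s in cohort.subjects],
                "age": [s.age for s in cohort.subjects],
                "sex": [s.sex for s in cohort.subjects],
                "education_years": [s.education_years for s in cohort.subjects],
                "converted_to_ad": [s.converted_to_ad for s in cohort.subjects],
            }
        )
        features = meta.merge(features, on="subject_id")
    except Exception as e:
        raise PipelineError("features", str(e)) from e
    features.to_csv(out / "features.csv", index=False)

    # --- partial correlation matrix (baseline, controlling age/sex/edu)
    stage("correlations")
    try:
        base = table[table["visit_year"] == 1].merge(
            meta[["subject_id", "age", "sex", "education_years"]], on="subject_id"
        )
        corr = _partial_corr_matrix(base, ["fi", "mmse", "bristol_adl"])
    except Exception as e:
        raise PipelineError("correlations", str(e)) from e

    # --- ROC battery
    stage("roc")
    try:
        auc_table, cutoffs = _roc_battery(base, meta, config, out, stamp)
    except Exception as e:
        raise PipelineError("roc", str(e)) from e

    # --- conversion prediction (aMCI only)
    stage("predict")
    try:
        conversion = _conversion_models(features, config)
    except Exception as e:
        raise PipelineError("predict", str(e)) from e
    _write_json(out / "fit.json", {**conversion, **stamp})

    # --- report
    stage("report")
    fi_means = (
        base.merge(meta[["subject_id", "group"]], on="subject_id")
        .groupby("group")["fi"].mean().to_dict()
    )
    report = {
        "group_fi_means": {g: float(v) for g, v in fi_means.items()},
        "partial_correlations": corr,
        "auc_table": auc_table,
        "cutoffs": cutoffs,
        "conversion": conversion,
        "n_subjects": len(cohort),
        **stamp,
    }
    _write_json(out / "report.json", report)
    stage("done")
    return report


def _partial_corr_matrix(base: pd.DataFrame, measures: list[str]) -> dict:
    covs = base[["age", "education_years"]].copy()
    covs["sex_male"] = (base["sex"] == "M").astype(float)
    out: dict = {}
    for i, a in enumerate(measures):
        for b in measures[i + 1:]:
            sub = pd.concat([base[[a, b]], covs], axis=1).dropna()
            r = partial_spearman(
                sub[a], sub[b], sub[["age", "education_years", "sex_male"]],
                covariate_names=("age", "sex", "education"),
            )
            out[f"{a}~{b}"] = {"rho": r.rho, "p": r.p_value, "n": r.n}
    return out


def _roc_battery(base, meta, config: PipelineConfig, out: Path, stamp: dict):
    df = base.merge(meta[["subject_id", "group"]], on="subject_id")
    auc_rows = {}
    cutoffs = {}
    for gneg, gpos in GROUP_PAIRS:
        pair_key = f"{gneg}_vs_{gpos}"
        pair_doc = {}
        sub_all = df[df["group"].isin([gneg, gpos])]
        for measure, direction in SCREENING_MEASURES.items():
            sub = sub_all.dropna(subset=[measure])
            roc = roc_curve(sub[measure], sub["group"], positive_label=gpos,
                            direction=direction)
            lo, hi = auc_ci(roc, n_boot=config.n_boot, seed=config.seed + 100)
            rep = optimal_cutoff(roc)
            auc_rows[f"{pair_key}:{measure}"] = {
                "auc": roc.auc, "ci_low": lo, "ci_high": hi, "n": len(sub),
            }
            cutoffs[f"{pair_key}:{measure}"] = {
                "cutoff": rep.cutoff, "sensitivity": rep.sensitivity,
                "specificity": rep.specificity, "ppv": rep.ppv, "npv": rep.npv,
            }
            pair_doc[measure] = {
                "thresholds": roc.thresholds.tolist(),
                "sens": roc.sens.tolist(),
                "spec": roc.spec.tolist(),
                "auc": roc.auc, "ci": [lo, hi], "direction": direction,
                "cutoff": cutoffs[f"{pair_key}:{measure}"],
            }
        _write_json(out / f"roc_{pair_key}.json", {**pair_doc, **stamp})
    return auc_rows, cutoffs


def _conversion_models(features: pd.DataFrame, config: PipelineConfig) -> dict:
    amci = features[features["group"] == "aMCI"].copy()
    if config.outcome_column not in amci.columns:
        raise ValueError(f"missing outcome column {config.outcome_column!r}")
    amci = amci.dropna(subset=[config.outcome_column])
    y = amci[config.outcome_column].astype(float).to_numpy()
    results: dict = {}
    # independent single-predictor models on rate-of-change, ranked by OR;
    # slopes standardised so ORs are per 1 SD of annual change
    for pred in ("reff_slope", "bristol_adl_slope", "blessed_adl_slope"):
        sub = amci.dropna(subset=[pred])
        ys = sub[config.outcome_column].astype(float).to_numpy()
        x = sub[[pred]].copy()
        sd = float(x[pred].std(ddof=1))
        # orient so larger = faster deterioration (efficacy falls, ADL rises)
        sign = -1.0 if pred == "reff_slope" else 1.0
        x[pred] = sign * x[pred] / sd
        fit = fit_logistic(x, ys)
        ci = fit.odds_ratio_ci().iloc[0]
        _, pct = classify(fit, x, ys)
        results[pred] = {
            "or": float(ci["or"]), "ci_low": float(ci["ci_low"]),
            "ci_high": float(ci["ci_high"]),
            "p": float(fit.pvalues[pred]),
            "nagelkerke_r2": nagelkerke_r2(fit),
            "pct_correct": pct,
            "n": fit.n,
            "separation": fit.separation,
        }
    return results
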