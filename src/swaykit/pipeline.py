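"""End-to-end orchestration: simulate/load -> calibrate -> extract ->
split -> reliability -> outliers -> screens -> models -> reports.

Every stage is a pure function of (inputs, config, seed); a rerun with
the same config reproduces outputs byte-identically.  The subject-level
split happens before any statistic is computed, and every training-side
artifact (ICCs, outlier fences, correlation screens, gates, fitted
models) is a function of the training subjects only — deleting the
validation subjects from the input cohort leaves them unchanged.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import correlation_screen, hv_age_prediction_interval, pairwise_group_tests
from .calibration import calibrate_trial
from .config import PipelineConfig
from .features import extract_drift_features, extract_sway_features, feature_dictionary
from .models import (
    combined_test_models,
    evaluate_model,
    fit_and_select,
    select_model_features,
    split_cohort,
)
from .reliability import filter_reliable, mask_outliers
from .scales import add_subpanels
from .synthetic import (
    DRIFT_TESTS,
    SWAY_STANCES,
    cohort_to_frame,
    frame_to_cohort,
    frame_to_trials,
    generate_cohort,
    trials_to_frame,
)


class PipelineError(RuntimeError):
    """A stage contract violation, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@contextmanager
def _stage(name: str, log: list):
    log.append(name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # surface the stage name with the failure
        raise PipelineError(name, str(exc)) from exc


def compute_feature_matrices(
    subjects, trials, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calibrate every trial and extract the 60/16 biomarker matrices.

    Returns wide frames, one row per (subject, trial_index).
    """
    dominant = {s.subject_id: s.dominant_hand for s in subjects}
    by_key: dict = {}
    for trial in trials:
        by_key[(trial.subject_id, trial.trial_index, trial.test)] = calibrate_trial(trial)
    sway_rows, drift_rows = [], []
    subject_trials = sorted({(t.subject_id, t.trial_index) for t in trials})
    for sid, idx in subject_trials:
        stances = {s: by_key.get((sid, idx, s)) for s in SWAY_STANCES}
        if all(v is not None for v in stances.values()):
            vec = extract_sway_features(stances, band=tuple(config.sway_band))
            sway_rows.append({"subject_id": sid, "trial_index": idx, **vec.values})
        left = by_key.get((sid, idx, DRIFT_TESTS[0]))
        right = by_key.get((sid, idx, DRIFT_TESTS[1]))
        if left is not None and right is not None:
            vec = extract_drift_features(
                left, right, dominant[sid], band=tuple(config.drift_band)
            )
            drift_rows.append({"subject_id": sid, "trial_index": idx, **vec.values})
    return pd.DataFrame(sway_rows), pd.DataFrame(drift_rows)


def subject_level(features: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Per-subject feature values: mean over trials (NaN-aware)."""
    cols = columns or [c for c in features.columns if c not in ("subject_id", "trial_index")]
    return features.groupby("subject_id")[list(cols)].mean()


@dataclass
class TrainingArtifacts:
    """Everything fitted on the training cohort only."""

    sway_report: object
    drift_report: object
    sway_masked: pd.DataFrame
    drift_masked: pd.DataFrame
    sway_screen: pd.DataFrame
    drift_screen: pd.DataFrame
    gated_sway: list
    gated_drift: list
    gate_notes: dict = field(default_factory=dict)


OUTCOME_COLUMNS = (
    "edss",
    "combiwise",
    "neurex_total",
    "neurex_postural_sway",
    "neurex_pronator_drift",
    "cerebellar_dom",
    "mri_infratentorial",
)


def _gate(report, screen, relevant, alpha, min_features=2):
    """Step-1 gate with a recorded fallback so tiny demo cohorts still model."""
    gated = select_model_features(report, screen, relevant, alpha)
    note = None
    if len(gated) < min_features:
        by_icc = report.icc_table.sort_values("icc", ascending=False)
        fallback = list(by_icc["feature"].head(max(min_features, len(report.retained))))
        gated = sorted(set(report.retained) | set(gated) | set(fallback[:min_features]))
        note = "gate produced <2 features; relaxed to ICC ranking"
    return gated, note


def train_training_artifacts(
    sway_features: pd.DataFrame,
    drift_features: pd.DataFrame,
    outcomes: pd.DataFrame,
    train_ids,
    config: PipelineConfig,
) -> TrainingArtifacts:
    """Reliability, masking, screening and gating on training subjects only."""
    train = set(train_ids)
    sway_tr = sway_features[sway_features["subject_id"].isin(train)].reset_index(drop=True)
    drift_tr = drift_features[drift_features["subject_id"].isin(train)].reset_index(drop=True)
    sway_report = filter_reliable(sway_tr, config.icc_threshold)
    drift_report = filter_reliable(drift_tr, config.icc_threshold)

    sway_masked, sway_mask = mask_outliers(sway_tr, sway_report.retained, config.iqr_multiplier)
    drift_masked, drift_mask = mask_outliers(drift_tr, drift_report.retained, config.iqr_multiplier)
    sway_report.outlier_mask = sway_mask
    drift_report.outlier_mask = drift_mask

    out_tr = outcomes.loc[outcomes.index.isin(train)]
    sway_subj = subject_level(sway_masked, sway_report.retained).reindex(out_tr.index)
    drift_subj = subject_level(drift_masked, drift_report.retained).reindex(out_tr.index)
    sway_screen = correlation_screen(sway_subj, out_tr[list(OUTCOME_COLUMNS)], config.alpha)
    drift_screen = correlation_screen(drift_subj, out_tr[list(OUTCOME_COLUMNS)], config.alpha)

    gated_sway, note_s = _gate(sway_report, sway_screen, list(config.sway_relevant), config.alpha)
    gated_drift, note_d = _gate(drift_report, drift_screen, list(config.drift_relevant), config.alpha)
    notes = {}
    if note_s:
        notes["sway"] = note_s
    if note_d:
        notes["drift"] = note_d
    return TrainingArtifacts(
        sway_report=sway_report,
        drift_report=drift_report,
        sway_masked=sway_masked,
        drift_masked=drift_masked,
        sway_screen=sway_screen,
        drift_screen=drift_screen,
        gated_sway=gated_sway,
        gated_drift=gated_drift,
        gate_notes=notes,
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full analysis; write artifacts + manifest to ``outdir``.

    Returns a dict of in-memory artifacts (frames, reports, models).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list = []
    artifacts: dict = {}

    with _stage("generate", log):
        if config.cohort_csv and config.trials_csv:
            subjects = frame_to_cohort(pd.read_csv(config.cohort_csv))
            trials = frame_to_trials(pd.read_csv(config.trials_csv))
        else:
            subjects, trials = generate_cohort(
                config.n_subjects,
                config.diagnosis_mix,
                config.n_trials,
                config.seed,
                config.generator,
            )
        cohort = add_subpanels(cohort_to_frame(subjects))
        cohort.to_csv(outdir / "cohort.csv", index=False)
        if config.write_trials:
            trials_to_frame(trials).to_csv(outdir / "trials.csv", index=False)
        artifacts["subjects"], artifacts["trials"], artifacts["cohort"] = subjects, trials, cohort

    with _stage("extract", log):
        sway_features, drift_features = compute_feature_matrices(subjects, trials, config)
        sway_features.to_csv(outdir / "sway_features.csv", index=False)
        drift_features.to_csv(outdir / "drift_features.csv", index=False)
        with open(outdir / "feature_dictionary.json", "w") as fh:
            json.dump(feature_dictionary(), fh, indent=2, sort_keys=True)
        artifacts["sway_features"], artifacts["drift_features"] = sway_features, drift_features

    with _stage("split", log):
        train_ids, val_ids = split_cohort(cohort, config.train_fraction, config.seed)
        artifacts["train_ids"], artifacts["validation_ids"] = train_ids, val_ids

    outcomes = cohort.set_index("subject_id")[list(OUTCOME_COLUMNS) + ["age", "diagnosis"]]

    with _stage("reliability", log):
        training = train_training_artifacts(
            sway_features, drift_features, outcomes, train_ids, config
        )
        training.sway_report.icc_table.to_csv(outdir / "sway_reliability.csv", index=False)
        training.drift_report.icc_table.to_csv(outdir / "drift_reliability.csv", index=False)
        training.sway_screen.to_csv(outdir / "sway_screen.csv", index=False)
        training.drift_screen.to_csv(outdir / "drift_screen.csv", index=False)
        artifacts["training"] = training

    with _stage("associate", log):
        association: dict = {}
        hv_n = int((cohort["diagnosis"] == "HV").sum())
        sway_subj_all = subject_level(sway_features)
        merged = cohort.merge(
            sway_subj_all[[config.age_feature]], left_on="subject_id", right_index=True
        )
        if hv_n >= 10 and config.age_feature in sway_subj_all.columns:
            age_model = hv_age_prediction_interval(
                merged, config.age_feature, level=config.pi_level
            )
            age_model.flags.to_csv(outdir / "age_abnormality_flags.csv", index=False)
            association["age_model"] = age_model
            groups = {
                d: g["value"].to_numpy()
                for d, g in age_model.flags.groupby("diagnosis")
                if len(g) >= 3
            }
            if len(groups) >= 2:
                pw = pairwise_group_tests(groups, config.alpha)
                pw.to_csv(outdir / "pairwise_group_tests.csv", index=False)
                association["pairwise"] = pw
        else:
            association["skipped"] = f"only {hv_n} HV subjects (<10); no normative age model"
        artifacts["association"] = association

    with _stage("model", log):
        # training rows use outlier-masked values; validation rows stay raw
        val_set = set(val_ids)
        sway_all = pd.concat(
            [
                subject_level(training.sway_masked),
                subject_level(sway_features[sway_features["subject_id"].isin(val_set)]),
            ]
        ).sort_index()
        drift_all = pd.concat(
            [
                subject_level(training.drift_masked),
                subject_level(drift_features[drift_features["subject_id"].isin(val_set)]),
            ]
        ).sort_index()

        reports = {}
        for block_name, outcome, gated, all_subj in (
            ("sway", config.sway_outcome, training.gated_sway, sway_all),
            ("drift", config.drift_outcome, training.gated_drift, drift_all),
        ):
            X = all_subj[list(gated)]
            data = X.join(outcomes[[outcome]]).dropna()
            is_val = data.index.isin(val_ids)
            X_tr, y_tr = data.loc[~is_val, X.columns], data.loc[~is_val, outcome].to_numpy()
            X_va, y_va = data.loc[is_val, X.columns], data.loc[is_val, outcome].to_numpy()
            model = fit_and_select(X_tr, y_tr, outcome=outcome, seed=config.seed)
            evaluate_model(model, X_va, y_va, X_tr, y_tr, seed=config.seed)
            reports[block_name] = model

        combined = combined_test_models(
            sway_all,
            drift_all,
            training.gated_sway,
            training.gated_drift,
            outcomes,
            list(config.global_outcomes),
            val_ids,
            seed=config.seed,
        )
        artifacts["models"] = {"test_specific": reports, "combined": combined}
        report_json = {
            "test_specific": {k: m.to_dict() for k, m in reports.items()},
            "combined": {
                outcome: {
                    "models": {k: m.to_dict() for k, m in res["models"].items()},
                    "comparison": res["comparison"],
                }
                for outcome, res in combined.items()
            },
            "gate_notes": training.gate_notes,
        }
        with open(outdir / "model_report.json", "w") as fh:
            json.dump(report_json, fh, indent=2, sort_keys=True)

    with _stage("manifest", log):
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "swaykit_version": __version__,
            "stages": log,
            "n_subjects": len(subjects),
            "train_ids": train_ids,
            "validation_ids": val_ids,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
        artifacts["manifest"] = manifest

    return artifacts
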