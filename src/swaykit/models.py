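"""Regularized disability-prediction models.

The model-development protocol mitigates overfitting in six steps:

1. gate features to those with test-retest ICC > 0.5 and at least one
   FDR-significant correlation with a relevant clinical/imaging outcome
   (both computed on training data only);
2. fit three linear strategies of increasing collinearity stringency —
   ridge, lasso, elastic net;
3. fit a PCA-score variant of each strategy;
4. pick the winner among the six candidates by cross-validated R^2;
5. refit the winner on the complete training cohort;
6. compare against the best single biomarker on the held-out
   validation cohort using Pearson r, R^2 and Lin's concordance
   correlation coefficient (CCC).

The subject-level 80/20 split happens before every analysis step so the
validation cohort never influences gating, standardization, or
hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

STRATEGIES = ("ridge", "lasso", "elastic_net")
REPRESENTATIONS = ("raw", "pca")

DEFAULT_ALPHAS = np.logspace(-3.0, 2.0, 11)
DEFAULT_L1_RATIOS = (0.1, 0.5, 0.9)
PCA_VARIANCE = 0.95
CV_FOLDS = 5


@dataclass
class ModelResult:
    """One fitted candidate (or tournament winner) plus its metrics."""

    outcome: str
    strategy: str
    representation: str
    selected_features: list
    coefficients: dict
    hyperparameters: dict
    cv_r_squared: float
    metrics: dict = field(default_factory=dict)  # pearson_r / r_squared / ccc on validation
    best_single: dict = field(default_factory=dict)
    estimator: object | None = None
    train_index: object | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "strategy": self.strategy,
            "representation": self.representation,
            "selected_features": list(self.selected_features),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "hyperparameters": self.hyperparameters,
            "cv_r_squared": self.cv_r_squared,
            "metrics": self.metrics,
            "best_single": self.best_single,
        }


def split_cohort(
    subjects: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Deterministic subject-level split, stratified by diagnosis.

    Returns (train_ids, validation_ids): disjoint and exhaustive.
    Strata too small to split (a single subject) go to training.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects to split")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    val_ids: list = []
    for _, group in subjects.groupby("diagnosis", sort=True):
        ids = group["subject_id"].tolist()
        rng.shuffle(ids)
        if len(ids) == 1:
            train_ids += ids
            continue
        n_train = int(np.clip(round(train_fraction * len(ids)), 1, len(ids) - 1))
        train_ids += ids[:n_train]
        val_ids += ids[n_train:]
    if not val_ids:  # degenerate mixes: force at least one validation subject
        val_ids.append(train_ids.pop())
    return sorted(train_ids), sorted(val_ids)


def select_model_features(
    reliability_report,
    correlations: pd.DataFrame,
    relevant_outcomes: Sequence[str],
    alpha: float = 0.05,
) -> list:
    """Step-1 gate: ICC-retained AND >= 1 BH-significant relevant correlation."""
    if not relevant_outcomes:
        raise ValueError("relevant_outcomes must be nonempty")
    retained = set(reliability_report.retained)
    sig = correlations[
        correlations["outcome"].isin(relevant_outcomes)
        & (correlations["p_adjusted"] < alpha)
    ]
    correlated = set(sig["feature"])
    return sorted(retained & correlated)


def ccc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments).

    CCC = 2 cov(y, yhat) / (var(y) + var(yhat) + (mean(y) - mean(yhat))^2).
    Penalizes both decorrelation and location/scale miscalibration, so
    |CCC| <= |Pearson r| with equality only for calibrated predictions.
    """
    y = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if y.shape != yp.shape or y.size < 2:
        raise ValueError("inputs must be equal-length vectors with n >= 2")
    vy, vp = np.var(y), np.var(yp)
    if vy == 0 and vp == 0:
        raise ValueError("both inputs have zero variance; CCC undefined")
    cov = np.mean((y - y.mean()) * (yp - yp.mean()))
    return float(2.0 * cov / (vy + vp + (y.mean() - yp.mean()) ** 2))


def _estimator(strategy: str, seed: int):
    if strategy == "ridge":
        return Ridge(), {"model__alpha": DEFAULT_ALPHAS}
    if strategy == "lasso":
        return Lasso(max_iter=50_000), {"model__alpha": DEFAULT_ALPHAS}
    if strategy == "elastic_net":
        return (
            ElasticNet(max_iter=50_000),
            {"model__alpha": DEFAULT_ALPHAS, "model__l1_ratio": list(DEFAULT_L1_RATIOS)},
        )
    raise ValueError(f"unknown strategy {strategy!r}")


def fit_and_select(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    outcome: str = "outcome",
    seed: int = 0,
    strategies: Sequence[str] = STRATEGIES,
    representations: Sequence[str] = REPRESENTATIONS,
    cv_folds: int = CV_FOLDS,
) -> ModelResult:
    """Run the 6-candidate tournament; return the winner refit on all
    training subjects.

    Features are standardized on training statistics inside each CV
    fold; regularization strength (and elastic-net mixing) is chosen by
    5-fold cross-validation over a log-spaced grid; the winner is the
    candidate with the highest cross-validated R^2.
    """
    if X_train.shape[1] < 2:
        raise ValueError("need >= 2 features")
    if X_train.shape[0] < 10:
        raise ValueError("need >= 10 training subjects")
    y = np.asarray(y_train, dtype=float)
    if np.std(y) == 0:
        raise ValueError("outcome has zero variance")

    candidates: list[ModelResult] = []
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for representation in representations:
        for strategy in strategies:
            model, grid = _estimator(strategy, seed)
            steps = [("scale", StandardScaler())]
            if representation == "pca":
                steps.append(("pca", PCA(n_components=PCA_VARIANCE, random_state=seed)))
            steps.append(("model", model))
            search = GridSearchCV(
                Pipeline(steps), grid, cv=cv, scoring="r2", n_jobs=None
            )
            with warnings.catch_warnings():
                # weak penalties on noisy folds stop early by design
                warnings.simplefilter("ignore", ConvergenceWarning)
                search.fit(X_train.to_numpy(float), y)
            best = search.best_estimator_
            fitted = best.named_steps["model"]
            if representation == "raw":
                coefs = dict(zip(X_train.columns, fitted.coef_))
                selected = [f for f, c in coefs.items() if abs(c) > 0]
            else:
                n_pc = best.named_steps["pca"].n_components_
                coefs = {f"PC{i + 1}": c for i, c in enumerate(fitted.coef_)}
                selected = list(X_train.columns)  # all features enter the scores
            hyper = {
                k.replace("model__", ""): (float(v) if np.isscalar(v) else v)
                for k, v in search.best_params_.items()
            }
            if representation == "pca":
                hyper["n_components"] = int(best.named_steps["pca"].n_components_)
            candidates.append(
                ModelResult(
                    outcome=outcome,
                    strategy=strategy,
                    representation=representation,
                    selected_features=selected,
                    coefficients=coefs,
                    hyperparameters=hyper,
                    cv_r_squared=float(search.best_score_),
                    estimator=best,
                    train_index=X_train.index,
                )
            )
    return max(candidates, key=lambda c: c.cv_r_squared)


def best_single_feature(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    seed: int = 0,
    cv_folds: int = CV_FOLDS,
) -> tuple[str, object]:
    """Feature whose univariate linear regression has the best CV R^2.

    Returns (feature name, fitted univariate model on full training).
    """
    from sklearn.model_selection import cross_val_score

    y = np.asarray(y_train, dtype=float)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = {}
    for feature in X_train.columns:
        x = X_train[[feature]].to_numpy(float)
        scores[feature] = cross_val_score(LinearRegression(), x, y, cv=cv, scoring="r2").mean()
    best = max(scores, key=scores.get)
    fit = LinearRegression().fit(X_train[[best]].to_numpy(float), y)
    return best, fit


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    r = float(np.corrcoef(y_true, y_pred)[0, 1]) if np.std(y_pred) > 0 else float("nan")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return {
        "pearson_r": r,
        "r_squared": 1.0 - ss_res / ss_tot,
        "ccc": ccc(y_true, y_pred),
    }


def evaluate_model(
    model: ModelResult,
    X_val: pd.DataFrame,
    y_val: np.ndarray,
    X_train: pd.DataFrame | None = None,
    y_train: np.ndarray | None = None,
    seed: int = 0,
) -> ModelResult:
    """Validation metrics for the winner and the best single predictor.

    Hard-fails if any validation subject also appears in the training
    index (leakage guard).  Fills ``model.metrics`` and
    ``model.best_single`` in place and returns the model.
    """
    if model.train_index is not None:
        overlap = set(X_val.index) & set(model.train_index)
        if overlap:
            raise ValueError(f"validation overlaps training: {sorted(overlap)[:5]}")
    y = np.asarray(y_val, dtype=float)
    y_pred = model.estimator.predict(X_val.to_numpy(float))
    model.metrics = _metrics(y, y_pred)
    if X_train is not None and y_train is not None:
        name, fit = best_single_feature(X_train, y_train, seed=seed)
        single_pred = fit.predict(X_val[[name]].to_numpy(float))
        model.best_single = {"feature": name, **_metrics(y, single_pred)}
    return model


def combined_test_models(
    sway_features: pd.DataFrame,
    drift_features: pd.DataFrame,
    gated_sway: Sequence[str],
    gated_drift: Sequence[str],
    outcomes: pd.DataFrame,
    outcome_names: Sequence[str],
    validation_ids: Sequence,
    seed: int = 0,
) -> dict:
    """Per global outcome: sway-only, drift-only and combined tournaments.

    Each feature block is gated independently beforehand; the combined
    block is their union.  Reports whether the combined model beats each
    single-test model on validation R^2.
    """
    blocks = {
        "sway": sway_features[list(gated_sway)],
        "drift": drift_features[list(gated_drift)],
    }
    union = pd.concat([blocks["sway"], blocks["drift"]], axis=1)
    if union.shape[1] == 0:
        raise ValueError("empty union feature block after gating")
    blocks["combined"] = union

    results: dict = {}
    val = set(validation_ids)
    for outcome in outcome_names:
        per_block = {}
        for name, X in blocks.items():
            if X.shape[1] < 2:
                continue
            data = pd.concat([X, outcomes[[outcome]]], axis=1).dropna()
            is_val = data.index.isin(val)
            X_tr, y_tr = data.loc[~is_val, X.columns], data.loc[~is_val, outcome]
            X_va, y_va = data.loc[is_val, X.columns], data.loc[is_val, outcome]
            model = fit_and_select(X_tr, y_tr.to_numpy(), outcome=outcome, seed=seed)
            evaluate_model(model, X_va, y_va.to_numpy(), X_tr, y_tr.to_numpy(), seed=seed)
            per_block[name] = model
        comparison = {}
        if "combined" in per_block:
            for name in ("sway", "drift"):
                if name in per_block:
                    comparison[f"combined_beats_{name}"] = bool(
                        per_block["combined"].metrics["r_squared"]
                        > per_block[name].metrics["r_squared"]
                    )
        results[outcome] = {"models": per_block, "comparison": comparison}
    return results
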