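"""Split determinism, feature gating, CCC closed forms, tournament
behavior under planted signal structures."""

import numpy as np
import pandas as pd
import pytest

from swaykit.models import (
    ModelResult,
    best_single_feature,
    ccc,
    combined_test_models,
    evaluate_model,
    fit_and_select,
    select_model_features,
    split_cohort,
)
from swaykit.reliability import filter_reliable


def _subject_frame(diagnoses):
    return pd.DataFrame(
        {"subject_id": [f"S{i}" for i in range(len(diagnoses))], "diagnosis": diagnoses}
    )


def test_split_sizes_and_determinism():
    frame = _subject_frame(["HV"] * 100)
    train, val = split_cohort(frame, 0.8, seed=4)
    assert len(train) == 80 and len(val) == 20
    assert not set(train) & set(val)
    train2, val2 = split_cohort(frame, 0.8, seed=4)
    assert train == train2 and val == val2


def test_split_stratified_by_diagnosis():
    frame = _subject_frame(["HV"] * 50 + ["RRMS"] * 50)
    train, val = split_cohort(frame, 0.8, seed=0)
    t = frame.set_index("subject_id").loc[train, "diagnosis"].value_counts()
    v = frame.set_index("subject_id").loc[val, "diagnosis"].value_counts()
    assert abs(t["HV"] - 40) <= 1 and abs(v["HV"] - 10) <= 1
    assert abs(t["RRMS"] - 40) <= 1 and abs(v["RRMS"] - 10) <= 1


def test_split_fraction_guard():
    frame = _subject_frame(["HV"] * 10)
    for bad in (0.0, 1.0, 1.5):
        with pytest.raises(ValueError):
            split_cohort(frame, bad, seed=0)


def _gating_fixture(rng):
    """20 features; exactly 5 pass both the ICC and correlation gates."""
    n = 300
    frame = {"subject_id": np.repeat([f"S{i}" for i in range(n)], 2),
             "trial_index": np.tile([1, 2], n)}
    outcome = rng.standard_normal(n)
    corr_rows = []
    for j in range(20):
        reliable = j < 10  # first 10 reliable
        correlated = j % 2 == 0  # even features correlated
        icc = 0.9 if reliable else 0.1
        between = rng.standard_normal((n, 1)) * np.sqrt(icc)
        frame[f"f{j}"] = (between + rng.standard_normal((n, 2)) * np.sqrt(1 - icc)).ravel()
        corr_rows.append(
            {"feature": f"f{j}", "outcome": "edss",
             "pearson_r": 0.6 if correlated else 0.0,
             "p_value": 1e-6 if correlated else 0.8,
             "p_adjusted": 1e-5 if correlated else 0.9, "n": n}
        )
    report = filter_reliable(pd.DataFrame(frame), threshold=0.5)
    return report, pd.DataFrame(corr_rows)


def test_gate_is_conjunction_of_icc_and_correlation(rng):
    report, screen = _gating_fixture(rng)
    gated = select_model_features(report, screen, ["edss"])
    assert gated == [f"f{j}" for j in range(0, 10, 2)]  # reliable AND correlated
    with pytest.raises(ValueError):
        select_model_features(report, screen, [])


def test_gate_ignores_irrelevant_outcomes(rng):
    report, screen = _gating_fixture(rng)
    assert select_model_features(report, screen, ["combiwise"]) == []


# ----------------------------------------------------------------------- ccc


def test_ccc_perfect_concordance(rng):
    y = rng.standard_normal(50)
    assert ccc(y, y) == pytest.approx(1.0)


@pytest.mark.parametrize("v,c", [(1.0, 1.0), (4.0, 2.0), (0.25, 3.0)])
def test_ccc_shift_closed_form(v, c, rng):
    """y_pred = y + c with var v: CCC = 2v / (2v + c^2)."""
    y = rng.standard_normal(200_000) * np.sqrt(v)
    assert ccc(y, y + c) == pytest.approx(2 * v / (2 * v + c**2), abs=0.01)


def test_ccc_independent_near_zero(rng):
    assert ccc(rng.standard_normal(100_000), rng.standard_normal(100_000)) == pytest.approx(
        0.0, abs=0.01
    )


def test_ccc_bounded_by_pearson(rng):
    for _ in range(200):
        n = rng.integers(5, 50)
        y = rng.standard_normal(n)
        yp = rng.standard_normal(n) + rng.uniform(-2, 2)
        r = np.corrcoef(y, yp)[0, 1]
        assert abs(ccc(y, yp)) <= abs(r) + 1e-12


def test_ccc_guards():
    with pytest.raises(ValueError):
        ccc(np.ones(10), np.ones(10))
    with pytest.raises(ValueError):
        ccc(np.ones(3), np.ones(4))


# ----------------------------------------------------------------- evaluate


def _fitted_identity_model(X, y):
    from sklearn.linear_model import LinearRegression

    est = LinearRegression().fit(X.to_numpy(float), y)
    return ModelResult(
        outcome="o", strategy="ridge", representation="raw",
        selected_features=list(X.columns), coefficients={}, hyperparameters={},
        cv_r_squared=1.0, estimator=est, train_index=X.index,
    )


def test_perfect_prediction_metrics(rng):
    X = pd.DataFrame({"f": rng.standard_normal(50)}, index=range(50))
    y = 2 * X["f"].to_numpy() + 1
    model = _fitted_identity_model(X, y)
    X_val = pd.DataFrame({"f": rng.standard_normal(30)}, index=range(100, 130))
    y_val = 2 * X_val["f"].to_numpy() + 1
    evaluate_model(model, X_val, y_val)
    assert model.metrics["pearson_r"] == pytest.approx(1.0)
    assert model.metrics["r_squared"] == pytest.approx(1.0)
    assert model.metrics["ccc"] == pytest.approx(1.0)


def test_constant_prediction_metrics(rng):
    class Constant:
        def __init__(self, c):
            self.c = c

        def predict(self, X):
            return np.full(len(X), self.c)

    X_val = pd.DataFrame({"f": rng.standard_normal(100)}, index=range(100))
    y_val = rng.standard_normal(100)
    model = ModelResult(
        outcome="o", strategy="ridge", representation="raw", selected_features=[],
        coefficients={}, hyperparameters={}, cv_r_squared=0.0,
        estimator=Constant(y_val.mean() + 0.01), train_index=pd.Index([])
    )
    evaluate_model(model, X_val, y_val)
    assert model.metrics["r_squared"] <= 0.0 + 1e-6
    assert model.metrics["ccc"] == pytest.approx(0.0, abs=0.05)


def test_validation_overlap_hard_failure(rng):
    X = pd.DataFrame({"f": rng.standard_normal(20)}, index=range(20))
    y = X["f"].to_numpy()
    model = _fitted_identity_model(X, y)
    with pytest.raises(ValueError, match="overlap"):
        evaluate_model(model, X.iloc[:5], y[:5])


# --------------------------------------------------------------- tournament


def test_fit_and_select_guards(rng):
    X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
    with pytest.raises(ValueError):
        fit_and_select(X[["a"]], rng.standard_normal(20))  # < 2 features
    with pytest.raises(ValueError):
        fit_and_select(X.iloc[:5], rng.standard_normal(5))  # < 10 subjects
    with pytest.raises(ValueError):
        fit_and_select(X, np.zeros(20))  # degenerate outcome


def test_sparse_signal_selects_lasso_family_and_support(rng):
    n, p = 200, 20
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"f{i}" for i in range(p)])
    y = 3 * X["f0"] + 2 * X["f1"] + 0.5 * rng.standard_normal(n)
    model = fit_and_select(X, y.to_numpy(), seed=0)
    assert model.strategy in ("lasso", "elastic_net")
    assert model.representation == "raw"
    coefs = np.array([model.coefficients[f] for f in X.columns])
    support = set(np.asarray(X.columns)[np.abs(coefs) > 0.1 * np.abs(coefs).max()])
    assert support == {"f0", "f1"}


def test_dense_signal_favors_ridge_family(rng):
    """Equal-weight combination of correlated features: ridge's mean CV
    R^2 beats lasso's across replicates."""
    diffs = []
    for rep in range(8):
        r = np.random.default_rng(400 + rep)
        n, p = 120, 15
        z = r.standard_normal((n, 1))
        X = pd.DataFrame(
            0.7 * z + 0.7 * r.standard_normal((n, p)), columns=[f"f{i}" for i in range(p)]
        )
        y = X.sum(axis=1).to_numpy() + 1.0 * r.standard_normal(n)
        ridge = fit_and_select(X, y, seed=rep, strategies=("ridge",), representations=("raw",))
        lasso = fit_and_select(X, y, seed=rep, strategies=("lasso",), representations=("raw",))
        diffs.append(ridge.cv_r_squared - lasso.cv_r_squared)
    assert np.mean(diffs) > 0


def test_pure_noise_outcome_low_cv_r2(rng):
    n, p = 200, 20
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"f{i}" for i in range(p)])
    y = rng.standard_normal(n)
    model = fit_and_select(X, y, seed=0)
    assert model.cv_r_squared <= 0.1


def test_best_single_feature_finds_signal(rng):
    n = 100
    X = pd.DataFrame(
        {
            "signal": rng.standard_normal(n),
            "noise1": rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
        }
    )
    y = 2 * X["signal"].to_numpy() + 0.3 * rng.standard_normal(n)
    name, fit = best_single_feature(X, y, seed=0)
    assert name == "signal"
    assert fit.coef_[0] == pytest.approx(2.0, abs=0.2)


def test_combined_blocks_beat_single_blocks(rng):
    """Outcome driven by one sway latent and one drift latent: the
    combined block wins on validation R^2."""
    wins = 0
    reps = 5
    for rep in range(reps):
        r = np.random.default_rng(500 + rep)
        n = 150
        ids = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
        zs, zd = r.standard_normal(n), r.standard_normal(n)
        sway = pd.DataFrame(
            {f"s{j}": zs + 0.5 * r.standard_normal(n) for j in range(3)}, index=ids
        )
        drift = pd.DataFrame(
            {f"d{j}": zd + 0.5 * r.standard_normal(n) for j in range(3)}, index=ids
        )
        outcome = pd.DataFrame({"y": zs + zd + 0.3 * r.standard_normal(n)}, index=ids)
        val_ids = ids[120:]
        results = combined_test_models(
            sway, drift, list(sway.columns), list(drift.columns),
            outcome, ["y"], val_ids, seed=rep,
        )
        comp = results["y"]["comparison"]
        wins += comp["combined_beats_sway"] and comp["combined_beats_drift"]
    assert wins >= reps - 1
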