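import numpy as np
import pandas as pd
import pytest

from nanotess.errors import DivergenceError, NanotessError, SplitError
from nanotess.modeling import (
    DNNModel,
    DNNParams,
    EndpointDataset,
    KNNModel,
    KNNParams,
    cross_validate,
    evaluate,
    knn_fit,
    knn_predict,
    make_split,
)

FAST_KNN = KNNParams(subset_sizes=(5,), n_iter=60)


def make_dataset(n=60, p=20, signal=(3, 7), noise_frac=0.05, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(size=(n, p)), index=[f"s{i}" for i in range(n)])
    y = 2.0 * X[signal[0]] - 1.5 * X[signal[1]]
    y = y + rng.normal(0, noise_frac * (y.max() - y.min()), size=n)
    return EndpointDataset(X=X, y=pd.Series(y, index=X.index, name="logP"))


# ---------------------------------------------------------------------------
# splitting

def test_split_sizes_100():
    ds = make_dataset(n=100)
    plan = make_split(ds, seed=0)
    assert (len(plan.train_ids), len(plan.test_ids)) == (80, 20)
    assert sorted(len(f) for f in plan.folds) == [16] * 5


def test_split_sizes_147_rounding():
    ds = make_dataset(n=147)
    plan = make_split(ds, seed=1)
    assert len(plan.train_ids) == round(0.8 * 147) == 118
    assert len(plan.test_ids) == 147 - 118
    sizes = sorted(len(f) for f in plan.folds)
    assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 118


def test_split_partition_and_reproducibility():
    ds = make_dataset(n=53)
    p1, p2 = make_split(ds, seed=9), make_split(ds, seed=9)
    assert p1 == p2
    assert set(p1.train_ids) | set(p1.test_ids) == set(ds.ids)
    assert not set(p1.train_ids) & set(p1.test_ids)
    fold_ids = [i for f in p1.folds for i in f]
    assert sorted(fold_ids) == sorted(p1.train_ids)


def test_split_too_small():
    with pytest.raises(SplitError):
        make_split(make_dataset(n=9), seed=0)


# ---------------------------------------------------------------------------
# evaluate

def test_evaluate_perfect_and_sign_flip():
    assert evaluate([1.0, 2, 3], [1.0, 2, 3]) == {"R2": 1.0, "RMSE": 0.0}
    out = evaluate([-1.0, -2, -3], [1.0, 2, 3])
    assert out["R2"] == pytest.approx(1.0)  # squared Pearson ignores the sign
    assert out["RMSE"] > 0


def test_evaluate_hand_example():
    out = evaluate([0.0, 1.0, 4.0], [0.0, 1.0, 2.0])
    assert out["RMSE"] == pytest.approx(np.sqrt(4 / 3))


def test_evaluate_constant_truth_undefined():
    out = evaluate([1.0, 2.0], [3.0, 3.0])
    assert np.isnan(out["R2"]) and out["RMSE"] > 0


def test_evaluate_agrees_with_brute_force_formulas():
    rng = np.random.default_rng(0)
    for _ in range(25):
        pred, obs = rng.normal(size=30), rng.normal(size=30)
        out = evaluate(pred, obs)
        rmse = np.sqrt(np.sum((pred - obs) ** 2) / len(obs))
        num = np.sum((pred - pred.mean()) * (obs - obs.mean()))
        r2 = num**2 / (np.sum((pred - pred.mean()) ** 2) * np.sum((obs - obs.mean()) ** 2))
        assert out["RMSE"] == pytest.approx(rmse, abs=1e-12)
        assert out["R2"] == pytest.approx(r2, abs=1e-12)


def test_evaluate_cod_definition():
    out = evaluate([0.0, 1.0, 4.0], [0.0, 1.0, 2.0], definition="cod")
    assert out["R2"] == pytest.approx(1 - 4 / 2)


# ---------------------------------------------------------------------------
# kNN

def test_knn_exact_neighbor_returns_training_value():
    X = pd.DataFrame({"a": [0.0, 1.0, 5.0]})
    y = pd.Series([10.0, 20.0, 30.0])
    m = KNNModel(KNNParams(subset_sizes=(1,), k_range=(1,), n_iter=1)).fit(X, y)
    assert knn_predict(m, pd.DataFrame({"a": [5.0]}))[0] == pytest.approx(30.0)


def test_knn_symmetric_equidistant_average():
    X = pd.DataFrame({"a": [0.0, 2.0, 50.0]})
    y = pd.Series([0.0, 2.0, 1.0])
    m = KNNModel(KNNParams(subset_sizes=(1,), k_range=(2,), n_iter=1)).fit(X, y)
    assert m.predict(pd.DataFrame({"a": [1.0]}))[0] == pytest.approx(1.0)


def test_knn_far_neighbor_limit():
    X = pd.DataFrame({"a": [0.0, 200.0, 400.0]})
    y = pd.Series([5.0, -7.0, -7.0])
    m = KNNModel(KNNParams(subset_sizes=(1,), k_range=(2,), n_iter=1)).fit(X, y)
    assert m.predict(pd.DataFrame({"a": [0.0]}))[0] == pytest.approx(5.0, abs=1e-6)


def test_knn_hand_computed_weights():
    # neighbors at distances 1 and 2: prediction = (e^-1 y1 + e^-2 y2)/(e^-1 + e^-2)
    X = pd.DataFrame({"a": [1.0, 3.0, 40.0]})
    y = pd.Series([2.0, 8.0, 0.0])
    m = KNNModel(KNNParams(subset_sizes=(1,), k_range=(2,), n_iter=1)).fit(X, y)
    got = m.predict(pd.DataFrame({"a": [2.0]}))[0]  # d=(1,1)? no: |2-1|=1, |2-3|=1
    assert got == pytest.approx(5.0)
    got = m.predict(pd.DataFrame({"a": [0.0]}))[0]  # d=(1,3) -> weights e^-1, e^-3
    expected = (np.exp(-1) * 2 + np.exp(-3) * 8) / (np.exp(-1) + np.exp(-3))
    assert got == pytest.approx(expected, abs=1e-12)


def test_knn_constant_target():
    X = pd.DataFrame(np.random.default_rng(0).uniform(size=(12, 3)))
    y = pd.Series(np.full(12, 4.2))
    m = KNNModel(FAST_KNN).fit(X, y)
    np.testing.assert_allclose(m.predict(X), 4.2)


def test_knn_prediction_ignores_unselected_columns():
    ds = make_dataset(seed=5)
    m = knn_fit(ds.X, ds.y, FAST_KNN)
    perturbed = ds.X.copy()
    untouched = [c for c in ds.X.columns if c not in m.selected_columns]
    perturbed[untouched] = perturbed[untouched] + 100.0
    np.testing.assert_array_equal(m.predict(ds.X), m.predict(perturbed))


def test_knn_variable_selection_recovers_planted_columns():
    """y depends only on columns {3, 7}: selection finds at least one of them
    in >= 90 of 100 seeds."""
    hits = 0
    for seed in range(100):
        ds = make_dataset(seed=seed)
        m = KNNModel(KNNParams(subset_sizes=(5,), n_iter=60, seed=seed)).fit(ds.X, ds.y)
        if {3, 7} & set(m.selected_columns):
            hits += 1
    assert hits >= 90


# ---------------------------------------------------------------------------
# DNN

def test_dnn_learns_linear_signal():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.uniform(size=(200, 8)))
    y = pd.Series(X.to_numpy()[:, :5] @ rng.normal(size=5))
    m = DNNModel(DNNParams(hidden=(32, 16, 8), epochs=60, seed=0)).fit(X, y)
    assert m.history[-1] < m.history[0]
    assert len(m.history) == 60


def test_dnn_constant_target_converges():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.uniform(size=(50, 4)))
    y = pd.Series(np.full(50, 2.5))
    m = DNNModel(DNNParams(hidden=(16, 8, 4), epochs=150, seed=1)).fit(X, y)
    assert m.history[-1] < 0.05
    assert np.allclose(m.predict(X), 2.5, atol=0.1)


def test_dnn_deterministic_under_seed():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.uniform(size=(40, 6)))
    y = pd.Series(rng.normal(size=40))
    params = DNNParams(hidden=(16, 8, 4), epochs=20, seed=11)
    a = DNNModel(params).fit(X, y)
    b = DNNModel(params).fit(X, y)
    assert abs(a.history[-1] - b.history[-1]) < 1e-6
    np.testing.assert_array_equal(a.predict(X), b.predict(X))


def test_dnn_divergence_reported():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.uniform(size=(20, 3)) * 1e200)
    y = pd.Series(rng.normal(size=20) * 1e200)
    with pytest.raises(DivergenceError):
        DNNModel(DNNParams(hidden=(8, 4, 2), epochs=5, seed=0)).fit(X, y)


# ---------------------------------------------------------------------------
# cross-validation protocol

def test_every_train_point_predicted_once():
    ds = make_dataset(n=40, seed=1)
    plan = make_split(ds, seed=2)
    report = cross_validate(ds, plan, lambda: KNNModel(FAST_KNN))
    assert sorted(report.cv_predictions.index) == sorted(plan.train_ids)
    assert sorted(report.test_predictions.index) == sorted(plan.test_ids)
    assert len(report.per_fold) == 5


def test_protocol_reproducible():
    ds = make_dataset(n=40, seed=1)
    plan = make_split(ds, seed=3)
    r1 = cross_validate(ds, plan, lambda: KNNModel(FAST_KNN))
    r2 = cross_validate(ds, plan, lambda: KNNModel(FAST_KNN))
    assert (r1.r2_cv, r1.rmse_cv, r1.r2_val, r1.rmse_val) == (
        r2.r2_cv, r2.rmse_cv, r2.r2_val, r2.rmse_val
    )


def test_no_test_leakage_into_cv():
    """CV metrics and fold predictions are identical when test rows change."""
    ds = make_dataset(n=40, seed=6)
    plan = make_split(ds, seed=6)
    base = cross_validate(ds, plan, lambda: KNNModel(FAST_KNN))

    X2, y2 = ds.X.copy(), ds.y.copy()
    test_ids = list(plan.test_ids)
    X2.loc[test_ids] = X2.loc[test_ids] * 1000 + 77.7
    y2.loc[test_ids] = -999.0
    mutated = EndpointDataset(X=X2, y=y2, endpoint=ds.endpoint)
    out = cross_validate(mutated, plan, lambda: KNNModel(FAST_KNN))
    pd.testing.assert_series_equal(base.cv_predictions, out.cv_predictions)
    assert base.r2_cv == out.r2_cv and base.rmse_cv == out.rmse_cv

    # changing only the test endpoint values never changes any prediction
    y3 = ds.y.copy()
    y3.loc[test_ids] = y3.loc[test_ids] + 123.0
    out3 = cross_validate(
        EndpointDataset(X=ds.X.copy(), y=y3, endpoint=ds.endpoint),
        plan, lambda: KNNModel(FAST_KNN),
    )
    pd.testing.assert_series_equal(base.test_predictions, out3.test_predictions)


def test_dataset_requires_complete_values():
    X = pd.DataFrame({"a": [1.0, 2.0]}, index=["u", "v"])
    with pytest.raises(NanotessError):
        EndpointDataset(X=X, y=pd.Series([1.0], index=["u"]))
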