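"""Grid-searched RBF SVM training, prediction and persistence."""

import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from cppopt import (FormatError, ValidationError, grid_search_train, load_model,
                    predict, save_model)
from cppopt.svm import GRID_FACTORS, _canonical_folds


def _blobs(n=200, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, 4))
    y = (np.arange(n) % 2).astype(int)
    X[y == 1, 0] += sep
    return pd.DataFrame(X, columns=list("abcd")), y


def test_grid_has_121_cells():
    X, y = _blobs()
    _, result = grid_search_train(X, y, seed=0)
    assert len(GRID_FACTORS) == 11
    assert result.cv_accuracy.shape == (11, 11)
    assert result.best_accuracy == result.cv_accuracy.max()


def test_separable_blobs_reach_high_cv_accuracy():
    X, y = _blobs()
    model, result = grid_search_train(X, y, seed=0)
    assert result.best_accuracy >= 0.99
    labels, _ = predict(model, X)
    assert np.mean(labels == y) >= 0.99


def test_decision_matches_reference_svm():
    """The persisted kernel expansion reproduces the solver's decisions."""
    X, y = _blobs(n=120, sep=2.0, seed=3)
    model, _ = grid_search_train(X, y, seed=0)
    Z = (X[model.feature_names].to_numpy() - model.center) / model.scale
    ref = SVC(C=model.hyperparams.C, gamma=model.hyperparams.gamma).fit(Z, y)
    np.testing.assert_allclose(model.decision_function(X), ref.decision_function(Z),
                               atol=1e-9)


def test_permuted_labels_give_chance_accuracy():
    X, y = _blobs(n=200, sep=6.0, seed=1)
    rng = np.random.default_rng(7)
    y_perm = rng.permutation(y)
    _, result = grid_search_train(X, y_perm, seed=0)
    assert 0.35 <= result.best_accuracy <= 0.65


def test_cv_accuracy_matches_independent_pipeline():
    """No leakage: an sklearn scaler+SVC loop over the exported folds agrees."""
    X, y = _blobs(n=100, sep=1.5, seed=5)
    model, result = grid_search_train(X, y, seed=0)
    hp = model.hyperparams
    i = list(result.c_values).index(hp.C)
    j = list(result.gamma_values).index(hp.gamma)
    pred = np.empty(y.size, dtype=int)
    for k in range(result.n_folds):
        tr, te = result.folds != k, result.folds == k
        sc = StandardScaler().fit(X[tr])
        clf = SVC(C=hp.C, gamma=hp.gamma).fit(sc.transform(X[tr]), y[tr])
        pred[te] = clf.predict(sc.transform(X[te]))
    assert np.mean(pred == y) == pytest.approx(result.cv_accuracy[i, j])


def test_best_cell_invariant_to_row_order():
    X, y = _blobs(n=80, sep=1.0, seed=2)
    _, r1 = grid_search_train(X, y, seed=0)
    perm = np.random.default_rng(0).permutation(len(y))
    _, r2 = grid_search_train(X.iloc[perm].reset_index(drop=True), y[perm], seed=0)
    assert r1.best == r2.best
    np.testing.assert_allclose(r1.cv_accuracy, r2.cv_accuracy)


def test_canonical_folds_are_stratified():
    X, y = _blobs(n=100, sep=1.0, seed=4)
    folds = _canonical_folds(X.to_numpy(), y, 10, seed=0)
    for k in range(10):
        assert np.bincount(y[folds == k], minlength=2).min() >= 4


def test_standardization_uses_training_stats():
    X, y = _blobs()
    model, _ = grid_search_train(X, y, seed=0)
    d1 = model.decision_function(X.iloc[:10])
    # a globally shifted batch must change the decisions -- proof that the
    # stored training moments, not the batch's own, are applied
    d2 = model.decision_function(X.iloc[:10] + 50.0)
    assert not np.allclose(d1, d2)


def test_unknown_and_missing_columns_rejected():
    X, y = _blobs()
    model, _ = grid_search_train(X, y, seed=0)
    with pytest.raises(ValidationError, match="unknown"):
        model.decision_function(X.rename(columns={"a": "zz"}))
    with pytest.raises(ValidationError, match="missing"):
        model.decision_function(X[["a", "b"]])


def test_single_class_rejected():
    X, _ = _blobs()
    with pytest.raises(ValidationError, match="both classes"):
        grid_search_train(X, np.zeros(len(X), int), seed=0)


def test_small_minority_reduces_folds():
    X, y = _blobs(n=40)
    y = np.zeros(40, int)
    y[:5] = 1
    with pytest.warns(UserWarning, match="reducing folds"):
        _, result = grid_search_train(X, y, seed=0)
    assert result.n_folds == 5


def test_zero_variance_feature_dropped():
    X, y = _blobs()
    X["const"] = 3.14
    model, _ = grid_search_train(X, y, seed=0)
    assert "const" in model.dropped_features
    assert "const" not in model.feature_names


def test_empty_feature_matrix_rejected():
    with pytest.raises(ValidationError):
        grid_search_train(pd.DataFrame(index=range(30)), np.zeros(30, int), seed=0)


def test_save_load_round_trip(tmp_path):
    X, y = _blobs(n=60, sep=2.0, seed=6)
    model, _ = grid_search_train(X, y, seed=0)
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    np.testing.assert_allclose(back.decision_function(X), model.decision_function(X),
                               atol=1e-9)
    assert back.hyperparams == model.hyperparams


def test_schema_version_checked(tmp_path):
    import json
    X, y = _blobs(n=60)
    model, _ = grid_search_train(X, y, seed=0)
    path = tmp_path / "model.json"
    save_model(model, path)
    payload = json.loads(path.read_text())
    payload["schema_version"] = 99
    path.write_text(json.dumps(payload))
    with pytest.raises(FormatError, match="version"):
        load_model(path)
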