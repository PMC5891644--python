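"""Classifier training, nested cross-validation and the model search."""

import warnings

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

import bfrehab as bf
from bfrehab.features import FeatureSpec
from bfrehab.model import (Candidate, CVScheme, SearchGrid, _fit_linear_fast,
                           cross_validate, model_search, preprocess_recording,
                           tie_break_key, train_classifier)
from bfrehab.signal import EpochSet, extract_epochs


def _noise_epochs(rng, n, n_ch=4, n_s=100):
    labels = np.array(["imagery", "rest"] * (n // 2))
    return EpochSet(rng.standard_normal((n, n_ch, n_s)), labels, 250.0, 0.5,
                    n_s / 250.0, [f"C{i}" for i in range(n_ch)])


@pytest.mark.parametrize("kind", ["LDA", "SVM", "REGLOG"])
def test_separable_toy_set_fit_perfectly(kind):
    X = np.array([[0.0, 0.0], [0.1, 0.2], [3.0, 3.0], [3.2, 2.9]])
    y = np.array(["rest", "rest", "imagery", "imagery"])
    state = train_classifier(kind, X, y, hyperparameter=1.0)
    assert np.array_equal(state.predict01(X), [0, 0, 1, 1])
    s = state.score(X)
    assert np.all(np.abs(s) <= 1.0)
    assert np.all(s[:2] < 0) and np.all(s[2:] > 0)


def test_lda_direction_matches_closed_form():
    rng = np.random.default_rng(5)
    cov = np.array([[2.0, 0.6], [0.6, 1.0]])
    mu0, mu1 = np.array([0.0, 0.0]), np.array([1.0, 0.5])
    L = np.linalg.cholesky(cov)
    X0 = rng.standard_normal((1000, 2)) @ L.T + mu0
    X1 = rng.standard_normal((1000, 2)) @ L.T + mu1
    X = np.vstack([X0, X1])
    y = np.array(["rest"] * 1000 + ["imagery"] * 1000)
    state = train_classifier("LDA", X, y)
    w_true = np.linalg.solve(cov, mu1 - mu0)
    cos = np.dot(state.weights, w_true) / (
        np.linalg.norm(state.weights) * np.linalg.norm(w_true))
    assert cos > 0.99


def test_fast_newton_logistic_matches_sklearn():
    """The path solver minimizes the same objective as the deployed model."""
    rng = np.random.default_rng(6)
    X = rng.standard_normal((80, 6)) + 0.6 * np.repeat([[1.0], [0.0]], 40, 0)
    y01 = np.repeat([1, 0], 40)
    ypm = np.where(y01 == 1, 1.0, -1.0)
    for c in (2.0 ** -6, 1.0, 2.0 ** 4):
        z = _fit_linear_fast("REGLOG", X, ypm, c)
        sk = LogisticRegression(C=c, solver="lbfgs", max_iter=5000,
                                tol=1e-10).fit(X, y01)
        np.testing.assert_allclose(z[:-1], sk.coef_.ravel(), atol=2e-3)
        np.testing.assert_allclose(z[-1], sk.intercept_[0], atol=2e-3)


def test_shuffled_labels_score_at_chance():
    accs = []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        eps = _noise_epochs(rng, 60)
        acc = cross_validate(Candidate(FeatureSpec("CSP", n_filters=4), "LDA"),
                             eps, CVScheme(2, 5), seed=seed)
        accs.append(acc)
    assert 0.4 <= np.mean(accs) <= 0.6


def test_nested_feature_fitting_avoids_leakage():
    """Fitting CSP on the full set before CV inflates accuracy on null data."""
    inflation = []
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        eps = _noise_epochs(rng, 24, n_ch=8, n_s=60)
        nested = cross_validate(Candidate(FeatureSpec("CSP"), "LDA"), eps,
                                CVScheme(1, 4), seed=seed)
        # leaky route: filters trained on all epochs including test folds
        from bfrehab.features import CSPExtractor
        X = CSPExtractor((6.0, 32.0), 6).fit(eps).transform(eps)
        y = (eps.labels == "imagery").astype(int)
        skf = StratifiedKFold(4, shuffle=True, random_state=seed)
        accs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for tr, te in skf.split(X, y):
                state = train_classifier("LDA", X[tr], eps.labels[tr])
                accs.append((state.predict01(X[te]) == y[te]).mean())
        inflation.append(np.mean(accs) - nested)
    assert np.mean(inflation) > 0


def test_cross_validate_requires_enough_epochs():
    rng = np.random.default_rng(0)
    eps = _noise_epochs(rng, 10)
    with pytest.raises(ValueError, match="10 epochs per class"):
        cross_validate(Candidate(FeatureSpec("CSP"), "LDA"), eps)


def test_restricted_grid_leaderboard_lengths(erd_cfg):
    runs = bf.simulate_session(erd_cfg, 2, 20)
    recs = [r for r, _ in runs]
    scheds = [s for _, s in runs]
    g1 = SearchGrid(("CSP",), ("LDA",), (0.5,), cv_scheme=CVScheme(1, 5))
    best, lb = model_search(recs, scheds, g1, seed=0)
    assert len(lb) == 1
    assert best.feature_spec.kind == "CSP" and best.classifier_kind == "LDA"
    g2 = SearchGrid(("CSP", "BP"), ("LDA",), (0.5, 1.0),
                    cv_scheme=CVScheme(1, 5))
    _, lb2 = model_search(recs, scheds, g2, seed=0)
    assert len(lb2) == 4
    assert np.all(np.diff(lb2["cv_accuracy"].to_numpy()) <= 1e-12)


def test_tie_break_ordering():
    rows = [
        {"feature": "FBCSP", "classifier": "LDA", "window_start_s": 0.5,
         "hyperparameter": None, "cv_accuracy": 0.9},
        {"feature": "BP", "classifier": "LDA", "window_start_s": 0.5,
         "hyperparameter": None, "cv_accuracy": 0.9},
        {"feature": "CSP", "classifier": "LDA", "window_start_s": 1.0,
         "hyperparameter": None, "cv_accuracy": 0.9},
        {"feature": "CSP", "classifier": "REGLOG", "window_start_s": 0.5,
         "hyperparameter": 0.5, "cv_accuracy": 0.9},
        {"feature": "CSP", "classifier": "SVM", "window_start_s": 0.5,
         "hyperparameter": 2.0, "cv_accuracy": 0.9},
    ]
    ranked = sorted(rows, key=tie_break_key)
    # same accuracy: earlier window first, then CSP < BP < FBCSP, then
    # smaller hyperparameter
    assert ranked[0]["classifier"] == "REGLOG"    # CSP, 0.5 s, hyper 0.5
    assert ranked[1]["classifier"] == "SVM"       # CSP, 0.5 s, hyper 2.0
    assert ranked[2]["feature"] == "BP"
    assert ranked[3]["feature"] == "FBCSP"
    assert ranked[4]["window_start_s"] == 1.0
    better = {"feature": "FBCSP", "classifier": "REGLOG", "window_start_s": 3.0,
              "hyperparameter": 1024.0, "cv_accuracy": 0.91}
    assert min(rows + [better], key=tie_break_key) is better


def test_search_determinism_and_model_round_trip(erd_cfg, tiny_grid, tmp_path):
    runs = bf.simulate_session(erd_cfg, 2, 20)
    recs = [r for r, _ in runs]
    scheds = [s for _, s in runs]
    m1, lb1 = model_search(recs, scheds, tiny_grid, seed=9)
    m2, lb2 = model_search(recs, scheds, tiny_grid, seed=9)
    assert lb1.equals(lb2)
    assert m1.to_json() == m2.to_json()

    path = tmp_path / "model.json"
    m1.save(path)
    loaded = bf.BCIModel.load(path)
    eps = extract_epochs(preprocess_recording(recs[0]), scheds[0],
                         m1.window_start_s)
    np.testing.assert_allclose(loaded.score_epochs(eps), m1.score_epochs(eps),
                               atol=1e-12)


def test_cv_accuracy_within_bounds(epochs_strong):
    acc = cross_validate(Candidate(FeatureSpec("CSP"), "LDA"), epochs_strong,
                         CVScheme(2, 10), seed=1)
    assert 0.0 <= acc <= 1.0
    assert acc >= 0.75  # strong injected ERD is decodable
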