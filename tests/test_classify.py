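"""Discriminant machinery: splits, Box's M, generalized distances, stepwise
selection, the LDA oracle equivalence, baselines, and metric identities."""

import math

import numpy as np
import pandas as pd
import pytest

from ecgquant import classify
from ecgquant.types import ValidationError


def _frame(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"x{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=names)


def _two_gaussians(rng, n=100, dim=3, delta=2.0, cov_scale_b=1.0):
    a = rng.normal(size=(n, dim))
    b = rng.normal(size=(n, dim)) * math.sqrt(cov_scale_b)
    b[:, 0] += delta
    X = _frame(np.vstack([a, b]))
    y = pd.Series(["healthy"] * n + ["disease"] * n, index=X.index, name="label")
    return X, y


# --- split -----------------------------------------------------------------

def test_split_counts_match_stratified_design():
    y = pd.Series(["healthy"] * 52 + ["disease"] * 194,
                  index=[f"s{i}" for i in range(246)])
    train, test = classify.split_train_test(y, fraction=0.5, seed=0)
    assert (y.loc[train] == "healthy").sum() == 26
    assert (y.loc[train] == "disease").sum() == 97
    assert len(train) + len(test) == 246
    assert set(train).isdisjoint(test)


def test_split_deterministic():
    y = pd.Series(["healthy"] * 10 + ["disease"] * 14)
    a = classify.split_train_test(y, seed=5)
    b = classify.split_train_test(y, seed=5)
    assert list(a[0]) == list(b[0]) and list(a[1]) == list(b[1])


def test_split_rejects_degenerate_fraction():
    y = pd.Series(["healthy"] * 5 + ["disease"] * 5)
    with pytest.raises(ValidationError):
        classify.split_train_test(y, fraction=1.0)
    with pytest.raises(ValidationError):
        classify.split_train_test(pd.Series(["healthy"] + ["disease"] * 5),
                                  fraction=0.5)


# --- Box's M ---------------------------------------------------------------

def test_box_m_identical_covariances_statistic_zero():
    S = np.array([[2.0, 0.3], [0.3, 1.0]])
    stat, p = classify.box_m_test([S, S], [50, 60])
    assert stat == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0)


def test_box_m_strongly_unequal_covariances_reject(rng):
    a = rng.normal(size=(200, 3))
    b = rng.normal(size=(200, 3)) * 3.0  # covariance 9I
    Sa, Sb = np.cov(a, rowvar=False), np.cov(b, rowvar=False)
    _, p = classify.box_m_test([Sa, Sb], [200, 200])
    assert p < 0.001


def test_box_m_requires_n_above_dim():
    S = np.eye(4)
    with pytest.raises(ValidationError):
        classify.box_m_test([S, S], [4, 10])


# --- generalized distance --------------------------------------------------

def test_distance_zero_at_class_mean():
    assert classify.generalized_distance(np.zeros(2), np.zeros(2), np.eye(2)) == 0.0


def test_distance_euclidean_reduction():
    x = np.array([1.0, 0.0])
    assert classify.generalized_distance(x, np.zeros(2), np.eye(2)) == pytest.approx(1.0)


def test_distance_log_determinant_term():
    d2 = classify.generalized_distance(np.zeros(2), np.zeros(2), 4 * np.eye(2),
                                       g1=math.log(16.0))
    assert d2 == pytest.approx(math.log(16.0), abs=1e-12)


def test_distance_affine_invariance(rng):
    """Mahalanobis distances are invariant under invertible linear maps when
    the covariance is transported consistently."""
    for _ in range(10):
        x = rng.normal(size=3)
        m = rng.normal(size=3)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        S = A @ A.T  # SPD
        d_orig = classify.generalized_distance(x, m, S)
        B = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        d_mapped = classify.generalized_distance(B @ x, B @ m, B @ S @ B.T)
        assert d_mapped == pytest.approx(d_orig, rel=1e-8)


# --- stepwise selection ----------------------------------------------------

def test_stepwise_finds_planted_feature(rng):
    hits = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        X, y = _two_gaussians(r, n=100, dim=1, delta=2.0)
        noise = pd.DataFrame(r.normal(size=(200, 20)),
                             columns=[f"n{i}" for i in range(20)], index=X.index)
        X = pd.concat([X, noise], axis=1)
        selected = classify.stepwise_select(X, y)
        hits += bool(selected) and selected[0] == "x0"
    assert hits >= 9


def test_stepwise_pure_noise_selects_almost_nothing(rng):
    X = _frame(rng.normal(size=(200, 20)))
    y = pd.Series(["healthy"] * 100 + ["disease"] * 100, index=X.index)
    selected = classify.stepwise_select(X, y, slentry=0.05, slstay=0.05)
    assert len(selected) <= 3  # false entries at roughly the nominal rate


def test_stepwise_never_enters_collinear_duplicate(rng):
    X, y = _two_gaussians(rng, n=80, dim=2, delta=3.0)
    X["dup"] = X["x0"]
    selected = classify.stepwise_select(X, y)
    assert not ("x0" in selected and "dup" in selected)


def test_stepwise_empty_when_nothing_significant(rng):
    X = _frame(rng.normal(size=(40, 3)))
    y = pd.Series(["healthy"] * 20 + ["disease"] * 20, index=X.index)
    assert classify.stepwise_select(X, y, slentry=1e-6, slstay=1e-6) == []


# --- SDA training and prediction -------------------------------------------

def _closed_form_lda_predict(X, y, X_new):
    """Independent two-class linear discriminant: w = Sp^-1 (m1 - m0),
    threshold at the midpoint of projected means (equal priors)."""
    labels = sorted(y.unique())
    m = {c: X[y == c].mean().to_numpy() for c in labels}
    pooled = sum((len(X[y == c]) - 1) * np.cov(X[y == c].to_numpy(), rowvar=False)
                 for c in labels) / (len(X) - 2)
    w = np.linalg.solve(pooled, m[labels[1]] - m[labels[0]])
    c0 = w @ m[labels[0]]
    c1 = w @ m[labels[1]]
    proj = X_new.to_numpy() @ w
    return np.where(np.abs(proj - c1) < np.abs(proj - c0), labels[1], labels[0])


def test_sda_pooled_matches_closed_form_lda(rng):
    """With a pooled covariance the generalized-distance rule is exactly the
    closed-form two-class linear discriminant."""
    for seed in range(5):
        r = np.random.default_rng(seed)
        X, y = _two_gaussians(r, n=60, dim=3, delta=1.0)
        model = classify.train_sda(X, y, features=list(X.columns))
        assert model.cov_mode == "pooled"
        X_new = _frame(r.normal(size=(50, 3)))
        got = classify.predict_sda(model, X_new).to_numpy()
        expected = _closed_form_lda_predict(X, y, X_new)
        assert (got == expected).all()


def test_sda_unequal_covariances_switch_to_per_class(rng):
    X, y = _two_gaussians(rng, n=150, dim=3, delta=1.0, cov_scale_b=9.0)
    model = classify.train_sda(X, y, features=list(X.columns))
    assert model.cov_mode == "per_class"
    assert model.g1["disease"] != 0.0


def test_sda_pooled_g1_is_zero(rng):
    X, y = _two_gaussians(rng, n=60, dim=2, delta=1.0)
    model = classify.train_sda(X, y, features=list(X.columns))
    assert all(v == 0.0 for v in model.g1.values())


def test_sda_no_signal_near_chance(rng):
    X = _frame(rng.normal(size=(400, 1)))
    y = pd.Series(["healthy"] * 200 + ["disease"] * 200, index=X.index)
    model = classify.train_sda(X, y, features=["x0"])
    acc = (classify.predict_sda(model, X) == y).mean()
    assert 0.35 < acc < 0.65


def test_sda_json_round_trip(rng):
    X, y = _two_gaussians(rng, n=50, dim=2, delta=2.0)
    model = classify.train_sda(X, y)
    back = classify.SDAModel.from_json(model.to_json())
    assert back.selected_features == model.selected_features
    assert back.cov_mode == model.cov_mode
    X_new = _frame(rng.normal(size=(20, 2)))
    pd.testing.assert_series_equal(classify.predict_sda(model, X_new),
                                   classify.predict_sda(back, X_new))


# --- baselines -------------------------------------------------------------

def test_baselines_fit_separable_data(rng):
    X, y = _two_gaussians(rng, n=40, dim=2, delta=8.0)
    svm = classify.train_svm(X, y, seed=0)
    llr = classify.train_llr(X, y, seed=0)
    assert (classify.predict_sklearn(svm, X) == y).all()
    assert (classify.predict_sklearn(llr, X) == y).all()


def test_svm_hyperparameters_deterministic(rng):
    X, y = _two_gaussians(rng, n=40, dim=3, delta=1.0)
    a = classify.train_svm(X, y, seed=3).get_params()["svc__C"]
    b = classify.train_svm(X, y, seed=3).get_params()["svc__C"]
    assert a == b


# --- evaluation ------------------------------------------------------------

def _report(tp, fn, tn, fp):
    return classify.ClassificationReport(tp=tp, fn=fn, tn=tn, fp=fp)


def test_metrics_hand_arithmetic():
    r = _report(9, 1, 8, 2)
    assert r.sensitivity == pytest.approx(0.90)
    assert r.specificity == pytest.approx(0.80)
    assert r.accuracy == pytest.approx(0.85)


def test_perfect_predictions():
    r = _report(10, 0, 5, 0)
    assert (r.sensitivity, r.specificity, r.accuracy) == (1.0, 1.0, 1.0)


def test_all_positive_predictor():
    truth = pd.Series(["disease"] * 7 + ["healthy"] * 3)
    pred = pd.Series(["disease"] * 10)
    r = classify.evaluate(pred, truth)
    assert r.sensitivity == 1.0 and r.specificity == 0.0


def test_metric_identities_on_random_confusions(rng):
    for _ in range(20):
        tp, fn, tn, fp = rng.integers(0, 30, 4)
        if tp + fn == 0 or tn + fp == 0:
            continue
        r = _report(int(tp), int(fn), int(tn), int(fp))
        assert r.sensitivity == tp / (tp + fn)
        assert r.specificity == tn / (tn + fp)
        assert r.accuracy == (tp + tn) / (tp + fn + tn + fp)


def test_evaluate_counts_from_labels(rng):
    truth = pd.Series(["disease", "disease", "healthy", "healthy", "disease"])
    pred = pd.Series(["disease", "healthy", "healthy", "disease", "disease"])
    r = classify.evaluate(pred, truth)
    assert (r.tp, r.fn, r.tn, r.fp) == (2, 1, 1, 1)
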