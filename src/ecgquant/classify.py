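"""Classifiers and evaluation: stepwise discriminant analysis from scratch,
SVM and L1-logistic baselines, and sensitivity/specificity/accuracy reports.

The discriminant classifies a subject to the class t minimizing the
generalized squared distance D_t^2 = d_t^2 + g1(t) + g2(t), where d_t^2 is
the squared Mahalanobis distance to the class mean, g1(t) = ln|S_t| enters
only when a homogeneity test (Box's M) rejects equal class covariances, and
g2(t) (the prior term) is identically zero because equal priors are assumed.
Variables enter and leave by a stepwise procedure on the partial F statistic
derived from Wilks' lambda.  The SVM and LASSO-logistic baselines wrap
scikit-learn; they exist for comparison, not as the contribution.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import ValidationError

logger = logging.getLogger(__name__)

#: class order: index 0 = negative (healthy), index 1 = positive (disease)
CLASS_ORDER: tuple[str, str] = ("healthy", "disease")


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def split_train_test(y: pd.Series, fraction: float = 0.5, seed: int = 0
                     ) -> tuple[pd.Index, pd.Index]:
    """Stratified random split of subjects; ``fraction`` goes to training.

    Per class, ``round(fraction * n)`` subjects are assigned to training
    (at least 1, never all), so near-equal halves mirror a 50/50 design.
    """
    if not 0 < fraction < 1:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for cls in sorted(y.unique()):
        ids = np.asarray(y.index[y == cls])
        if len(ids) < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 subjects")
        perm = rng.permutation(len(ids))
        n_train = int(round(fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return pd.Index(train_ids), pd.Index(test_ids)


# ---------------------------------------------------------------------------
# Box's M homogeneity test
# ---------------------------------------------------------------------------

def _ridge_if_singular(S: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Add a small ridge (1e-8 * trace/dim) when the matrix is not PD."""
    try:
        np.linalg.cholesky(S)
        return S
    except np.linalg.LinAlgError:
        p = S.shape[0]
        bump = ridge * np.trace(S) / p
        if bump <= 0:
            bump = ridge
        logger.warning("singular covariance: adding ridge %.3g", bump)
        return S + bump * np.eye(p)


def box_m_test(covariances: list[np.ndarray], sizes: list[int]) -> tuple[float, float]:
    """Box's M test of equality of class covariance matrices.

    Returns (chi-square statistic, p-value) using the standard chi-square
    approximation; requires each class size to exceed the dimension.
    """
    g = len(covariances)
    p = covariances[0].shape[0]
    ns = np.asarray(sizes, dtype=float)
    if (ns <= p).any():
        raise ValidationError("each class needs n > dimension for Box's M")
    dfs = ns - 1.0
    covs = [_ridge_if_singular(np.asarray(S, dtype=float)) for S in covariances]
    pooled = sum(df * S for df, S in zip(dfs, covs)) / dfs.sum()
    pooled = _ridge_if_singular(pooled)
    m_stat = dfs.sum() * _logdet(pooled) - sum(df * _logdet(S) for df, S in zip(dfs, covs))
    c1 = ((2 * p * p + 3 * p - 1) / (6.0 * (p + 1) * (g - 1))
          * ((1.0 / dfs).sum() - 1.0 / dfs.sum()))
    chi2 = max(m_stat * (1.0 - c1), 0.0)
    df = p * (p + 1) * (g - 1) / 2.0
    return float(chi2), float(stats.chi2.sf(chi2, df))


def _logdet(S: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValidationError("covariance matrix is not positive definite")
    return float(val)


# ---------------------------------------------------------------------------
# Stepwise variable selection on Wilks' lambda partial F
# ---------------------------------------------------------------------------

def _sscp(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) sums-of-squares-and-cross-products."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for cls in np.unique(y):
        block = X[y == cls]
        bc = block - block.mean(axis=0)
        W += bc.T @ bc
    return W, T


def _wilks(W: np.ndarray, T: np.ndarray, idx: list[int]) -> float:
    """Wilks' lambda det(W_S)/det(T_S) over the variable subset."""
    if not idx:
        return 1.0
    sub = np.ix_(idx, idx)
    sign_w, ld_w = np.linalg.slogdet(W[sub])
    sign_t, ld_t = np.linalg.slogdet(T[sub])
    if sign_w <= 0 or sign_t <= 0:
        return float("nan")
    return math.exp(ld_w - ld_t)


def _partial_f(lam_small: float, lam_big: float, n: int, g: int, p: int
               ) -> tuple[float, float]:
    """Partial F for one variable given p already-included ones.

    F = (n - g - p)/(g - 1) * (lambda_p / lambda_{p+1} - 1), with
    df (g - 1, n - g - p); valid for any number of groups in the one-way case.
    """
    df2 = n - g - p
    if df2 < 1 or not np.isfinite(lam_small) or not np.isfinite(lam_big) or lam_big <= 0:
        return 0.0, 1.0
    f_stat = max((lam_small / lam_big - 1.0) * df2 / (g - 1), 0.0)
    return f_stat, float(stats.f.sf(f_stat, g - 1, df2))


def stepwise_select(X: pd.DataFrame, y: pd.Series, slentry: float = 0.15,
                    slstay: float = 0.15) -> list[str]:
    """Forward stepping with backward elimination on the partial F statistic.

    At each step the candidate with the largest significant partial F
    (p < slentry) enters; then any included variable whose partial F
    p-value exceeds slstay leaves.  Stops when neither occurs.  Collinear
    candidates contribute no extra discrimination (partial F ~ 0) and never
    enter.  Deterministic given (X, y).
    """
    if not (0 < slentry < 1 and 0 < slstay < 1):
        raise ValidationError("slentry and slstay must lie in (0, 1)")
    values = X.to_numpy(dtype=float)
    labels = y.to_numpy()
    classes = np.unique(labels)
    g = len(classes)
    if g < 2:
        raise ValidationError("stepwise selection needs at least 2 classes")
    n, n_feat = values.shape
    W, T = _sscp(values, labels)
    included: list[int] = []
    seen: set[frozenset[int]] = set()
    for _ in range(2 * n_feat + 1):
        changed = False
        lam_cur = _wilks(W, T, included)
        # entry
        if n - g - len(included) >= 2:
            best_j, best_f, best_p = -1, 0.0, 1.0
            for j in range(n_feat):
                if j in included:
                    continue
                lam_new = _wilks(W, T, included + [j])
                f_stat, p_val = _partial_f(lam_cur, lam_new, n, g, len(included))
                if p_val < slentry and f_stat > best_f:
                    best_j, best_f, best_p = j, f_stat, p_val
            if best_j >= 0:
                included.append(best_j)
                changed = True
        # removal (never empties a selection made this very step)
        while len(included) > 1:
            lam_full = _wilks(W, T, included)
            worst_j, worst_p = -1, -1.0
            for j in included:
                rest = [k for k in included if k != j]
                lam_rest = _wilks(W, T, rest)
                _, p_val = _partial_f(lam_rest, lam_full, n, g, len(rest))
                if p_val > worst_p:
                    worst_j, worst_p = j, p_val
            if worst_p > slstay:
                included.remove(worst_j)
                changed = True
            else:
                break
        state = frozenset(included)
        if not changed or state in seen:
            break
        seen.add(state)
    if not included:
        logger.warning("stepwise selection: no variable met slentry=%g", slentry)
    return [str(X.columns[j]) for j in included]


# ---------------------------------------------------------------------------
# Generalized-squared-distance discriminant
# ---------------------------------------------------------------------------

@dataclass
class SDAModel:
    """Fitted stepwise discriminant: class statistics on the selected features.

    ``cov_mode='pooled'`` uses one within-class covariance and g1 = 0 for
    every class (the linear case); ``'per_class'`` uses each class's own
    covariance with g1(t) = ln|S_t| (the quadratic case).
    """

    selected_features: list[str]
    class_labels: list[str]
    class_means: dict[str, np.ndarray]
    cov_mode: str
    covariances: dict[str, np.ndarray]   # per class, or {"pooled": S}
    g1: dict[str, float]
    homogeneity_pvalue: float
    slentry: float = 0.15
    slstay: float = 0.15

    def to_json(self) -> str:
        payload = {
            "selected_features": self.selected_features,
            "class_labels": self.class_labels,
            "class_means": {k: v.tolist() for k, v in self.class_means.items()},
            "cov_mode": self.cov_mode,
            "covariances": {k: v.tolist() for k, v in self.covariances.items()},
            "g1": self.g1,
            "homogeneity_pvalue": self.homogeneity_pvalue,
            "slentry": self.slentry,
            "slstay": self.slstay,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SDAModel":
        d = json.loads(text)
        return cls(
            selected_features=d["selected_features"],
            class_labels=d["class_labels"],
            class_means={k: np.asarray(v, dtype=float) for k, v in d["class_means"].items()},
            cov_mode=d["cov_mode"],
            covariances={k: np.asarray(v, dtype=float) for k, v in d["covariances"].items()},
            g1={k: float(v) for k, v in d["g1"].items()},
            homogeneity_pvalue=float(d["homogeneity_pvalue"]),
            slentry=float(d["slentry"]), slstay=float(d["slstay"]),
        )


def generalized_distance(x: np.ndarray, mean: np.ndarray, cov: np.ndarray,
                         g1: float = 0.0) -> float:
    """D^2 = (x - m)' S^{-1} (x - m) + g1; g2 omitted under equal priors."""
    diff = np.asarray(x, dtype=float) - np.asarray(mean, dtype=float)
    try:
        sol = np.linalg.solve(cov, diff)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular covariance in distance computation: {exc}")
    return float(diff @ sol) + g1


def train_sda(X: pd.DataFrame, y: pd.Series, slentry: float = 0.15,
              slstay: float = 0.15, homogeneity_alpha: float = 0.10,
              features: list[str] | None = None) -> SDAModel:
    """Stepwise selection, homogeneity test, then class statistics.

    ``features`` bypasses the stepwise search (used for oracle comparisons).
    Covariances are ridge-regularized (1e-8 * trace/dim) only if singular.
    """
    selected = features if features is not None else stepwise_select(X, y, slentry, slstay)
    labels = sorted(y.unique())
    if not selected:
        # Degenerate but explicit: no discriminating variable; all distances
        # tie and prediction falls back to the first class label.
        return SDAModel(selected_features=[], class_labels=list(labels),
                        class_means={c: np.zeros(0) for c in labels},
                        cov_mode="pooled", covariances={"pooled": np.zeros((0, 0))},
                        g1={c: 0.0 for c in labels}, homogeneity_pvalue=1.0,
                        slentry=slentry, slstay=slstay)
    values = X[selected].to_numpy(dtype=float)
    yv = y.to_numpy()
    means: dict[str, np.ndarray] = {}
    per_class_cov: dict[str, np.ndarray] = {}
    sizes: list[int] = []
    for cls in labels:
        block = values[yv == cls]
        means[cls] = block.mean(axis=0)
        per_class_cov[cls] = _ridge_if_singular(np.cov(block, rowvar=False, ddof=1)
                                                .reshape(len(selected), len(selected)))
        sizes.append(len(block))
    p_dim = len(selected)
    if min(sizes) > p_dim:
        _, p_hom = box_m_test([per_class_cov[c] for c in labels], sizes)
    else:
        p_hom = 1.0  # too few subjects to test; keep the pooled (linear) rule
    if p_hom < homogeneity_alpha:
        cov_mode = "per_class"
        covariances = per_class_cov
        g1 = {c: _logdet(per_class_cov[c]) for c in labels}
    else:
        cov_mode = "pooled"
        dfs = np.asarray(sizes) - 1
        pooled = sum(df * per_class_cov[c] for df, c in zip(dfs, labels)) / dfs.sum()
        covariances = {"pooled": _ridge_if_singular(pooled)}
        g1 = {c: 0.0 for c in labels}
    return SDAModel(selected_features=list(selected), class_labels=list(labels),
                    class_means=means, cov_mode=cov_mode, covariances=covariances,
                    g1=g1, homogeneity_pvalue=p_hom, slentry=slentry, slstay=slstay)


def predict_sda(model: SDAModel, X: pd.DataFrame) -> pd.Series:
    """Assign each row to the class with the smallest generalized distance.

    Exact ties (including the empty-model case) resolve to the first class
    label, deterministically.
    """
    if not model.selected_features:
        return pd.Series(model.class_labels[0], index=X.index, name="prediction")
    values = X[model.selected_features].to_numpy(dtype=float)
    preds = []
    for row in values:
        best_cls, best_d = None, math.inf
        for cls in model.class_labels:
            cov = (model.covariances[cls] if model.cov_mode == "per_class"
                   else model.covariances["pooled"])
            d2 = generalized_distance(row, model.class_means[cls], cov, model.g1[cls])
            if d2 < best_d:
                best_cls, best_d = cls, d2
        preds.append(best_cls)
    return pd.Series(preds, index=X.index, name="prediction")


# ---------------------------------------------------------------------------
# Baselines (established implementations)
# ---------------------------------------------------------------------------

def _cv_folds(y: pd.Series, seed: int) -> StratifiedKFold:
    n_min = int(y.value_counts().min())
    return StratifiedKFold(n_splits=max(2, min(5, n_min)), shuffle=True,
                           random_state=seed)


def train_svm(X: pd.DataFrame, y: pd.Series, seed: int = 0):
    """RBF-kernel SVM; C and gamma by grid search on training cross-validation."""
    cv = _cv_folds(y, seed)
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
    grid = {"svc__C": [0.1, 1.0, 10.0, 100.0],
            "svc__gamma": ["scale", 0.01, 0.1, 1.0]}
    search = GridSearchCV(pipe, grid, cv=cv, n_jobs=1)
    search.fit(X.to_numpy(dtype=float), y.to_numpy())
    return search.best_estimator_


def train_llr(X: pd.DataFrame, y: pd.Series, seed: int = 0):
    """L1-penalized logistic regression; penalty by cross-validated deviance."""
    cv = _cv_folds(y, seed)
    model = Pipeline([
        ("scale", StandardScaler()),
        ("llr", LogisticRegressionCV(l1_ratios=(1,), solver="liblinear", Cs=10,
                                     cv=cv, scoring="neg_log_loss",
                                     use_legacy_attributes=False,
                                     random_state=seed, max_iter=2000)),
    ])
    model.fit(X.to_numpy(dtype=float), y.to_numpy())
    return model


def predict_sklearn(model, X: pd.DataFrame) -> pd.Series:
    return pd.Series(model.predict(X.to_numpy(dtype=float)), index=X.index,
                     name="prediction")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """2x2 confusion counts and the three headline proportions.

    Disease is the positive class: sensitivity = TP/(TP+FN) over diseased
    subjects, specificity = TN/(TN+FP) over healthy ones.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    method: str = ""
    feature_set: str = ""

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / total if total else float("nan")

    def as_dict(self) -> dict[str, object]:
        return {"method": self.method, "feature_set": self.feature_set,
                "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "accuracy": self.accuracy}

    def __str__(self) -> str:
        return (f"{self.feature_set or 'features'} + {self.method or 'method'}: "
                f"sensitivity {100 * self.sensitivity:.2f}%  "
                f"specificity {100 * self.specificity:.2f}%  "
                f"accuracy {100 * self.accuracy:.2f}%")


def evaluate(predictions: pd.Series, truth: pd.Series, method: str = "",
             feature_set: str = "", positive: str = "disease") -> ClassificationReport:
    """Confusion counts and sensitivity/specificity/accuracy on aligned labels."""
    predictions, truth = predictions.align(truth, join="inner")
    if len(predictions) == 0:
        raise ValidationError("no overlapping subjects between predictions and truth")
    pred = predictions.to_numpy()
    true = truth.to_numpy()
    pos_true = true == positive
    pos_pred = pred == positive
    return ClassificationReport(
        tp=int((pos_true & pos_pred).sum()),
        fn=int((pos_true & ~pos_pred).sum()),
        tn=int((~pos_true & ~pos_pred).sum()),
        fp=int((~pos_true & pos_pred).sum()),
        method=method, feature_set=feature_set,
    )
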