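"""End-to-end procedure: beats -> RR correction -> features -> (PCA) -> classifier.

Runs one cell, or the full grid, of the comparison design: feature set
(quantile vs mean) x dimension reduction (PCA vs none) x classifier
(SDA, SVM, L1-logistic), evaluated as sensitivity/specificity/accuracy on a
held-out stratified test half.  The T-wave-type proportions never enter the
PCA but are appended to the classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import classify, pca as pca_mod, rr
from .features import TTYPE_PROP_NAMES, build_feature_matrix
from .types import ValidationError

METHODS = ("sda", "svm", "llr")
FEATURE_SETS = ("mean", "quantile", "mean+pca", "quantile+pca")


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end run (defaults mirror the shipped design)."""

    min_beats: int = 30
    split_fraction: float = 0.5
    n_components: int = 8
    slentry: float = 0.15
    slstay: float = 0.15
    homogeneity_alpha: float = 0.10
    refit_alpha: bool = False   # refit RR exponents on healthy training beats


def _classifier_inputs(beats: pd.DataFrame, feature_set: str, seed: int,
                       config: PipelineConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Feature matrices for train and test subjects for one design cell."""
    kind = "mean" if feature_set.startswith("mean") else "quantile"
    use_pca = feature_set.endswith("+pca")
    fm = build_feature_matrix(beats, min_beats=config.min_beats, kind=kind)
    train_ids, test_ids = classify.split_train_test(fm.y, config.split_fraction, seed)
    X_train, X_test = fm.X.loc[train_ids], fm.X.loc[test_ids]
    y_train, y_test = fm.y.loc[train_ids], fm.y.loc[test_ids]
    if use_pca:
        numeric = [c for c in fm.X.columns if c not in TTYPE_PROP_NAMES]
        model = pca_mod.fit_pca(X_train[numeric])
        k = min(config.n_components, model.loadings.shape[1])
        pca_mod.select_components(model, k=k)
        Z_train = pca_mod.transform(model, X_train[numeric])
        Z_test = pca_mod.transform(model, X_test[numeric])
        X_train = pd.concat([Z_train, X_train[list(TTYPE_PROP_NAMES)]], axis=1)
        X_test = pd.concat([Z_test, X_test[list(TTYPE_PROP_NAMES)]], axis=1)
    return X_train, X_test, y_train, y_test


def run_cell(beats_adjusted: pd.DataFrame, feature_set: str, method: str,
             seed: int = 0, config: PipelineConfig | None = None
             ) -> classify.ClassificationReport:
    """Train and evaluate one (feature set, method) cell on adjusted beats."""
    if feature_set not in FEATURE_SETS:
        raise ValidationError(f"feature_set must be one of {FEATURE_SETS}")
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}")
    config = config or PipelineConfig()
    X_train, X_test, y_train, y_test = _classifier_inputs(
        beats_adjusted, feature_set, seed, config)
    if method == "sda":
        model = classify.train_sda(X_train, y_train, config.slentry, config.slstay,
                                   config.homogeneity_alpha)
        pred = classify.predict_sda(model, X_test)
    elif method == "svm":
        pred = classify.predict_sklearn(classify.train_svm(X_train, y_train, seed), X_test)
    else:
        pred = classify.predict_sklearn(classify.train_llr(X_train, y_train, seed), X_test)
    return classify.evaluate(pred, y_test, method=method, feature_set=feature_set)


def adjust(beats: pd.DataFrame, refit_alpha: bool = False) -> pd.DataFrame:
    """RR-correct the span columns, optionally refitting exponents on
    healthy beats instead of using the shipped defaults."""
    if refit_alpha:
        models = rr.fit_corrections(beats)
        alphas = {var: m.alpha for var, m in models.items()}
    else:
        alphas = rr.default_corrections()
    return rr.adjust_beat_table(beats, alphas)


def run_all(beats: pd.DataFrame, seed: int = 0,
            config: PipelineConfig | None = None,
            methods: tuple[str, ...] = METHODS,
            feature_sets: tuple[str, ...] = FEATURE_SETS) -> pd.DataFrame:
    """The full comparison grid; returns one row per (feature set, method)."""
    config = config or PipelineConfig()
    adjusted = adjust(beats, refit_alpha=config.refit_alpha)
    rows = []
    for fs in feature_sets:
        for method in methods:
            report = run_cell(adjusted, fs, method, seed=seed, config=config)
            rows.append(report.as_dict())
    return pd.DataFrame(rows)
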