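"""Dimension reduction of the quantile features by PCA, with loading reports.

The 144 quantile features are many relative to the number of subjects and
strongly correlated (neighbouring quantiles of one variable move together),
so the classifiers consume a handful of leading principal components
instead.  Features are standardized to zero mean and unit variance first —
spans (s), amplitudes (mV) and slopes (mV/s) live on incommensurate scales,
so this is PCA of the correlation structure.  The top-|loading| features of
each kept component double as a biomarker ranking.

The categorical T-wave-type features never enter the PCA; they rejoin the
feature set at the classification stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Fitted standardization + rotation.  ``loadings`` is features x components,
    columns orthonormal, each oriented so its largest-|value| entry is positive."""

    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    explained_ratio: np.ndarray
    n_components_kept: int


def fit_pca(X: pd.DataFrame) -> PCAModel:
    """Fit on training rows only; zero-variance columns are dropped with a warning."""
    if len(X) < 2:
        raise ValidationError("PCA needs at least 2 rows")
    values = X.to_numpy(dtype=float)
    scales_all = values.std(axis=0, ddof=1)
    keep = scales_all > 0
    if not keep.all():
        dropped = [n for n, k in zip(X.columns, keep) if not k]
        logger.warning("dropping zero-variance features before PCA: %s", dropped)
    names = [n for n, k in zip(X.columns, keep) if k]
    values = values[:, keep]
    means = values.mean(axis=0)
    scales = values.std(axis=0, ddof=1)
    Z = (values - means) / scales
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    return PCAModel(feature_names=names, means=means, scales=scales,
                    loadings=loadings,
                    explained_ratio=pca.explained_variance_ratio_.copy(),
                    n_components_kept=loadings.shape[1])


def select_components(model: PCAModel, k: int | None = 8,
                      cum_variance: float | None = None) -> int:
    """Fix the number of retained components.

    Either a fixed ``k`` (default 8) or the smallest count whose cumulative
    explained-variance ratio reaches ``cum_variance``; at least one
    component is always kept.  Records the choice in the model.
    """
    total = model.loadings.shape[1]
    if cum_variance is not None:
        cum = np.cumsum(model.explained_ratio)
        kept = int(np.searchsorted(cum, min(cum_variance, cum[-1])) + 1)
        kept = max(1, min(kept, total))
    else:
        if k is None or k < 1:
            raise ValidationError("k must be a positive integer")
        if k > total:
            raise ValidationError(f"k={k} exceeds available components ({total})")
        kept = int(k)
    model.n_components_kept = kept
    return kept


def top_loadings(model: PCAModel, k_vars: int = 5) -> list[list[str]]:
    """Per kept component: the ``k_vars`` features with largest absolute
    loading, in decreasing order; |loading| ties break by feature-name order."""
    out = []
    names = np.asarray(model.feature_names)
    for j in range(model.n_components_kept):
        col = np.abs(model.loadings[:, j])
        order = sorted(range(len(col)), key=lambda i: (-col[i], names[i]))
        out.append([str(names[i]) for i in order[:k_vars]])
    return out


def transform(model: PCAModel, X: pd.DataFrame) -> pd.DataFrame:
    """Project rows onto the kept components using *training* means/scales."""
    missing = [n for n in model.feature_names if n not in X.columns]
    if missing:
        raise ValidationError(f"transform input missing features: {missing}")
    values = X[model.feature_names].to_numpy(dtype=float)
    Z = (values - model.means) / model.scales
    k = model.n_components_kept
    scores = Z @ model.loadings[:, :k]
    return pd.DataFrame(scores, index=X.index,
                        columns=[f"PC{j + 1}" for j in range(k)])


def inverse_transform(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Back-project scores to standardized feature space (exact with all
    components kept, by orthogonality)."""
    k = scores.shape[1]
    return scores @ model.loadings[:, :k].T


def pca_report(model: PCAModel, k_vars: int = 5) -> str:
    """Text report: per component, the top features and its variance contribution."""
    tops = top_loadings(model, k_vars)
    kept = model.n_components_kept
    total = float(model.explained_ratio[:kept].sum())
    lines = [f"Principal components kept: {kept}  (contribution {100 * total:.2f}%)"]
    for j, names in enumerate(tops):
        pct = 100 * float(model.explained_ratio[j])
        lines.append(f"PC{j + 1}\t{', '.join(names)}\t{pct:.2f}%")
    return "\n".join(lines) + "\n"
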