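"""Subject-level features: eight sample quantiles per measurement variable.

Healthy subjects' per-beat distributions are typically unimodal and
light-tailed, while diseased subjects mix mostly-normal beats with a
minority of abnormal ones, giving skewed, heavy-tailed or multimodal
distributions.  Means wash that structure out; tail quantiles keep it.
Each of the 18 numeric measurement variables is summarized by the
percentiles p1, p5, p10, p25, p75, p90, p95, p99 — 144 features per
subject — plus the six T-wave-type proportions and the modal type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    FEATURE_BASE_NAMES,
    MEASUREMENT_COLUMNS,
    T_TYPES,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The eight percentiles, tail-heavy by design (the median carries little
#: group information when the bulk of beats is normal in both groups).
PERCENTILES: tuple[int, ...] = (1, 5, 10, 25, 75, 90, 95, 99)

#: Names of the six T-type proportion features.
TTYPE_PROP_NAMES: tuple[str, ...] = tuple(f"Ttype-prop_{t.value}" for t in T_TYPES)


def quantile_feature_names() -> list[str]:
    """The 144 feature names, variable-major: e.g. ``QT-int_p95``, ``Down-T-slo_p90``."""
    return [f"{FEATURE_BASE_NAMES[col]}_p{p}"
            for col in MEASUREMENT_COLUMNS for p in PERCENTILES]


def mean_feature_names() -> list[str]:
    """The 18 per-variable mean feature names (the comparison arm)."""
    return [f"{FEATURE_BASE_NAMES[col]}_mean" for col in MEASUREMENT_COLUMNS]


def sample_quantile(values: np.ndarray, p: float) -> float:
    """Order-statistic quantile with linear interpolation between closest
    ranks (position ``(n-1) * p/100`` on the 0-based sorted vector).

    Non-finite entries are ignored; an empty vector gives nan.
    """
    if not 0 < p < 100:
        raise ValidationError(f"percentile must be in (0, 100), got {p}")
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return float("nan")
    return float(np.quantile(values, p / 100.0, method="linear"))


@dataclass
class FeatureVector:
    """One subject's classification features."""

    subject_id: str
    label: str
    q: dict[str, float]            # 144 quantile entries, name -> value
    ttype_props: np.ndarray        # 6 proportions in T_TYPES order, sum 1
    ttype_mode: str
    n_beats: int


def summarize_subject(beats: pd.DataFrame, min_beats: int = 30) -> FeatureVector:
    """Summarize one subject's (already RR-corrected) beats.

    Each variable uses its own non-absent beats.  Subjects with fewer than
    ``min_beats`` beats are rejected — too few beats make tail quantiles
    meaningless.
    """
    if beats["subject_id"].nunique() != 1:
        raise ValidationError("summarize_subject expects beats of exactly one subject")
    n = len(beats)
    subject_id = str(beats["subject_id"].iloc[0])
    if n < min_beats:
        raise ValidationError(
            f"subject {subject_id}: {n} beats < min_beats={min_beats}")
    q: dict[str, float] = {}
    for col in MEASUREMENT_COLUMNS:
        base = FEATURE_BASE_NAMES[col]
        values = beats[col].to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        for p in PERCENTILES:
            q[f"{base}_p{p}"] = sample_quantile(finite, p) if len(finite) else float("nan")
    counts = beats["T_type"].value_counts()
    props = np.array([counts.get(t.value, 0) for t in T_TYPES], dtype=float)
    props /= props.sum()
    mode = T_TYPES[int(np.argmax(props))].value  # ties -> category order
    return FeatureVector(subject_id=subject_id, label=str(beats["label"].iloc[0]),
                         q=q, ttype_props=props, ttype_mode=mode, n_beats=n)


@dataclass
class FeatureMatrix:
    """Subjects-by-features design matrix plus labels and bookkeeping."""

    X: pd.DataFrame                 # numeric features, subject_id index
    y: pd.Series                    # "healthy" | "disease"
    imputed: pd.DataFrame           # boolean mask of median-imputed cells
    excluded: dict[str, str]        # subject_id -> exclusion reason
    ttype_mode: pd.Series           # modal T type per subject


def _assemble(rows: list[FeatureVector], numeric: list[dict[str, float]],
              excluded: dict[str, str]) -> FeatureMatrix:
    index = pd.Index([fv.subject_id for fv in rows], name="subject_id")
    X = pd.DataFrame(numeric, index=index)
    y = pd.Series([fv.label for fv in rows], index=index, name="label")
    if y.nunique() < 2:
        raise ValidationError("need subjects of both classes to build a feature matrix")
    all_nan = X.columns[X.isna().all()]
    if len(all_nan):
        logger.warning("dropping features absent for every subject: %s", list(all_nan))
        X = X.drop(columns=all_nan)
    imputed = X.isna()
    X = X.fillna(X.median())
    mode = pd.Series([fv.ttype_mode for fv in rows], index=index, name="ttype_mode")
    return FeatureMatrix(X=X, y=y, imputed=imputed, excluded=excluded, ttype_mode=mode)


def build_feature_matrix(beats: pd.DataFrame, min_beats: int = 30,
                         kind: str = "quantile") -> FeatureMatrix:
    """Build the subjects-by-features matrix from a beat table.

    ``kind='quantile'`` gives the 144 quantile features; ``kind='mean'``
    gives the 18 per-variable means (the classical summary, kept as the
    comparison arm).  Both append the 6 T-type proportions.  Sporadic
    absent entries are median-imputed (mask recorded); subjects below
    ``min_beats`` are excluded with a logged reason.
    """
    if kind not in ("quantile", "mean"):
        raise ValidationError(f"kind must be 'quantile' or 'mean', got {kind!r}")
    rows: list[FeatureVector] = []
    numeric: list[dict[str, float]] = []
    excluded: dict[str, str] = {}
    for subject_id, group in beats.groupby("subject_id", sort=True):
        try:
            fv = summarize_subject(group, min_beats=min_beats)
        except ValidationError as exc:
            logger.warning("excluding subject: %s", exc)
            excluded[str(subject_id)] = str(exc)
            continue
        if kind == "quantile":
            entry = dict(fv.q)
        else:
            entry = {}
            for col in MEASUREMENT_COLUMNS:
                values = group[col].to_numpy(dtype=float)
                finite = values[np.isfinite(values)]
                entry[f"{FEATURE_BASE_NAMES[col]}_mean"] = (
                    float(finite.mean()) if len(finite) else float("nan"))
        entry.update(dict(zip(TTYPE_PROP_NAMES, fv.ttype_props)))
        rows.append(fv)
        numeric.append(entry)
    if not rows:
        raise ValidationError("no subject met the min_beats requirement")
    return _assemble(rows, numeric, excluded)
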