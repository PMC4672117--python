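"""Heart-rate (RR) correction of time-span measurements by a power law.

Time spans such as QT lengthen with the beat period, so they are divided by
``RR**alpha`` before comparison across beats (Bazett's QTc = QT/sqrt(RR) is
the alpha = 0.5 case).  The exponent for each variable is chosen on the
fixed grid {0, 0.1, ..., 1.0} by fitting ``y = beta * RR**alpha`` on healthy
subjects' beats and keeping the grid value with the best R-square; the
shipped defaults are PR 0.2, P span 0.1, T span 0.5, QT 0.5 (Bazett), and
QRS span 0 (no RR dependence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ValidationError

#: The 11-point exponent grid.
DEFAULT_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(11))

#: Span variables eligible for correction (RR itself is never corrected).
CORRECTABLE_SPANS: tuple[str, ...] = ("PR", "QT", "Pspan", "QRSspan", "Tspan")


class DegenerateFitError(ValueError):
    """Raised when y is constant (SST = 0); callers should fall back to alpha = 0."""


@dataclass
class CorrectionModel:
    """A fitted per-variable correction: exponent, scale, and goodness of fit."""

    variable: str
    alpha: float
    beta: float
    r_square: float
    n_beats: int


def fit_power_exponent(y: np.ndarray, rr: np.ndarray,
                       grid: tuple[float, ...] = DEFAULT_GRID,
                       variable: str = "") -> CorrectionModel:
    """Select the grid exponent maximizing R-square for ``y ~ beta * RR**alpha``.

    beta is fit by least squares through the origin for each candidate
    alpha (the model has no intercept); R-square is nevertheless computed
    against the mean of y (1 - SSE/SST with SST about the mean) so fits are
    comparable across exponents.  Ties resolve to the smaller alpha.
    """
    y = np.asarray(y, dtype=float)
    rr = np.asarray(rr, dtype=float)
    mask = np.isfinite(y) & np.isfinite(rr)
    y, rr = y[mask], rr[mask]
    if len(y) < 10:
        raise ValidationError(f"need >= 10 finite (y, RR) pairs, got {len(y)}")
    if (rr <= 0).any():
        raise ValidationError("all RR values must be positive")
    sst = float(((y - y.mean()) ** 2).sum())
    if np.ptp(y) == 0 or sst == 0.0:
        raise DegenerateFitError(
            f"{variable or 'y'} is constant; no RR dependence to fit — use alpha = 0")
    best: CorrectionModel | None = None
    for alpha in sorted(grid):
        x = rr ** alpha
        beta = float((x @ y) / (x @ x))
        sse = float(((y - beta * x) ** 2).sum())
        r2 = 1.0 - sse / sst
        if best is None or r2 > best.r_square:
            best = CorrectionModel(variable=variable, alpha=float(alpha),
                                   beta=beta, r_square=r2, n_beats=len(y))
    return best


def apply_correction(y, rr, alpha: float):
    """Corrected value ``y / RR**alpha``; absent RR gives an absent result
    (except alpha = 0, which is the identity)."""
    if alpha == 0:
        return y
    return y / np.asarray(rr, dtype=float) ** alpha


def default_corrections() -> dict[str, float]:
    """The shipped exponents; QRS span is left unadjusted."""
    return {"QT": 0.5, "PR": 0.2, "Pspan": 0.1, "Tspan": 0.5, "QRSspan": 0.0}


def fit_corrections(beats: pd.DataFrame,
                    variables: tuple[str, ...] = CORRECTABLE_SPANS,
                    grid: tuple[float, ...] = DEFAULT_GRID,
                    healthy_only: bool = True) -> dict[str, CorrectionModel]:
    """Fit a :class:`CorrectionModel` per span variable on the beat table.

    Fitting uses healthy subjects' beats by default, so disease-related
    distortions do not leak into the correction law.
    """
    rows = beats[beats["label"] == "healthy"] if healthy_only else beats
    if rows.empty:
        raise ValidationError("no beats available to fit corrections on")
    return {
        var: fit_power_exponent(rows[var].to_numpy(), rows["RR"].to_numpy(),
                                grid=grid, variable=var)
        for var in variables
    }


def adjust_beat_table(beats: pd.DataFrame,
                      alphas: dict[str, float] | None = None) -> pd.DataFrame:
    """Return a copy of the beat table with span columns RR-corrected.

    ``alphas`` defaults to :func:`default_corrections`.  The RR column is
    kept raw; amplitudes and slopes are untouched.
    """
    alphas = default_corrections() if alphas is None else alphas
    out = beats.copy()
    rr = out["RR"].to_numpy(dtype=float)
    for var, alpha in alphas.items():
        if var in out.columns and alpha != 0:
            out[var] = out[var].to_numpy(dtype=float) / rr ** alpha
    return out


def corrections_report(models: dict[str, CorrectionModel]) -> str:
    """Small structured text report of fitted corrections."""
    lines = ["variable\talpha\tbeta\tr_square\tn_beats"]
    for var, m in models.items():
        lines.append(f"{var}\t{m.alpha:g}\t{m.beta:.6g}\t{m.r_square:.6f}\t{m.n_beats}")
    return "\n".join(lines) + "\n"
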