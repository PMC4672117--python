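"""Per-beat measurements: time spans, baseline, amplitudes, segment slopes.

All measurements are taken from a sampled signal plus the beat's fiducials.
The baseline (isoelectric level) is the pooled mean of samples in the PR,
ST, and TP segments; amplitudes are signed excursions from it; each of the
nine waveform segments gets an ordinary-least-squares slope in mV/s.
Missing fiducials propagate as ``nan`` for the measurements that need them
— a beat is never dropped for a single absent wave.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import BEAT_TABLE_COLUMNS
from .types import BeatMeasurements, FiducialBeat, SLOPE_NAMES

_NAN = float("nan")

#: slope name -> (start fiducial, end fiducial); TP crosses to the next beat.
SLOPE_SEGMENTS: dict[str, tuple[str, str]] = {
    "Up-P-slo": ("p_on", "p_peak"),
    "Down-P-slo": ("p_peak", "p_off"),
    "PR-slo": ("p_off", "qrs_on"),
    "Up-R-slo": ("qrs_on", "r_peak"),
    "Down-R-slo": ("r_peak", "qrs_off"),
    "ST-slo": ("qrs_off", "t_on"),
    "Up-T-slo": ("t_on", "t_peak"),
    "Down-T-slo": ("t_peak", "t_off"),
    "TP-slo": ("t_off", "next:p_on"),
}


def _span(a: int | None, b: int | None, fs: float) -> float:
    if a is None or b is None:
        return _NAN
    return (b - a) / fs


def time_spans(beat: FiducialBeat, next_beat: FiducialBeat | None) -> dict[str, float]:
    """The six time spans in seconds; spans with absent fiducials are nan.

    RR needs the next beat's R peak and is absent for the last beat of a
    record.
    """
    fs = beat.fs
    return {
        "RR": _span(beat.r_peak, next_beat.r_peak, fs) if next_beat is not None else _NAN,
        "PR": _span(beat.p_on, beat.qrs_on, fs),
        "QT": _span(beat.qrs_on, beat.t_off, fs),
        "Pspan": _span(beat.p_on, beat.p_off, fs),
        "QRSspan": _span(beat.qrs_on, beat.qrs_off, fs),
        "Tspan": _span(beat.t_on, beat.t_off, fs),
    }


def _window(signal: np.ndarray, a: int | None, b: int | None) -> np.ndarray | None:
    """Samples a..b inclusive, or None when a fiducial is absent / out of range."""
    if a is None or b is None or a > b or a < 0 or b >= len(signal):
        return None
    return signal[a:b + 1]


def estimate_baseline(signal: np.ndarray, beat: FiducialBeat,
                      next_beat: FiducialBeat | None) -> float:
    """Mean of all samples pooled across the PR, ST and TP segments.

    Unavailable segments (missing waves, or no next beat for TP) are simply
    left out of the pool; with no usable segment the baseline is nan.
    """
    next_p_on = next_beat.p_on if next_beat is not None else None
    segments = [
        _window(signal, beat.p_off, beat.qrs_on),
        _window(signal, beat.qrs_off, beat.t_on),
        _window(signal, beat.t_off, next_p_on),
    ]
    pooled = [seg for seg in segments if seg is not None and len(seg) > 0]
    if not pooled:
        return _NAN
    return float(np.concatenate(pooled).mean())


def wave_amplitude(signal: np.ndarray, wave_on: int | None, wave_off: int | None,
                   baseline: float) -> float:
    """Signed amplitude: the larger-|.|-excursion of max/min from the baseline.

    Ties in absolute value resolve to the positive excursion.
    """
    window = _window(signal, wave_on, wave_off)
    if window is None or math.isnan(baseline):
        return _NAN
    a = float(window.max()) - baseline
    b = float(window.min()) - baseline
    return a if abs(a) >= abs(b) else b


def segment_slope(times: np.ndarray, values: np.ndarray) -> float:
    """OLS slope (intercept included) of values (mV) on times (s), in mV/s."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2 or np.ptp(times) == 0:
        return _NAN
    return float(np.polyfit(times, values, 1)[0])


def _fiducial(beat: FiducialBeat, next_beat: FiducialBeat | None, name: str) -> int | None:
    if name.startswith("next:"):
        return getattr(next_beat, name[5:]) if next_beat is not None else None
    return getattr(beat, name)


def measure_beat(signal: np.ndarray, beat: FiducialBeat,
                 next_beat: FiducialBeat | None = None) -> BeatMeasurements:
    """Assemble one beat's full measurement row.

    Amplitude windows: P over p_on..p_off, R over the full QRS
    (qrs_on..qrs_off, so deep negative complexes are captured), T over
    t_on..t_off.  Slopes follow :data:`SLOPE_SEGMENTS`; the TP segment runs
    to the next beat's P onset and is absent for the last beat.
    """
    fs = beat.fs
    spans = time_spans(beat, next_beat)
    baseline = estimate_baseline(signal, beat, next_beat)
    slopes: dict[str, float] = {}
    for name, (start, end) in SLOPE_SEGMENTS.items():
        a = _fiducial(beat, next_beat, start)
        b = _fiducial(beat, next_beat, end)
        window = _window(signal, a, b)
        if window is None:
            slopes[name] = _NAN
        else:
            t = np.arange(a, b + 1) / fs
            slopes[name] = segment_slope(t, window)
    return BeatMeasurements(
        rr=spans["RR"], pr=spans["PR"], qt=spans["QT"],
        p_span=spans["Pspan"], qrs_span=spans["QRSspan"], t_span=spans["Tspan"],
        baseline=baseline,
        p_amp=wave_amplitude(signal, beat.p_on, beat.p_off, baseline),
        r_amp=wave_amplitude(signal, beat.qrs_on, beat.qrs_off, baseline),
        t_amp=wave_amplitude(signal, beat.t_on, beat.t_off, baseline),
        slopes=slopes,
        t_type=beat.t_type,
    )


def measure_record(signal: np.ndarray, beats: list[FiducialBeat],
                   subject_id: str, label: str,
                   first_beat_index: int = 0) -> pd.DataFrame:
    """Measure every beat of a record into the beat-table schema.

    The last beat has no successor, so its RR, TP slope, and TP baseline
    contribution are absent.
    """
    rows = []
    for i, beat in enumerate(beats):
        nxt = beats[i + 1] if i + 1 < len(beats) else None
        row = measure_beat(signal, beat, nxt).as_row()
        row["subject_id"] = subject_id
        row["label"] = label
        row["beat_index"] = first_beat_index + i
        rows.append(row)
    return pd.DataFrame(rows, columns=list(BEAT_TABLE_COLUMNS))
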