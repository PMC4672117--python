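"""Readers and writers: beat tables, WFDB-style records, annotation streams.

The tabular interchange format of record is comma-delimited UTF-8 text with a
header row, '.' decimal point, and a fixed column order (see
:data:`BEAT_TABLE_COLUMNS`).  Signals round-trip through a deliberately small
subset of the WFDB convention — a text header plus a 16-bit little-endian
sample file — sufficient for single- and few-lead synthetic records.
Annotation streams are the text form produced by ``rdann``-style dumps: one
event per line with sample number, symbol, subtype, channel and num fields;
'(' / ')' mark wave onsets/offsets with the num field selecting the wave
(0 = P, 1 = QRS, 2 = T), 'p' / 't' mark wave peaks, and an alphabetic beat
label marks the R peak.  The T-wave morphology class rides in the subtype
field of the 't' event.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AMP_COLUMNS,
    FIDUCIAL_ORDER,
    SLOPE_NAMES,
    SPAN_COLUMNS,
    FiducialBeat,
    T_TYPES,
    TWaveType,
    ValidationError,
)

#: Fixed column order of the per-beat table.
BEAT_TABLE_COLUMNS: tuple[str, ...] = (
    ("subject_id", "label", "beat_index")
    + SPAN_COLUMNS + AMP_COLUMNS + SLOPE_NAMES + ("T_type",)
)


class SchemaError(ValueError):
    """A delimited file does not match the expected column schema."""


def write_beat_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a beat table in the fixed interchange dialect (lossless for finite values)."""
    missing = [c for c in BEAT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"beat table missing columns: {missing}")
    table.loc[:, list(BEAT_TABLE_COLUMNS)].to_csv(path, index=False, encoding="utf-8")


def read_beat_table(path: str | Path) -> pd.DataFrame:
    """Read a beat table, enforcing the schema; raises :class:`SchemaError` naming absent columns."""
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in BEAT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"beat table missing columns: {missing}")
    table["subject_id"] = table["subject_id"].astype(str)
    return table[list(BEAT_TABLE_COLUMNS)]


# ---------------------------------------------------------------------------
# WFDB-style signal files (text header + format-16 samples)
# ---------------------------------------------------------------------------

_ADC_GAIN = 1000.0  # digital units per mV -> 1 uV quantization


def write_wfdb_record(header_path: str | Path, signal: np.ndarray, fs: float,
                      leads: list[str]) -> None:
    """Write ``signal`` (n_samples x n_leads, mV) as header + 16-bit sample file."""
    header_path = Path(header_path)
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[0] < signal.shape[1]:
        signal = signal.T
    n_samples, n_leads = signal.shape
    if len(leads) != n_leads:
        raise ValidationError(f"{n_leads} channels but {len(leads)} lead names")
    record = header_path.stem
    dat_name = record + ".dat"
    lines = [f"{record} {n_leads} {fs:g} {n_samples}"]
    for name in leads:
        lines.append(f"{dat_name} 16 {_ADC_GAIN:g}/mV 16 0 0 0 0 {name}")
    header_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    digital = np.clip(np.rint(signal * _ADC_GAIN), -32768, 32767).astype("<i2")
    (header_path.parent / dat_name).write_bytes(digital.reshape(-1).tobytes())


def read_wfdb_record(header_path: str | Path, lead: str) -> tuple[np.ndarray, float]:
    """Read one lead (mV) and the sampling rate from a WFDB-style record.

    Only format 16 (interleaved little-endian int16) is supported.  An
    unknown lead raises a :class:`ValidationError` listing available leads.
    """
    header_path = Path(header_path)
    lines = [ln for ln in header_path.read_text(encoding="utf-8").splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_leads = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    sig_lines = lines[1:1 + n_leads]
    names, gains, baselines, files, fmts = [], [], [], [], []
    for ln in sig_lines:
        tokens = ln.split()
        files.append(tokens[0])
        fmts.append(tokens[1].split("x")[0].split(":")[0].split("+")[0])
        gain_tok = tokens[2].split("/")[0] if len(tokens) > 2 else "200"
        if "(" in gain_tok:
            gain, base = gain_tok.rstrip(")").split("(")
        else:
            gain, base = gain_tok, "0"
        gains.append(float(gain) if float(gain) != 0 else 200.0)
        baselines.append(float(base))
        names.append(tokens[8] if len(tokens) > 8 else " ".join(tokens[8:]) or f"ch{len(names)}")
    if lead not in names:
        raise ValidationError(f"lead {lead!r} not found; available leads: {names}")
    idx = names.index(lead)
    if fmts[idx] != "16":
        raise ValidationError(f"unsupported signal format {fmts[idx]!r}; only format 16 is read")
    raw = np.frombuffer((header_path.parent / files[idx]).read_bytes(), dtype="<i2")
    channels = raw.reshape(-1, n_leads)
    return (channels[:, idx].astype(float) - baselines[idx]) / gains[idx], fs


# ---------------------------------------------------------------------------
# Annotation streams
# ---------------------------------------------------------------------------

#: symbol -> (field, wave-selected?) ; beat labels handled separately
_WAVE_BY_NUM = {0: "p", 1: "qrs", 2: "t"}
_BEAT_LABELS = set("NLRBAaJSVrFejnE/fQ?")

#: order index within a beat, for run-splitting during grouping
_FIDUCIAL_INDEX = {name: i for i, name in enumerate(FIDUCIAL_ORDER)}


def _classify_event(symbol: str, num: int) -> str | None:
    if symbol == "(":
        wave = _WAVE_BY_NUM.get(num)
        return None if wave is None else {"p": "p_on", "qrs": "qrs_on", "t": "t_on"}[wave]
    if symbol == ")":
        wave = _WAVE_BY_NUM.get(num)
        return None if wave is None else {"p": "p_off", "qrs": "qrs_off", "t": "t_off"}[wave]
    if symbol == "p":
        return "p_peak"
    if symbol == "t":
        return "t_peak"
    if symbol in _BEAT_LABELS:
        return "r_peak"
    return None


def write_annotations(beats: list[FiducialBeat], path: str | Path) -> None:
    """Write beats as an rdann-style text stream (inverse of :func:`read_annotations`)."""
    events: list[tuple[int, str, int, int]] = []  # sample, symbol, subtype, num
    for beat in beats:
        spec = [("p_on", "(", 0, 0), ("p_peak", "p", 0, 0), ("p_off", ")", 0, 0),
                ("qrs_on", "(", 0, 1), ("r_peak", "N", 0, 1), ("qrs_off", ")", 0, 1),
                ("t_on", "(", 0, 2),
                ("t_peak", "t", T_TYPES.index(beat.t_type), 2),
                ("t_off", ")", 0, 2)]
        for field, symbol, subtype, num in spec:
            sample = getattr(beat, field)
            if sample is not None:
                events.append((sample, symbol, subtype, num))
    events.sort(key=lambda e: e[0])
    with open(path, "w", encoding="utf-8") as fh:
        for sample, symbol, subtype, num in events:
            fh.write(f"{0.0:>12.3f} {sample:>9d} {symbol:>5s} {subtype:>5d} {0:>5d} {num:>5d}\n")


def read_annotations(path: str | Path, fs: float
                     ) -> tuple[list[FiducialBeat], list[tuple[FiducialBeat, str]]]:
    """Parse an annotation stream into per-beat fiducials.

    Events are grouped into maximal runs centred on one beat label; the
    delineator's pairing of P/T waves with their QRS is taken as
    authoritative, so a new beat starts whenever an event would move
    backwards in the within-beat fiducial order.  Beats with non-monotone
    indices or without a beat label are returned in the rejects list with a
    reason, never raised.
    """
    events: list[tuple[int, str, int, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            # with or without the leading elapsed-time column
            if tokens[0].replace(".", "").replace(":", "").isdigit() and len(tokens) >= 6:
                tokens = tokens[1:]
            if len(tokens) < 5:
                raise ValidationError(f"unparseable annotation line: {line!r}")
            sample, symbol, subtype, _chan, num = tokens[:5]
            events.append((int(sample), symbol, int(subtype), int(num)))
    # File order is kept: the delineator emits events beat by beat, and a
    # non-monotone sample inside a beat must surface as a reject, not be
    # silently re-sorted away.

    beats: list[FiducialBeat] = []
    rejects: list[tuple[FiducialBeat, str]] = []

    def close(fields: dict[str, int], t_subtype: int | None) -> None:
        if not fields:
            return
        t_type = T_TYPES[t_subtype] if t_subtype is not None and 0 <= t_subtype < 6 \
            else TWaveType.NORMAL
        beat = FiducialBeat(**fields, t_type=t_type, fs=fs)
        if beat.r_peak is None:
            rejects.append((beat, "no beat label"))
        elif (reason := beat.monotonicity_violation()) is not None:
            rejects.append((beat, reason))
        else:
            beats.append(beat)

    current: dict[str, int] = {}
    t_subtype: int | None = None
    for sample, symbol, subtype, num in events:
        field = _classify_event(symbol, num)
        if field is None:
            continue
        if field in current or (
            current and _FIDUCIAL_INDEX[field] <= max(_FIDUCIAL_INDEX[f] for f in current)
        ):
            close(current, t_subtype)
            current, t_subtype = {}, None
        current[field] = sample
        if field == "t_peak":
            t_subtype = subtype
    close(current, t_subtype)
    return beats, rejects
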