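"""Domain types shared across the pipeline.

A *beat* is the unit of measurement: nine fiducial sample indices (onset,
peak, offset of the P wave, the QRS complex, and the T wave) plus a
categorical T-wave morphology label.  A *subject* owns one or more records,
each a delineated beat sequence; the subject's binary diagnosis (healthy vs
disease) is the classification label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class TWaveType(str, Enum):
    """Six-category T-wave morphology label assigned per beat by the delineator."""

    NORMAL = "normal"
    INVERTED = "inverted"
    POSITIVE_MONOPHASIC = "pos_mono"
    NEGATIVE_MONOPHASIC = "neg_mono"
    BIPHASIC_NEG_POS = "biphasic_np"
    BIPHASIC_POS_NEG = "biphasic_pn"


#: Fixed category order used for probability vectors and proportion features.
T_TYPES: tuple[TWaveType, ...] = tuple(TWaveType)

#: Fiducial fields in temporal order within one beat.
FIDUCIAL_ORDER: tuple[str, ...] = (
    "p_on", "p_peak", "p_off",
    "qrs_on", "r_peak", "qrs_off",
    "t_on", "t_peak", "t_off",
)

#: The nine waveform segments whose slopes are measured, in canonical order.
SLOPE_NAMES: tuple[str, ...] = (
    "Up-P-slo", "Down-P-slo", "PR-slo",
    "Up-R-slo", "Down-R-slo", "ST-slo",
    "Up-T-slo", "Down-T-slo", "TP-slo",
)

#: Time-span table columns (seconds).
SPAN_COLUMNS: tuple[str, ...] = ("RR", "PR", "QT", "Pspan", "QRSspan", "Tspan")

#: Amplitude table columns (mV, signed, baseline-referenced).
AMP_COLUMNS: tuple[str, ...] = ("P_amp", "R_amp", "T_amp")

#: Table column -> feature base name used in reports ("-int"/"-amp"/"-slo" scheme).
FEATURE_BASE_NAMES: dict[str, str] = {
    "RR": "RR-int", "PR": "PR-int", "QT": "QT-int",
    "Pspan": "P-int", "QRSspan": "QRS-int", "Tspan": "T-int",
    "P_amp": "P-amp", "R_amp": "QRS-amp", "T_amp": "T-amp",
    **{s: s for s in SLOPE_NAMES},
}

#: The 18 numeric per-beat measurement columns, canonical order.
MEASUREMENT_COLUMNS: tuple[str, ...] = SPAN_COLUMNS + AMP_COLUMNS + SLOPE_NAMES


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class FiducialBeat:
    """Sample indices of one beat's fiducial points, 0-based at sampling rate ``fs``.

    A field is ``None`` when the delineator found no corresponding wave.
    Present indices must be strictly increasing in :data:`FIDUCIAL_ORDER`.
    """

    p_on: Optional[int] = None
    p_peak: Optional[int] = None
    p_off: Optional[int] = None
    qrs_on: Optional[int] = None
    r_peak: Optional[int] = None
    qrs_off: Optional[int] = None
    t_on: Optional[int] = None
    t_peak: Optional[int] = None
    t_off: Optional[int] = None
    t_type: TWaveType = TWaveType.NORMAL
    fs: float = 1000.0

    def monotonicity_violation(self) -> Optional[str]:
        """Return a reason string if present indices are not strictly increasing."""
        present = [(name, getattr(self, name)) for name in FIDUCIAL_ORDER
                   if getattr(self, name) is not None]
        for (a_name, a), (b_name, b) in zip(present, present[1:]):
            if b <= a:
                return f"non-monotone fiducials: {b_name}={b} <= {a_name}={a}"
        return None


@dataclass
class BeatMeasurements:
    """One beat's measurement row: 6 time spans (s), baseline and 3 amplitudes
    (mV), 9 segment slopes (mV/s), and the T-wave type.

    Absent measurements are ``nan`` (e.g. RR and the TP slope for the last
    beat of a record, or P-derived values when no P wave was delineated).
    """

    rr: float = float("nan")
    pr: float = float("nan")
    qt: float = float("nan")
    p_span: float = float("nan")
    qrs_span: float = float("nan")
    t_span: float = float("nan")
    baseline: float = float("nan")
    p_amp: float = float("nan")
    r_amp: float = float("nan")
    t_amp: float = float("nan")
    slopes: dict[str, float] = field(default_factory=dict)
    t_type: TWaveType = TWaveType.NORMAL

    def __post_init__(self) -> None:
        for name in SLOPE_NAMES:
            self.slopes.setdefault(name, float("nan"))

    def as_row(self) -> dict[str, object]:
        """Flatten to the beat-table column schema."""
        row: dict[str, object] = {
            "RR": self.rr, "PR": self.pr, "QT": self.qt,
            "Pspan": self.p_span, "QRSspan": self.qrs_span, "Tspan": self.t_span,
            "P_amp": self.p_amp, "R_amp": self.r_amp, "T_amp": self.t_amp,
        }
        row.update({name: self.slopes.get(name, float("nan")) for name in SLOPE_NAMES})
        row["T_type"] = self.t_type.value
        return row


@dataclass
class SubjectRecord:
    """One subject: id, binary label, and delineated records.

    ``records`` maps record id -> list of beats; the signal itself is not
    retained once measurements are taken.
    """

    subject_id: str
    label: str  # "healthy" | "disease"
    records: dict[str, list[FiducialBeat]] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("healthy", "disease"):
            raise ValidationError(f"label must be 'healthy' or 'disease', got {self.label!r}")
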