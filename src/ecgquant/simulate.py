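"""Synthetic cohorts of delineated heartbeats with known ground truth.

Two generators live here:

* :func:`simulate_beat_table` draws per-beat measurement tables for a
  two-group cohort.  Time spans follow the power law ``span = beta * RR**alpha
  * exp(eps)`` so that the RR-correction stage has a recoverable ground truth.
  The disease group mixes a majority of normal beats with a minority of
  "abnormal" beats (location shift + variance inflation), producing the
  heavy-tailed / multimodal per-subject distributions that quantile features
  are designed to capture, while healthy subjects stay unimodal and
  light-tailed.

* :func:`simulate_waveform` renders a single piecewise-linear beat whose
  segment slopes, baseline-referenced amplitudes, and fiducial spans are known
  exactly, as a fixture for the measurement stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AMP_COLUMNS,
    SLOPE_NAMES,
    FiducialBeat,
    SubjectRecord,
    T_TYPES,
    TWaveType,
    ValidationError,
)

#: Variables that may carry an RR power-law dependence.
RR_DEPENDENT_SPANS: tuple[str, ...] = ("PR", "QT", "Pspan", "Tspan", "QRSspan")

#: Physiological floor for the RR interval (s); draws below it are rejected.
RR_LOWER_BOUND = 0.3

#: Abnormal mixture component inflates variance by this factor (sd doubles).
ABNORMAL_VARIANCE_INFLATION = 4.0

# Noise floors so variables whose mean is ~0 (e.g. the PR-segment slope)
# still receive jitter: sd = noise_cv * max(|mean|, floor).
_AMP_NOISE_FLOOR = 0.05   # mV
_SLOPE_NOISE_FLOOR = 2.0  # mV/s


def _default_span_betas() -> dict[str, float]:
    return {"PR": 0.16, "QT": 0.40, "Pspan": 0.10, "QRSspan": 0.09, "Tspan": 0.18}


def _default_span_alphas() -> dict[str, float]:
    return {"PR": 0.2, "QT": 0.5, "Pspan": 0.1, "QRSspan": 0.0, "Tspan": 0.5}


def _default_amp_means() -> dict[str, float]:
    return {"P_amp": 0.15, "R_amp": 1.2, "T_amp": 0.3}


def _default_slope_means() -> dict[str, float]:
    return {
        "Up-P-slo": 3.0, "Down-P-slo": -3.0, "PR-slo": 0.0,
        "Up-R-slo": 60.0, "Down-R-slo": -80.0, "ST-slo": 0.5,
        "Up-T-slo": 3.0, "Down-T-slo": -4.0, "TP-slo": 0.0,
    }


@dataclass
class GroupSpec:
    """Generative law for one diagnostic group.

    Time spans (s): ``beta * RR**alpha * exp(eps)``, ``eps ~ N(0, noise_cv)``
    (multiplicative lognormal noise keeps spans positive and matches the
    ratio form of the RR corrections; an additive error would not).
    Amplitudes (mV) and slopes (mV/s): ``mean + N(0, sd)`` with
    ``sd = noise_cv * max(|mean|, floor)``.

    With probability ``abnormal_fraction`` a beat is drawn from the abnormal
    component: ``abnormal_shift`` is added to the named variables and the
    noise variance is inflated fourfold, yielding heavy tails and mixtures.
    """

    label: str
    n_subjects: int = 20
    beats_per_subject: int = 200
    rr_mean: float = 1.0
    rr_sd: float = 0.1
    span_betas: dict[str, float] = field(default_factory=_default_span_betas)
    span_alphas: dict[str, float] = field(default_factory=_default_span_alphas)
    amp_means: dict[str, float] = field(default_factory=_default_amp_means)
    slope_means: dict[str, float] = field(default_factory=_default_slope_means)
    noise_cv: float = 0.05
    abnormal_fraction: float = 0.0
    abnormal_shift: dict[str, float] = field(default_factory=dict)
    ttype_probs: tuple[float, ...] = (0.90, 0.02, 0.02, 0.02, 0.02, 0.02)
    seed: int = 0

    def validate(self) -> None:
        if self.label not in ("healthy", "disease"):
            raise ValidationError(f"label must be healthy|disease, got {self.label!r}")
        if self.n_subjects <= 0 or self.beats_per_subject <= 0:
            raise ValidationError("n_subjects and beats_per_subject must be positive")
        if self.rr_mean <= 0:
            raise ValidationError("rr_mean must be positive")
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValidationError("abnormal_fraction must lie in [0, 1]")
        probs = np.asarray(self.ttype_probs, dtype=float)
        if probs.shape != (6,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("ttype_probs must be 6 nonnegative entries summing to 1")
        extra = set(self.span_alphas) - set(RR_DEPENDENT_SPANS)
        if extra:
            raise ValidationError(f"unknown span variables in span_alphas: {sorted(extra)}")


def healthy_default(**overrides) -> GroupSpec:
    """Reference healthy group: unimodal, light-tailed, mostly normal T waves."""
    return replace(GroupSpec(label="healthy"), **overrides)


def disease_default(**overrides) -> GroupSpec:
    """Reference disease group.

    Most beats follow the same law as healthy beats; a 15% minority carries
    shifted intervals, flattened/inverted T waves and steeper repolarization
    slopes, so per-subject distributions of PR, QT and the T slopes become
    heavy-tailed or bimodal while their means move only slightly.
    """
    spec = GroupSpec(
        label="disease",
        rr_mean=0.9,
        rr_sd=0.15,
        noise_cv=0.08,
        abnormal_fraction=0.15,
        abnormal_shift={
            "QT": 0.08, "PR": 0.04, "Tspan": 0.05,
            "T_amp": -0.4, "R_amp": -0.5,
            "Up-T-slo": -5.0, "Down-T-slo": 6.0,
        },
        ttype_probs=(0.50, 0.15, 0.10, 0.10, 0.08, 0.07),
    )
    return replace(spec, **overrides)


@dataclass
class SyntheticCohort:
    """A generated two-group cohort: the per-beat table plus its provenance."""

    beats: pd.DataFrame
    subjects: list[SubjectRecord]
    truth: tuple[GroupSpec, GroupSpec]
    seed: int


def _truncated_normal_rr(rng: np.random.Generator, mean: float, sd: float,
                         size: int) -> np.ndarray:
    if sd <= 0:
        return np.full(size, mean)
    a = (RR_LOWER_BOUND - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _simulate_group(spec: GroupSpec, rng: np.random.Generator,
                    id_prefix: str) -> tuple[pd.DataFrame, list[SubjectRecord]]:
    frames: list[pd.DataFrame] = []
    subjects: list[SubjectRecord] = []
    sd_scale = math.sqrt(ABNORMAL_VARIANCE_INFLATION)
    for i in range(spec.n_subjects):
        n = spec.beats_per_subject
        subject_id = f"{id_prefix}{i:03d}"
        rr = _truncated_normal_rr(rng, spec.rr_mean, spec.rr_sd, n)
        abnormal = rng.random(n) < spec.abnormal_fraction
        noise_sd = np.where(abnormal, spec.noise_cv * sd_scale, spec.noise_cv)

        cols: dict[str, np.ndarray] = {"RR": rr}
        for var, beta in spec.span_betas.items():
            alpha = spec.span_alphas.get(var, 0.0)
            eps = rng.normal(0.0, 1.0, n) * noise_sd
            values = beta * rr ** alpha * np.exp(eps)
            values = values + abnormal * spec.abnormal_shift.get(var, 0.0)
            cols[var] = values
        for var, mean in {**spec.amp_means, **spec.slope_means}.items():
            floor = _AMP_NOISE_FLOOR if var in AMP_COLUMNS else _SLOPE_NOISE_FLOOR
            base_sd = spec.noise_cv * max(abs(mean), floor)
            values = mean + rng.normal(0.0, 1.0, n) * base_sd * np.where(abnormal, sd_scale, 1.0)
            values = values + abnormal * spec.abnormal_shift.get(var, 0.0)
            cols[var] = values

        ttype_idx = rng.choice(6, size=n, p=np.asarray(spec.ttype_probs, dtype=float))
        frame = pd.DataFrame(cols)
        frame.insert(0, "subject_id", subject_id)
        frame.insert(1, "label", spec.label)
        frame.insert(2, "beat_index", np.arange(n))
        frame["T_type"] = [T_TYPES[k].value for k in ttype_idx]
        frames.append(frame)
        subjects.append(SubjectRecord(subject_id=subject_id, label=spec.label))
    return pd.concat(frames, ignore_index=True), subjects


def simulate_beat_table(healthy: GroupSpec, disease: GroupSpec,
                        seed: int = 0) -> SyntheticCohort:
    """Draw a two-group cohort of per-beat measurements.

    Fully reproducible from ``seed``; the per-group seeds inside the specs
    are folded into the stream so distinct specs give distinct draws.
    """
    healthy.validate()
    disease.validate()
    ss = np.random.SeedSequence([seed, healthy.seed, disease.seed])
    rng_h, rng_d = (np.random.default_rng(s) for s in ss.spawn(2))
    beats_h, subj_h = _simulate_group(healthy, rng_h, "H")
    beats_d, subj_d = _simulate_group(disease, rng_d, "D")
    beats = pd.concat([beats_h, beats_d], ignore_index=True)
    return SyntheticCohort(beats=beats, subjects=subj_h + subj_d,
                           truth=(healthy, disease), seed=seed)


# ---------------------------------------------------------------------------
# Piecewise-linear waveform fixtures
# ---------------------------------------------------------------------------

@dataclass
class BeatShape:
    """Ground truth for one piecewise-linear beat.

    The beat starts at P onset (time 0) and occupies one RR period.  Each
    wave is a triangle rising linearly from the baseline to its signed peak
    amplitude and back; connecting segments (PR, ST, TP) sit on the constant
    baseline, so their slopes are exactly zero.  ``*_rise`` is the fraction
    of the wave span spent rising.
    """

    rr: float = 1.0          # s, R-peak to R-peak (= beat period here)
    pr: float = 0.16         # s, P onset -> QRS onset
    qt: float = 0.40         # s, QRS onset -> T offset
    p_span: float = 0.10
    qrs_span: float = 0.08
    t_span: float = 0.16
    baseline: float = 0.0    # mV
    p_amp: float = 0.15      # mV relative to baseline, signed
    r_amp: float = 1.2
    t_amp: float = 0.3
    p_rise: float = 0.5
    qrs_rise: float = 0.5
    t_rise: float = 0.5
    t_type: TWaveType = TWaveType.NORMAL

    def validate(self) -> None:
        spans = {"p_span": self.p_span, "qrs_span": self.qrs_span,
                 "t_span": self.t_span, "pr": self.pr, "qt": self.qt}
        for name, value in spans.items():
            if value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.p_span > self.pr:
            raise ValidationError("P wave overlaps QRS onset (p_span > pr)")
        if self.qrs_span + self.t_span > self.qt:
            raise ValidationError("QRS and T waves overlap within the QT interval")
        if self.pr + self.qt >= self.rr:
            raise ValidationError("beat spans exceed the RR interval")

    def fiducials(self, fs: float) -> FiducialBeat:
        """Fiducial sample indices on the grid of ``fs`` (P onset at 0)."""
        r = lambda t: int(round(t * fs))
        t_on_time = self.pr + self.qt - self.t_span
        return FiducialBeat(
            p_on=0,
            p_peak=r(self.p_rise * self.p_span),
            p_off=r(self.p_span),
            qrs_on=r(self.pr),
            r_peak=r(self.pr + self.qrs_rise * self.qrs_span),
            qrs_off=r(self.pr + self.qrs_span),
            t_on=r(t_on_time),
            t_peak=r(t_on_time + self.t_rise * self.t_span),
            t_off=r(self.pr + self.qt),
            t_type=self.t_type,
            fs=fs,
        )

    def expected_slopes(self, fs: float) -> dict[str, float]:
        """Segment slopes implied by the grid-snapped shape (mV/s).

        Up/Down slopes are amplitude over (rounded) rise/fall time; PR, ST
        and TP segments lie on the baseline, slope 0.  TP assumes an
        identical following beat.
        """
        f = self.fiducials(fs)
        def ramp(amp: float, a: int, b: int) -> float:
            return amp * fs / (b - a) if b > a else float("nan")
        return {
            "Up-P-slo": ramp(self.p_amp, f.p_on, f.p_peak),
            "Down-P-slo": ramp(-self.p_amp, f.p_peak, f.p_off),
            "PR-slo": 0.0,
            "Up-R-slo": ramp(self.r_amp, f.qrs_on, f.r_peak),
            "Down-R-slo": ramp(-self.r_amp, f.r_peak, f.qrs_off),
            "ST-slo": 0.0,
            "Up-T-slo": ramp(self.t_amp, f.t_on, f.t_peak),
            "Down-T-slo": ramp(-self.t_amp, f.t_peak, f.t_off),
            "TP-slo": 0.0,
        }


def simulate_waveform(shape: BeatShape, fs: float = 1000.0
                      ) -> tuple[np.ndarray, FiducialBeat]:
    """Render one beat as a sampled mV trace over one RR period.

    Returns the signal (``round(rr*fs)`` samples) and the beat's fiducials.
    Because every breakpoint lands on an integer sample, segment slopes and
    amplitudes are recovered exactly by least squares downstream.
    """
    if fs < 250:
        raise ValidationError(f"fs must be >= 250 Hz, got {fs}")
    shape.validate()
    f = shape.fiducials(fs)
    n = int(round(shape.rr * fs))
    base = shape.baseline
    xp = [f.p_on, f.p_peak, f.p_off, f.qrs_on, f.r_peak, f.qrs_off,
          f.t_on, f.t_peak, f.t_off, n]
    fp = [base, base + shape.p_amp, base, base, base + shape.r_amp, base,
          base, base + shape.t_amp, base, base]
    signal = np.interp(np.arange(n), xp, fp)
    return signal, f


def simulate_record(shape: BeatShape, n_beats: int, fs: float = 1000.0
                    ) -> tuple[np.ndarray, list[FiducialBeat]]:
    """Tile ``n_beats`` identical beats into one record with shifted fiducials."""
    if n_beats <= 0:
        raise ValidationError("n_beats must be positive")
    signal, first = simulate_waveform(shape, fs)
    period = len(signal)
    beats = []
    for k in range(n_beats):
        shifted = FiducialBeat(
            **{name: getattr(first, name) + k * period
               for name in ("p_on", "p_peak", "p_off", "qrs_on", "r_peak",
                            "qrs_off", "t_on", "t_peak", "t_off")},
            t_type=first.t_type, fs=fs)
        beats.append(shifted)
    return np.tile(signal, n_beats), beats
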