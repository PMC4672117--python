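"""Measurement correctness: hand-computed examples, oracle comparisons, and
exact recovery on piecewise-linear fixtures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgquant import measurements as meas
from ecgquant import simulate as sim
from ecgquant.types import SLOPE_NAMES, FiducialBeat


def _beats_pair(fs=1000):
    b0 = FiducialBeat(p_on=0, p_peak=25, p_off=50, qrs_on=100, r_peak=140,
                      qrs_off=180, t_on=400, t_peak=480, t_off=560, fs=fs)
    b1 = FiducialBeat(p_on=1000, p_peak=1025, p_off=1050, qrs_on=1100,
                      r_peak=1140, qrs_off=1180, t_on=1400, t_peak=1480,
                      t_off=1560, fs=fs)
    return b0, b1


# --- time spans ------------------------------------------------------------

def test_time_spans_direct_division():
    b0, b1 = _beats_pair()
    spans = meas.time_spans(b0, b1)
    assert spans["RR"] == pytest.approx(1.0)
    assert spans["PR"] == pytest.approx(0.100)
    assert spans["QT"] == pytest.approx(0.460)
    assert spans["QRSspan"] == pytest.approx(0.080)
    assert spans["Pspan"] == pytest.approx(0.050)
    assert spans["Tspan"] == pytest.approx(0.160)


def test_missing_p_wave_leaves_other_spans():
    b0, b1 = _beats_pair()
    b0.p_on = b0.p_peak = b0.p_off = None
    spans = meas.time_spans(b0, b1)
    assert math.isnan(spans["PR"]) and math.isnan(spans["Pspan"])
    assert spans["QT"] == pytest.approx(0.460)


def test_last_beat_has_no_rr():
    b0, _ = _beats_pair()
    assert math.isnan(meas.time_spans(b0, None)["RR"])


# --- baseline --------------------------------------------------------------

def test_baseline_constant_segments():
    b0, b1 = _beats_pair()
    signal = np.full(2000, 0.3)
    assert meas.estimate_baseline(signal, b0, b1) == pytest.approx(0.3)


def test_baseline_pools_samples_not_segment_means():
    """PR two samples at 0.0, ST two at 0.6, TP two at 0.6 -> pooled mean 0.4
    (averaging the three segment means would give the same here only by
    accident of equal sizes; the pooled rule is what is asserted)."""
    b0 = FiducialBeat(p_on=0, p_peak=1, p_off=2, qrs_on=3, r_peak=4, qrs_off=5,
                      t_on=6, t_peak=7, t_off=8, fs=1000)
    b1 = FiducialBeat(p_on=9, p_peak=10, p_off=11, qrs_on=12, r_peak=13,
                      qrs_off=14, t_on=15, t_peak=16, t_off=17, fs=1000)
    signal = np.zeros(20)
    signal[2:4] = 0.0    # PR: samples 2..3
    signal[5:7] = 0.6    # ST: samples 5..6
    signal[8:10] = 0.6   # TP: samples 8..9
    assert meas.estimate_baseline(signal, b0, b1) == pytest.approx(0.4)


def test_baseline_without_next_beat_uses_remaining_segments():
    b0, _ = _beats_pair()
    signal = np.full(600, 0.1)
    assert meas.estimate_baseline(signal, b0, None) == pytest.approx(0.1)


def test_baseline_absent_when_all_segments_missing():
    beat = FiducialBeat(qrs_on=10, r_peak=20, qrs_off=30, fs=1000)
    assert math.isnan(meas.estimate_baseline(np.zeros(100), beat, None))


# --- amplitudes ------------------------------------------------------------

def test_amplitude_positive_excursion():
    signal = np.linspace(0.1, 0.5, 11)
    assert meas.wave_amplitude(signal, 0, 10, 0.1) == pytest.approx(0.4)


def test_amplitude_negative_excursion_wins():
    signal = np.array([0.0, 0.2, -0.6, 0.1])
    assert meas.wave_amplitude(signal, 0, 3, 0.0) == pytest.approx(-0.6)


def test_amplitude_zero_on_flat_window():
    signal = np.full(10, 0.25)
    assert meas.wave_amplitude(signal, 0, 9, 0.25) == 0.0


def test_amplitude_tie_breaks_positive():
    signal = np.array([0.4, -0.4])
    assert meas.wave_amplitude(signal, 0, 1, 0.0) == pytest.approx(0.4)


@given(st.lists(st.floats(-2, 2), min_size=2, max_size=40), st.floats(-1, 1))
@settings(max_examples=100, deadline=None)
def test_amplitude_antisymmetric_about_baseline(values, baseline):
    """Negating the signal about the baseline negates the amplitude (up to
    the positive tie-break)."""
    signal = np.asarray(values)
    a = meas.wave_amplitude(signal, 0, len(signal) - 1, baseline)
    b = meas.wave_amplitude(2 * baseline - signal, 0, len(signal) - 1, baseline)
    assert abs(a + b) < 1e-9 or (a == b and a >= 0)  # tie -> both positive


# --- slopes ----------------------------------------------------------------

def test_slope_exact_linear():
    t = np.linspace(0, 1, 50)
    assert meas.segment_slope(t, 2 * t) == pytest.approx(2.0, abs=1e-12)


def test_slope_two_points():
    assert meas.segment_slope([0.0, 0.1], [0.0, 0.5]) == pytest.approx(5.0)


def test_slope_flat():
    assert meas.segment_slope(np.arange(5) / 10, np.full(5, 0.3)) == pytest.approx(0.0, abs=1e-12)


def test_slope_absent_below_two_points():
    assert math.isnan(meas.segment_slope([0.1], [0.5]))
    assert math.isnan(meas.segment_slope([0.1, 0.1], [0.5, 0.7]))


def test_slope_matches_normal_equations_oracle(rng):
    """OLS slope agrees with the explicit normal-equations solution to 1e-9."""
    for _ in range(50):
        n = rng.integers(2, 200)
        t = np.sort(rng.uniform(0, 1, n))
        if np.ptp(t) == 0:
            continue
        v = rng.normal(0, 1, n)
        A = np.stack([t, np.ones(n)], axis=1)
        oracle = np.linalg.solve(A.T @ A, A.T @ v)[0]
        assert meas.segment_slope(t, v) == pytest.approx(oracle, abs=1e-9)


# --- full beat on waveform fixtures ----------------------------------------

def _random_shape(rng):
    return sim.BeatShape(
        rr=rng.uniform(0.7, 1.3),
        pr=rng.uniform(0.12, 0.22),
        qt=rng.uniform(0.32, 0.46),
        p_span=rng.uniform(0.06, 0.11),
        qrs_span=rng.uniform(0.06, 0.1),
        t_span=rng.uniform(0.12, 0.18),
        baseline=rng.uniform(-0.2, 0.2),
        p_amp=rng.uniform(-0.3, 0.3),
        r_amp=rng.uniform(-1.5, 1.5),
        t_amp=rng.uniform(-0.5, 0.5),
        p_rise=rng.uniform(0.3, 0.7),
        qrs_rise=rng.uniform(0.3, 0.7),
        t_rise=rng.uniform(0.3, 0.7),
    )


def test_measure_beat_recovers_ground_truth(rng):
    """On 100 random piecewise-linear fixtures every measurement matches the
    snapped ground truth to 1e-6."""
    fs = 1000.0
    for _ in range(100):
        shape = _random_shape(rng)
        signal, beats = sim.simulate_record(shape, 2, fs=fs)
        f = beats[0]
        bm = meas.measure_beat(signal, f, beats[1])
        assert bm.rr == pytest.approx(shape.rr, abs=1.5 / fs)
        assert bm.pr == pytest.approx((f.qrs_on - f.p_on) / fs, abs=1e-9)
        assert bm.qt == pytest.approx((f.t_off - f.qrs_on) / fs, abs=1e-9)
        assert bm.baseline == pytest.approx(shape.baseline, abs=1e-9)
        assert bm.p_amp == pytest.approx(shape.p_amp, abs=1e-6)
        assert bm.r_amp == pytest.approx(shape.r_amp, abs=1e-6)
        assert bm.t_amp == pytest.approx(shape.t_amp, abs=1e-6)
        for name, truth in shape.expected_slopes(fs).items():
            assert bm.slopes[name] == pytest.approx(truth, abs=1e-6), name


def test_measure_beat_emits_exactly_nine_slopes(default_shape):
    signal, beats = sim.simulate_record(default_shape, 2)
    bm = meas.measure_beat(signal, beats[0], beats[1])
    assert set(bm.slopes) == set(SLOPE_NAMES)
    assert len(bm.slopes) == 9


def test_last_beat_lacks_rr_and_tp(default_shape):
    signal, beats = sim.simulate_record(default_shape, 2)
    bm = meas.measure_beat(signal, beats[1], None)
    assert math.isnan(bm.rr)
    assert math.isnan(bm.slopes["TP-slo"])


def test_measure_record_table_shape(default_shape):
    signal, beats = sim.simulate_record(default_shape, 5)
    table = meas.measure_record(signal, beats, "S1", "healthy")
    assert len(table) == 5
    assert table["RR"].notna().sum() == 4
    assert (table["subject_id"] == "S1").all()
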