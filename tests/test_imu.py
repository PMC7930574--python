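"""Landmark extraction from throw IMU traces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from judoperf.errors import LandmarkNotFoundError, NoOnsetError
from judoperf.imu import (
    DetectorConfig,
    ImuTrace,
    TechniqueLandmarks,
    cronbach_alpha,
    detect_accel_peaks,
    detect_horizontal_position,
    detect_onset,
    extract_landmarks,
    resultant_magnitude,
    select_technique_repetition,
)
from judoperf.synthetic import ThrowPhaseParams, simulate_imu_repetition

DT = 0.001


@pytest.mark.parametrize(
    "xyz, expected",
    [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0), ((1.0, 2.0, 2.0), 3.0)],
)
def test_resultant_magnitude_known_triples(xyz, expected):
    x, y, z = ([v] for v in xyz)
    assert resultant_magnitude(x, y, z)[0] == pytest.approx(expected)


def test_resultant_magnitude_rejects_length_mismatch():
    with pytest.raises(ValueError):
        resultant_magnitude([1.0, 2.0], [1.0], [1.0, 2.0])


class TestOnset:
    def test_step_signal_detected_at_step(self):
        g = np.zeros(3000)
        g[1200:] = 1.0
        assert detect_onset(g, DT) == pytest.approx(1200.0)

    def test_subsustain_transient_is_ignored(self):
        g = np.zeros(3000)
        g[1200:1230] = 1.0  # 30 ms < the 50 ms sustain rule
        with pytest.raises(NoOnsetError):
            detect_onset(g, DT)

    def test_flat_signal_has_no_onset(self):
        with pytest.raises(NoOnsetError):
            detect_onset(np.zeros(2000), DT)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_onset(np.zeros(100), DT)


class TestAccelPeaks:
    def test_reference_bumps_recovered(self, noiseless_throw):
        trace, truth = noiseless_throw
        onset = detect_onset(trace.gyro_y, trace.dt)
        peaks = detect_accel_peaks(trace.accel_t, trace.dt, onset)
        times = [p[0] for p in peaks]
        mags = [p[1] for p in peaks]
        for t_obs, t_true in zip(times, (399.0, 898.0, 1172.0)):
            assert t_obs == pytest.approx(t_true, abs=2.0)
        for m_obs, m_true in zip(mags, (6.4, 3.0, 26.4)):
            assert m_obs == pytest.approx(m_true, rel=0.01)

    def test_two_bumps_reports_count(self):
        t = np.arange(0, 2.0, DT) * 1000.0
        a = 1.0 + 5.0 * np.exp(-0.5 * ((t - 700) / 40) ** 2) \
                + 20.0 * np.exp(-0.5 * ((t - 1400) / 40) ** 2)
        with pytest.raises(LandmarkNotFoundError) as err:
            detect_accel_peaks(a, DT, 300.0)
        assert err.value.found == 2

    def test_noisy_bumps_within_5ms(self, reference_params):
        params = reference_params.replace(noise_sd_accel=0.05)
        trace, truth = simulate_imu_repetition(params, seed=123)
        peaks = detect_accel_peaks(trace.accel_t, trace.dt, truth.onset_time)
        for (t_obs, _), t_true in zip(peaks, (399.0, 898.0, 1172.0)):
            assert t_obs == pytest.approx(t_true, abs=5.0)


class TestHorizontalPosition:
    def test_logistic_midpoint_recovered(self, noiseless_throw):
        trace, truth = noiseless_throw
        thor = detect_horizontal_position(trace.gyro_y, trace.dt, truth.onset_time)
        assert thor == pytest.approx(818.0, abs=2.0)

    def test_linear_ramp_has_no_inflection(self):
        g = np.concatenate([np.zeros(500), np.linspace(0, 5, 1500)])
        with pytest.raises(LandmarkNotFoundError):
            detect_horizontal_position(g, DT, 500.0)

    def test_gaussian_cdf_inflects_at_mean(self):
        from scipy.stats import norm

        t = np.arange(0, 2.5, DT) * 1000.0
        mu = 1300.0
        g = norm.cdf(t, loc=mu, scale=120.0)
        thor = detect_horizontal_position(g, DT, 400.0)
        assert thor == pytest.approx(mu - 400.0, abs=2.0)


class TestExtractLandmarks:
    def test_reference_roundtrip_all_six(self, noiseless_throw):
        trace, truth = noiseless_throw
        lm = extract_landmarks(trace)
        assert lm.tpeak1 == pytest.approx(truth.tpeak1, abs=2.0)
        assert lm.tpeak2 == pytest.approx(truth.tpeak2, abs=2.0)
        assert lm.tpeak3 == pytest.approx(truth.tpeak3, abs=2.0)
        assert lm.thor == pytest.approx(truth.thor, abs=2.0)
        assert lm.max1 == pytest.approx(truth.max1, rel=0.01)
        assert lm.max2 == pytest.approx(truth.max2, rel=0.01)
        assert lm.max3 == pytest.approx(truth.max3, rel=0.01)
        # ordering invariants
        assert 0 < lm.tpeak1 < lm.tpeak2 < lm.tpeak3
        assert 0 < lm.thor < lm.tpeak3

    def test_still_trace_raises_no_onset(self):
        n = 3000
        accel = np.column_stack([np.ones(n), np.zeros(n), np.zeros(n)])
        gyro = np.zeros((n, 3))
        with pytest.raises(NoOnsetError):
            extract_landmarks(ImuTrace(dt=DT, accel=accel, gyro=gyro))

    def test_time_shift_equivariance(self, reference_params):
        trace, truth = simulate_imu_repetition(reference_params)
        shifted, _ = simulate_imu_repetition(reference_params.replace(onset_time=550.0))
        lm0 = extract_landmarks(trace)
        lm1 = extract_landmarks(shifted)
        assert lm1.onset_time - lm0.onset_time == pytest.approx(250.0, abs=1.5)
        for attr in ("tpeak1", "tpeak2", "tpeak3", "thor"):
            assert getattr(lm1, attr) == pytest.approx(getattr(lm0, attr), abs=1.5)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_amplitude_scaling_scales_magnitudes_only(self, noiseless_throw, c):
        trace, truth = noiseless_throw
        scaled = ImuTrace(dt=trace.dt, accel=trace.accel * c, gyro=trace.gyro)
        lm0 = extract_landmarks(trace)
        lm1 = extract_landmarks(scaled)
        for attr in ("tpeak1", "tpeak2", "tpeak3", "thor", "onset_time"):
            assert getattr(lm1, attr) == pytest.approx(getattr(lm0, attr), abs=1.0)
        for attr in ("max1", "max2", "max3"):
            assert getattr(lm1, attr) == pytest.approx(c * getattr(lm0, attr), rel=1e-6)


def _lm(thor):
    return TechniqueLandmarks(onset_time=300.0, tpeak1=400.0, tpeak2=900.0,
                              tpeak3=1170.0, thor=thor, max1=6.0, max2=3.0, max3=26.0)


class TestRepetitionSelection:
    def test_worst_rating_excluded_then_quickest_thor(self):
        reps = [(_lm(850.0), 7), (_lm(800.0), 5), (_lm(900.0), 8)]
        # worst rating (5) is excluded even though it has the quickest Thor
        assert select_technique_repetition(reps) == 0

    def test_rating_tie_excludes_slowest_thor(self):
        reps = [(_lm(850.0), 7), (_lm(800.0), 7), (_lm(900.0), 7)]
        assert select_technique_repetition(reps) == 1

    def test_single_repetition_rejected(self):
        with pytest.raises(ValueError):
            select_technique_repetition([(_lm(850.0), 7)])


class TestCronbachAlpha:
    def test_identical_raters_give_one(self):
        assert cronbach_alpha([[1, 2, 3], [1, 2, 3]]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # rater variances 1 and 7/3; total-score variance 19/3
        assert cronbach_alpha([[1, 2, 3], [1, 2, 4]]) == pytest.approx(18 / 19)

    def test_constant_ratings_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha([[2, 2, 2], [2, 2, 2]])


@settings(max_examples=25, deadline=None)
@given(
    shift=st.floats(min_value=-0.5, max_value=0.5),
    scale=st.floats(min_value=0.5, max_value=3.0),
)
def test_resultant_magnitude_scales_homogeneously(shift, scale):
    rng = np.random.default_rng(7)
    x, y, z = rng.normal(size=(3, 50)) + shift
    base = resultant_magnitude(x, y, z)
    scaled = resultant_magnitude(scale * x, scale * y, scale * z)
    assert np.allclose(scaled, scale * base)
    assert (base >= 0).all()
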