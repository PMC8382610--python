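"""Thresholds, peak verification, contraction and sustained-activation detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usmuscle import (
    ActivationThreshold,
    ContractionDetector,
    SampledSignal,
    SustainedActivationDetector,
    baseline_threshold,
    detect_contraction,
    detect_sustained_activation,
    emg_preprocess,
    torque_preprocess,
    verify_peak,
)
from usmuscle.detection import moving_average


def thr(value):
    return ActivationThreshold(baseline_mean=value, baseline_sd=0.0, multiplier=3.0)


class TestBaselineThreshold:
    def test_constant_baseline_zero_sd(self):
        t = baseline_threshold([0.2] * 100, multiplier=3.0)
        assert t.value == pytest.approx(0.2)
        assert t.baseline_sd == pytest.approx(0.0, abs=1e-12)

    def test_alternating_two_point_closed_form(self):
        # mean 0.5; sample SD of k copies each of {0,1} -> sqrt(n/(n-1))/2
        n = 1000
        baseline = np.tile([0.0, 1.0], n // 2)
        t = baseline_threshold(baseline, multiplier=2.0)
        sd = np.sqrt(n / (n - 1)) / 2
        assert t.value == pytest.approx(0.5 + 2 * sd)

    def test_uses_sample_sd(self):
        t = baseline_threshold([0.0, 1.0], multiplier=1.0)
        assert t.baseline_sd == pytest.approx(np.std([0, 1], ddof=1))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            baseline_threshold([0.1], multiplier=3.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        values=st.lists(st.floats(0, 1), min_size=2, max_size=50),
        m1=st.floats(0.5, 3),
        m2=st.floats(0.5, 3),
    )
    def test_monotone_in_multiplier(self, values, m1, m2):
        lo, hi = sorted([m1, m2])
        t_lo = baseline_threshold(values, lo)
        t_hi = baseline_threshold(values, hi)
        assert t_hi.value >= t_lo.value
        if t_lo.baseline_sd > 0 and hi > lo:
            assert t_hi.value > t_lo.value


class TestVerifyPeak:
    def test_seven_of_ten_passes(self, flat_series):
        values = [0.1] * 7 + [0.01] * 3 + [0.01] * 5
        npd = flat_series(values)
        assert verify_peak(npd, 0, thr(0.05))

    def test_six_of_ten_fails(self, flat_series):
        values = [0.1] * 6 + [0.01] * 4 + [0.01] * 5
        npd = flat_series(values)
        assert not verify_peak(npd, 0, thr(0.05))

    def test_all_below_fails(self, flat_series):
        npd = flat_series([0.01] * 20)
        assert not verify_peak(npd, 3, thr(0.05))

    def test_first_sample_must_exceed(self, flat_series):
        values = [0.01] + [0.1] * 9 + [0.1] * 5
        npd = flat_series(values)
        assert not verify_peak(npd, 0, thr(0.05))

    def test_truncated_window_uses_remaining(self, flat_series):
        # 3 samples left, ceil(0.7*3)=3 must all exceed
        npd = flat_series([0.01] * 10 + [0.1, 0.1, 0.1])
        assert verify_peak(npd, 10, thr(0.05))
        npd2 = flat_series([0.01] * 10 + [0.1, 0.01, 0.1])
        assert not verify_peak(npd2, 10, thr(0.05))

    def test_window_scales_with_fps(self):
        from usmuscle import NPDSeries

        # at 80 fps a 0.25 s window is 20 samples; 13 above (need 14) fails
        values = [0.1] * 13 + [0.01] * 7 + [0.01] * 5
        npd = NPDSeries(values=np.array(values, dtype=float), fps=80.0)
        assert not verify_peak(npd, 0, thr(0.05))
        values[13] = 0.1  # 14 of 20
        npd = NPDSeries(values=np.array(values, dtype=float), fps=80.0)
        assert verify_peak(npd, 0, thr(0.05))


def two_peak_series():
    """Baseline, contraction transient, tensed quiet, relaxation transient."""
    return np.array(
        [0.01] * 40 + [0.2] * 12 + [0.005] * 40 + [0.2] * 12 + [0.01] * 20
    )


class TestDetectContraction:
    def test_pure_baseline_returns_none(self, flat_series):
        npd = flat_series([0.01] * 200)
        assert detect_contraction(npd, thr(0.05), 0.5, 4.0) is None

    def test_two_peak_hand_trace(self, flat_series):
        npd = flat_series(two_peak_series())
        ev = detect_contraction(npd, thr(0.05), 0.5)
        assert ev is not None and ev.complete
        assert ev.onset_frame == 40
        assert ev.offset_frame == 92
        assert ev.peak_npd == pytest.approx(0.2)
        assert ev.onset_time_s == pytest.approx((40 + 1) / 40)

    def test_truncated_before_second_peak(self, flat_series):
        npd = flat_series(two_peak_series()[:80])
        ev = detect_contraction(npd, thr(0.05), 0.5)
        assert ev is not None and not ev.complete
        assert ev.onset_frame == 40
        assert ev.offset_frame is None

    def test_broad_peak_not_split(self, flat_series):
        # dips shorter than the 0.25 s quiet floor must not produce an offset
        values = [0.01] * 40 + [0.2] * 12 + [0.01] * 4 + [0.2] * 12 + [0.01] * 60
        ev = detect_contraction(flat_series(values), thr(0.05), 0.5)
        assert ev is not None and not ev.complete

    def test_ordering_invariant(self, flat_series):
        ev = detect_contraction(flat_series(two_peak_series()), thr(0.05), 0.5)
        assert ev.onset_frame < ev.offset_frame

    def test_empty_window_rejected(self, flat_series):
        npd = flat_series([0.01] * 20)
        with pytest.raises(ValueError, match="search window"):
            detect_contraction(npd, thr(0.05), 2.0, 1.0)

    def test_detector_estimator_per_cue(self, flat_series):
        series = np.concatenate([two_peak_series(), two_peak_series()])
        npd = flat_series(series)
        det = ContractionDetector().fit([0.01] * 50 + [0.011] * 50)
        events = det.predict(npd, cues=[0.5, 3.6])
        assert len(events) == 2
        assert all(e is not None and e.complete for e in events)
        assert events[1].onset_frame == 124 + 40


class TestPreprocessing:
    def test_emg_zero_input(self):
        env = emg_preprocess(SampledSignal(values=np.zeros(4000), fs=1200))
        assert np.all(env.values == 0.0)

    def test_emg_dc_rejected(self):
        env = emg_preprocess(SampledSignal(values=np.ones(6000), fs=1200))
        assert np.abs(env.values[-1000:]).max() < 1e-3

    def test_emg_envelope_nonnegative(self):
        rng = np.random.default_rng(0)
        env = emg_preprocess(SampledSignal(values=rng.normal(0, 1, 5000), fs=1200))
        assert np.all(env.values >= 0.0)

    def test_emg_low_fs_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            emg_preprocess(SampledSignal(values=np.zeros(100), fs=800))

    def test_torque_constant_preserved(self):
        sig = SampledSignal(values=np.full(500, 3.7), fs=1000)
        assert np.allclose(torque_preprocess(sig).values, 3.7)

    def test_torque_impulse_eleven_window(self):
        x = np.zeros(201)
        x[100] = 1.0
        sm = torque_preprocess(SampledSignal(values=x, fs=1000))
        assert sm.values[100] == pytest.approx(1 / 11)

    def test_torque_interior_mean_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 400)
        sm = torque_preprocess(SampledSignal(values=x, fs=1000))
        assert sm.values[5:-5].mean() == pytest.approx(
            moving_average(x, 11)[5:-5].mean(), abs=1e-9
        )

    def test_moving_average_edges_shrink_symmetrically(self):
        x = np.arange(10.0)
        out = moving_average(x, 5)
        assert out[0] == x[0]  # half-width shrinks to 0 at the edge
        assert out[1] == pytest.approx(x[:3].mean())
        assert out[5] == pytest.approx(x[3:8].mean())


class TestSustainedActivation:
    fs = 1000.0

    def make(self, values):
        return SampledSignal(values=np.asarray(values, dtype=float), fs=self.fs)

    def test_always_below_none(self):
        sig = self.make(np.full(3000, 0.1))
        assert detect_sustained_activation(sig, thr(0.5)) is None

    def test_exact_hold_onset_time(self):
        values = np.full(4000, 0.1)
        values[1500:2500] = 1.0  # exactly 1 s above
        sig = self.make(values)
        assert detect_sustained_activation(sig, thr(0.5)) == pytest.approx(1.5)

    def test_short_burst_ignored(self):
        values = np.full(4000, 0.1)
        values[1500:2000] = 1.0  # 0.5 s burst only
        sig = self.make(values)
        assert detect_sustained_activation(sig, thr(0.5)) is None

    def test_estimator_wrapper(self):
        rng = np.random.default_rng(2)
        baseline = rng.normal(0.1, 0.01, 2000)
        values = np.concatenate([baseline, np.full(1500, 1.0)])
        det = SustainedActivationDetector().fit(baseline)
        onset = det.predict(self.make(values))
        assert onset == pytest.approx(2.0, abs=0.01)


def test_gaussian_baseline_false_positive_rate():
    """Mean+3SD exceedance on stationary Gaussian noise stays near the 0.135%
    Gaussian tail and below the 1.5% rest-period bound."""
    rng = np.random.default_rng(7)
    values = rng.normal(0.02, 0.002, 50_000)
    t = baseline_threshold(values, 3.0)
    frac = np.mean(values > t.value)
    assert frac <= 0.015
    assert frac == pytest.approx(0.00135, abs=0.0008)
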