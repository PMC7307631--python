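"""Latency analytics: LED flash detection, two latency measures, utilities."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from pawtrigger import (
    LedTrace,
    MotionScript,
    ReachEvent,
    SessionConfig,
    compare_latency_methods,
    detect_flashes,
    generate_pose_trace,
    ground_truth_latency,
    nyquist_limit,
    px_to_mm,
    render_frames,
    run_trial_from_trace,
    timestamp_latency,
)
from pawtrigger.errors import AlignmentError, CalibrationError, InputError, InsufficientDataError
from pawtrigger.latency import roi_mean_trace
from pawtrigger.synthetic import default_led_roi


def _trace(values, skip=800, dt=10.0, **kw):
    values = np.asarray(values, dtype=float)
    return LedTrace(values, dt * np.arange(len(values)), skip_frames=skip, **kw)


def _alternating(n, lo=49.0, hi=51.0):
    v = np.full(n, lo)
    v[1::2] = hi
    return v


class TestDetectFlashes:
    def test_hand_checked_threshold_crossing(self):
        v = _alternating(1000)
        v[900:914] = 80.0
        trace = _trace(v, baseline_mean=50.0, baseline_sd=1.0)
        assert detect_flashes(trace, k_sd=3.0) == [900]

    def test_flash_before_skip_window_never_reported(self):
        v = _alternating(1000)
        v[700:714] = 80.0
        trace = _trace(v, baseline_mean=50.0, baseline_sd=1.0)
        assert detect_flashes(trace) == []

    def test_flash_spanning_skip_boundary_not_reported(self):
        v = _alternating(1000)
        v[795:806] = 80.0
        trace = _trace(v, baseline_mean=50.0, baseline_sd=1.0)
        assert detect_flashes(trace) == []

    def test_flat_trace_no_onsets_with_warning(self):
        trace = _trace(np.full(900, 50.0))
        with pytest.warns(UserWarning, match="zero-variance"):
            assert detect_flashes(trace) == []

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(0)
        v = 50.0 + rng.normal(0, 1.0, 2000)
        for onset in (900, 1300, 1700):
            v[onset : onset + 14] += 40.0
        onsets1 = detect_flashes(_trace(v.copy()))
        onsets2 = detect_flashes(_trace(v + 123.4))
        assert onsets1 == onsets2 == [900, 1300, 1700]

    def test_sustained_pulse_single_onset_with_rearming(self):
        v = _alternating(1200)
        v[850:900] = 80.0
        v[1000:1050] = 80.0
        trace = _trace(v, baseline_mean=50.0, baseline_sd=1.0)
        assert detect_flashes(trace) == [850, 1000]

    def test_single_frame_noise_spike_debounced(self):
        v = _alternating(1000)
        v[850] = 80.0  # isolated spike: not a pulse
        v[900:914] = 80.0
        trace = _trace(v, baseline_mean=50.0, baseline_sd=1.0)
        assert detect_flashes(trace) == [900]

    def test_trace_shorter_than_skip_rejected(self):
        with pytest.raises(InputError):
            detect_flashes(_trace(np.full(100, 50.0), skip=800))

    def test_noise_up_to_third_of_flash_amplitude(self):
        """Rendered-video recovery: every post-skip flash found exactly once,
        onset within 1 frame, for pixel noise SDs up to amplitude/3."""
        positions = np.full((1000, 8, 2), 0.0)
        positions[:, :4, 0] = (70, 82, 94, 106)
        positions[:, 4:, 0] = (150, 162, 174, 186)
        positions[:, :, 1] = 190.0
        scheduled = [820, 870, 930]
        roi = default_led_roi()
        x, y, w, h = roi
        amp = render_frames(positions[:1], led_schedule=[(0, 1)])[0][
            y : y + h, x : x + w
        ].mean() - 16.0
        for noise_sd in (0.0, amp / 6.0, amp / 3.0):
            frames = render_frames(
                positions,
                led_schedule=[(o, 14) for o in scheduled],
                noise_sd=noise_sd,
                seed=3,
            )
            trace = LedTrace(
                roi_mean_trace(frames, roi),
                10.0 * np.arange(len(frames)),
                roi=roi,
                skip_frames=800,
            )
            trace.fit_baseline(guard_times_ms=[10.0 * o for o in scheduled])
            onsets = detect_flashes(trace)
            assert len(onsets) == len(scheduled)
            assert all(abs(a - b) <= 1 for a, b in zip(onsets, scheduled))


def _run_scripted_trial(processing_delay=0.0, device_latency=0.0, frame_rate=50.0):
    script = MotionScript(
        duration=20.0,
        frame_rate=frame_rate,
        reach_events=tuple(
            ReachEvent(t, "left", 40.0, 0.1) for t in (4.0, 8.0, 12.0, 16.0)
        ),
        baseline_jitter_sd=0.0,
        drop_probability=0.0,
        timestamp_jitter_sd=0.0,
        seed=1,
    )
    trace, _ = generate_pose_trace(script)
    session = SessionConfig(
        buffer_duration=2.0,
        recording_duration=18.0,
        processing_delay_ms=processing_delay,
        input_frame_rate=frame_rate,
    )
    from pawtrigger import MockDevice

    rec = run_trial_from_trace(
        trace, session, device=MockDevice(latency_ms=device_latency)
    )
    return trace, rec


class TestTimestampLatency:
    def test_plain_subtraction(self):
        trace, rec = _run_scripted_trial()
        res = timestamp_latency(rec)
        assert res.n == 4
        assert res.mean == pytest.approx(0.0, abs=1e-9)

    def test_injected_constant_delay_recovered(self):
        _, rec = _run_scripted_trial(processing_delay=30.0)
        res = timestamp_latency(rec)
        assert res.mean == pytest.approx(30.0, abs=1e-9)
        assert res.sd == pytest.approx(0.0, abs=1e-9)

    def test_zero_event_trial_signals_empty(self, short_session_config):
        script = MotionScript(
            duration=20.0, frame_rate=50.0, baseline_jitter_sd=0.0,
            drop_probability=0.0, timestamp_jitter_sd=0.0, seed=2,
        )
        trace, _ = generate_pose_trace(script)
        rec = run_trial_from_trace(trace, short_session_config)
        assert timestamp_latency(rec) is None


class TestGroundTruthLatency:
    def _render_with_lamp_delay(self, trace, rec, lamp_delay_ms, skip=100):
        onsets = [
            int(np.searchsorted(trace.timestamps_ms, e.dispatch_time + lamp_delay_ms))
            for e in rec.events
        ]
        frames = render_frames(
            trace.positions, led_schedule=[(o, 10) for o in onsets]
        )
        roi = default_led_roi()
        led = LedTrace(
            roi_mean_trace(frames, roi), trace.timestamps_ms,
            roi=roi, skip_frames=skip,
        )
        led.fit_baseline(guard_times_ms=[e.frame_time for e in rec.events])
        return detect_flashes(led)

    def test_scripted_lamp_delay_recovered(self):
        trace, rec = _run_scripted_trial(processing_delay=10.0, device_latency=5.0)
        lamp = 35.0
        onsets = self._render_with_lamp_delay(trace, rec, lamp)
        gt = ground_truth_latency(onsets, rec.events, trace.timestamps_ms)
        ts = timestamp_latency(rec)
        frame_period = 1000.0 / trace.frame_rate
        assert gt.n == len(rec.events)
        assert abs(gt.mean - ts.mean - lamp) <= frame_period

    def test_zero_delay_flash_bounded_by_frame_period(self):
        trace, rec = _run_scripted_trial()
        onsets = self._render_with_lamp_delay(trace, rec, 0.0)
        gt = ground_truth_latency(onsets, rec.events, trace.timestamps_ms)
        assert gt.mean <= 1000.0 / trace.frame_rate

    def test_event_without_onset_flagged_unmatched(self):
        trace, rec = _run_scripted_trial()
        onsets = self._render_with_lamp_delay(trace, rec, 0.0)[:-1]
        gt = ground_truth_latency(onsets, rec.events, trace.timestamps_ms)
        assert gt.unmatched == 1

    def test_more_onsets_than_events_is_alignment_error(self):
        trace, rec = _run_scripted_trial()
        onsets = self._render_with_lamp_delay(trace, rec, 0.0) + [900]
        with pytest.raises(AlignmentError):
            ground_truth_latency(onsets, rec.events[:3], trace.timestamps_ms)


class TestCompareLatencyMethods:
    def test_closed_form_t(self):
        pairs = [(2.0, 1.0), (3.0, 1.0), (4.0, 2.0), (2.0, 1.0)]  # diffs 1,2,2,1
        res = compare_latency_methods(pairs)
        assert res.t == pytest.approx(5.196, abs=0.001)
        assert res.df == 3

    def test_identical_pairs_zero_variance(self):
        res = compare_latency_methods([(5.0, 5.0)] * 4)
        assert res.zero_variance
        assert res.mean_difference == 0.0

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_latency_methods([(1.0, 2.0)])

    def test_monte_carlo_size_under_null(self):
        """With 5 truly identical methods the paired t rejects ~5% of the time."""
        rng = np.random.default_rng(0)
        crit = sps.t.ppf(0.975, df=4)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(40.0, 5.0, 5)
            b = a + rng.normal(0.0, 2.0, 5)
            res = compare_latency_methods(list(zip(a, b)))
            rejections += abs(res.t) > crit
        assert abs(rejections / n_rep - 0.05) < 0.02


class TestUtilities:
    @pytest.mark.parametrize(
        "rate, expected", [(65.59, 32.80), (0.0, 0.0), (90.0, 45.0)]
    )
    def test_nyquist_limit(self, rate, expected):
        assert nyquist_limit(rate) == pytest.approx(expected, abs=1e-9)

    def test_nyquist_rejects_negative(self):
        with pytest.raises(InputError):
            nyquist_limit(-1.0)

    @pytest.mark.parametrize(
        "px, scale, mm",
        [(256.0, 44.0 / 256.0, 44.0), (0.0, 1.0, 0.0), (5.0, 44.0 / 256.0, 0.859375)],
    )
    def test_px_to_mm(self, px, scale, mm):
        assert px_to_mm(px, scale) == pytest.approx(mm, abs=1e-6)

    def test_px_to_mm_rejects_bad_scale(self):
        with pytest.raises(CalibrationError):
            px_to_mm(5.0, 0.0)
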