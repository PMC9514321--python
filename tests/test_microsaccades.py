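import numpy as np
import pytest
from hypothesis import given, strategies as st

from gazedecode.io_core import EyeRecording
from gazedecode.microsaccades import (
    Candidate,
    DegenerateCandidatesError,
    Microsaccade,
    binocular_speed,
    cluster_candidates,
    delimit_and_filter,
    detect_microsaccades,
    main_sequence_qc,
    saccade_rate,
    select_candidates,
)
from tests.conftest import match_planted


def ramp_recording(n=500, vx_left=10.0, vx_right=10.0):
    t_s = np.arange(n) * 0.002
    z = np.zeros(n)
    return EyeRecording(
        time=np.arange(n) * 2.0,
        lx=vx_left * t_s, ly=z.copy(),
        rx=vx_right * t_s, ry=z.copy(),
        lp=np.full(n, 1000.0), rp=np.full(n, 1000.0),
        l_valid=np.ones(n, bool), r_valid=np.ones(n, bool),
    )


class TestBinocularSpeed:
    def test_linear_ramp_gives_exact_speed(self):
        speed, _ = binocular_speed(ramp_recording(vx_left=10.0, vx_right=10.0))
        assert speed[10:-10] == pytest.approx(np.full(480, 10.0), abs=1e-9)

    def test_stationary_gaze_zero_speed(self):
        speed, _ = binocular_speed(ramp_recording(vx_left=0.0, vx_right=0.0))
        assert np.nanmax(speed) == pytest.approx(0.0, abs=1e-12)

    def test_monocular_ramp_averages_to_half(self):
        speed, _ = binocular_speed(ramp_recording(vx_left=10.0, vx_right=0.0))
        assert speed[10:-10] == pytest.approx(np.full(480, 5.0), abs=1e-9)

    def test_single_eye_fallback_warns(self):
        rec = ramp_recording(vx_left=10.0)
        rec.r_valid[:] = False
        rec.rx[:] = np.nan
        rec.ry[:] = np.nan
        rec.rp[:] = np.nan
        with pytest.warns(UserWarning, match="monocular"):
            speed, _ = binocular_speed(rec)
        assert speed[10:-10] == pytest.approx(np.full(480, 10.0), abs=1e-9)


class TestSelectCandidates:
    def _trace_with_peaks(self, peak_speeds, n=500):
        speed = np.full(n, 0.5)
        accel = np.zeros(n)
        idx = np.linspace(20, n - 20, len(peak_speeds)).astype(int)
        for i, v in zip(idx, peak_speeds):
            speed[i] = v
        time = np.arange(n) * 2.0
        return speed, accel, time

    def test_top_six_of_ten_peaks_in_one_window(self):
        speeds = [5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
        speed, accel, time = self._trace_with_peaks(speeds)
        cands = select_candidates(speed, accel, time)
        assert len(cands) == 6
        assert sorted(c.peak_velocity for c in cands) == [9, 10, 11, 12, 13, 14]

    def test_fewer_than_six_peaks_all_kept(self):
        speed, accel, time = self._trace_with_peaks([5, 8, 11])
        assert len(select_candidates(speed, accel, time)) == 3

    def test_constant_trace_has_no_candidates(self):
        n = 500
        assert select_candidates(np.ones(n), np.zeros(n), np.arange(n) * 2.0) == []

    def test_masked_peaks_excluded(self):
        speed, accel, time = self._trace_with_peaks([5, 8, 11])
        mask = np.ones_like(speed, dtype=bool)
        assert select_candidates(speed, accel, time, exclude_mask=mask) == []


class TestClusterCandidates:
    def _cloud(self, n, pv_mu, acc_mu, rng):
        return [
            Candidate(index=i, peak_time_ms=2.0 * i,
                      peak_velocity=max(rng.normal(pv_mu, 0.15 * pv_mu), 0.1),
                      initial_accel=rng.normal(acc_mu, 0.2 * abs(acc_mu) + 1),
                      final_accel=rng.normal(-acc_mu, 0.2 * abs(acc_mu) + 1))
            for i in range(n)
        ]

    def test_two_cloud_recovery_at_least_95_percent(self):
        rng = np.random.default_rng(0)
        noise = self._cloud(200, pv_mu=2.0, acc_mu=50.0, rng=rng)
        sacc = self._cloud(200, pv_mu=30.0, acc_mu=2500.0, rng=rng)
        cands = noise + sacc
        labels = cluster_candidates(cands, seed=0)
        truth = np.r_[np.zeros(200, bool), np.ones(200, bool)]
        assert np.mean(labels == truth) >= 0.95

    def test_variance_confined_to_one_component(self):
        # features perfectly collinear: only one eigenvalue survives the 5% rule
        rng = np.random.default_rng(1)
        cands = []
        for i in range(100):
            v = rng.uniform(1, 40)
            cands.append(Candidate(i, 2.0 * i, v, 10 * v, -10 * v))
        labels = cluster_candidates(cands, seed=0)
        pv = np.array([c.peak_velocity for c in cands])
        assert pv[labels].mean() > pv[~labels].mean()

    def test_duplicate_candidates_degenerate(self):
        cands = [Candidate(i, 2.0 * i, 5.0, 10.0, -10.0) for i in range(10)]
        with pytest.raises(DegenerateCandidatesError):
            cluster_candidates(cands, seed=0)
        with pytest.raises(DegenerateCandidatesError):
            cluster_candidates(cands[:1], seed=0)


class TestDelimitAndFilter:
    def _synthetic_event(self, amp_arcmin, dur_ms, n=400, peak_at=200):
        """Minimum-jerk step of given amplitude/duration planted in quiet gaze."""
        from gazedecode.synth import _min_jerk_profile

        rec = ramp_recording(n=n, vx_left=0.0, vx_right=0.0)
        m = int(dur_ms / 2)
        prof = _min_jerk_profile(m + 1) * (amp_arcmin / 60.0)
        i0 = peak_at - m // 2
        for arr in (rec.lx, rec.rx):
            arr[i0 : i0 + m + 1] += prof
            arr[i0 + m + 1 :] += prof[-1]
        speed, accel = binocular_speed(rec)
        cands = select_candidates(speed, accel, rec.time)
        best = max(cands, key=lambda c: c.peak_velocity)
        return rec, speed, [best]

    def test_retained_event_arithmetic(self):
        """60 arcmin over ~20 ms: mean velocity = 1 deg / 0.02 s = 50 deg/s."""
        rec, speed, cands = self._synthetic_event(60.0, 20.0)
        events = delimit_and_filter(rec, speed, cands, np.array([True]))
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude_arcmin == pytest.approx(60.0, rel=0.1)
        assert ev.mean_velocity == pytest.approx(
            (ev.amplitude_arcmin / 60.0) / (ev.duration_ms / 1000.0)
        )
        assert 30.0 < ev.mean_velocity < 80.0

    def test_too_short_event_rejected(self):
        # inject a speed bump whose above-threshold extent is 3 samples (6 ms),
        # below the 8 ms minimum
        rec = ramp_recording(n=100, vx_left=0.0, vx_right=0.0)
        rec.lx[51:] += 0.2
        rec.rx[51:] += 0.2
        speed = np.full(100, 0.1)
        speed[49:52] = [20.0, 30.0, 20.0]
        cands = [Candidate(index=50, peak_time_ms=100.0, peak_velocity=30.0,
                           initial_accel=1000.0, final_accel=-1000.0)]
        assert delimit_and_filter(rec, speed, cands, np.array([True])) == []

    def test_overlarge_amplitude_rejected(self):
        rec, speed, cands = self._synthetic_event(150.0, 30.0)
        assert delimit_and_filter(rec, speed, cands, np.array([True])) == []

    def test_every_emitted_event_satisfies_all_filters(self, detection):
        for ev in detection.saccades:
            assert ev.duration_ms >= 8.0
            assert 10.0 <= ev.amplitude_arcmin <= 120.0
            assert 3.0 <= ev.mean_velocity <= 120.0


class TestMainSequence:
    def test_collinear_events_have_r_1(self):
        sacs = [
            Microsaccade(10.0 * i, 10.0 * i + 20, 10.0 * i + 10, a, 60 * a / 60.0, 20.0)
            for i, a in enumerate([10, 20, 30, 40])
        ]
        qc = main_sequence_qc(sacs)
        assert qc.r == pytest.approx(1.0)
        assert qc.passed

    def test_independent_velocities_fail_most_seeds(self):
        fails = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            sacs = [
                Microsaccade(30.0 * i, 30.0 * i + 20, 30.0 * i + 10,
                             rng.uniform(10, 120), rng.uniform(5, 100), 20.0)
                for i in range(30)
            ]
            if not main_sequence_qc(sacs).passed:
                fails += 1
        assert fails >= 0.95 * n_seeds

    def test_fewer_than_three_events_indeterminate(self):
        qc = main_sequence_qc([])
        assert qc.r is None and qc.passed is None


class TestSaccadeRate:
    def _events(self, peak_times):
        return [Microsaccade(t - 10, t + 10, t, 30.0, 40.0, 20.0) for t in peak_times]

    def test_rate_arithmetic(self):
        assert saccade_rate(self._events([100, 2000, 5000]), 0, 6000) == pytest.approx(0.5)
        assert saccade_rate([], 0, 6000) == 0.0
        assert saccade_rate(self._events([100, 300]), 0, 500) == pytest.approx(4.0)

    def test_zero_length_period_rejected(self):
        with pytest.raises(ValueError):
            saccade_rate([], 100, 100)

    @given(
        times=st.lists(st.floats(0, 9999), min_size=0, max_size=30),
        split=st.floats(1000, 9000),
    )
    def test_rate_additivity_over_concatenated_periods(self, times, split):
        events = self._events(sorted(times))
        r1 = saccade_rate(events, 0, split)
        r2 = saccade_rate(events, split, 10_000)
        total = saccade_rate(events, 0, 10_000)
        assert total * 10_000 == pytest.approx(r1 * split + r2 * (10_000 - split), abs=1e-6)


class TestEndToEndDetection:
    def test_oracle_recall_precision_on_default_noise(self, coupled_session, detection):
        planted = coupled_session.ground_truth.saccades
        tp = match_planted(planted, detection.saccades)
        recall = tp / len(planted)
        precision = tp / len(detection.saccades)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_main_sequence_qc_passes_on_default_session(self, detection):
        assert detection.qc.passed
        assert detection.qc.r > 0.6

    def test_determinism(self, coupled_session, preprocessed):
        _, blinks = preprocessed
        a = detect_microsaccades(coupled_session.recording, blinks, seed=0)
        b = detect_microsaccades(coupled_session.recording, blinks, seed=0)
        assert [e.onset_ms for e in a.saccades] == [e.onset_ms for e in b.saccades]
        assert a.qc.r == b.qc.r
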