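"""Escape-response extraction: latency, stages, turning, speed, QC tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sharkescape import kinematics as km
from sharkescape import simulate as sim


def make_track(**kwargs):
    return sim.gen_escape_track(sim.TrackSimParams(**kwargs))


def synthetic_track(angle, com=None, fps=240.0, stimulus_frame=10):
    n = len(angle)
    com = np.zeros((n, 2)) if com is None else np.asarray(com, dtype=float)
    head = com + 0.08 * np.column_stack(
        [np.cos(np.radians(angle)), np.sin(np.radians(angle))]
    )
    return km.EscapeTrack(fps=fps, stimulus_frame=stimulus_frame, head_xy=head,
                          com_xy=com, body_angle=np.asarray(angle, dtype=float))


class TestDetectResponse:
    def test_stationary_track_is_a_non_response(self):
        track = synthetic_track(np.zeros(100))
        responded, onset = km.detect_response(track)
        assert not responded and onset is None

    @pytest.mark.parametrize("latency", [0, 1, 3, 12])
    def test_generated_latency_round_trips(self, latency):
        track = make_track(latency_frames=latency, jitter_sd=0.0)
        responded, onset = km.detect_response(track)
        assert responded
        assert onset == track.stimulus_frame + latency

    def test_no_baseline_frames_rejected(self):
        track = synthetic_track(np.zeros(50), stimulus_frame=0)
        with pytest.raises(ValueError):
            km.detect_response(track)

    def test_full_cohort_responsiveness_is_total(self):
        metrics = [
            km.extract_metrics(make_track(latency_frames=l, seed=s))
            for s, l in enumerate([1, 2, 3, 4, 5, 6])
        ]
        assert all(m.responded for m in metrics)


class TestLatency:
    @pytest.mark.parametrize(
        "frames,expected", [(1, 4.16), (12, 50.00), (0, 0.0), (2, 8.33), (8, 33.33)]
    )
    def test_frame_quantization_with_truncation(self, frames, expected):
        assert km.latency_ms(100 + frames, 100, 240.0) == pytest.approx(expected)

    def test_onset_before_stimulus_rejected(self):
        with pytest.raises(ValueError):
            km.latency_ms(99, 100, 240.0)

    @given(frames=st.integers(0, 40), fps=st.sampled_from([120.0, 240.0, 500.0]))
    def test_latency_is_a_truncated_frame_multiple(self, frames, fps):
        lat = km.latency_ms(frames, 0, fps)
        exact = frames * 1000.0 / fps
        assert 0 <= exact - lat < 0.01 + 1e-9


class TestStageSegmentation:
    def test_double_bend_track_classified_with_boundary(self):
        params = sim.TrackSimParams(latency_frames=2, jitter_sd=0.0, stage2=True)
        track = sim.gen_escape_track(params)
        _, onset = km.detect_response(track)
        seg = km.stage_segment(track, onset)
        assert seg.response_type == "double_bend"
        expected_end = onset + int(round(params.stage1_duration * params.fps))
        assert abs(seg.stage1[1] - expected_end) <= 2  # smoothing slack

    def test_stage1_only_track_is_single_bend(self):
        track = make_track(stage2=False, jitter_sd=0.0)
        _, onset = km.detect_response(track)
        assert km.stage_segment(track, onset).response_type == "single_bend"

    def test_cohort_single_bend_counts_by_temperature(self):
        # 1 single-bend at the cold extreme, 2 at the warm, none in between
        plan = {25.0: [False, True, False], 27.0: [False] * 3,
                29.0: [False] * 3, 31.0: [True, False, True]}
        counts = {}
        seed = 0
        for temp, singles in plan.items():
            n = 0
            for is_single in singles:
                track = make_track(stage2=not is_single, seed=seed)
                seed += 1
                m = km.extract_metrics(track)
                n += m.response_type == "single_bend"
            counts[temp] = n
        assert [counts[t] for t in (25.0, 27.0, 29.0, 31.0)] == [1, 0, 0, 2]


class TestOmegaS1:
    def test_constant_turn_rate_recovered(self):
        track = make_track(stage1_turn_rate=1234.0, jitter_sd=0.0)
        m = km.extract_metrics(track)
        assert m.omega_s1 == pytest.approx(1234.0, rel=1e-6)

    def test_sinusoidal_bend_peak_rate(self):
        # raised-cosine bend: theta = A(1 - cos(2*pi*f*t)), peak rate 2*pi*f*A
        # reached mid-bend, safely inside stage 1
        fps, f, amp = 240.0, 4.0, 15.0
        t = np.arange(0, 0.5, 1 / fps)
        angle = np.concatenate([np.zeros(20), amp * (1 - np.cos(2 * np.pi * f * t))])
        com = np.zeros((angle.size, 2))
        com[20:, 0] = np.linspace(0, 0.3, angle.size - 20)
        track = synthetic_track(angle, com, stimulus_frame=15)
        _, onset = km.detect_response(track, displacement_threshold=0.002)
        seg = km.stage_segment(track, onset)
        peak = km.omega_s1(track, seg.stage1)
        assert peak == pytest.approx(2 * np.pi * f * amp, rel=0.02)

    def test_fast_turning_magnitude_round_trip(self):
        track = make_track(stage1_turn_rate=2038.0, jitter_sd=0.0)
        m = km.extract_metrics(track)
        assert m.omega_s1 == pytest.approx(2038.0, rel=1e-6)


class TestSpeedAcceleration:
    def test_uniform_motion(self):
        n, v, fps = 120, 0.9, 240.0
        t = np.arange(n) / fps
        com = np.column_stack([v * t, np.zeros(n)])
        com[:20] = com[20]  # stationary before the stimulus window
        track = synthetic_track(np.zeros(n), com - com[0], stimulus_frame=20)
        u, a = km.umax_amax(track, onset=30)
        assert u == pytest.approx(v, rel=1e-9)
        assert a == pytest.approx(0.0, abs=1e-6)

    def test_constant_acceleration_from_rest(self):
        n, a0, fps = 120, 25.0, 240.0
        t = np.arange(n) / fps
        com = np.column_stack([0.5 * a0 * t**2, np.zeros(n)])
        track = synthetic_track(np.zeros(n), com, stimulus_frame=5)
        u, a = km.umax_amax(track, onset=5)
        t_end = (n - 1) / fps
        assert a == pytest.approx(a0, rel=1e-9)
        assert u == pytest.approx(a0 * t_end, rel=0.02)

    def test_noise_bounded_acceleration_on_uniform_motion(self):
        # smoothed 2nd derivative of iid noise has variance sigma^2 * ||c||^2
        rng = np.random.default_rng(0)
        n, v, fps, sd = 200, 1.0, 240.0, 1e-4
        t = np.arange(n) / fps
        com = np.column_stack([v * t, np.zeros(n)]) + rng.normal(0, sd, (n, 2))
        track = synthetic_track(np.zeros(n), com, stimulus_frame=10)
        _, a = km.umax_amax(track, onset=10)
        from scipy.signal import savgol_coeffs
        c = savgol_coeffs(5, 2, deriv=2, delta=1 / fps)
        bound = 6.0 * sd * np.linalg.norm(c) * math.sqrt(2)
        assert a <= bound

    def test_too_few_frames_rejected(self):
        track = synthetic_track(np.zeros(12), stimulus_frame=5)
        with pytest.raises(ValueError):
            km.umax_amax(track, onset=8)


class TestMaximalPerformance:
    def _metrics(self, lat, omega, u, a, trial=1, responded=True):
        return km.EscapeMetrics(responded=responded, response_type="double_bend",
                                latency_ms=lat, omega_s1=omega, u_max=u, a_max=a,
                                trial_index=trial)

    def test_identical_trials_return_their_values(self):
        trials = [self._metrics(10.0, 1500.0, 1.0, 30.0, t) for t in (1, 2, 3)]
        best = km.maximal_performance(trials)
        assert (best.latency_ms, best.omega_s1, best.u_max, best.a_max) == \
            (10.0, 1500.0, 1.0, 30.0)

    def test_variables_may_come_from_different_trials(self):
        trials = [
            self._metrics(26.4, 1400.0, 1.2, 28.0, 1),
            self._metrics(30.0, 1900.0, 1.0, 26.0, 2),
            self._metrics(33.0, 1500.0, 1.1, 35.0, 3),
        ]
        best = km.maximal_performance(trials)
        assert best.latency_ms == 26.4
        assert best.omega_s1 == 1900.0
        assert best.a_max == 35.0

    def test_single_responder_flagged(self):
        trials = [
            km.EscapeMetrics(responded=False, trial_index=1),
            self._metrics(12.5, 1600.0, 1.3, 33.0, 2),
            km.EscapeMetrics(responded=False, trial_index=3),
        ]
        best = km.maximal_performance(trials)
        assert best.n_trials == 1
        assert best.latency_ms == 12.5

    def test_order_invariant_and_idempotent(self):
        trials = [self._metrics(26.4, 1400.0, 1.2, 28.0, 1),
                  self._metrics(30.0, 1900.0, 1.0, 26.0, 2)]
        a = km.maximal_performance(trials)
        b = km.maximal_performance(trials[::-1])
        assert (a.latency_ms, a.omega_s1, a.u_max, a.a_max) == \
            (b.latency_ms, b.omega_s1, b.u_max, b.a_max)
        again = km.maximal_performance([a])
        assert again.latency_ms == a.latency_ms

    def test_no_responders_rejected(self):
        with pytest.raises(ValueError):
            km.maximal_performance([km.EscapeMetrics(responded=False)])


class TestRigidMotionInvariance:
    @given(angle_deg=st.floats(-180, 180), dx=st.floats(-5, 5), dy=st.floats(-5, 5))
    def test_metrics_unchanged_by_rotation_and_translation(self, angle_deg, dx, dy):
        track = make_track(latency_frames=2, jitter_sd=0.0, seed=9)
        c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
        rot = np.array([[c, -s], [s, c]])
        moved = km.EscapeTrack(
            fps=track.fps,
            stimulus_frame=track.stimulus_frame,
            head_xy=track.head_xy @ rot.T + [dx, dy],
            com_xy=track.com_xy @ rot.T + [dx, dy],
            body_angle=track.body_angle + angle_deg,
        )
        m0 = km.extract_metrics(track)
        m1 = km.extract_metrics(moved)
        assert m1.latency_ms == m0.latency_ms
        assert m1.omega_s1 == pytest.approx(m0.omega_s1, rel=1e-9)
        assert m1.u_max == pytest.approx(m0.u_max, rel=1e-9)
        assert m1.a_max == pytest.approx(m0.a_max, rel=1e-7, abs=1e-9)


class TestTemperatureRegression:
    def _table(self, temps, values, rtype="double_bend"):
        return pd.DataFrame(
            {"temperature_c": temps, "value": values, "response_type": rtype}
        )

    def test_exact_linear_relationship(self):
        temps = np.repeat([25.0, 27.0, 29.0, 31.0], 5)
        values = 2.0 * temps - 10.0
        reg = km.temperature_regression(self._table(temps, values), "value")
        assert reg.slope == pytest.approx(2.0)
        assert reg.p_value < 1e-12

    def test_f_p_value_matches_permutation_null(self):
        rng = np.random.default_rng(1)
        temps = np.repeat([25.0, 27.0, 29.0, 31.0], 6)
        values = 0.4 * temps + rng.normal(0, 2.0, temps.size)
        reg = km.temperature_regression(self._table(temps, values), "value")
        perm_f = []
        for _ in range(4000):
            shuffled = rng.permutation(values)
            r = np.corrcoef(temps, shuffled)[0, 1]
            perm_f.append(r**2 / (1 - r**2) * (temps.size - 2))
        p_perm = np.mean(np.asarray(perm_f) >= reg.f_stat)
        assert reg.p_value == pytest.approx(p_perm, abs=0.02)

    def test_latency_declines_with_warming_in_group_mean_cohort(self):
        group_means = {25.0: 26.4, 27.0: 17.9, 29.0: 18.75, 31.0: 14.3}
        rng = np.random.default_rng(2)
        temps, values = [], []
        for t, mu in group_means.items():
            temps.extend([t] * 10)
            values.extend(np.maximum(2.0, rng.normal(mu, 3.0, 10)))
        reg = km.temperature_regression(
            self._table(np.array(temps), np.array(values)), "value", log_transform=True
        )
        assert reg.slope < 0
        assert reg.p_value < 0.05

    def test_single_bends_excluded(self):
        temps = np.repeat([25.0, 27.0, 29.0, 31.0], 3)
        df = self._table(temps, np.linspace(1, 2, temps.size))
        df.loc[:3, "response_type"] = "single_bend"
        reg = km.temperature_regression(df, "value")
        assert reg.n == temps.size - 4


class TestQCTests:
    def test_grubbs_flags_the_gross_outlier(self):
        idx, g, crit = km.grubbs_test([1.0, 1.1, 0.9, 10.0])
        assert idx == 3
        assert g > crit

    def test_grubbs_passes_clean_data(self):
        idx, _, _ = km.grubbs_test([0.9, 1.0, 1.05, 1.1, 0.95, 1.0])
        assert idx is None

    def test_grubbs_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            km.grubbs_test([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            km.grubbs_test([1.0, 2.0])

    def test_bartlett_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        chi2, df, p = km.bartlett_test([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_bartlett_detects_unequal_variances(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1.0, 20)
        b = rng.normal(0, 10.0, 20)
        chi2, df, p = km.bartlett_test([a, b])
        assert p < 0.01

    def test_bartlett_null_simulation_is_calibrated(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 15) for _ in range(3)]
            _, _, p = km.bartlett_test(groups)
            rejections += p < 0.05
        assert rejections / n_sim < 0.12
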