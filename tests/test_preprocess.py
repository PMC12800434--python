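"""Tests for gap filling, rigid pose estimation, load transforms, filtering
and resampling."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from liftsim.data import ForceRecord, MarkerSet
from liftsim.errors import ConfigError, GapError, PoseEstimationError, TimelineError
from liftsim.preprocess import (FilterSpec, RigidTransformSeries, estimate_box_pose,
                                fill_marker_gaps, kabsch, lowpass_filter,
                                preprocess_trial, resample_to_common_timeline,
                                transform_loads_to_global)


def _markerset(time, **traj):
    return MarkerSet(np.asarray(time, float), 1.0 / (time[1] - time[0]),
                     {k: np.asarray(v, float) for k, v in traj.items()})


class TestGapFill:
    def test_cubic_trajectory_recovered_exactly(self):
        t = np.linspace(0, 1, 101)
        y = np.stack([t**3 - t, 2 * t**2, np.zeros_like(t)], axis=1)
        gappy = y.copy()
        gappy[40:43] = np.nan
        ms = _markerset(t, M=gappy)
        filled = fill_marker_gaps(ms)
        # natural cubic splines reproduce cubics away from the boundary knots
        assert np.abs(filled.data["M"][40:43] - y[40:43]).max() < 1e-6

    def test_no_gaps_identity(self):
        t = np.linspace(0, 1, 50)
        y = np.stack([np.sin(t), np.cos(t), t], axis=1)
        filled = fill_marker_gaps(_markerset(t, M=y.copy()))
        assert np.array_equal(filled.data["M"], y)

    def test_spike_flagged_and_replaced(self):
        t = np.linspace(0, 1, 101)
        y = np.stack([np.sin(2 * np.pi * t), np.zeros_like(t), np.zeros_like(t)],
                     axis=1)
        spiked = y.copy()
        spiked[50, 0] += 0.1
        filled = fill_marker_gaps(_markerset(t, M=spiked))
        assert np.abs(filled.data["M"][50] - y[50]).max() < 1e-3

    def test_leading_gap_raises_with_marker_name(self):
        t = np.linspace(0, 1, 20)
        y = np.ones((20, 3))
        y[0] = np.nan
        with pytest.raises(GapError, match="LEAD"):
            fill_marker_gaps(_markerset(t, LEAD=y))

    def test_all_invalid_marker_raises(self):
        t = np.linspace(0, 1, 20)
        with pytest.raises(GapError):
            fill_marker_gaps(_markerset(t, M=np.full((20, 3), np.nan)))


class TestBoxPose:
    def test_exact_recovery_of_rigid_motion(self, box):
        rng = np.random.default_rng(3)
        R_true = Rotation.from_euler("z", 0.4).as_matrix()
        t_true = np.array([0.3, 0.7, 0.0])
        t = np.arange(5) * 0.01
        data = {}
        for n, off in box.corner_marker_offsets.items():
            data[n] = np.tile(R_true @ off + t_true, (5, 1))
        pose = estimate_box_pose(MarkerSet(t, 100.0, data), box)
        assert np.abs(pose.rotation[0] - R_true).max() < 1e-9
        assert np.abs(pose.translation[0] - t_true).max() < 1e-9
        assert pose.rms_residual.max() < 1e-9

    def test_identity_pose(self, box):
        t = np.arange(3) * 0.01
        data = {n: np.tile(off, (3, 1)) for n, off in box.corner_marker_offsets.items()}
        pose = estimate_box_pose(MarkerSet(t, 100.0, data), box)
        assert np.allclose(pose.rotation[0], np.eye(3), atol=1e-12)
        assert np.allclose(pose.translation[0], 0.0, atol=1e-12)

    def test_noisy_recovery_matches_nonlinear_least_squares(self, box):
        """Kabsch vs a brute-force nonlinear LSQ over (angle, translation)."""
        rng = np.random.default_rng(7)
        R_true = Rotation.from_euler("z", -0.25).as_matrix()
        t_true = np.array([0.42, 0.63, 0.0])
        local = np.stack(list(box.corner_marker_offsets.values()))
        obs = local @ R_true.T + t_true + rng.normal(0, 1e-3, (8, 3))
        R, tr, rms = kabsch(local, obs)

        def resid(p):
            Rz = Rotation.from_euler("xyz", p[:3]).as_matrix()
            return (local @ Rz.T + p[3:] - obs).ravel()

        sol = least_squares(resid, np.zeros(6), method="lm")
        R_o = Rotation.from_euler("xyz", sol.x[:3]).as_matrix()
        assert np.abs(R - R_o).max() < 1e-6
        assert np.abs(tr - sol.x[3:]).max() < 1e-6
        assert np.abs(tr - t_true).max() < 2e-3  # mm-noise -> sub-2mm translation

    def test_kabsch_agrees_with_scipy_align_vectors(self, box):
        rng = np.random.default_rng(11)
        local = np.stack(list(box.corner_marker_offsets.values()))
        R_true = Rotation.from_euler("z", 0.8).as_matrix()
        obs = local @ R_true.T + rng.normal(0, 1e-4, (8, 3))
        R, tr, _ = kabsch(local, obs)
        est, _ = Rotation.align_vectors(obs - obs.mean(0), local - local.mean(0))
        assert np.abs(R - est.as_matrix()).max() < 1e-9

    def test_too_few_markers_raises(self, box):
        t = np.arange(2) * 0.01
        names = list(box.corner_marker_offsets)[:2]
        data = {n: np.tile(box.corner_marker_offsets[n], (2, 1)) for n in names}
        with pytest.raises(PoseEstimationError):
            estimate_box_pose(MarkerSet(t, 100.0, data), box)


class TestLoadTransform:
    @staticmethod
    def _record(force, cop, moment=None, t=None):
        t = np.arange(3) * 0.001 if t is None else t
        n = len(t)
        mk = lambda v: np.tile(np.asarray(v, float), (n, 1))
        return ForceRecord("handle_right", t, 1000.0, mk(force),
                           mk(moment if moment is not None else [0, 0, 0]),
                           mk(cop), frame="local")

    @staticmethod
    def _poses(angle, translation, t):
        n = len(t)
        R = np.tile(Rotation.from_euler("z", angle).as_matrix(), (n, 1, 1))
        return RigidTransformSeries(t, R, np.tile(translation, (n, 1)), np.zeros(n))

    def test_identity_pose_is_identity(self):
        t = np.arange(3) * 0.001
        rec = self._record([1.0, 2.0, 0.0], [0.1, 0.2, 0.0], t=t)
        out = transform_loads_to_global(rec, self._poses(0.0, np.zeros(3), t))
        assert np.allclose(out.force, rec.force)
        assert np.allclose(out.cop, rec.cop)
        assert out.frame == "global"

    def test_quarter_turn_rotates_forward_force(self):
        t = np.arange(3) * 0.001
        rec = self._record([5.0, 0.0, 0.0], [0.0, 0.0, 0.0], t=t)
        out = transform_loads_to_global(rec, self._poses(np.pi / 2,
                                                         np.array([1.0, 0, 0]), t))
        assert np.allclose(out.force[0], [0.0, 5.0, 0.0], atol=1e-12)
        assert np.allclose(out.cop[0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_synthetic_round_trip_matches_ground_truth(self, trial, box):
        markers = fill_marker_gaps(trial.markers)
        pose = estimate_box_pose(markers, box)
        out = transform_loads_to_global(trial.ehfm["right"], pose)
        gt = trial.ground_truth
        assert np.abs(out.force - gt.ehf_global).max() < 1e-9
        assert np.abs(out.moment - gt.ehm_global).max() < 1e-9

    def test_misaligned_timeline_raises(self):
        t = np.arange(3) * 0.001
        rec = self._record([1, 0, 0], [0, 0, 0], t=t + 10.0)
        with pytest.raises(TimelineError, match="support"):
            transform_loads_to_global(rec, self._poses(0.0, np.zeros(3), t))


class TestButterworth:
    def test_dc_gain_unity(self):
        y = np.full(2000, 3.7)
        out = lowpass_filter(y, 1000.0, FilterSpec())
        assert np.abs(out - 3.7).max() < 1e-9

    @pytest.mark.parametrize("freq,rtol", [(1.0, 0.01), (50.0, 0.05)])
    def test_attenuation_matches_analytic_squared_response(self, freq, rtol):
        """Zero-phase 4th-order Butterworth: |H|^2 = 1/(1 + (f/fc)^8) applied
        twice (forward-backward)."""
        fs, fc = 1000.0, 10.0
        t = np.arange(0, 8.0, 1 / fs)
        y = np.sin(2 * np.pi * freq * t)
        out = lowpass_filter(y, fs, FilterSpec(order=4, cutoff_hz=fc))
        mid = slice(len(t) // 4, 3 * len(t) // 4)  # trim transients
        amp = np.abs(out[mid]).max()
        # the discrete (bilinear) filter realizes the analytic response at
        # the prewarped frequencies f' = (fs/pi) tan(pi f / fs)
        warp = lambda f: fs / np.pi * np.tan(np.pi * f / fs)
        expected = 1.0 / (1.0 + (warp(freq) / warp(fc)) ** 8)  # two passes of |H|
        assert np.isclose(amp, expected, rtol=rtol, atol=1e-12)
        # and stays within 8% of the continuous-time prediction here
        assert np.isclose(amp, 1.0 / (1.0 + (freq / fc) ** 8), rtol=0.08)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            lowpass_filter(np.zeros(100), 100.0, FilterSpec(cutoff_hz=50.0))

    def test_idempotent_in_band(self):
        # a 2 Hz signal is far inside the 10 Hz passband: filtering changes
        # it by well under 0.5%
        fs = 1000.0
        t = np.arange(0, 6.0, 1 / fs)
        y = np.sin(2 * np.pi * 2.0 * t)
        out = lowpass_filter(y, fs, FilterSpec())
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.abs(out[mid] - y[mid]).max() < 0.005


class TestResample:
    def test_identity_on_identical_timelines(self):
        t = np.arange(100) / 100.0
        y = np.sin(t)
        out = resample_to_common_timeline(t, y, t.copy())
        assert np.array_equal(out, y)

    def test_decimation_of_sinusoid_matches_analytic(self):
        t_hi = np.arange(0, 2, 0.001)
        t_lo = np.arange(0, 1.999, 0.01)
        y = np.sin(2 * np.pi * 2.0 * t_hi)
        out = resample_to_common_timeline(t_hi, y, t_lo)
        assert np.abs(out - np.sin(2 * np.pi * 2.0 * t_lo)).max() < 1e-3

    def test_target_outside_support_raises(self):
        with pytest.raises(TimelineError):
            resample_to_common_timeline(np.arange(10.0), np.arange(10.0),
                                        np.array([5.0, 11.0]))


class TestPreprocessTrial:
    def test_pure_function_bit_identical(self, trial):
        a = preprocess_trial(trial)
        b = preprocess_trial(trial)
        assert np.array_equal(a.grf.force, b.grf.force)
        assert np.array_equal(a.markers.data["MC3"], b.markers.data["MC3"])

    def test_output_on_marker_timeline(self, trial):
        proc = preprocess_trial(trial)
        assert proc.rate == trial.meta.marker_rate
        assert np.allclose(proc.time, proc.grf.time)
        assert proc.ehfm["right"].frame == "global"

    def test_global_hand_loads_near_ground_truth(self, trial):
        # noise-free: transform + 10 Hz filtering leaves the (smooth) hand
        # load within a few tenths of a newton of the global-frame truth
        proc = preprocess_trial(trial)
        gt = trial.ground_truth.ehf_global[::10]
        err = np.abs(proc.ehfm["right"].force - gt)
        assert err.max() < 2.0  # transient at the ramp corners
        mask = trial.ground_truth.grip_fraction[::10] == 1.0
        assert err[mask].max() < 1.0


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.floats(-np.pi, np.pi), st.floats(-1, 1), st.floats(-1, 1))
def test_pose_interpolation_consistent_at_knots(angle, tx, ty):
    t = np.array([0.0, 1.0])
    R = np.tile(Rotation.from_euler("z", angle).as_matrix(), (2, 1, 1))
    tr = np.tile([tx, ty, 0.0], (2, 1))
    series = RigidTransformSeries(t, R, tr, np.zeros(2))
    mid = series.interpolated(np.array([0.0, 0.5, 1.0]))
    assert np.abs(mid.rotation[1] - R[0]).max() < 1e-9
    assert np.abs(mid.translation[1] - tr[0]).max() < 1e-9
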