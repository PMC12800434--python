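"""Tests for grip event detection, phase normalization, quartile RMSEs,
peak finding, residual compliance and repeated-measures statistics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liftsim import TaskConfig
from liftsim.data import MarkerSet
from liftsim.errors import EventDetectionError, LiftsimError
from liftsim.metrics import (HandlingPhase, QUARTILE_SLICES, build_report,
                             detect_grip_events, find_phase_peaks,
                             phases_from_events, residual_compliance,
                             rm_anova_bonferroni, rmse_quartiles,
                             segment_and_normalize)
from liftsim.synthetic import plan_box_trajectory


def _corner_markers(task, box, rate=100.0, noise=0.0, seed=0):
    """Box corner markers straight from the planned trajectory (no human)."""
    traj = plan_box_trajectory(task, box)
    t = np.arange(int(traj.duration * rate) + 1) / rate
    pos = traj.pos(t)
    rng = np.random.default_rng(seed)
    data = {}
    for name, off in box.corner_marker_offsets.items():
        xyz = np.stack([pos[:, 0] + off[0], pos[:, 1] + off[1],
                        np.full(t.shape[0], off[2])], axis=1)
        data[name] = xyz + rng.normal(0, noise, xyz.shape)
    return MarkerSet(t, rate, data), traj


class TestGripDetection:
    def test_recovers_planted_events_within_one_frame(self, box):
        task = TaskConfig(n_repetitions=2, grip_ramp_duration=0.0)
        markers, traj = _corner_markers(task, box)
        events = detect_grip_events(markers, box)
        truth = traj.move_intervals.ravel()
        detected = np.array([e.time for e in events])
        assert detected.shape == truth.shape
        assert np.abs(detected - truth).max() <= 0.010 + 1e-9  # +-10 ms at 100 Hz

    def test_constant_trajectory_raises(self, box):
        t = np.arange(200) / 100.0
        data = {n: np.tile(off, (200, 1))
                for n, off in box.corner_marker_offsets.items()}
        with pytest.raises(EventDetectionError, match="constant"):
            detect_grip_events(MarkerSet(t, 100.0, data), box)

    def test_twenty_repetitions_give_twenty_phase_pairs(self, box):
        task = TaskConfig(n_repetitions=20, grip_ramp_duration=0.0)
        markers, _ = _corner_markers(task, box)
        events = detect_grip_events(markers, box)
        phases = phases_from_events(events, markers, box)
        kinds = [p.kind for p in phases]
        assert kinds.count("lifting") == 20
        assert kinds.count("lowering") == 20
        assert kinds == ["lifting", "lowering"] * 20

    def test_events_alternate_on_off(self, box):
        task = TaskConfig(n_repetitions=3)
        markers, _ = _corner_markers(task, box)
        events = detect_grip_events(markers, box)
        assert [e.kind for e in events] == ["grip_on", "grip_off"] * 6

    def test_robust_to_marker_noise(self, box):
        task = TaskConfig(n_repetitions=2, grip_ramp_duration=0.0)
        markers, traj = _corner_markers(task, box, noise=5e-4, seed=3)
        events = detect_grip_events(markers, box)
        truth = traj.move_intervals.ravel()
        detected = np.array([e.time for e in events])
        assert detected.shape == truth.shape
        assert np.abs(detected - truth).max() < 0.25


class TestSegmentNormalize:
    def test_linear_ramp_exact(self):
        t = np.arange(101) / 100.0
        y = 3.0 * t + 1.0
        ph = HandlingPhase("lifting", 0.1, 0.9)
        out = segment_and_normalize(t, y, [ph])[0]
        expect = 3.0 * ph.times + 1.0
        assert np.allclose(out, expect, atol=1e-12)

    def test_identity_round_trip(self):
        ph = HandlingPhase("lifting", 0.0, 1.0)
        t = ph.times  # 101 samples spanning exactly the phase
        y = np.sin(2 * np.pi * t / 100.0)
        out = segment_and_normalize(t, y, [ph])[0]
        assert np.allclose(out, y, atol=1e-12)

    def test_time_reversal_mirrors_profile(self):
        t = np.linspace(0.0, 1.0, 201)
        y = np.exp(-((t - 0.3) ** 2) / 0.01)
        ph = HandlingPhase("lifting", 0.0, 1.0)
        fwd = segment_and_normalize(t, y, [ph])[0]
        rev = segment_and_normalize(t, y[::-1], [ph])[0]
        assert np.allclose(rev, fwd[::-1], atol=1e-6)
        assert np.isclose(np.linalg.norm(rev), np.linalg.norm(fwd), rtol=1e-6)

    def test_short_phase_rejected(self):
        t = np.arange(101) / 100.0
        with pytest.raises(LiftsimError, match="samples"):
            segment_and_normalize(t, t, [HandlingPhase("lifting", 0.10, 0.13)])


class TestQuartileRmse:
    def test_identity_gives_zero(self):
        y = np.random.default_rng(0).normal(size=101)
        qr = rmse_quartiles(y, y, 15.0)
        assert all(v == 0.0 for v in qr.values.values())

    def test_constant_offset(self):
        y = np.zeros(101)
        qr = rmse_quartiles(y + 2.5, y, 15.0)
        assert all(np.isclose(v, 2.5) for v in qr.values.values())
        assert all(np.isclose(v, 2.5 / 15.0) for v in qr.normalized.values())

    def test_offset_confined_to_first_quartile(self):
        ref = np.zeros(101)
        est = np.zeros(101)
        est[:26] = 4.0  # samples 0..25 belong to Q1 (boundary owned below)
        qr = rmse_quartiles(est, ref, 1.0)
        assert np.isclose(qr.values["Q1"], 4.0)
        assert qr.values["Q2"] == qr.values["Q3"] == qr.values["Q4"] == 0.0

    def test_window_sizes(self):
        sizes = [QUARTILE_SLICES[k].stop - QUARTILE_SLICES[k].start
                 for k in ("Q1", "Q2", "Q3", "Q4")]
        assert sizes == [26, 25, 25, 25]
        assert sum(sizes) == 101

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_whole_phase_rmse_conserved_by_quartiles(self, seed):
        """Whole-phase RMSE^2 equals the sample-count-weighted mean of the
        quartile RMSE^2 (exact windowing identity)."""
        rng = np.random.default_rng(seed)
        est, ref = rng.normal(size=(2, 101))
        qr = rmse_quartiles(est, ref, 1.0)
        counts = np.array([26, 25, 25, 25])
        whole = np.mean((est - ref) ** 2)
        parts = np.array([qr.values[k] ** 2 for k in ("Q1", "Q2", "Q3", "Q4")])
        assert np.isclose(whole, (counts * parts).sum() / 101.0, rtol=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(LiftsimError):
            rmse_quartiles(np.zeros(100), np.zeros(100), 1.0)


class TestPhasePeaks:
    def test_planted_gaussian_bumps_recovered(self):
        x = np.arange(101.0)
        y = 2.0 + 5.0 * np.exp(-((x - 15) ** 2) / 20.0) \
            + 7.0 * np.exp(-((x - 90) ** 2) / 12.0)
        pk = find_phase_peaks(y)
        assert pk.initial_time == 15.0
        assert pk.final_time == 90.0
        assert np.isclose(pk.initial_magnitude, y[15])
        assert np.isclose(pk.final_magnitude, y[90])
        assert not pk.fallback

    def test_monotone_series_falls_back_to_boundary_maxima(self):
        y = np.linspace(1.0, 2.0, 101)
        pk = find_phase_peaks(y)
        assert pk.fallback
        assert pk.initial_time == 50.0 and pk.final_time == 100.0

    def test_initial_before_final_by_construction(self):
        x = np.arange(101.0)
        y = 1 + np.exp(-((x - 40) ** 2) / 30) + np.exp(-((x - 60) ** 2) / 30)
        pk = find_phase_peaks(y)
        assert pk.initial_time < pk.final_time

    def test_tie_breaks_toward_earlier_sample(self):
        y = np.ones(101)
        y[[10, 20]] = 2.0  # two equal local maxima in the first half
        y[80] = 3.0
        pk = find_phase_peaks(y)
        assert pk.initial_time == 10.0


class TestResidualCompliance:
    def test_zero_residual_passes_with_threshold_margin(self):
        net = np.full(50, 800.0)
        rc = residual_compliance(np.zeros(50), net, np.zeros(50))
        assert rc.peak_pass and rc.rms_pass
        assert np.isclose(rc.peak_threshold, 40.0)
        assert np.isclose(rc.rms_threshold, 40.0)

    def test_six_percent_residual_fails_both(self):
        net = np.full(50, 1000.0)
        rc = residual_compliance(np.full(50, 60.0), net, np.zeros(50))
        assert not rc.peak_pass and not rc.rms_pass

    def test_hand_loads_enter_net_external_force(self):
        grf = np.full(50, 900.0)
        ehf = np.full(50, -150.0)  # box pulls the hands down
        rc = residual_compliance(np.zeros(50), grf, ehf)
        assert np.isclose(rc.peak_threshold, 0.05 * 750.0)

    def test_app_compliance_pattern_on_synthetic_trial(self, results, proc):
        """Measured loads keep residuals inside the 5% recommendation;
        embodied-mass approaches break the peak criterion at a 0.3 s ramp."""
        for app, expect_pass in (("APP1", True), ("APP2", False), ("APP3", False)):
            res = results[app]
            sel = np.isfinite(res.jrf.resultant) if app != "APP1" else \
                np.ones(proc.time.shape[0], dtype=bool)
            rc = residual_compliance(res.so.residual_force[sel, 1],
                                     proc.grf.force[sel, 1],
                                     2.0 * proc.ehfm["right"].force[sel, 1])
            assert rc.peak_pass is expect_pass, app
            if app == "APP1":
                assert rc.rms_pass


class TestRmAnova:
    @staticmethod
    def _fixture(n=20, seed=0):
        rng = np.random.default_rng(seed)
        subj = rng.normal(0, 2.0, (n, 1))
        cond = np.array([0.0, 1.0, 1.6])
        return 10.0 + subj + cond + rng.normal(0, 1.0, (n, 3))

    def test_identical_conditions_null_result(self):
        col = np.random.default_rng(1).normal(size=20)
        Y = np.stack([col, col, col], axis=1)
        res = rm_anova_bonferroni(Y)
        assert res["F"] == 0.0
        assert all(p["p_bonf"] == 1.0 for p in res["posthoc"].values())

    def test_matches_statsmodels_and_pingouin(self):
        """F and dfs against statsmodels AnovaRM; epsilon and corrected p
        against pingouin — independent implementations."""
        import pandas as pd
        import pingouin as pg
        from statsmodels.stats.anova import AnovaRM

        Y = self._fixture()
        res = rm_anova_bonferroni(Y)
        n = Y.shape[0]
        long = pd.DataFrame({
            "y": Y.ravel(),
            "cond": np.tile(["a", "b", "c"], n),
            "subj": np.repeat(np.arange(n), 3),
        })
        sm = AnovaRM(long, "y", "subj", within=["cond"]).fit()
        F_sm = float(sm.anova_table["F Value"].iloc[0])
        assert np.isclose(res["F"], F_sm, atol=1e-10)
        pgt = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                          correction=True)
        assert np.isclose(res["gg_epsilon"], float(pgt["eps"].iloc[0]), atol=1e-10)
        assert np.isclose(res["p_gg"], float(pgt["p_GG_corr"].iloc[0]), atol=1e-10)

    def test_bonferroni_matches_scipy_paired_t(self):
        from scipy import stats as ss
        Y = self._fixture(seed=4)
        res = rm_anova_bonferroni(Y)
        for (i, j), key in zip([(0, 1), (0, 2), (1, 2)],
                               ["APP1-APP2", "APP1-APP3", "APP2-APP3"]):
            _, p = ss.ttest_rel(Y[:, i], Y[:, j])
            assert np.isclose(res["posthoc"][key]["p_bonf"], min(1.0, 3 * p),
                              atol=1e-12)

    def test_translation_invariance(self):
        Y = self._fixture(seed=2)
        a = rm_anova_bonferroni(Y)
        b = rm_anova_bonferroni(Y + 123.4)
        assert np.isclose(a["F"], b["F"], rtol=1e-10)
        assert np.isclose(a["gg_epsilon"], b["gg_epsilon"], rtol=1e-10)

    def test_too_few_repetitions_rejected(self):
        with pytest.raises(LiftsimError):
            rm_anova_bonferroni(np.zeros((2, 3)))


class TestBuildReport:
    @staticmethod
    def _rows(n_rep, jitter=0.0):
        rng = np.random.default_rng(0)
        rows = []
        for rep in range(n_rep):
            for app in ("APP1", "APP2"):
                for kind in ("lifting", "lowering"):
                    rows.append({"approach": app, "phase_kind": kind,
                                 "peak_N": 5000.0 + jitter * rng.normal()})
        return rows

    def test_single_repetition_has_nan_sd(self):
        rep = build_report(self._rows(1))
        assert np.isnan(rep["summary"][("peak_N", "std")]).all()
        assert np.allclose(rep["summary"][("peak_N", "mean")], 5000.0)

    def test_identical_repetitions_have_zero_sd(self):
        rep = build_report(self._rows(20))
        assert np.allclose(rep["summary"][("peak_N", "std")], 0.0)
        assert (rep["summary"][("peak_N", "count")] == 20).all()

    def test_empty_rows_rejected(self):
        with pytest.raises(LiftsimError):
            build_report([])
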