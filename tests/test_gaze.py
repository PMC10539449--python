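"""Gaze pipeline: frames, smoothing, I-DT segmentation, exclusion rules."""

import math

import numpy as np
import pandas as pd
import pytest

from racquetvr import agent as ag
from racquetvr import gaze as gz

FS = 120.0


def _gaze_from_angles(yaw_deg, pitch_deg, valid=None):
    yaw = np.radians(np.asarray(yaw_deg, dtype=float))
    pitch = np.radians(np.asarray(pitch_deg, dtype=float))
    n = len(yaw)
    t = np.arange(n) / FS
    g = np.column_stack([np.sin(yaw) * np.cos(pitch), np.sin(pitch),
                         np.cos(yaw) * np.cos(pitch)])
    return pd.DataFrame({
        "t": t, "gx": g[:, 0], "gy": g[:, 1], "gz": g[:, 2],
        "valid": np.ones(n, bool) if valid is None else np.asarray(valid, bool),
    })


def _head(n, yaw=0.0, pitch=0.0):
    t = np.arange(n) / 90.0
    return pd.DataFrame({
        "t": t, "hx": np.zeros(n), "hy": np.full(n, 1.6), "hz": np.zeros(n),
        "hyaw": np.full(n, yaw), "hpitch": np.full(n, pitch),
    })


def _ego(yaw, pitch, valid=None):
    n = len(yaw)
    t = np.arange(n) / FS
    return gz.EgocentricGaze(pd.DataFrame({
        "t": t, "yaw": np.asarray(yaw, float), "pitch": np.asarray(pitch, float),
        "valid": np.ones(n, bool) if valid is None else np.asarray(valid, bool),
    }))


class TestEgocentricConversion:
    def test_gaze_along_facing_is_origin(self):
        g = _gaze_from_angles([0.0] * 20, [0.0] * 20)
        ego = gz.to_egocentric(g, _head(20))
        np.testing.assert_allclose(ego.samples["yaw"], 0, atol=1e-9)
        np.testing.assert_allclose(ego.samples["pitch"], 0, atol=1e-9)

    def test_head_pitched_up_world_horizontal_gaze(self):
        g = _gaze_from_angles([0.0] * 20, [0.0] * 20)  # world-horizontal
        ego = gz.to_egocentric(g, _head(20, pitch=10.0))
        np.testing.assert_allclose(ego.samples["pitch"], -10.0, atol=1e-9)

    def test_random_orientations_match_rotation_matrix_oracle(self, rng):
        n = 100
        yaw_h = rng.uniform(-60, 60, n)
        pitch_h = rng.uniform(-40, 40, n)
        gvec = rng.normal(size=(n, 3))
        gvec /= np.linalg.norm(gvec, axis=1, keepdims=True)
        t = np.arange(n) / FS
        gdf = pd.DataFrame({"t": t, "gx": gvec[:, 0], "gy": gvec[:, 1],
                            "gz": gvec[:, 2], "valid": np.ones(n, bool)})
        head = pd.DataFrame({"t": t, "hx": 0.0, "hy": 1.6, "hz": 0.0,
                             "hyaw": yaw_h, "hpitch": pitch_h})
        ego = gz.to_egocentric(gdf, head)
        for i in range(0, n, 7):
            cy, sy = math.cos(math.radians(yaw_h[i])), math.sin(math.radians(yaw_h[i]))
            cp, sp = math.cos(math.radians(pitch_h[i])), math.sin(math.radians(pitch_h[i]))
            Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
            Rx = np.array([[1, 0, 0], [0, cp, sp], [0, -sp, cp]])
            d = (Ry @ Rx).T @ gvec[i]
            assert ego.samples["yaw"][i] == pytest.approx(
                math.degrees(math.atan2(d[0], d[2])), abs=1e-9)
            assert ego.samples["pitch"][i] == pytest.approx(
                math.degrees(math.atan2(d[1], math.hypot(d[0], d[2]))), abs=1e-9)

    def test_invalid_samples_propagate(self):
        valid = np.ones(20, bool)
        valid[3] = False
        g = _gaze_from_angles([0.0] * 20, [0.0] * 20, valid=valid)
        ego = gz.to_egocentric(g, _head(20))
        assert not ego.samples["valid"][3]


class TestSmoothing:
    def test_median_removes_single_sample_spike(self):
        yaw = np.zeros(240)
        yaw[120] = 30.0
        out = gz.smooth_gaze(_ego(yaw, np.zeros(240)))
        assert abs(out.samples["yaw"]).max() < 0.5

    def test_constant_trace_unchanged(self):
        out = gz.smooth_gaze(_ego(np.full(240, 5.0), np.full(240, -3.0)))
        np.testing.assert_allclose(out.samples["yaw"], 5.0, atol=1e-9)
        np.testing.assert_allclose(out.samples["pitch"], -3.0, atol=1e-9)

    def test_sinusoid_attenuation_matches_transfer_function(self):
        # zero-phase 2nd-order Butterworth: |H|^2 = 1/(1 + (f/15)^4)
        n = 2400
        t = np.arange(n) / FS
        f = 2.0
        yaw = 10.0 * np.sin(2 * np.pi * f * t)
        out = gz.smooth_gaze(_ego(yaw, np.zeros(n)))
        mid = out.samples["yaw"].to_numpy()[400:-400]
        gain = (mid.max() - mid.min()) / 20.0
        assert gain == pytest.approx(1.0 / (1.0 + (f / 15.0) ** 4), abs=0.01)

    def test_yaw_seam_is_handled_by_unwrapping(self):
        yaw = np.where(np.arange(240) % 2 == 0, 179.5, -179.5)
        out = gz.smooth_gaze(_ego(yaw, np.zeros(240)))
        # smoothing across the seam must stay near the seam, not average to 0
        mags = np.abs(out.samples["yaw"].to_numpy())
        assert (mags > 170).all()


def _bruteforce_idt(t, yaw, pitch, dmax=3.0, min_dur=0.1):
    """O(n^2) maximal-window re-implementation (independent oracle)."""
    def disp(i, j):
        best = 0.0
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                best = max(best, math.hypot(yaw[a] - yaw[b], pitch[a] - pitch[b]))
        return best

    out = []
    i, n = 0, len(t)
    while i < n:
        j = i
        while j + 1 < n and disp(i, j + 1) <= dmax:
            j += 1
        if t[j] - t[i] >= min_dur:
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


class TestFixationDetection:
    def test_constant_150ms_is_one_fixation(self):
        n = 19  # spans exactly 0.15 s at 120 Hz
        fx = gz.detect_fixations(_ego(np.zeros(n), np.zeros(n)))
        assert len(fx) == 1
        assert fx[0].duration == pytest.approx(0.15, abs=1e-9)

    def test_alternating_large_steps_yield_no_fixations(self):
        yaw = np.where(np.arange(120) % 2 == 0, 5.0, -5.0)
        assert gz.detect_fixations(_ego(yaw, np.zeros(120))) == []

    def test_random_walks_match_bruteforce_oracle(self, rng):
        for _ in range(60):
            n = 180
            yaw = np.cumsum(rng.normal(0, 0.6, n))
            pitch = np.cumsum(rng.normal(0, 0.6, n))
            t = np.arange(n) / FS
            got = gz.detect_fixations(_ego(yaw, pitch))
            want = _bruteforce_idt(t, yaw, pitch)
            assert len(got) == len(want)
            for f, (i, j) in zip(got, want):
                assert f.t_onset == pytest.approx(t[i], abs=1e-12)
                assert f.t_offset == pytest.approx(t[j], abs=1e-12)

    def test_emitted_fixations_satisfy_both_thresholds(self, rng):
        yaw = np.cumsum(rng.normal(0, 0.4, 400))
        pitch = np.cumsum(rng.normal(0, 0.4, 400))
        ego = _ego(yaw, pitch)
        for f in gz.detect_fixations(ego):
            assert f.duration >= 0.1
            sel = (ego.samples["t"] >= f.t_onset) & (ego.samples["t"] <= f.t_offset)
            assert gz._dispersion_pairwise(
                yaw[sel.to_numpy()], pitch[sel.to_numpy()]) <= 3.0 + 1e-9

    def test_translation_invariance(self, rng):
        yaw = np.cumsum(rng.normal(0, 0.5, 300))
        pitch = np.cumsum(rng.normal(0, 0.5, 300))
        a = gz.detect_fixations(_ego(yaw, pitch))
        b = gz.detect_fixations(_ego(yaw + 17.0, pitch - 8.0))
        assert [(f.t_onset, f.duration) for f in a] == [
            (f.t_onset, f.duration) for f in b]

    def test_bbox_metric_variant(self):
        # 2+2 deg box passes bbox<=3? (max-min yaw)+(max-min pitch)=4 > 3: no
        yaw = np.tile([0.0, 2.0], 30)
        pitch = np.tile([0.0, 2.0], 30)
        assert gz.detect_fixations(_ego(yaw, pitch), metric="bbox") == []
        assert len(gz.detect_fixations(_ego(yaw, pitch), metric="pairwise")) == 1


class TestExclusion:
    def test_long_contiguous_gap_excludes(self):
        valid = np.ones(600, bool)
        valid[100:118] = False  # 18 samples = 0.15 s
        excluded, reason = gz.exclude_trial(_ego(np.zeros(600), np.zeros(600), valid).samples)
        assert excluded and "lost" in reason

    def test_scattered_missing_fraction_excludes(self):
        valid = np.ones(600, bool)
        valid[::4] = False  # 25% missing, scattered
        excluded, reason = gz.exclude_trial(_ego(np.zeros(600), np.zeros(600), valid).samples)
        assert excluded and "fraction" in reason

    def test_boundary_values_are_retained(self):
        # exactly 0.100 s gap (12 samples at 120 Hz) and exactly 20% missing
        valid = np.ones(600, bool)
        valid[100:112] = False
        scattered = np.ones(600, bool)
        scattered[:240:2] = False  # 120/600 = 20%
        assert not gz.exclude_trial(
            _ego(np.zeros(600), np.zeros(600), valid).samples)[0]
        assert not gz.exclude_trial(
            _ego(np.zeros(600), np.zeros(600), scattered).samples)[0]

    def test_exclusion_is_monotone_in_missingness(self, rng):
        valid = rng.random(600) > 0.05
        base = _ego(np.zeros(600), np.zeros(600), valid).samples
        was_excluded = gz.exclude_trial(base)[0]
        worse = valid.copy()
        worse[rng.integers(0, 600, 80)] = False
        more = gz.exclude_trial(_ego(np.zeros(600), np.zeros(600), worse).samples)[0]
        assert more or not was_excluded


class TestBounceFixation:
    F = lambda self, onset, dur: gz.Fixation(onset, dur, 0.0, 0.0)

    def test_spanning_fixation_selected(self):
        fx = [self.F(0.5, 0.2), self.F(1.4, 0.4)]
        assert gz.bounce_fixation(fx, t_bounce=1.58) is fx[1]

    def test_immediately_prior_branch(self):
        fx = [self.F(0.9, 0.38)]  # ends 1.28, bounce 1.58: 0.3 s prior
        assert gz.bounce_fixation(fx, t_bounce=1.58) is fx[0]

    def test_prior_branch_respects_lookback(self):
        fx = [self.F(0.2, 0.2)]  # ends 1.18 s before the bounce
        assert gz.bounce_fixation(fx, t_bounce=1.58) is None

    def test_latest_onset_wins_among_intersecting(self):
        fx = [self.F(1.40, 0.12), self.F(1.55, 0.1)]
        assert gz.bounce_fixation(fx, t_bounce=1.58) is fx[1]

    def test_empty_list_gives_none(self):
        assert gz.bounce_fixation([], 1.58) is None


class TestAggregation:
    def _metrics(self, pitches, onsets=None, durs=None):
        out = []
        for i, p in enumerate(pitches):
            out.append(gz.GazeTrialMetrics(
                excluded=False, bounce_fix=gz.Fixation(1.3, 0.4, 0.0, p),
                onset_rel_launch=(onsets or [1.3] * len(pitches))[i],
                duration=(durs or [0.4] * len(pitches))[i], pitch=p))
        return out

    def test_identical_trials_zero_sd(self):
        agg = gz.aggregate_gaze(self._metrics([2.0] * 10))
        assert agg["fixation_pitch_sd"] == 0.0
        assert agg["fixation_pitch"] == 2.0

    def test_median_onset(self):
        agg = gz.aggregate_gaze(self._metrics([0, 0, 0], onsets=[1, 2, 10]))
        assert agg["fixation_onset"] == 2

    def test_insufficient_trials_missing(self):
        assert gz.aggregate_gaze(self._metrics([1.0])) is None

    def test_monte_carlo_sd_consistency(self, rng):
        # recovered pitch SD converges on the generating sigma
        sigma = 2.5
        agg = gz.aggregate_gaze(self._metrics(rng.normal(0, sigma, 4000)))
        assert agg["fixation_pitch_sd"] == pytest.approx(sigma, rel=0.05)


class TestPipelineRecovery:
    def test_noiseless_pitch_recovered_within_tenth_degree(
            self, noiseless_trial, traj_normal):
        m = gz.process_trial(noiseless_trial.gaze, noiseless_trial.motion,
                             t_bounce=traj_normal.t_bounce)
        assert not m.excluded and m.bounce_fix is not None
        assert abs(m.pitch - noiseless_trial.truth["pitch"]) < 0.1
        assert m.duration == pytest.approx(
            noiseless_trial.truth["fixation_duration"], abs=0.05)
        assert m.onset_rel_launch == pytest.approx(
            noiseless_trial.truth["fixation_onset"], abs=0.05)

    def test_injected_gap_excludes_trial(self, noiseless_trial, traj_normal):
        g = noiseless_trial.gaze.copy()
        g.loc[50:70, "valid"] = False
        m = gz.process_trial(g, noiseless_trial.motion,
                             t_bounce=traj_normal.t_bounce)
        assert m.excluded
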