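"""Tracking, trajectory extraction, change-point detection (with an
independent exhaustive-search oracle) and TMRM/ratio event ordering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import redoxhcs as rx
from redoxhcs.errors import ValidationError
from redoxhcs.kinetics import (
    RedoxEvent,
    Trajectory,
    detect_biphasic,
    extract_trajectories,
    order_events,
    track_nuclei,
)
from redoxhcs.quantify import ratio_image
from redoxhcs.segment import SegmentationParams, ring_rois, segment_nuclei, \
    subtract_background, LabelMap


def brute_force_changepoints(y: np.ndarray, min_seg: int = 3) -> RedoxEvent:
    """Naive exhaustive piecewise-constant fit with direct segment means."""
    y = np.asarray(y, dtype=float)
    n = len(y)

    def sse(a, b):
        seg = y[a:b]
        return float(((seg - seg.mean()) ** 2).sum())

    candidates = {0: (sse(0, n), ())}
    best = None
    for c in range(min_seg, n - min_seg + 1):
        r = sse(0, c) + sse(c, n)
        if best is None or r < best[0]:
            best = (r, (c,))
    candidates[1] = best
    best = None
    for c1 in range(min_seg, n - 2 * min_seg + 1):
        for c2 in range(c1 + min_seg, n - min_seg + 1):
            r = sse(0, c1) + sse(c1, c2) + sse(c2, n)
            if best is None or r < best[0]:
                best = (r, (c1, c2))
    candidates[2] = best

    scale = float(np.ptp(y))
    floor = n * (1e-12 * max(scale, 1e-30)) ** 2
    best_m, best_bic = 0, None
    for m, (rss, cps) in sorted(candidates.items()):
        bic = n * np.log(max(rss, floor) / n) + (2 * m + 1) * np.log(n)
        if best_bic is None or bic < best_bic - 1e-9:
            best_m, best_bic = m, bic
    rss, cps = candidates[best_m]
    bounds = [0, *cps, n]
    levels = [float(y[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]
    out = RedoxEvent(n_changepoints_detected=best_m)
    if best_m >= 1:
        out.t_surge = cps[0]
        out.level_baseline, out.level_surge = levels[0], levels[1]
    else:
        out.level_baseline = levels[0]
    if best_m == 2:
        out.t_secondary = cps[1]
        out.level_final = levels[2]
    return out


def _steps(levels, lengths):
    return np.concatenate([np.full(n, v) for v, n in zip(levels, lengths)])


class TestTrackNuclei:
    def _label_stack(self, n_frames, shift=0):
        base = np.zeros((64, 64), np.int32)
        base[10:18, 10:18] = 1
        base[40:48, 30:38] = 2
        return [np.roll(base, (shift * i, shift * i), axis=(0, 1))
                for i in range(n_frames)]

    def test_static_cells_yield_full_length_tracks(self):
        tracks = track_nuclei(self._label_stack(5), max_displacement_px=5)
        assert len(tracks) == 2
        assert all(t.start_frame == 0 and t.end_frame == 4 for t in tracks)

    def test_drifting_cells_keep_identity(self):
        tracks = track_nuclei(self._label_stack(8, shift=2),
                              max_displacement_px=5)
        assert len(tracks) == 2
        for t in tracks:
            assert len(set(t.labels)) == 1  # same label throughout

    def test_vanishing_cell_terminates_track(self):
        stack = self._label_stack(6)
        for f in range(3, 6):
            stack[f] = np.where(stack[f] == 2, 0, stack[f])
        tracks = track_nuclei(stack, max_displacement_px=5)
        ends = sorted(t.end_frame for t in tracks)
        assert ends == [2, 5]

    def test_displacement_limit_breaks_links(self):
        tracks = track_nuclei(self._label_stack(4, shift=8),
                              max_displacement_px=5)
        # every frame starts fresh tracks: nothing within reach
        assert all(t.end_frame == t.start_frame for t in tracks)

    def test_identity_preservation_rate_on_simulated_drift(self):
        rng = np.random.default_rng(0)
        base = np.zeros((128, 128), np.int32)
        centers = [(16 + 32 * i, 16 + 32 * j) for i in range(4)
                   for j in range(4)]
        for lab, (r, c) in enumerate(centers, 1):
            base[r - 4:r + 4, c - 4:c + 4] = lab
        stack = [base]
        for _ in range(9):
            dy, dx = rng.integers(-2, 3, 2)
            stack.append(np.roll(stack[-1], (dy, dx), axis=(0, 1)))
        tracks = track_nuclei(stack, max_displacement_px=6)
        full = [t for t in tracks if t.start_frame == 0 and t.end_frame == 9
                and len(set(t.labels)) == 1]
        assert len(full) / 16 >= 0.99

    def test_needs_at_least_two_frames(self):
        with pytest.raises(ValidationError):
            track_nuclei([np.zeros((8, 8), np.int32)])


class TestExtractTrajectories:
    def test_constant_scene_gives_constant_trajectory(self):
        labels = np.zeros((32, 32), np.int32)
        labels[8:16, 8:16] = 1
        rings = [LabelMap(labels, kind="ring")] * 4
        ratios = [ratio_image(np.full((32, 32), 2.0), np.full((32, 32), 4.0),
                              1.0)] * 4
        tracks = track_nuclei([labels] * 4, 5)
        (traj,) = extract_trajectories(tracks, ratios, rings)
        np.testing.assert_allclose(traj.ratio, 0.5)

    def test_length_one_track_is_fine(self):
        labels = np.zeros((16, 16), np.int32)
        labels[4:8, 4:8] = 1
        empty = np.zeros((16, 16), np.int32)
        tracks = track_nuclei([labels, empty], 5)
        ratios = [ratio_image(np.full((16, 16), 1.0), np.full((16, 16), 2.0),
                              0.5)] * 2
        trajs = extract_trajectories(tracks, ratios, [labels, empty])
        assert len(trajs) == 1 and len(trajs[0]) == 1

    def test_end_to_end_ratio_recovery_from_rendered_timelapse(self, cal):
        # one field re-rendered per frame with every cell following the
        # biphasic curve; same seed keeps geometry fixed across frames
        k = rx.KineticParams(t_surge=3, t_release=6, t_secondary=9,
                             trajectory_noise_sd=0.0)
        frames = range(12)
        true_r = rx.piecewise_ratio(k, np.arange(12))
        nuclei, rings, ratios, truths = [], [], [], []
        params = SegmentationParams()
        for t in frames:
            f_t = float(cal.oxidized_fraction_for_ratio(true_r[t]))
            scene = rx.SceneSpec(n_cells=8, field_shape=(160, 160),
                                 min_spacing_px=40.0, oxidized_fraction=f_t)
            # time-lapse acquisition: longer exposure than plate screening
            fimg, truth = rx.generate_field(
                scene, cal, rx.NoiseSpec(photon_scale=150.0), seed=31)
            nuc = segment_nuclei(subtract_background(
                np.asarray(fimg.channels["nuclear"], float)), params)
            nuclei.append(nuc)
            rings.append(ring_rois(nuc, params))
            ratios.append(ratio_image(
                subtract_background(np.asarray(fimg.channels["ex405"], float)),
                subtract_background(np.asarray(fimg.channels["ex488"], float)),
            ))
        tracks = track_nuclei(nuclei, 5)
        trajs = extract_trajectories(tracks, ratios, rings)
        full = [tr for tr in trajs if len(tr) == 12]
        assert len(full) >= 6
        for tr in full:
            rel = np.abs(tr.ratio - true_r) / true_r
            assert np.nanmax(rel) < 0.10
            assert np.nanmedian(rel) < 0.05


class TestDetectBiphasic:
    def test_noiseless_biphasic_recovered_exactly(self):
        y = _steps([0.4, 0.65, 1.2], [20, 20, 20])
        ev = detect_biphasic(y)
        assert ev.n_changepoints_detected == 2
        assert (ev.t_surge, ev.t_secondary) == (20, 40)
        assert ev.level_baseline == pytest.approx(0.4)
        assert ev.level_surge == pytest.approx(0.65)
        assert ev.level_final == pytest.approx(1.2)

    def test_constant_trajectory_has_no_changepoints(self):
        ev = detect_biphasic(np.full(40, 0.5))
        assert ev.n_changepoints_detected == 0
        assert ev.level_baseline == pytest.approx(0.5)

    def test_single_step_detected_as_one_changepoint(self):
        ev = detect_biphasic(_steps([0.4, 1.2], [15, 15]))
        assert ev.n_changepoints_detected == 1
        assert ev.t_surge == 15

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValidationError, match="short"):
            detect_biphasic(np.ones(8), min_segment_len=3)

    @pytest.mark.parametrize("case", range(24))
    def test_equals_exhaustive_search_oracle(self, case):
        rng = np.random.default_rng(case)
        n = int(rng.integers(20, 101))
        m_true = case % 3
        cps = np.sort(rng.choice(np.arange(5, n - 5), size=m_true,
                                 replace=False)) if m_true else []
        levels = np.cumsum(rng.uniform(0.2, 1.0, m_true + 1)) + 0.3
        bounds = [0, *[int(c) for c in cps], n]
        y = np.concatenate([
            np.full(b - a, lv) for a, b, lv in
            zip(bounds[:-1], bounds[1:], levels)
        ]) + rng.normal(0, 0.05, n)
        got = detect_biphasic(y)
        want = brute_force_changepoints(y)
        assert got.n_changepoints_detected == want.n_changepoints_detected
        assert got.t_surge == want.t_surge
        assert got.t_secondary == want.t_secondary
        for a, b in ((got.level_baseline, want.level_baseline),
                     (got.level_surge, want.level_surge),
                     (got.level_final, want.level_final)):
            if a is None:
                assert b is None
            else:
                assert a == pytest.approx(b)

    @given(scale=st.floats(0.1, 20.0), shift=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_changepoints_invariant_to_affine_transform(self, scale, shift):
        rng = np.random.default_rng(7)
        y = _steps([0.4, 0.65, 1.2], [15, 15, 15]) + rng.normal(0, 0.03, 45)
        a = detect_biphasic(y)
        b = detect_biphasic(scale * y + shift)
        assert (a.t_surge, a.t_secondary) == (b.t_surge, b.t_secondary)
        assert a.n_changepoints_detected == b.n_changepoints_detected

    def test_noisy_changepoints_localized_within_two_frames(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(50):
            y = _steps([0.4, 0.65, 1.2], [20, 20, 20]) + \
                rng.normal(0, 0.04, 60)
            ev = detect_biphasic(y)
            if (ev.n_changepoints_detected == 2
                    and abs(ev.t_surge - 20) <= 2
                    and abs(ev.t_secondary - 40) <= 2):
                hits += 1
        assert hits >= 45


class TestOrderEvents:
    def _traj(self, ratio, tmrm):
        return Trajectory(track_id=0, t=np.arange(len(ratio)), ratio=ratio,
                          tmrm=tmrm)

    def test_lag_arithmetic(self):
        n = 30
        ratio = np.full(n, 0.4)
        ratio[:5] += np.array([0.001, -0.001, 0.0005, -0.0005, 0.0])
        ratio[14:] = 1.2  # sustained rise from frame 14
        tmrm = np.ones(n)
        tmrm[10:] = 0.2  # sustained loss from frame 10
        assert order_events(self._traj(ratio, tmrm)) == 4

    def test_tmrm_never_lost_gives_missing_lag(self):
        n = 30
        ratio = np.full(n, 0.4) + np.linspace(0, 0.001, n)
        ratio[20:] = 1.5
        tmrm = np.ones(n)
        assert order_events(self._traj(ratio, tmrm)) is None

    def test_requires_tmrm_channel(self):
        with pytest.raises(ValidationError):
            order_events(Trajectory(track_id=0, t=np.arange(10),
                                    ratio=np.ones(10)))

    def test_simulated_death_shows_tmrm_loss_first(self):
        k = rx.KineticParams()  # default: TMRM half-loss precedes the surge
        lags = []
        for i in range(100):
            traj, _ = rx.simulate_redox_trajectory(k, 80, seed=13, track_id=i)
            lag = order_events(traj)
            if lag is not None:
                lags.append(lag)
        assert len(lags) >= 95
        assert np.mean(np.array(lags) > 0) >= 0.95
        assert np.median(lags) > 0
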