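"""Tracker stages: background, detection, linking, median trace, unit
conversion — validated closed-loop against the renderer's ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stampede.errors import CalibrationWarning, InsufficientDataError
from stampede.simulate import ArenaGeometry, ImagingParams, TrajectorySet, render_frames
from stampede.track import (
    Detection,
    detect_flies,
    detect_stack,
    estimate_background,
    link_tracks,
    median_centroid_trace,
    tracks_to_mm,
)
from stampede.video import FrameStack


def _scene(xs_mm, ys_mm=None, noise=0.0, seed=0):
    """Render one frame with flies at the given x positions (mm)."""
    arena = ArenaGeometry()
    ys = ys_mm if ys_mm is not None else [2.5] * len(xs_mm)
    trajs = TrajectorySet(
        t_s=[0.0],
        x_mm=[[x] for x in xs_mm],
        y_mm=[[y] for y in ys],
        fps=25.0,
        fly_ids=tuple(range(len(xs_mm))),
        arena=arena,
    )
    img = ImagingParams(noise_sigma=noise, seed=seed)
    return render_frames(trajs, img), img


class TestBackground:
    def test_constant_stack_background_equals_any_frame(self):
        frames = np.full((12, 8, 16), 200, dtype=np.uint8)
        stack = FrameStack(frames, fps=25.0, px_per_mm=4.0)
        bg = estimate_background(stack, stride=2)
        assert np.array_equal(bg.image, frames[0].astype(float))
        assert bg.n_samples == 6

    def test_median_removes_a_moving_fly(self):
        """A fly occupying each pixel in a minority of frames leaves no
        trace in the temporal median."""
        arena = ArenaGeometry()
        xs = np.linspace(10, 140, 9)
        trajs = TrajectorySet(
            t_s=np.arange(9) / 25.0,
            x_mm=xs[None, :],
            y_mm=np.full((1, 9), 2.5),
            fps=25.0,
            fly_ids=(0,),
            arena=arena,
        )
        img = ImagingParams(noise_sigma=0.0)
        stack = render_frames(trajs, img)
        bg = estimate_background(stack, stride=1)
        assert np.all(bg.image == img.bg_level)

    def test_too_few_sampled_frames_raises(self):
        frames = np.zeros((5, 4, 4), dtype=np.uint8)
        stack = FrameStack(frames, fps=25.0, px_per_mm=4.0)
        with pytest.raises(InsufficientDataError):
            estimate_background(stack, stride=3)


class TestDetection:
    def test_frame_equal_to_background_yields_nothing(self):
        stack, img = _scene([40.0])
        bg = estimate_background(
            FrameStack(np.full((3, *stack.frame_shape), img.bg_level, np.uint8),
                       fps=25.0, px_per_mm=4.0), stride=1)
        assert detect_flies(np.full(stack.frame_shape, img.bg_level, np.uint8), bg) == []

    def test_single_silhouette_centroid_within_half_pixel(self):
        stack, img = _scene([40.25])
        bg_stack = FrameStack(
            np.full((3, *stack.frame_shape), img.bg_level, np.uint8),
            fps=25.0, px_per_mm=4.0)
        bg = estimate_background(bg_stack, stride=1)
        dets = detect_flies(stack.frames[0], bg)
        assert len(dets) == 1
        expected_x = img.margin_px + 40.25 * img.px_per_mm
        expected_y = img.margin_px + 2.5 * img.px_per_mm
        assert abs(dets[0].x_px - expected_x) < 0.5
        assert abs(dets[0].y_px - expected_y) < 0.5

    def test_two_well_separated_silhouettes_give_two_detections(self):
        img = ImagingParams()
        sep_mm = (4 * img.blob_sigma_px + 1) / img.px_per_mm  # just over 4 sigma
        stack, _ = _scene([60.0, 60.0 + sep_mm])
        bg_stack = FrameStack(
            np.full((3, *stack.frame_shape), img.bg_level, np.uint8),
            fps=25.0, px_per_mm=4.0)
        bg = estimate_background(bg_stack, stride=1)
        assert len(detect_flies(stack.frames[0], bg)) == 2

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        xs=st.lists(
            st.floats(min_value=10.0, max_value=140.0), min_size=1, max_size=4
        ).filter(lambda v: all(abs(a - b) > 5.0 for i, a in enumerate(v)
                               for b in v[i + 1:])),
    )
    def test_raising_threshold_never_adds_detections(self, xs):
        """For well-separated unimodal silhouettes the detection count is
        monotone non-increasing in the threshold."""
        stack, img = _scene(xs)
        bg_stack = FrameStack(
            np.full((3, *stack.frame_shape), img.bg_level, np.uint8),
            fps=25.0, px_per_mm=4.0)
        bg = estimate_background(bg_stack, stride=1)
        counts = [
            len(detect_flies(stack.frames[0], bg, threshold=th))
            for th in (20.0, 50.0, 90.0, 130.0, 160.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestLinking:
    def test_single_fly_track_reproduces_detections(self):
        dets = [[Detection(10.0 + f, 5.0, 20, 100.0)] for f in range(10)]
        linked = link_tracks(dets, gate_px=5.0)
        assert len(linked) == 1
        tr = linked.tracks[0]
        assert np.array_equal(tr.frames, np.arange(10))
        assert np.allclose(tr.x_px, 10.0 + np.arange(10))
        assert not tr.interpolated.any()

    def test_gap_of_one_frame_is_interpolated_and_flagged(self):
        dets = [[Detection(float(f), 5.0, 20, 100.0)] for f in range(6)]
        dets[3] = []  # missed detection
        linked = link_tracks(dets, gate_px=5.0, max_gap=2)
        assert len(linked) == 1
        tr = linked.tracks[0]
        assert np.array_equal(tr.frames, np.arange(6))
        assert tr.x_px[3] == pytest.approx(3.0)
        assert list(tr.interpolated) == [False, False, False, True, False, False]

    def test_gap_beyond_max_gap_starts_a_new_track(self):
        dets = [[Detection(float(f), 5.0, 20, 100.0)] for f in range(10)]
        dets[3] = dets[4] = dets[5] = []
        linked = link_tracks(dets, gate_px=5.0, max_gap=2)
        assert len(linked) == 2

    def test_displacement_above_gate_is_never_linked(self):
        dets = [[Detection(0.0, 0.0, 20, 100.0)], [Detection(50.0, 0.0, 20, 100.0)]]
        linked = link_tracks(dets, gate_px=10.0, max_gap=0)
        assert len(linked) == 2

    def test_every_track_point_is_a_detection_or_flagged(self):
        """Detection conservation on a closed-loop two-fly scene."""
        rng = np.random.default_rng(4)
        dets = []
        for f in range(50):
            frame = [
                Detection(20.0 + 0.5 * f + rng.normal(0, 0.1), 5.0, 20, 100.0),
                Detection(200.0 - 0.5 * f + rng.normal(0, 0.1), 5.0, 20, 100.0),
            ]
            if f % 17 == 5:
                frame = frame[:1]  # drop the second fly occasionally
            dets.append(frame)
        linked = link_tracks(dets, gate_px=5.0, max_gap=2)
        claimed = {}
        for tr in linked.tracks:
            for f, x, interp in zip(tr.frames, tr.x_px, tr.interpolated):
                if interp:
                    continue
                match = [d for d in dets[f] if d.x_px == x]
                assert len(match) == 1
                key = (f, match[0].x_px)
                assert key not in claimed  # one detection claimed at most once
                claimed[key] = tr.track_id


class TestMedianTrace:
    def test_median_of_three_detections(self):
        dets = [[Detection(10.0, 1.0, 9, 50.0), Detection(20.0, 2.0, 9, 50.0),
                 Detection(100.0, 3.0, 9, 50.0)]]
        trace = median_centroid_trace(dets)
        assert trace[0, 0] == 20.0
        assert trace[0, 1] == 2.0

    def test_empty_frame_yields_nan_not_zero(self):
        trace = median_centroid_trace([[], [Detection(5.0, 5.0, 9, 50.0)]])
        assert np.isnan(trace[0]).all()
        assert trace[1, 0] == 5.0

    @settings(derandomize=True, max_examples=50)
    @given(
        xs=st.lists(st.floats(min_value=0, max_value=500), min_size=3, max_size=9),
        shift=st.floats(min_value=-1e6, max_value=1e6),
    )
    def test_median_robust_to_minority_perturbation(self, xs, shift):
        """Perturbing fewer than half of the detections cannot push the
        median outside the span of the originals."""
        k = (len(xs) - 1) // 2
        perturbed = [x + shift for x in xs[:k]] + xs[k:]
        dets = [[Detection(x, 0.0, 9, 50.0) for x in perturbed]]
        med = median_centroid_trace(dets)[0, 0]
        assert min(xs) <= med <= max(xs)


class TestUnitConversion:
    def _one_track(self, xs_px, frames=None):
        from stampede.track import LinkedTracks, Track

        n = len(xs_px)
        return LinkedTracks(tracks=(Track(
            track_id=0,
            frames=np.asarray(frames if frames is not None else range(n)),
            x_px=np.asarray(xs_px, float),
            y_px=np.full(n, 10.0),
            interpolated=np.zeros(n, bool),
        ),))

    def test_pixel_to_mm_arithmetic(self):
        tracks = self._one_track([608.0])
        trajs = tracks_to_mm(tracks, px_per_mm=4.0, arena_origin_px=0.0, fps=25.0)
        assert trajs.x_mm[0, 0] == pytest.approx(152.0)

    def test_origin_shift_translates_positions(self):
        tracks = self._one_track([100.0, 104.0])
        a = tracks_to_mm(tracks, px_per_mm=4.0, arena_origin_px=0.0, fps=25.0)
        b = tracks_to_mm(tracks, px_per_mm=4.0, arena_origin_px=8.0, fps=25.0)
        assert np.allclose(a.x_mm - b.x_mm, 2.0)

    def test_out_of_arena_positions_warn(self):
        tracks = self._one_track([5000.0])
        with pytest.warns(CalibrationWarning):
            tracks_to_mm(tracks, px_per_mm=4.0, arena_origin_px=0.0, fps=25.0)


class TestClosedLoop:
    def _recover(self, trajs, stack, noise_seedless=True):
        dets = detect_stack(stack, bg_stride=5)
        linked = link_tracks(dets, gate_px=10.0, max_gap=2)
        rec = tracks_to_mm(
            linked, px_per_mm=stack.px_per_mm, arena_origin_px=stack.origin_px,
            fps=stack.fps)
        return linked, rec

    def test_two_flies_recovered_without_identity_swaps(self, two_fly_scene):
        trajs, stack = two_fly_scene
        linked, rec = self._recover(trajs, stack)
        assert len(linked) == 2
        for i in range(2):
            # match by initial position, then require agreement throughout
            j = int(np.argmin(np.abs(trajs.x_mm[:, 0] - rec.x_mm[i, 0])))
            err_px = (rec.x_mm[i] - trajs.x_mm[j]) * stack.px_per_mm
            assert np.sum(np.abs(err_px) > 4.0) == 0  # no swapped frames
            rmse = np.sqrt(np.nanmean(err_px**2))
            assert rmse < 0.5

    def test_recovery_with_pixel_noise(self):
        from conftest import make_two_fly_trajectories

        trajs = make_two_fly_trajectories(seed_a=7, seed_b=8, duration_s=10.0)
        stack = render_frames(trajs, ImagingParams(noise_sigma=5.0, seed=1))
        linked, rec = self._recover(trajs, stack)
        assert len(linked) == 2
        for i in range(2):
            j = int(np.argmin(np.abs(trajs.x_mm[:, 0] - rec.x_mm[i, 0])))
            err_px = (rec.x_mm[i] - trajs.x_mm[j]) * stack.px_per_mm
            rmse = np.sqrt(np.nanmean(err_px**2))
            assert rmse < 1.5
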