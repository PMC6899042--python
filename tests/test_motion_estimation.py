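import numpy as np
import pytest

from cardiomvp import (
    BlockMatchConfig,
    FrameSequence,
    ROI,
    best_match,
    compute_motion_field,
    mae,
    mean_speed_trace,
)
from cardiomvp.motion_estimation import MotionField
from tests.conftest import smooth_texture, translating_sequence


def brute_force_mae(cur_block, prev_block, normalized=True):
    """Independent double-loop oracle for the matching criterion."""
    total = 0.0
    n_rows, n_cols = cur_block.shape
    for m in range(n_rows):
        for n in range(n_cols):
            total += abs(float(cur_block[m, n]) - float(prev_block[m, n]))
    return total / (n_rows * n_cols) if normalized else total


def exhaustive_best_match(cur, prev, origin, N, w):
    """Independent triple-loop search with the same tie-break rule."""
    r, c = origin
    block = cur[r : r + N, c : c + N].astype(float)
    best = None
    for i in range(-w, w + 1):
        for j in range(-w, w + 1):
            ref = prev[r + i : r + i + N, c + j : c + j + N].astype(float)
            value = np.abs(block - ref).sum()
            key = (value, i * i + j * j, i, j)
            if best is None or key < best[0]:
                best = (key, (i, j))
    return best[1]


class TestMae:
    def test_identical_tiles_give_zero(self, rng):
        tile = smooth_texture(rng, (16, 16))
        assert mae(tile, tile) == 0.0

    def test_constant_offset(self):
        a = np.zeros((2, 2))
        b = np.full((2, 2), 10.0)
        assert mae(a, b, normalized=True) == 10.0
        assert mae(a, b, normalized=False) == 40.0

    def test_matches_double_loop_oracle(self, rng):
        a = rng.uniform(0, 255, (4, 4))
        b = rng.uniform(0, 255, (4, 4))
        assert mae(a, b) == pytest.approx(brute_force_mae(a, b), rel=1e-12)
        assert mae(a, b, normalized=False) == pytest.approx(
            brute_force_mae(a, b, normalized=False), rel=1e-12
        )

    def test_symmetric(self, rng):
        a = rng.uniform(0, 255, (8, 8))
        b = rng.uniform(0, 255, (8, 8))
        assert mae(a, b) == mae(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            mae(np.zeros((4, 4)), np.zeros((5, 5)))


class TestBestMatch:
    def test_static_scene_gives_zero_offset(self, rng):
        frame = smooth_texture(rng)
        cfg = BlockMatchConfig()
        di, dj, value = best_match(frame, frame, (24, 24), cfg)
        assert (di, dj) == (0.0, 0.0) and value == 0.0

    def test_integer_shift_recovered(self, rng):
        seq = translating_sequence(rng, (2, -1), n_frames=2)
        cfg = BlockMatchConfig(subpixel=False)
        di, dj, _ = best_match(seq.frames[1], seq.frames[0], (24, 24), cfg)
        # matching offset is the negated scene displacement
        assert (-di, -dj) == (2.0, -1.0)

    def test_equals_exhaustive_search_on_many_random_instances(self, rng):
        """Integer-mode argmin is identical to an independent triple-loop search."""
        cfg = BlockMatchConfig(subpixel=False)
        for _ in range(120):
            prev = rng.integers(0, 256, (32, 32)).astype(np.uint8)
            cur = rng.integers(0, 256, (32, 32)).astype(np.uint8)
            di, dj, _ = best_match(cur, prev, (8, 8), cfg)
            assert (di, dj) == exhaustive_best_match(cur, prev, (8, 8), 16, 4)

    def test_search_window_bounds_enforced(self, rng):
        frame = smooth_texture(rng)
        with pytest.raises(ValueError, match="search window"):
            best_match(frame, frame, (2, 24), BlockMatchConfig())

    def test_tie_break_prefers_zero_motion(self):
        flat = np.full((32, 32), 100, dtype=np.uint8)
        di, dj, _ = best_match(flat, flat, (8, 8), BlockMatchConfig(subpixel=False))
        assert (di, dj) == (0.0, 0.0)

    def test_subpixel_stays_within_half_pixel_of_integer_minimum(self, rng):
        seq = translating_sequence(rng, (1, 0), n_frames=2)
        int_cfg = BlockMatchConfig(subpixel=False)
        sub_cfg = BlockMatchConfig(subpixel=True)
        di0, dj0, _ = best_match(seq.frames[1], seq.frames[0], (24, 24), int_cfg)
        di1, dj1, _ = best_match(seq.frames[1], seq.frames[0], (24, 24), sub_cfg)
        assert abs(di1 - di0) <= 0.5 and abs(dj1 - dj0) <= 0.5


class TestComputeMotionField:
    def test_static_video_gives_identically_zero_field(self, rng):
        frame = smooth_texture(rng)
        seq = FrameSequence(
            np.repeat(frame[None], 10, axis=0), frame_rate=150.0, pixel_size=0.5
        )
        field = compute_motion_field(seq, ROI(0, 0, 64, 64))
        assert np.all(field.vectors == 0.0)
        assert field.n_transitions == 9

    def test_uniform_translation_recovered_at_all_grid_points(self, rng):
        seq = translating_sequence(rng, (1, 0), n_frames=4)
        field = compute_motion_field(seq, ROI(0, 0, 64, 64), BlockMatchConfig(subpixel=False))
        np.testing.assert_array_equal(field.vectors[..., 0], 0.0)  # x
        np.testing.assert_array_equal(field.vectors[..., 1], 1.0)  # y

    def test_grid_count_arithmetic(self, rng):
        # 64x64 frame, N=16, w=4: block centers r with r-8-4 >= 0 and
        # r-8+16+4 <= 64 -> r in [12, 52]; stride-4 grid points {12,...,52}
        seq = translating_sequence(rng, (0, 0), n_frames=2)
        field = compute_motion_field(seq, ROI(0, 0, 64, 64))
        assert field.grid_rows.tolist() == list(range(12, 53, 4))
        assert field.vectors.shape == (1, 11, 11, 2)
        assert field.n_dropped_grid_points > 0

    def test_matches_best_match_at_every_grid_point(self, rng):
        prev = smooth_texture(rng)
        cur = smooth_texture(rng)
        seq = FrameSequence(np.stack([prev, cur]), frame_rate=150.0, pixel_size=0.5)
        for cfg in (BlockMatchConfig(subpixel=False), BlockMatchConfig(subpixel=True)):
            field = compute_motion_field(seq, ROI(0, 0, 64, 64), cfg)
            for a, r in enumerate(field.grid_rows):
                for b, c in enumerate(field.grid_cols):
                    di, dj, _ = best_match(cur, prev, (r - 8, c - 8), cfg)
                    np.testing.assert_allclose(
                        field.vectors[0, a, b], [-dj, -di], atol=1e-12
                    )

    def test_too_small_roi_rejected(self, rng):
        seq = translating_sequence(rng, (0, 0), n_frames=2)
        with pytest.raises(ValueError, match="ROI too small"):
            compute_motion_field(seq, ROI(0, 0, 4, 4))


class TestMeanSpeedTrace:
    def test_zero_field_gives_zero_trace(self):
        field = MotionField(
            vectors=np.zeros((5, 3, 3, 2)),
            grid_rows=np.arange(3),
            grid_cols=np.arange(3),
            transition_times=np.arange(1, 6) / 150.0,
        )
        trace = mean_speed_trace(field, 150.0, 0.5)
        assert np.all(trace.speeds == 0.0)

    def test_uniform_field_calibration(self):
        vectors = np.zeros((2, 4, 4, 2))
        vectors[..., 0] = 3.0
        vectors[..., 1] = 4.0
        field = MotionField(vectors, np.arange(4), np.arange(4), np.array([1 / 150, 2 / 150]))
        trace = mean_speed_trace(field, 150.0, 0.5)
        np.testing.assert_allclose(trace.speeds, 375.0)  # 5 px/frame * 0.5 * 150

    def test_matches_direct_recomputation(self, rng):
        vectors = rng.normal(0, 2, size=(3, 5, 6, 2))
        field = MotionField(vectors, np.arange(5), np.arange(6), np.arange(1, 4) / 100.0)
        trace = mean_speed_trace(field, 100.0, 0.65)
        expected = [
            np.mean([np.hypot(*vectors[t, a, b][::-1]) for a in range(5) for b in range(6)])
            * 0.65
            * 100.0
            for t in range(3)
        ]
        np.testing.assert_allclose(trace.speeds, expected, rtol=1e-12)


class TestFieldProperties:
    def test_calibration_linearity(self, rng):
        seq = translating_sequence(rng, (1, 1), n_frames=3)
        field = compute_motion_field(seq, ROI(0, 0, 64, 64))
        t1 = mean_speed_trace(field, 150.0, 0.5)
        t2 = mean_speed_trace(field, 150.0, 1.0)
        np.testing.assert_allclose(t2.speeds, 2.0 * t1.speeds, rtol=1e-12)

    def test_rotation_invariance_of_mean_speed(self, rng):
        """Rotating the whole scene by 90 deg leaves the speed trace unchanged."""
        seq = translating_sequence(rng, (1, 0), n_frames=4)
        rot = FrameSequence(
            np.stack([np.rot90(f) for f in seq.frames]),
            frame_rate=seq.frame_rate,
            pixel_size=seq.pixel_size,
        )
        cfg = BlockMatchConfig(subpixel=False)
        roi = ROI(0, 0, 64, 64)
        trace = mean_speed_trace(
            compute_motion_field(seq, roi, cfg), seq.frame_rate, seq.pixel_size
        )
        trace_rot = mean_speed_trace(
            compute_motion_field(rot, roi, cfg), seq.frame_rate, seq.pixel_size
        )
        np.testing.assert_allclose(trace_rot.speeds, trace.speeds, rtol=1e-9)

    def test_magnitude_bound(self, rng):
        prev = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        cur = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        seq = FrameSequence(np.stack([prev, cur]), frame_rate=150.0, pixel_size=0.5)
        field = compute_motion_field(seq, ROI(0, 0, 64, 64))
        assert np.all(np.abs(field.vectors) <= 4.5)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [dict(N=1), dict(w=0), dict(grid_stride=0), dict(grid_stride=17)])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BlockMatchConfig(**kwargs)
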