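"""Block-matching motion estimation with the mean-absolute-error criterion.

Each frame is divided into square N x N blocks.  For a maximum displacement of
w pixels per frame, the block in the current frame is matched against the
block at every integer offset (i, j), |i|,|j| <= w, in the previous frame —
a search window of width N + 2w — and the offset minimising the mean absolute
error (MAE)

    MAE(i, j) = (1/N^2) * sum_m sum_n | f_t(m, n) - f_{t-1}(m+i, n+j) |

is the match.  Defaults are N = 16 and w = 4, with one vector for every
4 x 4 pixels inside the region of interest.  The stored motion vector is the
*negated* matching offset, i.e. the displacement of scene content from the
previous to the current frame; downstream speeds only use the magnitude, which
is convention-independent.

Ties at equal MAE go to the offset with the smallest Euclidean norm, then to
row-major order — deterministic, and biased toward "no motion".

Sub-pixel refinement (on by default, ``subpixel=False`` restores the pure
integer search) fits a parabola per axis through the *squared* MAE at offsets
-1/0/+1 around the integer minimum.  Near perfect alignment the MAE of a
smoothly textured scene grows linearly with |misalignment|, so the squared
MAE is locally quadratic and its parabola vertex is an asymptotically unbiased
sub-pixel estimate; a parabola on the raw MAE (a V-shaped cost) systematically
pulls the estimate toward the integer grid.  Refinement is only applied when
the integer minimum is interior to the search range, the parabola is convex
and the minimum is not an exact (zero-error) match, and the refined component
is clamped to ±(w + 0.5).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .beat_analysis import VelocityTrace
from .video_io import ROI, FrameSequence

__all__ = [
    "BlockMatchConfig",
    "MotionField",
    "mae",
    "best_match",
    "compute_motion_field",
    "mean_speed_trace",
]


@dataclasses.dataclass(frozen=True)
class BlockMatchConfig:
    """Parameters of the block-matching search.

    N : block edge length in pixels.
    w : maximum displacement per frame in pixels (search window N + 2w wide).
    grid_stride : spacing of the vector grid inside the ROI, in pixels.
    subpixel : per-axis parabolic refinement of the integer minimum.
    mae_normalized : divide the absolute-difference sum by N^2.  The argmin —
        and therefore every vector — is unaffected; only reported MAE values
        change scale.
    """

    N: int = 16
    w: int = 4
    grid_stride: int = 4
    subpixel: bool = True
    mae_normalized: bool = True

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if not 1 <= self.grid_stride <= self.N:
            raise ValueError("grid_stride must lie in [1, N]")


@dataclasses.dataclass
class MotionField:
    """Motion vectors on a regular grid for every consecutive frame pair.

    vectors : (transitions, grid_rows, grid_cols, 2) array of per-frame
        displacements in pixels; component 0 is x (column), component 1 is y
        (row).  transitions = frame count - 1.
    grid_rows, grid_cols : pixel coordinates (block centers) of the grid.
    transition_times : seconds, stamped at the later frame of each pair.
    n_dropped_grid_points : requested grid points excluded because their block
        or search window would leave the frame.
    """

    vectors: np.ndarray
    grid_rows: np.ndarray
    grid_cols: np.ndarray
    transition_times: np.ndarray
    n_dropped_grid_points: int = 0

    @property
    def n_transitions(self) -> int:
        return self.vectors.shape[0]

    @property
    def speeds_px(self) -> np.ndarray:
        """Vector magnitudes sqrt(x^2 + y^2), pixels/frame."""
        return np.sqrt((self.vectors**2).sum(axis=-1))


def mae(block_current: np.ndarray, block_previous: np.ndarray, normalized: bool = True) -> float:
    """Mean absolute error between two equally shaped intensity tiles."""
    a = np.asarray(block_current, dtype=np.float64)
    b = np.asarray(block_previous, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"block shapes differ: {a.shape} vs {b.shape}")
    total = float(np.abs(a - b).sum())
    return total / a.size if normalized else total


def _offset_priority(w: int) -> np.ndarray:
    """Flat indices into the (2w+1, 2w+1) offset grid in tie-break order."""
    side = 2 * w + 1
    offs = [(i, j) for i in range(-w, w + 1) for j in range(-w, w + 1)]
    order = sorted(range(len(offs)), key=lambda k: (offs[k][0] ** 2 + offs[k][1] ** 2, offs[k]))
    return np.asarray(order, dtype=np.intp).reshape(side * side)


def _refine_axis(m_minus: np.ndarray, m_zero: np.ndarray, m_plus: np.ndarray) -> np.ndarray:
    """Sub-pixel correction from squared-MAE parabola; 0 where not applicable."""
    a, b, c = m_minus**2, m_zero**2, m_plus**2
    denom = a - 2 * b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (a - c) / denom
    ok = (denom > 0) & (m_zero > 0)
    return np.clip(np.where(ok, delta, 0.0), -0.5, 0.5)


def best_match(
    frame_current: np.ndarray,
    frame_previous: np.ndarray,
    block_origin: tuple[int, int],
    cfg: BlockMatchConfig = BlockMatchConfig(),
) -> tuple[float, float, float]:
    """Match one block; returns ``(offset_row, offset_col, mae_value)``.

    ``block_origin`` is the top-left corner of the N x N block in the current
    frame.  The returned offset is the argmin of the MAE over all integer
    offsets in [-w, w]^2 (sub-pixel refined if configured); the MAE value is
    the one at the integer minimum, normalized per the config.  The block and
    its full search window must lie inside both frames.
    """
    cur = np.asarray(frame_current, dtype=np.float64)
    prev = np.asarray(frame_previous, dtype=np.float64)
    N, w = cfg.N, cfg.w
    r, c = block_origin
    if r - w < 0 or c - w < 0 or r + N + w > prev.shape[0] or c + N + w > prev.shape[1]:
        raise ValueError("search window exits the frame for this block")
    block = cur[r : r + N, c : c + N]
    side = 2 * w + 1
    vol = np.empty((side, side))
    for i in range(-w, w + 1):
        for j in range(-w, w + 1):
            ref = prev[r + i : r + i + N, c + j : c + j + N]
            vol[i + w, j + w] = np.abs(block - ref).sum()
    flat = vol.reshape(-1)
    order = _offset_priority(w)
    best = order[int(np.argmin(flat[order]))]
    bi, bj = divmod(int(best), side)
    value = vol[bi, bj] / (N * N) if cfg.mae_normalized else vol[bi, bj]
    di, dj = float(bi - w), float(bj - w)
    if cfg.subpixel:
        if 0 < bi < side - 1:
            di += float(_refine_axis(vol[bi - 1, bj], vol[bi, bj], vol[bi + 1, bj]))
        if 0 < bj < side - 1:
            dj += float(_refine_axis(vol[bi, bj - 1], vol[bi, bj], vol[bi, bj + 1]))
        di = float(np.clip(di, -(w + 0.5), w + 0.5))
        dj = float(np.clip(dj, -(w + 0.5), w + 0.5))
    return di, dj, float(value)


def _valid_grid(
    start: int, extent: int, frame_extent: int, cfg: BlockMatchConfig
) -> tuple[np.ndarray, int]:
    """Grid coordinates (block centers) along one axis, and the dropped count."""
    half = cfg.N // 2
    requested = np.arange(start, start + extent, cfg.grid_stride)
    top = requested - half
    ok = (top - cfg.w >= 0) & (top + cfg.N + cfg.w <= frame_extent)
    return requested[ok], int((~ok).sum())


def _block_sums(diff: np.ndarray, tops_r: np.ndarray, tops_c: np.ndarray, N: int) -> np.ndarray:
    """Sum of ``diff`` over N x N windows with the given top-left corners."""
    S = np.zeros((diff.shape[0] + 1, diff.shape[1] + 1))
    np.cumsum(diff, axis=0, out=S[1:, 1:])
    np.cumsum(S[1:, 1:], axis=1, out=S[1:, 1:])
    r0, c0 = tops_r[:, None], tops_c[None, :]
    return S[r0 + N, c0 + N] - S[r0 + N, c0] - S[r0, c0 + N] + S[r0, c0]


def compute_motion_field(
    seq: FrameSequence, roi: ROI, cfg: BlockMatchConfig = BlockMatchConfig()
) -> MotionField:
    """Block-matching vectors for every frame pair and ROI grid point.

    Grid points are spaced ``cfg.grid_stride`` pixels apart inside the ROI and
    serve as block centers; points whose block or search window would leave
    the frame are dropped (not padded) and counted.  Results are identical to
    calling :func:`best_match` at every grid point, but the search is
    evaluated with integral images over whole frames, which is what makes
    full-length videos tractable.
    """
    if seq.n_frames < 2:
        raise ValueError("need at least 2 frames")
    roi.validate_within(seq.frame_shape)
    H, W = seq.frame_shape
    N, w = cfg.N, cfg.w
    half = N // 2
    grid_rows, dropped_r = _valid_grid(roi.row_start, roi.height, H, cfg)
    grid_cols, dropped_c = _valid_grid(roi.col_start, roi.width, W, cfg)
    if grid_rows.size == 0 or grid_cols.size == 0:
        raise ValueError("ROI too small: no block fits with its search window")
    n_dropped = dropped_r * max(grid_cols.size + dropped_c, 1) + dropped_c * grid_rows.size

    tops_r = grid_rows - half
    tops_c = grid_cols - half
    side = 2 * w + 1
    order = _offset_priority(w)
    frames = seq.frames.astype(np.float64, copy=False)
    T = seq.n_frames
    vectors = np.empty((T - 1, grid_rows.size, grid_cols.size, 2))

    for t in range(1, T):
        cur, prev = frames[t], frames[t - 1]
        vol = np.empty((grid_rows.size, grid_cols.size, side, side))
        for i in range(-w, w + 1):
            rs = slice(max(0, -i), H - max(0, i))
            for j in range(-w, w + 1):
                cs = slice(max(0, -j), W - max(0, j))
                diff = np.zeros((H, W))
                diff[rs, cs] = np.abs(
                    cur[rs, cs]
                    - prev[rs.start + i : rs.stop + i, cs.start + j : cs.stop + j]
                )
                vol[:, :, i + w, j + w] = _block_sums(diff, tops_r, tops_c, N)

        flat = vol.reshape(grid_rows.size, grid_cols.size, side * side)
        best = order[np.argmin(flat[:, :, order], axis=-1)]
        bi, bj = np.divmod(best, side)
        di = (bi - w).astype(np.float64)
        dj = (bj - w).astype(np.float64)

        if cfg.subpixel:
            gr = np.arange(grid_rows.size)[:, None]
            gc = np.arange(grid_cols.size)[None, :]
            m0 = vol[gr, gc, bi, bj]
            interior_i = (bi > 0) & (bi < side - 1)
            bi_c = np.clip(bi, 1, side - 2)
            d_i = _refine_axis(vol[gr, gc, bi_c - 1, bj], m0, vol[gr, gc, bi_c + 1, bj])
            di += np.where(interior_i, d_i, 0.0)
            interior_j = (bj > 0) & (bj < side - 1)
            bj_c = np.clip(bj, 1, side - 2)
            d_j = _refine_axis(vol[gr, gc, bi, bj_c - 1], m0, vol[gr, gc, bi, bj_c + 1])
            dj += np.where(interior_j, d_j, 0.0)
            np.clip(di, -(w + 0.5), w + 0.5, out=di)
            np.clip(dj, -(w + 0.5), w + 0.5, out=dj)

        # motion vector = negated matching offset; x = column, y = row
        vectors[t - 1, :, :, 0] = -dj
        vectors[t - 1, :, :, 1] = -di

    return MotionField(
        vectors=vectors,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        transition_times=np.arange(1, T) / seq.frame_rate,
        n_dropped_grid_points=n_dropped,
    )


def mean_speed_trace(field: MotionField, frame_rate: float, pixel_size: float) -> VelocityTrace:
    """ROI-averaged vector magnitude per transition, converted to um/s.

    speed = mean over grid points of sqrt(x^2 + y^2) [px/frame]
            * pixel_size [um/px] * frame_rate [frame/s]
    """
    if field.vectors.size == 0:
        raise ValueError("empty motion field")
    if frame_rate <= 0 or pixel_size <= 0:
        raise ValueError("frame_rate and pixel_size must be positive")
    speeds = field.speeds_px.mean(axis=(1, 2)) * pixel_size * frame_rate
    return VelocityTrace(times=field.transition_times.copy(), speeds=speeds)
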