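"""Grayscale video I/O for the motion-analysis pipeline.

Frames are held as a single (time, row, column) integer array together with the
two calibration constants everything downstream depends on: the frame rate in
Hz and the pixel size in micrometres per pixel.  Neither is ever defaulted —
velocities in physical units are meaningless without them, so absence is an
error at construction time.

Coordinates are 0-based ``(row, column)`` with the origin at the top-left;
a region of interest (ROI) is half-open, ``[start, start + extent)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["FrameSequence", "ROI", "read_frames", "write_frames", "crop_roi"]

_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclasses.dataclass(frozen=True)
class ROI:
    """Rectangular region of interest: half-open pixel window of a frame."""

    row_start: int
    col_start: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI extents must be positive")

    @property
    def row_stop(self) -> int:
        return self.row_start + self.height

    @property
    def col_stop(self) -> int:
        return self.col_start + self.width

    def validate_within(self, frame_shape: tuple[int, int]) -> None:
        """Raise if the ROI is not fully inside a frame of the given shape."""
        h, w = frame_shape
        if self.row_stop > h or self.col_stop > w:
            raise ValueError(
                f"ROI {self} extends outside the {h}x{w} frame"
            )


@dataclasses.dataclass
class FrameSequence:
    """Ordered grayscale frames plus acquisition calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative integer intensities, one 2-D frame per time point.
    frame_rate : float
        Acquisition rate in frames per second (Hz), > 0.
    pixel_size : float
        Micrometres per pixel, > 0.
    bit_depth : int, optional
        Bits per sample.  Inferred from the array dtype when omitted
        (uint8 -> 8, uint16 -> 16).
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(
                f"frames must be a (time, row, column) array, got ndim={frames.ndim}"
            )
        if frames.shape[0] < 1:
            raise ValueError("a FrameSequence needs at least one frame")
        if not np.issubdtype(frames.dtype, np.integer):
            raise ValueError("frame intensities must be integer-typed")
        if self.frame_rate is None or self.frame_rate <= 0:
            raise ValueError("frame_rate must be a positive number of Hz")
        if self.pixel_size is None or self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (micrometres/pixel)")
        if self.bit_depth is None:
            self.bit_depth = int(frames.dtype.itemsize * 8)
        if frames.min() < 0 or frames.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities must lie in [0, 2^{self.bit_depth} - 1]"
            )
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds, frame 0 at t = 0."""
        return np.arange(self.n_frames) / self.frame_rate


def _read_directory(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF frames found in {path}")
    frames = []
    for f in files:
        arr = iio.imread(f)
        if arr.ndim != 2:
            raise ValueError(
                f"{f.name}: expected a single grayscale channel, got shape {arr.shape}"
            )
        frames.append(arr)
    shapes = {a.shape for a in frames}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
    return np.stack(frames)


def _read_stack(path: Path) -> np.ndarray:
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        if "C" in axes or "S" in axes:
            raise ValueError(
                f"{path.name}: multi-channel input is not supported; "
                "convert to grayscale first"
            )
        arr = series.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: cannot interpret axes {axes!r} as a stack")
    return arr


def read_frames(path: str | Path, frame_rate: float, pixel_size: float) -> FrameSequence:
    """Read a multi-page TIFF or a directory of single-frame images.

    Directory frames are taken in lexicographic filename order.  Both
    calibration constants are required; there are no defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = _read_directory(path) if path.is_dir() else _read_stack(path)
    if arr.shape[0] < 2:
        raise ValueError(
            f"{path}: fewer than 2 frames; motion estimation needs frame pairs"
        )
    return FrameSequence(arr, frame_rate=frame_rate, pixel_size=pixel_size)


def write_frames(seq: FrameSequence, path: str | Path) -> None:
    """Write a sequence back to disk.

    A ``.tif``/``.tiff`` path gets a multi-page TIFF; any other path is
    treated as a directory of numbered PNG frames.  Intensities round-trip
    exactly through :func:`read_frames` in either case.
    """
    path = Path(path)
    if seq.n_frames < 1:
        raise ValueError("refusing to write an empty sequence")
    if path.suffix.lower() in {".tif", ".tiff"}:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, seq.frames, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = len(str(seq.n_frames - 1))
        for t in range(seq.n_frames):
            iio.imwrite(path / f"frame_{t:0{width}d}.png", seq.frames[t])


def crop_roi(seq: FrameSequence, roi: ROI) -> FrameSequence:
    """Return the ROI sub-window of every frame; calibration is preserved."""
    roi.validate_within(seq.frame_shape)
    return FrameSequence(
        seq.frames[:, roi.row_start : roi.row_stop, roi.col_start : roi.col_stop].copy(),
        frame_rate=seq.frame_rate,
        pixel_size=seq.pixel_size,
        bit_depth=seq.bit_depth,
    )
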