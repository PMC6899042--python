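import numpy as np
import pytest
from scipy import ndimage

from cardiomvp import FrameSequence


def smooth_texture(rng: np.random.Generator, shape=(64, 64), sigma=1.5) -> np.ndarray:
    """Blurred-noise texture with enough local contrast for block matching."""
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    tex = (tex - tex.mean()) / tex.std()
    return np.clip(128.0 + 45.0 * tex, 0, 255).astype(np.uint8)


def translating_sequence(
    rng: np.random.Generator,
    shift: tuple[int, int],
    n_frames: int = 3,
    shape: tuple[int, int] = (64, 64),
    frame_rate: float = 150.0,
    pixel_size: float = 0.5,
) -> FrameSequence:
    """Every pixel translates by an integer ``shift`` (row, col) per frame.

    Frames are crops of one big texture at sliding offsets, so the motion is
    exactly uniform with no boundary effects.  The crop origin moves by
    ``-shift`` per frame, so scene content moves by ``+shift``.
    """
    h, w = shape
    dr, dc = shift
    margin_r, margin_c = abs(dr) * n_frames, abs(dc) * n_frames
    big = smooth_texture(rng, (h + 2 * margin_r + 2, w + 2 * margin_c + 2))
    frames = []
    for t in range(n_frames):
        r0 = margin_r - t * dr
        c0 = margin_c - t * dc
        frames.append(big[r0 : r0 + h, c0 : c0 + w])
    return FrameSequence(
        np.stack(frames), frame_rate=frame_rate, pixel_size=pixel_size
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
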