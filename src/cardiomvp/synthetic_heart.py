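"""Seeded generators: beating-wall videos and replicate densitometry tables.

The video generator is the test harness for the motion pipeline.  It renders
a textured wall whose velocity follows a prescribed beat waveform, so every
quantity the pipeline measures (peak systolic/diastolic speed, beat period,
beat count) is known by construction.

The waveform for one beat period is a contraction lobe — a negative half-sine
of amplitude ``peak_systolic_speed`` lasting ``systolic_lobe_duration`` —
followed by a relaxation lobe, a positive half-sine whose amplitude is
``peak_diastolic_speed`` and whose duration is solved from the area balance

    peak_systolic_speed * systolic_duration
        = peak_diastolic_speed * diastolic_duration,

so the wall returns exactly to its baseline position each beat (zero net
drift) while both peak speeds remain independently prescribable.  The rest of
the period is quiescent.

Textures are Gaussian-blurred white noise: block matching needs local
contrast with a correlation length of a few pixels, not anatomical realism.
Rendering uses linear sub-pixel intensity interpolation, with additive
Gaussian sensor noise clipped to the bit depth.  All generators are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .video_io import ROI, FrameSequence

__all__ = [
    "BeatWaveformSpec",
    "DensitometrySpec",
    "wall_velocity_waveform",
    "wall_displacement",
    "render_video",
    "suggested_roi",
    "preset",
    "PRESET_NAMES",
    "simulate_densitometry",
]

# Chamber/genotype peak wall speeds (systolic, diastolic) in um/s used by the
# presets; frame rate 150 Hz, 8-bit frames, matching the acquisition the
# pipeline is meant for.
_PRESET_SPEEDS: dict[str, tuple[float, float]] = {
    "wt_atrium": (183.0, 140.0),
    "nsh_atrium": (64.0, 35.0),
    "wt_ventricle": (189.0, 136.0),
    "nsh_ventricle": (29.0, 22.0),
}
PRESET_NAMES = tuple(_PRESET_SPEEDS)


@dataclasses.dataclass(frozen=True)
class BeatWaveformSpec:
    """Full parameterisation of a synthetic beating-wall video.

    Speeds are um/s, durations seconds, pixel_size um/px, frame_rate Hz,
    noise_sd in intensity units of the rendered bit depth.
    """

    peak_systolic_speed: float
    peak_diastolic_speed: float
    beat_period: float = 0.5
    systolic_lobe_duration: float = 0.12
    pixel_size: float = 0.325
    frame_rate: float = 150.0
    duration: float = 10.0
    texture_blur_sigma: float = 2.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "beat_period",
            "systolic_lobe_duration",
            "pixel_size",
            "frame_rate",
            "duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_systolic_speed < 0 or self.peak_diastolic_speed < 0:
            raise ValueError("peak speeds must be non-negative")
        if (self.peak_systolic_speed == 0) != (self.peak_diastolic_speed == 0):
            raise ValueError(
                "infeasible spec: area balance needs both peak speeds zero or both positive"
            )
        if self.systolic_lobe_duration + self.diastolic_lobe_duration >= self.beat_period:
            raise ValueError(
                "infeasible spec: systolic + diastolic lobes exceed the beat period"
            )

    @property
    def diastolic_lobe_duration(self) -> float:
        """Solved from area balance so the wall drifts by zero per beat."""
        if self.peak_diastolic_speed == 0:
            return 0.0
        return (
            self.systolic_lobe_duration
            * self.peak_systolic_speed
            / self.peak_diastolic_speed
        )

    @property
    def peak_frame_displacement_px(self) -> float:
        """Largest per-frame displacement the waveform produces, in pixels."""
        return self.peak_systolic_speed / (self.pixel_size * self.frame_rate)

    @property
    def stroke_amplitude_px(self) -> float:
        """Total wall excursion over one contraction, in pixels."""
        um = 2.0 * self.peak_systolic_speed * self.systolic_lobe_duration / math.pi
        return um / self.pixel_size


@dataclasses.dataclass(frozen=True)
class DensitometrySpec:
    """Replicate structure of a synthetic co-IP densitometry experiment.

    ``true_fold`` is the ground-truth binding fold of the mutant condition
    versus the reference; band noise is multiplicative log-normal with
    log-scale SD ``noise_sigma``; input-band intensities are positive
    truncated normals of mean ``input_mean`` and CV ``input_cv``.
    """

    true_fold: float = 1.0
    n_replicates: int = 10
    input_mean: float = 1000.0
    input_cv: float = 0.1
    noise_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_fold <= 0:
            raise ValueError("true_fold must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.input_mean <= 0 or self.input_cv < 0 or self.noise_sigma < 0:
            raise ValueError("non-positive intensity parameters")


def wall_velocity_waveform(spec: BeatWaveformSpec, t: np.ndarray | float) -> np.ndarray | float:
    """Signed wall speed in um/s at time(s) ``t`` (contraction negative)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tau = np.mod(t, spec.beat_period)
    ts, td = spec.systolic_lobe_duration, spec.diastolic_lobe_duration
    v = np.zeros_like(tau)
    in_sys = tau < ts
    v[in_sys] = -spec.peak_systolic_speed * np.sin(np.pi * tau[in_sys] / ts)
    in_dia = (tau >= ts) & (tau < ts + td)
    v[in_dia] = spec.peak_diastolic_speed * np.sin(np.pi * (tau[in_dia] - ts) / td)
    return v if v.ndim else float(v)


def wall_displacement(spec: BeatWaveformSpec, t: np.ndarray | float) -> np.ndarray | float:
    """Integrated waveform: wall position offset in um (closed form)."""
    t = np.asarray(t, dtype=float)
    tau = np.mod(t, spec.beat_period)
    ts, td = spec.systolic_lobe_duration, spec.diastolic_lobe_duration
    vs, vd = spec.peak_systolic_speed, spec.peak_diastolic_speed
    stroke = 2.0 * vs * ts / np.pi  # total excursion of the contraction
    x = np.zeros_like(tau)
    in_sys = tau < ts
    x[in_sys] = -vs * ts / np.pi * (1.0 - np.cos(np.pi * tau[in_sys] / ts))
    in_dia = (tau >= ts) & (tau < ts + td)
    x[in_dia] = -stroke + vd * td / np.pi * (
        1.0 - np.cos(np.pi * (tau[in_dia] - ts) / td)
    )
    return x if x.ndim else float(x)


def _texture(rng: np.random.Generator, shape: tuple[int, int], blur_sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if blur_sigma > 0:
        noise = ndimage.gaussian_filter(noise, blur_sigma)
    noise = (noise - noise.mean()) / noise.std()
    return 128.0 + 45.0 * noise


def render_video(
    spec: BeatWaveformSpec,
    geometry: str = "translating_band",
    frame_shape: tuple[int, int] = (256, 256),
) -> FrameSequence:
    """Render a seeded video of a beating wall.

    ``translating_band``: a textured horizontal band rigidly translates
    vertically by the integrated waveform displacement.  ``contracting_
    annulus``: a textured ring about the frame center displaces radially by
    the same displacement.  Both are rendered with linear sub-pixel intensity
    interpolation; Gaussian sensor noise of SD ``spec.noise_sd`` is added and
    clipped to 8 bits.
    """
    H, W = frame_shape
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.frame_rate))
    t = np.arange(n_frames) / spec.frame_rate
    disp_px = np.asarray(wall_displacement(spec, t)) / spec.pixel_size
    amp = int(math.ceil(spec.stroke_amplitude_px))

    if geometry == "translating_band":
        if amp + 12 >= H // 2:
            raise ValueError("displacement amplitude exceeds the frame margins")
        tex = _texture(rng, (H, W), spec.texture_blur_sigma)
        base = np.full((H, W), 110.0)
        band_top, band_bottom = amp + 4, H - 4
        base[band_top:band_bottom, :] = tex[band_top:band_bottom, :]

        def sample(d: float) -> np.ndarray:
            # content at rest position m maps to output row m + d
            return ndimage.shift(base, (d, 0.0), order=1, mode="nearest")

    elif geometry == "contracting_annulus":
        tex = _texture(rng, (2 * H, 2 * W), spec.texture_blur_sigma)
        cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
        rows, cols = np.mgrid[0:H, 0:W].astype(float)
        rho = np.hypot(rows - cy, cols - cx)
        with np.errstate(invalid="ignore", divide="ignore"):
            ur = np.where(rho > 0, (rows - cy) / rho, 0.0)
            uc = np.where(rho > 0, (cols - cx) / rho, 0.0)
        r_out = min(H, W) / 2.0 - 6.0
        r_in = r_out / 2.0
        if r_in - amp <= 2.0:
            raise ValueError("displacement amplitude exceeds the annulus margins")

        def sample(d: float) -> np.ndarray:
            src_r = rows - d * ur + H / 2.0  # offset into the oversized texture
            src_c = cols - d * uc + W / 2.0
            img = ndimage.map_coordinates(tex, [src_r, src_c], order=1, mode="nearest")
            ring = (rho - d >= r_in) & (rho - d <= r_out)
            return np.where(ring, img, 110.0)

    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    frames = np.empty((n_frames, H, W), dtype=np.uint8)
    for k in range(n_frames):
        img = sample(float(disp_px[k]))
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=(H, W))
        frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return FrameSequence(
        frames, frame_rate=spec.frame_rate, pixel_size=spec.pixel_size, bit_depth=8
    )


def suggested_roi(
    spec: BeatWaveformSpec,
    geometry: str = "translating_band",
    frame_shape: tuple[int, int] = (256, 256),
) -> ROI:
    """An ROI that stays on moving texture at every phase of the beat.

    For the translating band this is the set of rows covered by the band at
    both displacement extremes, shrunk by a margin for the block and search
    window extents, so every grid vector measures wall motion rather than
    static background.
    """
    H, W = frame_shape
    amp = int(math.ceil(spec.stroke_amplitude_px))
    if geometry == "translating_band":
        band_top, band_bottom = amp + 4, H - 4
        # band moves up by up to `amp`: rows always inside are [band_top, bottom-amp)
        top = band_top + 16
        bottom = band_bottom - amp - 16
        if bottom - top < 16:
            raise ValueError("frame too small for a stable ROI at this amplitude")
        return ROI(top, 16, bottom - top, W - 32)
    if geometry == "contracting_annulus":
        r_out = min(H, W) / 2.0 - 6.0
        r_in = r_out / 2.0
        half = int((r_in + r_out) / 2.0 / math.sqrt(2.0)) - amp - 16
        cy, cx = H // 2, W // 2
        if half < 8:
            raise ValueError("frame too small for a stable annulus ROI")
        return ROI(cy - half, cx - half, 2 * half, 2 * half)
    raise ValueError(f"unknown geometry {geometry!r}")


def preset(name: str, seed: int = 0, duration: float = 10.0) -> BeatWaveformSpec:
    """Named chamber/genotype presets carrying reference peak wall speeds.

    Beat period 0.5 s (120 beats/min) and a 0.12 s systolic lobe are
    generator-side choices in the physiological range for embryonic fish
    hearts; pixel size 0.325 um/px keeps the fastest preset (189 um/s at
    150 fps, i.e. 3.9 px/frame) inside the default w = 4 search range.
    """
    try:
        vs, vd = _PRESET_SPEEDS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESET_SPEEDS)}"
        ) from None
    return BeatWaveformSpec(
        peak_systolic_speed=vs,
        peak_diastolic_speed=vd,
        seed=seed,
        duration=duration,
    )


def simulate_densitometry(
    spec: DensitometrySpec,
    conditions: list[tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Replicate band-intensity table for a set of conditions.

    ``conditions`` is a list of (label, true_fold) pairs; the reference
    condition (fold 1) is conventionally labelled "WT".  When omitted, a
    two-condition WT/mutant design using ``spec.true_fold`` is generated.
    Per replicate: input ~ positive-truncated Normal(input_mean,
    (input_cv * input_mean)^2); ip = true_fold * input * exp(eps) with
    eps ~ Normal(0, noise_sigma^2).
    """
    if conditions is None:
        conditions = [("WT", 1.0), ("mutant", spec.true_fold)]
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, fold in conditions:
        if fold <= 0:
            raise ValueError(f"condition {label!r}: true fold must be positive")
        sd = spec.input_cv * spec.input_mean
        inputs = rng.normal(spec.input_mean, sd, size=spec.n_replicates)
        while np.any(inputs <= 0):  # positive truncation by redraw
            bad = inputs <= 0
            inputs[bad] = rng.normal(spec.input_mean, sd, size=bad.sum())
        eps = rng.normal(0.0, spec.noise_sigma, size=spec.n_replicates)
        ips = fold * inputs * np.exp(eps)
        for rep in range(spec.n_replicates):
            rows.append(
                {
                    "condition": label,
                    "replicate": rep + 1,
                    "ip_intensity": ips[rep],
                    "input_intensity": inputs[rep],
                }
            )
    return pd.DataFrame(rows)
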