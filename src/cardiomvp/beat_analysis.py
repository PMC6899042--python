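"""Beat segmentation and chamber-level summaries of wall-velocity traces.

A velocity trace is the mean motion-vector magnitude inside an ROI over time,
in um/s.  Because speeds are magnitudes, contraction (systole) and relaxation
(diastole) both show up as positive lobes: each heartbeat appears as a large
peak (systole) followed by a smaller peak (diastole).  The steps here are

1. optional moving-average smoothing,
2. beat-period estimation from the trace autocorrelation,
3. period-anchored pairing of systolic and diastolic peaks,
4. per-chamber summary (maximum systolic/diastolic peak speed, heart rate),
5. group comparison with a pooled-variance two-sided Student's t-test.

Period-anchored pairing, rather than a global amplitude threshold, is used
because the diastolic peak of a strong beat can exceed the systolic peak of a
weak one; windows of one beat period anchored on the tallest peak keep the
large/small assignment local to each beat.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "VelocityTrace",
    "BeatTable",
    "ChamberSummary",
    "GroupComparison",
    "smooth_trace",
    "estimate_period",
    "detect_beats",
    "summarize_chamber",
    "compare_groups",
]


@dataclasses.dataclass
class VelocityTrace:
    """Mean wall-speed time series in um/s.

    ``times`` are seconds (strictly increasing), ``speeds`` are non-negative
    vector magnitudes, so both cardiac phases have positive values.
    """

    times: np.ndarray
    speeds: np.ndarray
    chamber: str = ""
    specimen: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.times.shape != self.speeds.shape or self.times.ndim != 1:
            raise ValueError("times and speeds must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.speeds < 0):
            raise ValueError("speeds are magnitudes and must be non-negative")

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.times)))

    def with_speeds(self, speeds: np.ndarray) -> "VelocityTrace":
        return dataclasses.replace(self, speeds=np.asarray(speeds, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "speed_um_per_s": self.speeds})


@dataclasses.dataclass
class BeatTable:
    """One record per detected beat (systolic then diastolic peak)."""

    beats: pd.DataFrame  # systolic_peak_time, systolic_peak_speed,
    #                      diastolic_peak_time, diastolic_peak_speed
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.beats)


@dataclasses.dataclass
class ChamberSummary:
    """Per-specimen chamber summary derived from a beat table."""

    max_systolic_speed: float
    max_diastolic_speed: float
    mean_systolic_speed: float
    mean_diastolic_speed: float
    heart_rate: float  # beats/min
    n_beats: int


@dataclasses.dataclass
class GroupComparison:
    """Two-group comparison of one summary metric."""

    metric: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t_statistic: float
    p_value: float
    significant: bool  # at the conventional 0.05 level


def smooth_trace(trace: VelocityTrace, window: int) -> VelocityTrace:
    """Centered moving average; endpoints use the truncated window.

    ``window`` must be odd (so the average is centered), >= 1 and no longer
    than the trace.  ``window == 1`` is the identity.
    """
    n = len(trace)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    if window == 1:
        return trace.with_speeds(trace.speeds.copy())
    half = window // 2
    padded = np.concatenate([np.zeros(1), np.cumsum(trace.speeds)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    smoothed = (padded[hi] - padded[lo]) / (hi - lo)
    return trace.with_speeds(smoothed)


def estimate_period(
    trace: VelocityTrace,
    band: tuple[float, float] = (0.2, 2.0),
    min_peak_fraction: float = 0.2,
) -> float:
    """Beat period from the autocorrelation of the mean-subtracted trace.

    The first/strongest non-zero-lag autocorrelation maximum whose lag lies in
    the physiological band (default 0.2-2.0 s, i.e. 30-300 beats/min) gives
    the period.  A peak is only accepted if its autocorrelation exceeds
    ``min_peak_fraction`` of the zero-lag value, which rejects aperiodic
    (noise) traces.
    """
    x = trace.speeds - trace.speeds.mean()
    n = x.size
    if n < 4 or not np.any(x):
        raise ValueError("no periodicity detected: trace too short or constant")
    dt = trace.dt
    ac = signal.correlate(x, x, mode="full")[n - 1 :]
    lo = max(int(math.ceil(band[0] / dt)), 1)
    hi = min(int(math.floor(band[1] / dt)), n - 2)
    if hi <= lo:
        raise ValueError("no periodicity detected: band shorter than two samples")
    peaks, _ = signal.find_peaks(ac[lo : hi + 1])
    peaks += lo
    peaks = peaks[ac[peaks] >= min_peak_fraction * ac[0]]
    if peaks.size == 0:
        raise ValueError("no periodicity detected in the physiological band")
    best = peaks[np.argmax(ac[peaks])]
    return float(best * dt)


def detect_beats(
    trace: VelocityTrace,
    period: float,
    min_prominence_fraction: float = 0.2,
) -> BeatTable:
    """Pair systolic and diastolic peaks beat by beat.

    Candidate peaks are local maxima with prominence of at least
    ``min_prominence_fraction`` times the trace's 95th percentile.  Windows of
    one beat period are anchored on the tallest candidate; the tallest
    candidate in each window is that beat's systolic peak, and the tallest
    candidate strictly between consecutive systolic peaks (or before the end
    of the trace, for the final beat) is the diastolic peak.  Beats with no
    diastolic candidate, or whose chosen diastolic peak exceeds the systolic
    one, are dropped and counted in ``n_dropped``.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    speeds, times = trace.speeds, trace.times
    prominence = min_prominence_fraction * np.percentile(speeds, 95)
    cand, _ = signal.find_peaks(speeds, prominence=max(prominence, 0.0) or None)
    if cand.size < 2:
        raise ValueError("fewer than 2 candidate peaks; cannot form beats")

    anchor_time = times[cand[np.argmax(speeds[cand])]]
    window_index = np.round((times[cand] - anchor_time) / period).astype(int)

    systolic_idx: list[int] = []
    for k in np.unique(window_index):
        members = cand[window_index == k]
        systolic_idx.append(members[np.argmax(speeds[members])])
    systolic_idx = sorted(systolic_idx)
    if len(systolic_idx) < 2:
        raise ValueError("fewer than 2 systolic peaks detected")

    cand_set = np.asarray(cand)
    records, dropped = [], 0
    bounds = [times[i] for i in systolic_idx[1:]] + [times[-1] + trace.dt]
    for sys_i, t_next in zip(systolic_idx, bounds):
        t_sys = times[sys_i]
        mask = (times[cand_set] > t_sys) & (times[cand_set] < t_next)
        between = cand_set[mask]
        between = between[between != sys_i]
        if between.size == 0:
            dropped += 1
            continue
        dia_i = between[np.argmax(speeds[between])]
        if speeds[dia_i] > speeds[sys_i]:
            dropped += 1
            continue
        records.append(
            {
                "systolic_peak_time": t_sys,
                "systolic_peak_speed": speeds[sys_i],
                "diastolic_peak_time": times[dia_i],
                "diastolic_peak_speed": speeds[dia_i],
            }
        )
    return BeatTable(pd.DataFrame(records), n_dropped=dropped)


def summarize_chamber(beats: BeatTable) -> ChamberSummary:
    """Chamber summary: per-beat peak extrema and heart rate.

    Heart rate is 60 over the median interval between consecutive systolic
    peaks, in beats/min.  The maxima are taken over detected beats; the means
    of the per-beat peaks are reported alongside since either convention can
    be wanted for cross-specimen averaging.
    """
    df = beats.beats
    if len(df) < 2:
        raise ValueError("need at least 2 beats to summarize a chamber")
    intervals = np.diff(np.sort(df["systolic_peak_time"].to_numpy()))
    return ChamberSummary(
        max_systolic_speed=float(df["systolic_peak_speed"].max()),
        max_diastolic_speed=float(df["diastolic_peak_speed"].max()),
        mean_systolic_speed=float(df["systolic_peak_speed"].mean()),
        mean_diastolic_speed=float(df["diastolic_peak_speed"].mean()),
        heart_rate=60.0 / float(np.median(intervals)),
        n_beats=len(df),
    )


def _metric_values(summaries: list[ChamberSummary], metric: str) -> np.ndarray:
    if not summaries:
        raise ValueError("empty group")
    if not hasattr(summaries[0], metric):
        raise ValueError(f"unknown metric {metric!r}")
    return np.array([getattr(s, metric) for s in summaries], dtype=float)


def compare_groups(
    summaries_a: list[ChamberSummary],
    summaries_b: list[ChamberSummary],
    metric: str = "max_systolic_speed",
) -> GroupComparison:
    """Pooled-variance two-sided Student's t-test on one summary metric."""
    a = _metric_values(summaries_a, metric)
    b = _metric_values(summaries_b, metric)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):  # both groups constant
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    return GroupComparison(
        metric=metric,
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / math.sqrt(a.size)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / math.sqrt(b.size)),
        n_b=int(b.size),
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p < 0.05),
    )
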