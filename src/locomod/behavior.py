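"""Treadmill-speed resampling and behavioral-state segmentation.

Every imaging frame is labelled STATIONARY, LOCOMOTION, or EXCLUDED.
Locomotion requires three simultaneous criteria on the 40 Hz speed trace:
instantaneous speed >= 0.1 cm/s, 0.25 Hz low-pass filtered speed
>= 0.1 cm/s, and mean speed >= 0.1 cm/s over a 2 s window centered on the
frame.  Inter-locomotion gaps strictly shorter than 500 ms are merged into
locomotion.  Stationary frames within 3 s after or 0.2 s before a
locomotion period are excluded, as are frames that move above threshold
without satisfying all three criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .filters import smooth_lowpass

__all__ = [
    "State",
    "SpeedSeries",
    "resample_speed",
    "segment_states",
    "enumerate_epochs",
    "runs_of",
]


class State(IntEnum):
    STATIONARY = 0
    LOCOMOTION = 1
    EXCLUDED = 2


@dataclass
class SpeedSeries:
    """Uniformly sampled, nonnegative treadmill speed."""

    time_s: np.ndarray
    speed_cm_s: np.ndarray
    fs_hz: float = 40.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.speed_cm_s = np.asarray(self.speed_cm_s, dtype=float)
        if self.time_s.shape != self.speed_cm_s.shape:
            raise ValueError("time and speed must have equal length")
        if np.any(self.speed_cm_s < 0):
            raise ValueError("speed must be nonnegative")

    def __len__(self) -> int:
        return self.speed_cm_s.size


def resample_speed(
    raw_times: np.ndarray,
    raw_values: np.ndarray,
    target_hz: float = 40.0,
    kind: str = "speed",
) -> SpeedSeries:
    """Linearly interpolate encoder samples onto the imaging frame grid.

    Parameters
    ----------
    raw_times
        Strictly increasing sample times in seconds (the encoder runs at
        ~12 kHz; any rate is accepted).
    raw_values
        Speeds in cm/s (``kind="speed"``) or cumulative positions in cm
        (``kind="position"``; differentiated before interpolation).
    target_hz
        Output frame rate, default the 40 Hz imaging rate.

    The output grid starts at ``raw_times[0]`` and is clipped at zero
    (encoder jitter can produce tiny negative derivatives).
    """
    t = np.asarray(raw_times, dtype=float)
    v = np.asarray(raw_values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape or t.size < 2:
        raise ValueError("raw_times and raw_values must be equal-length 1D, n >= 2")
    if np.any(np.diff(t) <= 0):
        raise ValueError("raw timestamps must be strictly increasing")
    if kind == "position":
        v = np.gradient(v, t)
    elif kind != "speed":
        raise ValueError(f"kind must be 'speed' or 'position', got {kind!r}")
    n_out = int(np.floor((t[-1] - t[0]) * target_hz)) + 1
    t_out = t[0] + np.arange(n_out) / target_hz
    speed = np.clip(np.interp(t_out, t, v), 0.0, None)
    return SpeedSeries(time_s=t_out, speed_cm_s=speed, fs_hz=target_hz)


def runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open ``[start, end)`` index ranges of the True runs of a mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [mask.size]))
    return [
        (int(bounds[i]), int(bounds[i + 1]))
        for i in range(len(bounds) - 1)
        if mask[bounds[i]]
    ]


def _centered_mean(v: np.ndarray, half: int) -> np.ndarray:
    """Mean over a centered window of ``2*half + 1`` frames, truncated at edges."""
    n = v.size
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def segment_states(
    speed: SpeedSeries | np.ndarray,
    v_thresh: float = 0.1,
    lp_cutoff_hz: float = 0.25,
    lp_order: int = 60,
    window_s: float = 2.0,
    merge_gap_s: float = 0.5,
    excl_after_s: float = 3.0,
    excl_before_s: float = 0.2,
    fs_hz: float = 40.0,
) -> np.ndarray:
    """Label every frame STATIONARY, LOCOMOTION, or EXCLUDED.

    Rule order: the three locomotion criteria, then merging of
    inter-locomotion gaps strictly shorter than ``merge_gap_s``, then the
    exclusion windows around the final locomotion periods (merging first,
    because the windows reference the merged periods).  Frames whose
    instantaneous speed reaches threshold without all three criteria
    holding fit neither printed state and are EXCLUDED.

    Returns an ``int8`` array of :class:`State` codes.
    """
    if isinstance(speed, SpeedSeries):
        v, fs = speed.speed_cm_s, speed.fs_hz
    else:
        v, fs = np.asarray(speed, dtype=float), fs_hz
    n = v.size
    if n == 0:
        raise ValueError("empty speed series")
    if n / fs < window_s:
        raise ValueError(f"speed series shorter than the {window_s} s averaging window")

    inst = v >= v_thresh
    filt = smooth_lowpass(v, cutoff_hz=lp_cutoff_hz, order=lp_order, fs_hz=fs) >= v_thresh
    half = int(round(window_s * fs / 2))
    win = _centered_mean(v, half) >= v_thresh
    loco = inst & filt & win

    # Merge: any gap between locomotion runs strictly shorter than merge_gap_s.
    min_gap = int(round(merge_gap_s * fs))
    loco_runs = runs_of(loco)
    for (s0, e0), (s1, _) in zip(loco_runs[:-1], loco_runs[1:]):
        if s1 - e0 < min_gap:
            loco[e0:s1] = True

    labels = np.full(n, State.EXCLUDED, dtype=np.int8)
    labels[loco] = State.LOCOMOTION

    before = int(round(excl_before_s * fs))
    after = int(round(excl_after_s * fs))
    near = np.zeros(n, dtype=bool)
    for s0, e0 in runs_of(loco):
        near[max(0, s0 - before) : s0] = True
        near[e0 : min(n, e0 + after)] = True
    stationary = (v < v_thresh) & ~loco & ~near
    labels[stationary] = State.STATIONARY
    return labels


def enumerate_epochs(labels: np.ndarray, fs_hz: float = 40.0) -> pd.DataFrame:
    """Maximal runs of equal state, in temporal order.

    Returns a DataFrame with columns ``state`` (State name), ``start_frame``,
    ``end_frame`` (half-open), ``start_s``, ``end_s`` and an ``excluded``
    flag so excluded stretches are carried but easy to drop.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return pd.DataFrame(
            columns=["state", "start_frame", "end_frame", "start_s", "end_s", "excluded"]
        )
    edges = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate(([0], edges, [labels.size]))
    rows = []
    for s0, e0 in zip(bounds[:-1], bounds[1:]):
        state = State(int(labels[s0]))
        rows.append(
            {
                "state": state.name,
                "start_frame": int(s0),
                "end_frame": int(e0),
                "start_s": s0 / fs_hz,
                "end_s": e0 / fs_hz,
                "excluded": state is State.EXCLUDED,
            }
        )
    return pd.DataFrame(rows)
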