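"""Straight-line, frame-by-frame restatement of the state-labelling rules.

Deliberately unoptimized: explicit Python loops for the window average,
gap merging and exclusion windows, and a hand-written forward-backward
convolution for the zero-phase low-pass, independent of the package's
vectorized implementation.
"""

from __future__ import annotations

import numpy as np

STATIONARY, LOCOMOTION, EXCLUDED = 0, 1, 2


def _hamming_sinc(order: int, cutoff_hz: float, fs_hz: float) -> np.ndarray:
    m = order + 1
    n = np.arange(m) - order / 2.0
    fc = cutoff_hz / fs_hz
    h = 2 * fc * np.sinc(2 * fc * n)
    w = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(m) / order)
    taps = h * w
    return taps / taps.sum()


def _zero_phase_filter(x: np.ndarray, taps: np.ndarray, pad: int) -> np.ndarray:
    # even (mirror) extension without repeating the endpoints
    ext = np.concatenate((x[pad:0:-1], x, x[-2 : -(pad + 2) : -1]))
    fwd = np.convolve(ext, taps)[: ext.size]  # causal forward pass
    bwd = np.convolve(fwd[::-1], taps)[: ext.size][::-1]
    return bwd[pad : pad + x.size]


def brute_force_segment(
    speed: np.ndarray,
    fs_hz: float = 40.0,
    v_thresh: float = 0.1,
    lp_cutoff_hz: float = 0.25,
    lp_order: int = 60,
    window_s: float = 2.0,
    merge_gap_s: float = 0.5,
    excl_after_s: float = 3.0,
    excl_before_s: float = 0.2,
) -> np.ndarray:
    v = np.asarray(speed, dtype=float)
    n = v.size
    taps = _hamming_sinc(lp_order, lp_cutoff_hz, fs_hz)
    filt = _zero_phase_filter(v, taps, 3 * lp_order)

    half = int(round(window_s * fs_hz / 2))
    loco = [False] * n
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win_mean = sum(v[lo:hi]) / (hi - lo)
        loco[i] = v[i] >= v_thresh and filt[i] >= v_thresh and win_mean >= v_thresh

    # merge inter-locomotion gaps strictly shorter than merge_gap_s
    min_gap = int(round(merge_gap_s * fs_hz))
    if True in loco:
        first = loco.index(True)
        last = n - 1 - loco[::-1].index(True)
        i = first
        while i <= last:
            if not loco[i]:
                j = i
                while not loco[j]:
                    j += 1
                if (j - i) < min_gap:
                    for k in range(i, j):
                        loco[k] = True
                i = j
            else:
                i += 1

    labels = [EXCLUDED] * n
    for i in range(n):
        if loco[i]:
            labels[i] = LOCOMOTION

    before = int(round(excl_before_s * fs_hz))
    after = int(round(excl_after_s * fs_hz))
    for i in range(n):
        if labels[i] == LOCOMOTION:
            continue
        if v[i] >= v_thresh:
            continue  # moving but not locomotion: excluded
        near = False
        # within `before` frames before a locomotion frame?
        for j in range(i + 1, min(n, i + before + 1)):
            if loco[j]:
                near = True
                break
        # within `after` frames after a locomotion frame?
        if not near:
            for j in range(max(0, i - after), i):
                if loco[j]:
                    near = True
                    break
        if not near:
            labels[i] = STATIONARY
    return np.asarray(labels, dtype=np.int8)


def random_speed_trace(rng: np.random.Generator, duration_s: float = 30.0, fs_hz: float = 40.0) -> np.ndarray:
    """Piecewise speed trace exercising all rule branches (levels straddle 0.1 cm/s)."""
    n = int(duration_s * fs_hz)
    v = np.zeros(n)
    levels = np.array([0.0, 0.0, 0.05, 0.09, 0.12, 0.5, 1.0, 4.0])
    i = 0
    while i < n:
        seg = int(rng.uniform(0.2, 5.0) * fs_hz)
        level = rng.choice(levels)
        v[i : i + seg] = level
        i += seg
    v += rng.uniform(0.0, 0.02, n)  # jitter keeps values off the exact threshold
    return v
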