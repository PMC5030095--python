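"""Raw fluorescence to neuropil-corrected dF/F0.

The baseline F0 of a neuron is the 5th percentile of its 1 Hz low-pass
smoothed fluorescence, taken per 60 s trial and averaged across all trials
of the session (dark and visual-stimulation trials pooled), so a single
baseline serves both sensory contexts.  dF/F0 = (F - F0) / F0.

Neuropil decontamination factorizes the nonnegative (ROI, neuropil) trace
matrix with NMF by multiplicative updates and returns the component most
correlated with the ROI trace as the demixed somatic signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import smooth_lowpass

__all__ = [
    "DffSeries",
    "DemixResult",
    "compute_f0",
    "compute_dff",
    "nmf_demix",
]


@dataclass
class DffSeries:
    """Relative fluorescence change of one neuron, with its shared baseline.

    ``dff`` may span a whole session (trials concatenated); ``f0`` is the
    single scalar baseline used for every trial and context of the neuron.
    """

    dff: np.ndarray
    f0: float
    neuron_id: str | None = None
    trial_id: np.ndarray | None = None
    fs_hz: float = 40.0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError(f"baseline f0 must be positive, got {self.f0}")


def compute_f0(
    trials: np.ndarray | list,
    percentile: float = 5.0,
    cutoff_hz: float = 1.0,
    order: int = 60,
    fs_hz: float = 40.0,
    smooth: bool = True,
) -> float | np.ndarray:
    """Baseline fluorescence from per-trial low percentiles.

    Parameters
    ----------
    trials
        Raw fluorescence, shaped ``(n_trials, n_frames)`` for one neuron or
        ``(n_neurons, n_trials, n_frames)`` for a batch; a single 1D trace
        is treated as one trial.
    percentile
        Percentile of the smoothed trace taken per trial (linear
        interpolation between order statistics).
    smooth
        If False, skip the low-pass step (used when the input is already
        smoothed).

    Returns
    -------
    The mean across trials of the per-trial percentiles: a scalar for one
    neuron, an ``(n_neurons,)`` array for a batch.
    """
    arr = np.asarray(trials, dtype=float)
    if arr.size == 0:
        raise ValueError("compute_f0 requires at least one trial")
    scalar = arr.ndim <= 2
    if arr.ndim == 1:
        arr = arr[None, :]
    if smooth:
        arr = smooth_lowpass(arr, cutoff_hz=cutoff_hz, order=order, fs_hz=fs_hz, axis=-1)
    per_trial = np.percentile(arr, percentile, axis=-1)
    f0 = per_trial.mean(axis=-1)
    return float(f0) if scalar else f0


def compute_dff(f: np.ndarray, f0: float | np.ndarray) -> np.ndarray:
    """dF/F0 = (F - F0) / F0 with a strictly positive scalar baseline.

    ``f0`` broadcasts against the leading axes of ``f`` so a batch of
    neurons can be normalized in one call.  Output may be negative.
    """
    f = np.asarray(f, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise ValueError("baseline f0 must be positive")
    if f0.ndim and f0.shape[0] != f.shape[0]:
        raise ValueError("f0 batch size does not match trace batch size")
    if f0.ndim:
        f0 = f0.reshape(f0.shape + (1,) * (f.ndim - f0.ndim))
    return (f - f0) / f0


@dataclass
class DemixResult:
    """Outcome of NMF demixing of an (ROI + neuropil) trace matrix."""

    weights: np.ndarray  # (n_traces, rank) nonnegative mixing weights
    components: np.ndarray  # (rank, n_frames) nonnegative component traces
    errors: np.ndarray  # squared reconstruction error, one entry per iteration + init
    soma_index: int  # component most correlated with the ROI trace
    soma_trace: np.ndarray = field(repr=False)  # weights[0, j] * components[j]


def _frob2(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def nmf_demix(
    sources: np.ndarray,
    rank: int = 2,
    n_iter: int = 200,
    tol: float = 1e-10,
    seed: int = 0,
) -> DemixResult:
    """Demix a nonnegative trace matrix by Lee-Seung multiplicative updates.

    Parameters
    ----------
    sources
        ``(n_traces, n_frames)`` nonnegative matrix; row 0 is the somatic
        ROI trace, later rows the surrounding-neuropil traces.  Shift each
        trace by its minimum beforehand if it can be negative.
    rank
        Number of components; must be >= 1 and <= n_traces.
    n_iter, tol
        Update count and relative-improvement stopping tolerance.  With
        ``n_iter=0`` the seeded random initialization is returned unchanged.

    Notes
    -----
    The squared Frobenius reconstruction error is recorded after every
    update pair and is non-increasing, a property of the multiplicative
    update rule that the test-suite asserts per iteration.
    """
    x = np.asarray(sources, dtype=float)
    if x.ndim != 2:
        raise ValueError("sources must be a 2D (n_traces, n_frames) matrix")
    if np.min(x) < 0:
        raise ValueError("sources must be nonnegative; shift traces by their minimum first")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > x.shape[0]:
        raise ValueError(f"rank {rank} exceeds number of traces {x.shape[0]}")

    rng = np.random.default_rng(seed)
    n, t = x.shape
    scale = np.sqrt(max(x.mean(), np.finfo(float).tiny) / rank)
    w = scale * (0.5 + rng.random((n, rank)))
    h = scale * (0.5 + rng.random((rank, t)))
    eps = 1e-12

    errors = [_frob2(x - w @ h)]
    for _ in range(n_iter):
        h *= (w.T @ x) / (w.T @ w @ h + eps)
        w *= (x @ h.T) / (w @ (h @ h.T) + eps)
        errors.append(_frob2(x - w @ h))
        if errors[-2] - errors[-1] <= tol * max(errors[0], eps):
            break

    roi = x[0] - x[0].mean()
    roi_sd = np.linalg.norm(roi)
    corrs = np.zeros(rank)
    if roi_sd > 0:
        for j in range(rank):
            cj = h[j] - h[j].mean()
            denom = roi_sd * np.linalg.norm(cj)
            corrs[j] = (roi @ cj) / denom if denom > 0 else 0.0
    soma_index = int(np.argmax(corrs))
    soma_trace = w[0, soma_index] * h[soma_index]
    return DemixResult(
        weights=w,
        components=h,
        errors=np.asarray(errors),
        soma_index=soma_index,
        soma_trace=soma_trace,
    )
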