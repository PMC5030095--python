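"""Synthetic behavior, stimulus, spiking and GCaMP fluorescence.

The generator emulates the statistical structure the analysis assumes:

* a head-fixed mouse that runs in bouts occupying ~26% of the time in
  darkness and ~41% during visual-stimulation sessions (alternating
  exponential bout/gap renewal process, context-specific gap means);
* interleaved 60 s dark and stimulation trials, each stimulation trial
  bracketed by grey screen and containing one randomized block of eight
  grating directions (static phase then drifting phase);
* per-neuron inhomogeneous-Poisson spiking with multiplicative visual and
  locomotion gains (optionally gated so the locomotion gain applies only
  while visual drive is present), passed through a causal single
  exponential calcium kernel with a shared slow neuropil signal, additive
  Gaussian noise, and a positive offset.

Every neuron carries its generative parameters as a :class:`GroundTruth`
record, so downstream estimates can be checked against the analytic
locomotion modulation index (g - 1) / (g + 1) of a rate gain g.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .behavior import SpeedSeries
from .filters import smooth_lowpass

__all__ = [
    "Context",
    "Phase",
    "BoutModel",
    "StimulusSchedule",
    "GroundTruth",
    "RawTraceSet",
    "Session",
    "ARCHETYPES",
    "generate_schedule",
    "generate_speed",
    "generate_spikes",
    "spikes_to_fluorescence",
    "make_population",
    "simulate_session",
]


class Context:
    """Per-frame visual context codes."""

    DARK = 0
    GREY = 1
    GRATING = 2
    NAMES = {DARK: "DARK", GREY: "GREY", GRATING: "GRATING"}


class Phase:
    """Grating phase codes (NONE outside grating frames)."""

    NONE = -1
    STATIC = 0
    DRIFTING = 1


@dataclass
class BoutModel:
    """Renewal-process description of running behavior.

    Gap means per context are derived from the target run fractions so the
    long-run fraction of time in locomotion converges to ``p_run_dark`` in
    darkness and ``p_run_stim`` during stimulation sessions (bout and gap
    durations are exponential, so fraction = bout / (bout + gap)).
    """

    p_run_dark: float = 0.26
    p_run_stim: float = 0.41
    mean_bout_s: float = 10.0
    speed_mean_cm_s: float = 5.0
    speed_sd_cm_s: float = 1.5
    speed_floor_cm_s: float = 0.5  # keeps bout frames robustly above 0.1 cm/s

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_run_dark < 1.0 and 0.0 <= self.p_run_stim < 1.0):
            raise ValueError("run fractions must lie in [0, 1)")
        if self.mean_bout_s <= 0:
            raise ValueError("mean bout duration must be positive")
        if self.speed_mean_cm_s < 0 or self.speed_sd_cm_s < 0 or self.speed_floor_cm_s < 0:
            raise ValueError("speeds must be nonnegative")

    def mean_gap_s(self, context: str) -> float:
        """Mean stationary gap for ``context`` in {"dark", "stim"} (inf if p_run=0)."""
        p = self.p_run_dark if context == "dark" else self.p_run_stim
        if p == 0.0:
            return np.inf
        return self.mean_bout_s * (1.0 - p) / p


@dataclass
class StimulusSchedule:
    """Per-frame stimulus labels for a session of concatenated 60 s trials."""

    context: np.ndarray  # int8 Context codes
    direction_deg: np.ndarray  # float; NaN outside grating frames
    phase: np.ndarray  # int8 Phase codes
    trial_id: np.ndarray  # int32, per frame
    trial_kind: np.ndarray  # per trial: "dark" | "stim"
    fs_hz: float = 40.0

    def __post_init__(self) -> None:
        n = self.context.size
        for arr in (self.direction_deg, self.phase, self.trial_id):
            if arr.size != n:
                raise ValueError("all per-frame arrays must have equal length")

    @property
    def n_frames(self) -> int:
        return int(self.context.size)

    @property
    def n_trials(self) -> int:
        return int(len(self.trial_kind))

    def stimulus_id(self) -> np.ndarray:
        """Integer stimulus identity per frame (used for sample homogeneity).

        0 = dark, 1 = grey, 10 + 2*direction_index + phase for gratings, so
        a change of direction or of static/drifting phase breaks a
        homogeneous period.
        """
        sid = self.context.astype(np.int64).copy()
        g = self.context == Context.GRATING
        if np.any(g):
            dir_idx = np.round(self.direction_deg[g] / 45.0).astype(np.int64) % 8
            sid[g] = 10 + 2 * dir_idx + self.phase[g]
        return sid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "context": [Context.NAMES[int(c)] for c in self.context],
                "direction_deg": self.direction_deg,
                "phase": self.phase,
                "trial_id": self.trial_id,
            }
        )


def generate_schedule(
    n_trials_dark: int,
    n_trials_stim: int,
    static_s: float = 4.5,
    drift_s: float = 2.0,
    trial_s: float = 60.0,
    grey_lead_s: float = 2.0,
    n_directions: int = 8,
    fs_hz: float = 40.0,
    seed: int = 0,
) -> StimulusSchedule:
    """Randomly interleaved dark and visual-stimulation trials.

    Each stimulation trial starts and ends with grey screen and contains
    one block of ``n_directions`` grating presentations (equally spaced
    directions in randomized order, drawn without replacement per block),
    each a ``static_s`` stationary phase followed by a ``drift_s``
    drifting phase.
    """
    if n_trials_dark < 0 or n_trials_stim < 0:
        raise ValueError("trial counts must be nonnegative")
    if not 4.0 <= static_s <= 5.0:
        raise ValueError("static phase duration must lie in [4, 5] s")
    if drift_s <= 0:
        raise ValueError("drift phase duration must be positive")
    pres_s = static_s + drift_s
    if grey_lead_s + n_directions * pres_s >= trial_s:
        raise ValueError("grating block does not fit in the trial with grey at both ends")

    rng = np.random.default_rng(seed)
    kinds = np.array(["dark"] * n_trials_dark + ["stim"] * n_trials_stim)
    kinds = kinds[rng.permutation(kinds.size)]

    frames_per_trial = int(round(trial_s * fs_hz))
    n = frames_per_trial * kinds.size
    context = np.full(n, Context.DARK, dtype=np.int8)
    direction = np.full(n, np.nan)
    phase = np.full(n, Phase.NONE, dtype=np.int8)
    trial_id = np.repeat(np.arange(kinds.size, dtype=np.int32), frames_per_trial)

    directions = np.arange(n_directions) * (360.0 / n_directions)
    for t, kind in enumerate(kinds):
        if kind != "stim":
            continue
        base = t * frames_per_trial
        context[base : base + frames_per_trial] = Context.GREY
        cursor = base + int(round(grey_lead_s * fs_hz))
        for d in directions[rng.permutation(n_directions)]:
            n_static = int(round(static_s * fs_hz))
            n_drift = int(round(drift_s * fs_hz))
            context[cursor : cursor + n_static + n_drift] = Context.GRATING
            direction[cursor : cursor + n_static + n_drift] = d
            phase[cursor : cursor + n_static] = Phase.STATIC
            phase[cursor + n_static : cursor + n_static + n_drift] = Phase.DRIFTING
            cursor += n_static + n_drift
    return StimulusSchedule(
        context=context,
        direction_deg=direction,
        phase=phase,
        trial_id=trial_id,
        trial_kind=kinds,
        fs_hz=fs_hz,
    )


def generate_speed(
    bout_model: BoutModel,
    schedule: StimulusSchedule,
    seed: int = 0,
) -> SpeedSeries:
    """Running speed from an alternating bout/gap renewal process.

    State transitions are drawn per frame (geometric waiting times, the
    discrete analogue of the exponential renewal process); the gap hazard
    depends on the context of the current frame, so run fractions converge
    to the context targets of the bout model.  Within bouts the speed is a
    1 Hz-smoothed clipped Gaussian around ``speed_mean_cm_s``; outside
    bouts it is exactly zero.
    """
    n = schedule.n_frames
    if n == 0:
        raise ValueError("schedule is empty")
    fs = schedule.fs_hz
    dt = 1.0 / fs
    rng = np.random.default_rng(seed)

    stim_frame = schedule.context != Context.DARK
    p_start_dark = 0.0 if np.isinf(bout_model.mean_gap_s("dark")) else dt / bout_model.mean_gap_s("dark")
    p_start_stim = 0.0 if np.isinf(bout_model.mean_gap_s("stim")) else dt / bout_model.mean_gap_s("stim")
    p_stop = dt / bout_model.mean_bout_s

    u = rng.random(n)
    running = np.zeros(n, dtype=bool)
    state = False
    for i in range(n):
        if state:
            running[i] = True
            if u[i] < p_stop:
                state = False
        else:
            p_start = p_start_stim if stim_frame[i] else p_start_dark
            if u[i] < p_start:
                state = True
                running[i] = True

    raw = rng.normal(bout_model.speed_mean_cm_s, bout_model.speed_sd_cm_s, n)
    if n > 3 * 60:
        raw = smooth_lowpass(raw, cutoff_hz=1.0, order=60, fs_hz=fs)
    profile = np.clip(raw, bout_model.speed_floor_cm_s, None)
    speed = np.where(running, profile, 0.0)
    return SpeedSeries(time_s=np.arange(n) / fs, speed_cm_s=speed, fs_hz=fs)


@dataclass
class GroundTruth:
    """Generative parameters of one synthetic neuron.

    ``loco_gain_*`` act multiplicatively on the firing rate while the
    animal runs, so a neuron with gain g and a rate-linear readout has an
    expected locomotion modulation index of (g - 1) / (g + 1) in that
    context.  With ``gating_flag`` the locomotion gain applies only while
    visual (grating) drive is present.
    """

    neuron_id: str
    archetype: str = "CUSTOM"
    baseline_rate_hz: float = 1.0
    visual_gain: float = 0.0
    tuning_pref_deg: float = 0.0
    tuning_width: float = 0.0  # cosine-bump exponent; 0 = untuned drive
    loco_gain_dark: float = 1.0
    loco_gain_stim: float = 1.0
    gating_flag: bool = False
    neuropil_alpha: float = 0.1
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("baseline_rate_hz", "visual_gain", "loco_gain_dark", "loco_gain_stim",
                     "neuropil_alpha", "noise_sd", "tuning_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.archetype == "NULL" and not (
            self.loco_gain_dark == 1.0 and self.loco_gain_stim == 1.0
        ):
            raise ValueError("NULL archetype must have unit locomotion gains")

    def expected_lmi(self, context: str = "dark") -> float:
        g = self.loco_gain_dark if context == "dark" else self.loco_gain_stim
        return (g - 1.0) / (g + 1.0)

    def to_dict(self) -> dict:
        return asdict(self)


# Archetype response profiles: context-independent locomotion drive (VIP- and
# PV-like), context-dependent drive gated by visual input (SST-like), visually
# tuned excitatory drive, and a non-responsive NULL control.
ARCHETYPES: dict[str, dict] = {
    "EXC_LIKE": dict(baseline_rate_hz=0.8, visual_gain=2.0, tuning_width=4.0,
                     loco_gain_dark=1.2, loco_gain_stim=1.8, gating_flag=False),
    "VIP_LIKE": dict(baseline_rate_hz=1.0, visual_gain=0.0, tuning_width=0.0,
                     loco_gain_dark=4.0, loco_gain_stim=4.0, gating_flag=False),
    "SST_LIKE": dict(baseline_rate_hz=0.6, visual_gain=2.5, tuning_width=0.0,
                     loco_gain_dark=1.0, loco_gain_stim=3.0, gating_flag=True),
    "PV_LIKE": dict(baseline_rate_hz=1.5, visual_gain=1.0, tuning_width=0.0,
                    loco_gain_dark=2.0, loco_gain_stim=2.0, gating_flag=False),
    "NULL": dict(baseline_rate_hz=1.0, visual_gain=0.0, tuning_width=0.0,
                 loco_gain_dark=1.0, loco_gain_stim=1.0, gating_flag=False),
}


def _tuning_factor(gt: GroundTruth, direction_deg: np.ndarray) -> np.ndarray:
    """Multiplicative visual drive 1 + visual_gain * bump(direction)."""
    if gt.visual_gain == 0.0:
        return np.ones_like(direction_deg, dtype=float)
    if gt.tuning_width == 0.0:
        bump = np.ones_like(direction_deg, dtype=float)
    else:
        delta = np.deg2rad(direction_deg - gt.tuning_pref_deg)
        bump = ((1.0 + np.cos(delta)) / 2.0) ** gt.tuning_width
    return 1.0 + gt.visual_gain * bump


def generate_spikes(
    gts: GroundTruth | list[GroundTruth],
    speed: SpeedSeries,
    schedule: StimulusSchedule,
    seed: int = 0,
) -> np.ndarray:
    """Per-frame Poisson spike counts under the multiplicative rate model.

    rate(t) = baseline * tuning(direction(t)) * G(t), with G(t) the
    context-specific locomotion gain while the animal runs (and, for gated
    neurons, only while a grating is on screen), else 1.  Returns an
    ``(n_neurons, n_frames)`` int array (a single GroundTruth gives one row).
    """
    gt_list = [gts] if isinstance(gts, GroundTruth) else list(gts)
    n = schedule.n_frames
    if len(speed) != n:
        raise ValueError("speed and schedule lengths differ")
    fs = schedule.fs_hz
    running = speed.speed_cm_s > 0
    grating = schedule.context == Context.GRATING
    stim_frame = schedule.context != Context.DARK

    rng = np.random.default_rng(seed)
    rates = np.empty((len(gt_list), n))
    for i, gt in enumerate(gt_list):
        tuning = np.ones(n)
        if np.any(grating):
            tuning[grating] = _tuning_factor(gt, schedule.direction_deg[grating])
        g_ctx = np.where(stim_frame, gt.loco_gain_stim, gt.loco_gain_dark)
        apply = running & grating if gt.gating_flag else running
        gain = np.where(apply, g_ctx, 1.0)
        rates[i] = gt.baseline_rate_hz * tuning * gain / fs
    return rng.poisson(rates)


@dataclass
class RawTraceSet:
    """Raw somatic fluorescence traces plus the shared neuropil signal."""

    f: np.ndarray  # (n_neurons, n_frames), strictly positive
    neuropil: np.ndarray  # (n_frames,) shared field-of-view signal
    meta: pd.DataFrame  # neuron_id, animal_id, cell_type, layer
    fs_hz: float = 40.0

    def __post_init__(self) -> None:
        if self.f.ndim != 2:
            raise ValueError("f must be (n_neurons, n_frames)")
        if np.any(self.f <= 0):
            raise ValueError("fluorescence must be strictly positive")
        if len(self.meta) != self.f.shape[0]:
            raise ValueError("meta rows must match number of neurons")


def spikes_to_fluorescence(
    spikes: np.ndarray,
    kernel_decay_s: float = 0.7,
    kernel_amp: float = 0.2,
    neuropil_alpha: float | np.ndarray = 0.0,
    noise_sd: float | np.ndarray = 0.0,
    offset: float = 100.0,
    fs_hz: float = 40.0,
    seed: int = 0,
    neuropil: np.ndarray | None = None,
    neuropil_level: float = 0.5,
    neuropil_mod: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Calcium-indicator forward model.

    F = offset * (1 + kernel_amp * (spikes (*) exp kernel)) + alpha * neuropil + noise

    The kernel is a causal single exponential with instantaneous rise and
    1/e decay time ``kernel_decay_s`` (GCaMP6f-like).  The neuropil trace
    is a shared slow (0.3 Hz low-passed) fluctuation around
    ``neuropil_level * offset``; pass ``neuropil`` to reuse one signal
    across calls.  ``neuropil_alpha`` and ``noise_sd`` may be per-neuron
    arrays.  Returns ``(F, neuropil_trace)`` with F clipped to a tiny
    positive floor (fluorescence is physically nonnegative).
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if kernel_decay_s <= 0:
        raise ValueError("kernel decay must be positive")
    spikes = np.atleast_2d(np.asarray(spikes, dtype=float))
    n_neurons, n = spikes.shape
    rng = np.random.default_rng(seed)

    from scipy.signal import lfilter

    decay = np.exp(-1.0 / (fs_hz * kernel_decay_s))
    conv = lfilter([1.0], [1.0, -decay], spikes, axis=-1)

    if neuropil is None:
        slow = rng.normal(0.0, 1.0, n)
        if n > 3 * 60:
            slow = smooth_lowpass(slow, cutoff_hz=0.3, order=60, fs_hz=fs_hz)
            sd = slow.std()
            if sd > 0:
                slow = slow / sd
        neuropil = neuropil_level * offset * np.clip(1.0 + neuropil_mod * slow, 0.0, None)

    alpha = np.broadcast_to(np.asarray(neuropil_alpha, dtype=float), (n_neurons,))
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_neurons,))
    noise = rng.normal(0.0, 1.0, (n_neurons, n)) * sd[:, None]
    f = offset * (1.0 + kernel_amp * conv) + alpha[:, None] * neuropil + noise
    return np.maximum(f, 1e-3), neuropil


def make_population(
    population: dict[str, int],
    animal_id: str = "m0",
    layer: str = "L2/3",
    seed: int = 0,
    rate_sigma: float = 0.3,
    alpha_range: tuple[float, float] = (0.05, 0.15),
    noise_sd: float = 2.0,
    directions: np.ndarray | None = None,
) -> list[GroundTruth]:
    """Ground-truth records for a mixed-archetype population.

    Baseline rates are lognormal around the archetype mean (cortical
    firing rates are approximately lognormal across a population), tuning
    preferences are drawn from the stimulus directions, and neuropil
    contamination varies per neuron within ``alpha_range``.
    """
    rng = np.random.default_rng(seed)
    if directions is None:
        directions = np.arange(8) * 45.0
    # an unquoted NULL key in a YAML config parses as None; map it back
    population = {("NULL" if k is None else k): v for k, v in population.items()}
    gts: list[GroundTruth] = []
    i = 0
    for archetype, count in population.items():
        base = ARCHETYPES[archetype]
        for _ in range(count):
            rate = base["baseline_rate_hz"] * rng.lognormal(0.0, rate_sigma)
            gts.append(
                GroundTruth(
                    neuron_id=f"{animal_id}_n{i:04d}",
                    archetype=archetype,
                    baseline_rate_hz=rate,
                    visual_gain=base["visual_gain"],
                    tuning_pref_deg=float(rng.choice(directions)),
                    tuning_width=base["tuning_width"],
                    loco_gain_dark=base["loco_gain_dark"],
                    loco_gain_stim=base["loco_gain_stim"],
                    gating_flag=base["gating_flag"],
                    neuropil_alpha=float(rng.uniform(*alpha_range)),
                    noise_sd=noise_sd,
                )
            )
            i += 1
    return gts


@dataclass
class Session:
    """One simulated animal: behavior, stimulus, traces, and ground truth."""

    animal_id: str
    schedule: StimulusSchedule
    speed: SpeedSeries
    traces: RawTraceSet
    ground_truth: list[GroundTruth] = field(repr=False)


def simulate_session(
    sim_cfg: dict,
    animal_id: str = "m0",
    seed: int = 0,
) -> Session:
    """Generate one full session from a ``simulate:`` config block.

    Recognized keys (all optional, with the defaults of the underlying
    generators): ``population`` (archetype -> count), ``n_trials_dark``,
    ``n_trials_stim``, ``static_s``, ``drift_s``, ``bout`` (BoutModel
    kwargs), ``kernel_decay_s``, ``kernel_amp``, ``offset``, ``noise_sd``,
    ``rate_sigma``, ``alpha_range``, ``layer``, ``fs_hz``.
    """
    fs = float(sim_cfg.get("fs_hz", 40.0))
    ss = np.random.SeedSequence(seed)
    s_sched, s_speed, s_pop, s_spk, s_fl = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5))

    schedule = generate_schedule(
        n_trials_dark=int(sim_cfg.get("n_trials_dark", 8)),
        n_trials_stim=int(sim_cfg.get("n_trials_stim", 12)),
        static_s=float(sim_cfg.get("static_s", 4.5)),
        drift_s=float(sim_cfg.get("drift_s", 2.0)),
        fs_hz=fs,
        seed=s_sched,
    )
    bout = BoutModel(**sim_cfg.get("bout", {}))
    speed = generate_speed(bout, schedule, seed=s_speed)
    gts = make_population(
        sim_cfg.get("population", {"EXC_LIKE": 4, "VIP_LIKE": 4, "SST_LIKE": 4,
                                   "PV_LIKE": 4, "NULL": 4}),
        animal_id=animal_id,
        layer=sim_cfg.get("layer", "L2/3"),
        seed=s_pop,
        rate_sigma=float(sim_cfg.get("rate_sigma", 0.3)),
        alpha_range=tuple(sim_cfg.get("alpha_range", (0.05, 0.15))),
        noise_sd=float(sim_cfg.get("noise_sd", 2.0)),
    )
    spikes = generate_spikes(gts, speed, schedule, seed=s_spk)
    f, neuropil = spikes_to_fluorescence(
        spikes,
        kernel_decay_s=float(sim_cfg.get("kernel_decay_s", 0.7)),
        kernel_amp=float(sim_cfg.get("kernel_amp", 0.2)),
        neuropil_alpha=np.array([gt.neuropil_alpha for gt in gts]),
        noise_sd=np.array([gt.noise_sd for gt in gts]),
        offset=float(sim_cfg.get("offset", 100.0)),
        fs_hz=fs,
        seed=s_fl,
    )
    meta = pd.DataFrame(
        {
            "neuron_id": [gt.neuron_id for gt in gts],
            "animal_id": animal_id,
            "cell_type": [gt.archetype for gt in gts],
            "layer": sim_cfg.get("layer", "L2/3"),
        }
    )
    traces = RawTraceSet(f=f, neuropil=neuropil, meta=meta, fs_hz=fs)
    return Session(animal_id=animal_id, schedule=schedule, speed=speed,
                   traces=traces, ground_truth=gts)
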