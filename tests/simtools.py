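"""Shared builders for synthetic-session tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from locomod.behavior import segment_states
from locomod.pipeline import analyze_session, process_session
from locomod.simulate import (
    ARCHETYPES,
    BoutModel,
    GroundTruth,
    RawTraceSet,
    Session,
    generate_schedule,
    generate_speed,
    generate_spikes,
    spikes_to_fluorescence,
)


def child_seeds(seed: int | np.random.SeedSequence, n: int) -> list[int]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def build_session(
    population: dict[str, int],
    animal_id: str,
    seed: int,
    n_trials_dark: int = 8,
    n_trials_stim: int = 12,
    neuropil_alpha: float = 0.1,
    noise_sd: float = 2.0,
    rate_sigma: float = 0.3,
    baseline_override: float | None = None,
    gain_override: tuple[float, float] | None = None,
) -> Session:
    """One session of archetype neurons with per-neuron rate heterogeneity."""
    seeds = child_seeds(seed, 5)
    schedule = generate_schedule(n_trials_dark, n_trials_stim, seed=seeds[0])
    speed = generate_speed(BoutModel(), schedule, seed=seeds[1])
    rng = np.random.default_rng(seeds[2])
    gts: list[GroundTruth] = []
    i = 0
    for archetype, count in population.items():
        base = ARCHETYPES[archetype]
        for _ in range(count):
            g_dark, g_stim = (
                gain_override
                if gain_override is not None
                else (base["loco_gain_dark"], base["loco_gain_stim"])
            )
            gts.append(
                GroundTruth(
                    neuron_id=f"{animal_id}_n{i:04d}",
                    archetype=archetype,
                    baseline_rate_hz=(baseline_override or base["baseline_rate_hz"])
                    * rng.lognormal(0.0, rate_sigma),
                    visual_gain=base["visual_gain"],
                    tuning_pref_deg=float(rng.choice(np.arange(8) * 45.0)),
                    tuning_width=base["tuning_width"],
                    loco_gain_dark=g_dark,
                    loco_gain_stim=g_stim,
                    gating_flag=base["gating_flag"],
                    neuropil_alpha=neuropil_alpha,
                    noise_sd=noise_sd,
                )
            )
            i += 1
    spikes = generate_spikes(gts, speed, schedule, seed=seeds[3])
    f, neuropil = spikes_to_fluorescence(
        spikes,
        neuropil_alpha=neuropil_alpha,
        noise_sd=noise_sd,
        seed=seeds[4],
    )
    meta = pd.DataFrame(
        {
            "neuron_id": [gt.neuron_id for gt in gts],
            "animal_id": animal_id,
            "cell_type": [gt.archetype for gt in gts],
            "layer": "L2/3",
        }
    )
    return Session(animal_id, schedule, speed, RawTraceSet(f, neuropil, meta), gts)


def analyze_sessions(
    sessions: list[Session],
    analyze_cfg: dict,
    seed: int,
) -> dict:
    """Process + segment + analyze a list of sessions; concatenate outputs."""
    results, splits, diffs, metas = [], [], [], []
    boot_cfg = None
    for session, s in zip(sessions, child_seeds(seed, len(sessions))):
        dff, _ = process_session(session)
        labels = segment_states(session.speed)
        out = analyze_session(session, dff, labels, analyze_cfg, seed=s)
        results.append(out["results"])
        splits.append(out["splits"])
        diffs.extend(out["diffs"])
        metas.append(session.traces.meta)
        boot_cfg = out["boot_cfg"]
    return {
        "results": pd.concat(results, ignore_index=True),
        "splits": pd.concat(splits, ignore_index=True),
        "diffs": diffs,
        "meta": pd.concat(metas, ignore_index=True),
        "boot_cfg": boot_cfg,
    }
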