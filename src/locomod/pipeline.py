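"""End-to-end orchestration: simulate -> process -> segment -> analyze ->
classify -> report.

Every stage is seeded from one root seed via ``numpy.random.SeedSequence``
spawning, so a given (config, seed) pair reproduces every output table
byte for byte.  Stage outputs are plain delimited text plus a JSON
provenance record (config hash, seed, package version).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import State, enumerate_epochs, segment_states
from .config import config_hash, default_config, merge_config
from .context import (
    classify_context,
    flag_high_variability,
    flag_high_variability_neurons,
    split_odd_even,
)
from .modulation import (
    BootstrapConfig,
    bin_values,
    bootstrap_lmi,
    classify_responsiveness,
    compute_lmi,
    compute_osi_dsi,
    cross_correlate,
    extract_sample_bins,
)
from .report import aggregate_per_animal, run_population_tests
from .simulate import Context, Phase, Session, simulate_session
from .traces import compute_dff, compute_f0, nmf_demix

__all__ = [
    "CONTEXT_CODE",
    "context_masks",
    "process_session",
    "analyze_session",
    "classify_population",
    "run_pipeline",
]

CONTEXT_CODE = {"dark": Context.DARK, "grey": Context.GREY, "stim": Context.GRATING}

_FLOAT_FMT = "%.10g"


def context_masks(schedule, contexts: list[str]) -> dict[str, np.ndarray]:
    """Per-frame boolean mask for each analysis context.

    ``dark`` covers dark-trial frames, ``grey`` the grey-screen frames of
    stimulation trials, and ``stim`` the grating frames (static and
    drifting phases pooled).
    """
    return {ctx: schedule.context == CONTEXT_CODE[ctx] for ctx in contexts}


def _stim_context_of_bins(stim_id: np.ndarray) -> np.ndarray:
    """Map bin stimulus ids onto analysis context names."""
    out = np.full(stim_id.shape, "stim", dtype=object)
    out[stim_id == Context.DARK] = "dark"
    out[stim_id == Context.GREY] = "grey"
    return out


def process_session(session: Session, proc_cfg: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Raw traces to dF/F0 with one baseline per neuron.

    Optionally demixes each ROI trace against the shared neuropil signal
    (NMF) before the baseline step.  Returns ``(dff, f0)`` with ``dff``
    shaped ``(n_neurons, n_frames)``.
    """
    cfg = merge_config(default_config()["process"], proc_cfg)
    f = session.traces.f
    if cfg["demix"]["enabled"]:
        corrected = np.empty_like(f)
        for i in range(f.shape[0]):
            stack = np.vstack([f[i], session.traces.neuropil])
            stack = stack - stack.min(axis=1, keepdims=True)
            res = nmf_demix(stack, rank=int(cfg["demix"]["rank"]),
                            n_iter=int(cfg["demix"]["n_iter"]),
                            tol=float(cfg["demix"]["tol"]), seed=i)
            # keep the demixed somatic component on a positive offset so the
            # percentile baseline stays well-defined
            corrected[i] = res.soma_trace + f[i].min()
        f = corrected
    n_trials = session.schedule.n_trials
    per_trial = f.reshape(f.shape[0], n_trials, -1)
    f0 = compute_f0(per_trial, percentile=float(cfg["percentile"]),
                    cutoff_hz=float(cfg["cutoff_hz"]), order=int(cfg["filter_order"]),
                    fs_hz=session.traces.fs_hz)
    return compute_dff(f, f0), np.atleast_1d(f0)


def analyze_session(
    session: Session,
    dff: np.ndarray,
    labels: np.ndarray,
    analyze_cfg: dict | None = None,
    seed: int = 0,
) -> dict:
    """Per-neuron LMI statistics for every analysis context of one session.

    Returns a dict with ``results`` (long table: neuron x context),
    ``splits`` (odd/even epoch LMIs), ``diffs`` (per-neuron across-context
    bootstrap difference of LMI, stim - dark), ``tuning`` (per-neuron
    OSI/DSI from drifting-phase responses, when gratings were shown) and
    optionally ``xcorr``.
    """
    cfg = merge_config(default_config()["analyze"], analyze_cfg)
    boot_cfg = BootstrapConfig(
        n_boot=int(cfg["n_boot"]),
        inter_sample_corr=float(cfg["inter_sample_corr"]),
        ci_level=float(cfg["ci_level"]),
        lmi_thresh=float(cfg["lmi_thresh"]),
        min_samples=int(cfg["min_samples"]),
        min_state_s=float(cfg["min_state_s"]),
    )
    fs = session.traces.fs_hz
    schedule = session.schedule
    meta = session.traces.meta
    contexts = list(cfg["contexts"])
    masks = context_masks(schedule, contexts)

    sid = schedule.stimulus_id()
    bins = extract_sample_bins(labels, sid, fs_hz=fs, bin_s=float(cfg["bin_s"]),
                               spacing_s=float(cfg["spacing_s"]))
    vals = bin_values(dff, bins, fs_hz=fs, bin_s=float(cfg["bin_s"]))
    vals = np.atleast_2d(vals)
    bin_ctx = _stim_context_of_bins(bins["stim_id"].to_numpy()) if len(bins) else np.array([])
    bin_state = bins["state"].to_numpy() if len(bins) else np.array([])

    n_neurons = dff.shape[0]
    root = np.random.SeedSequence(seed)
    neuron_seeds = root.spawn(n_neurons)

    # visual tuning from drifting-phase responses per direction
    directions = np.arange(8) * 45.0
    drifting = schedule.phase == Phase.DRIFTING
    tuning_rows = []
    if np.any(drifting):
        for i in range(n_neurons):
            per_dir = np.array([
                dff[i, drifting & (schedule.direction_deg == d)].mean()
                for d in directions
            ])
            # dF/F0 means can dip below 0; tuning indices need nonnegative drive
            res = compute_osi_dsi(np.clip(per_dir, 0.0, None), directions,
                                  neuron_id=meta["neuron_id"].iloc[i])
            tuning_rows.append(
                dict(neuron_id=res.neuron_id, osi=res.osi, dsi=res.dsi,
                     pref_direction_deg=res.pref_direction_deg, valid=res.valid)
            )

    result_rows, split_rows, diff_rows, xcorr_rows = [], [], [], []
    for i in range(n_neurons):
        nid = meta["neuron_id"].iloc[i]
        ctx_seeds = dict(zip(contexts, neuron_seeds[i].spawn(len(contexts))))
        per_ctx: dict[str, tuple] = {}
        for ctx in contexts:
            mask = masks[ctx]
            res = compute_lmi(dff[i], labels, mask, fs_hz=fs,
                              min_state_s=boot_cfg.min_state_s,
                              neuron_id=nid, context=ctx)
            sel = bin_ctx == ctx if len(bins) else np.zeros(0, bool)
            lv = vals[i, sel & (bin_state == State.LOCOMOTION)] if len(bins) else np.empty(0)
            sv = vals[i, sel & (bin_state == State.STATIONARY)] if len(bins) else np.empty(0)
            rng = np.random.default_rng(ctx_seeds[ctx])
            bres = bootstrap_lmi(lv, sv, boot_cfg, rng)
            res.ci_low, res.ci_high = bres.ci_low, bres.ci_high
            res.n_samples_locomotion = int(lv.size)
            res.n_samples_stationary = int(sv.size)
            res.valid = bool(res.valid and bres.valid)
            res.responsive_class = (
                classify_responsiveness(res.lmi, res.ci_low, res.ci_high, boot_cfg)
                if res.valid else "NONE"
            )
            per_ctx[ctx] = (res, bres)
            result_rows.append(
                dict(neuron_id=nid, animal_id=meta["animal_id"].iloc[i],
                     cell_type=meta["cell_type"].iloc[i], layer=meta["layer"].iloc[i],
                     context=ctx, r_l=res.r_l, r_s=res.r_s, lmi=res.lmi,
                     ci_low=res.ci_low, ci_high=res.ci_high,
                     n_samples_locomotion=res.n_samples_locomotion,
                     n_samples_stationary=res.n_samples_stationary,
                     responsive_class=res.responsive_class, valid=res.valid)
            )
            split = split_odd_even(dff[i], labels, mask, neuron_id=nid, context=ctx)
            split_rows.append(
                dict(neuron_id=nid, animal_id=meta["animal_id"].iloc[i],
                     cell_type=meta["cell_type"].iloc[i], layer=meta["layer"].iloc[i],
                     context=ctx, lmi_odd=split.lmi_odd, lmi_even=split.lmi_even,
                     variability=split.variability, valid=split.valid)
            )
            if cfg.get("xcorr"):
                try:
                    lags, corr, zero = cross_correlate(
                        dff[i], session.speed.speed_cm_s, mask,
                        max_lag_s=float(cfg["max_lag_s"]), fs_hz=fs)
                except ValueError:
                    continue
                for lag, c in zip(lags, corr):
                    xcorr_rows.append(dict(neuron_id=nid, context=ctx,
                                           lag_s=float(lag), corr=float(c)))

        if "dark" in per_ctx and "stim" in per_ctx:
            rd, bd = per_ctx["dark"]
            rs, bs = per_ctx["stim"]
            diff_rows.append(
                dict(neuron_id=nid, res_dark=rd, res_stim=rs,
                     boot_dark=bd.boot, boot_stim=bs.boot)
            )

    return {
        "results": pd.DataFrame(result_rows),
        "splits": pd.DataFrame(split_rows),
        "diffs": diff_rows,
        "tuning": pd.DataFrame(tuning_rows),
        "xcorr": pd.DataFrame(xcorr_rows) if cfg.get("xcorr") else None,
        "boot_cfg": boot_cfg,
    }


def classify_population(
    diffs: list[dict],
    splits: pd.DataFrame,
    meta: pd.DataFrame,
    boot_cfg: BootstrapConfig,
    classify_cfg: dict | None = None,
) -> pd.DataFrame:
    """Population-level CD / CI / OTHER labels.

    Flags the most variable neurons of each population, then classifies
    each neuron from its across-context bootstrap difference and
    responsiveness.  With ``variability_scope: "neuron"`` (default) the
    flagged set is the top ``100 - variability_pct`` % of neurons by
    their largest odd/even LMI difference across contexts; with
    ``"context"`` flags are drawn per context separately.
    """
    cfg = merge_config(default_config()["classify"], classify_cfg)
    if cfg.get("variability_scope", "neuron") == "neuron":
        group_cols = ("cell_type",) if cfg["group_by_cell_type"] else ()
        nflags = flag_high_variability_neurons(
            splits, pct=float(cfg["variability_pct"]),
            group_cols=group_cols, min_n=int(cfg["min_group_n"]))

        def _hv(nid: str, ctx: str) -> bool:
            return bool(nflags.get(nid, True))
    else:
        group_cols = ("cell_type", "context") if cfg["group_by_cell_type"] else ("context",)
        flags = flag_high_variability(splits, pct=float(cfg["variability_pct"]),
                                      group_cols=group_cols, min_n=int(cfg["min_group_n"]))
        by_ctx = splits.assign(high_var=flags).set_index(["neuron_id", "context"])["high_var"]

        def _hv(nid: str, ctx: str) -> bool:
            return bool(by_ctx.get((nid, ctx), True))

    meta_idx = meta.set_index("neuron_id")
    rows = []
    for d in diffs:
        nid = d["neuron_id"]
        hv_dark = _hv(nid, "dark")
        hv_stim = _hv(nid, "stim")
        cc = classify_context(
            d["res_dark"], d["res_stim"], d["boot_dark"], d["boot_stim"],
            hv_dark, hv_stim, boot_cfg,
            delta_band=float(cfg["delta_band"]),
            ci_requires_both=bool(cfg["ci_requires_both"]),
        )
        rows.append(
            dict(neuron_id=nid,
                 cell_type=meta_idx.loc[nid, "cell_type"],
                 layer=meta_idx.loc[nid, "layer"],
                 animal_id=meta_idx.loc[nid, "animal_id"],
                 lmi_dark=d["res_dark"].lmi, lmi_stim=d["res_stim"].lmi,
                 delta_lmi=cc.delta_lmi, diff_ci_low=cc.diff_ci_low,
                 diff_ci_high=cc.diff_ci_high,
                 significant_diff=cc.significant_diff,
                 high_var_dark=hv_dark, high_var_stim=hv_stim,
                 label=cc.label, valid=cc.valid)
        )
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: dict | None = None, seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline on simulated sessions; return all tables.

    With ``out_dir`` every stage writes its delimited outputs there plus a
    ``provenance.json`` (config hash, seed, version).  The returned dict
    carries ``sessions``, ``neurons``, ``splits``, ``classification``,
    ``summaries``, ``tests`` and per-session ``labels``/``epochs``.
    """
    cfg = merge_config(default_config(), config)
    if not cfg["simulate"]["enabled"]:
        raise ValueError(
            "run_pipeline requires simulate.enabled; to analyze recorded data, "
            "drive the stage functions directly (see locomod.cli for file-based stages)"
        )
    root = np.random.SeedSequence(seed)
    n_animals = int(cfg["simulate"]["n_animals"])
    animal_seeds = root.spawn(n_animals)

    sessions, all_results, all_splits, all_diffs, metas = [], [], [], [], []
    all_tuning = []
    labels_by_animal, epochs_by_animal = {}, {}
    xcorrs = []
    boot_cfg = None
    for a in range(n_animals):
        animal_id = f"m{a:02d}"
        s_sim, s_an = animal_seeds[a].spawn(2)
        session = simulate_session(cfg["simulate"], animal_id=animal_id,
                                   seed=int(s_sim.generate_state(1)[0] % (2**31)))
        dff, _f0 = process_session(session, cfg["process"])
        labels = segment_states(session.speed, fs_hz=session.speed.fs_hz, **cfg["segment"])
        out = analyze_session(session, dff, labels, cfg["analyze"],
                              seed=int(s_an.generate_state(1)[0] % (2**31)))
        sessions.append(session)
        all_results.append(out["results"])
        all_splits.append(out["splits"])
        all_diffs.extend(out["diffs"])
        all_tuning.append(out["tuning"])
        metas.append(session.traces.meta)
        if out["xcorr"] is not None:
            xcorrs.append(out["xcorr"].assign(animal_id=animal_id))
        boot_cfg = out["boot_cfg"]
        labels_by_animal[animal_id] = labels
        epochs_by_animal[animal_id] = enumerate_epochs(labels, fs_hz=session.speed.fs_hz)

    neurons = pd.concat(all_results, ignore_index=True)
    splits = pd.concat(all_splits, ignore_index=True)
    meta = pd.concat(metas, ignore_index=True)
    classification = classify_population(all_diffs, splits, meta, boot_cfg, cfg["classify"])
    summaries = aggregate_per_animal(neurons)
    tests = run_population_tests(summaries, min_animals=int(cfg["report"]["min_animals"]))

    tuning = pd.concat(all_tuning, ignore_index=True)
    result = {
        "sessions": sessions,
        "neurons": neurons,
        "splits": splits,
        "tuning": tuning,
        "classification": classification,
        "summaries": summaries,
        "tests": tests,
        "labels": labels_by_animal,
        "epochs": epochs_by_animal,
        "xcorr": pd.concat(xcorrs, ignore_index=True) if xcorrs else None,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write(neurons, out_dir / "neurons.csv")
        _write(splits, out_dir / "splits.csv")
        _write(classification, out_dir / "classification.csv")
        if len(tuning):
            _write(tuning, out_dir / "tuning.csv")
        _write(summaries, out_dir / "summaries.csv")
        _write(tests, out_dir / "tests.csv")
        if result["xcorr"] is not None:
            _write(result["xcorr"], out_dir / "xcorr.csv")
        for animal_id, labels in labels_by_animal.items():
            fs = cfg["fs_hz"]
            lab_df = pd.DataFrame(
                {"frame": np.arange(labels.size),
                 "time_s": np.arange(labels.size) / fs,
                 "state": [State(int(v)).name for v in labels]}
            )
            _write(lab_df, out_dir / f"labels_{animal_id}.csv")
            _write(epochs_by_animal[animal_id], out_dir / f"epochs_{animal_id}.csv")
        provenance = {
            "seed": int(seed),
            "config_hash": config_hash(cfg),
            "version": __version__,
            "n_animals": n_animals,
            "n_neurons": int(meta.shape[0]),
        }
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return result
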