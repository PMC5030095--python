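"""Delimited-text readers and writers for the pipeline's on-disk formats.

Everything is plain text: speed and schedule tables, wide trace tables
(one column per neuron plus the shared neuropil), state labels, result
tables, and a JSON ground-truth document keyed by neuron id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import SpeedSeries, State
from .simulate import Context, GroundTruth, RawTraceSet, Session, StimulusSchedule

__all__ = [
    "write_session",
    "read_session",
    "write_labels",
    "read_labels",
]

_FLOAT_FMT = "%.10g"
_CTX_CODE = {name: code for code, name in Context.NAMES.items()}


def write_session(session: Session, out_dir: str | Path) -> None:
    """Write one simulated session: speed, schedule, traces, metadata, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time_s": session.speed.time_s, "speed_cm_s": session.speed.speed_cm_s}
    ).to_csv(out / "speed.csv", index=False, float_format=_FLOAT_FMT)
    session.schedule.to_frame().to_csv(out / "schedule.csv", index=False, float_format=_FLOAT_FMT)

    traces = pd.DataFrame(
        session.traces.f.T, columns=session.traces.meta["neuron_id"].tolist()
    )
    traces["neuropil"] = session.traces.neuropil
    traces.to_csv(out / "traces.csv", index=False, float_format=_FLOAT_FMT)
    session.traces.meta.to_csv(out / "meta.csv", index=False)

    truth = {gt.neuron_id: gt.to_dict() for gt in session.ground_truth}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

    with open(out / "session.json", "w") as fh:
        json.dump(
            {"animal_id": session.animal_id, "fs_hz": session.traces.fs_hz,
             "trial_kind": list(session.schedule.trial_kind)},
            fh, indent=2,
        )


def read_session(in_dir: str | Path) -> Session:
    """Rebuild a :class:`Session` from the tables written by :func:`write_session`."""
    src = Path(in_dir)
    info = json.loads((src / "session.json").read_text())
    fs = float(info["fs_hz"])

    sp = pd.read_csv(src / "speed.csv")
    speed = SpeedSeries(sp["time_s"].to_numpy(), sp["speed_cm_s"].to_numpy(), fs_hz=fs)

    sched = pd.read_csv(src / "schedule.csv")
    schedule = StimulusSchedule(
        context=np.array([_CTX_CODE[c] for c in sched["context"]], dtype=np.int8),
        direction_deg=sched["direction_deg"].to_numpy(dtype=float),
        phase=sched["phase"].to_numpy(dtype=np.int8),
        trial_id=sched["trial_id"].to_numpy(dtype=np.int32),
        trial_kind=np.asarray(info["trial_kind"]),
        fs_hz=fs,
    )

    # keep_default_na: the NULL archetype must stay the string "NULL"
    meta = pd.read_csv(src / "meta.csv", keep_default_na=False)
    traces = pd.read_csv(src / "traces.csv")
    f = traces[meta["neuron_id"].tolist()].to_numpy().T
    neuropil = traces["neuropil"].to_numpy()
    truth_doc = json.loads((src / "ground_truth.json").read_text())
    gts = [GroundTruth(**rec) for rec in truth_doc.values()]
    gts.sort(key=lambda g: list(meta["neuron_id"]).index(g.neuron_id))
    return Session(
        animal_id=info["animal_id"],
        schedule=schedule,
        speed=speed,
        traces=RawTraceSet(f=f, neuropil=neuropil, meta=meta, fs_hz=fs),
        ground_truth=gts,
    )


def write_labels(labels: np.ndarray, path: str | Path, fs_hz: float = 40.0) -> None:
    pd.DataFrame(
        {"frame": np.arange(labels.size),
         "time_s": np.arange(labels.size) / fs_hz,
         "state": [State(int(v)).name for v in labels]}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_labels(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return np.array([State[s] for s in df["state"]], dtype=np.int8)
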