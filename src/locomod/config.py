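"""Configuration handling: defaults, YAML overrides, provenance hashing."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["default_config", "demo_config", "load_config", "merge_config", "config_hash"]


def default_config() -> dict:
    """Full pipeline configuration with the analysis defaults.

    Simulation defaults emulate the recorded sessions: 60 s trials at
    40 Hz (8 dark + 12 stimulation trials, randomly interleaved), running
    ~26% of the time in darkness and ~41% during stimulation, gratings
    4.5 s static + 2 s drifting over 8 directions.  Analysis defaults are
    the published ones (1 Hz / 60th-order baseline filter, 5th percentile,
    0.1 cm/s three-criterion segmentation, R = 0.35, 10000 resamples, 95%
    CI, 0.2 LMI threshold, 5% variability exclusion).
    """
    return {
        "fs_hz": 40.0,
        "simulate": {
            "enabled": True,
            "n_animals": 2,
            "n_trials_dark": 8,
            "n_trials_stim": 12,
            "static_s": 4.5,
            "drift_s": 2.0,
            "population": {"EXC_LIKE": 4, "VIP_LIKE": 4, "SST_LIKE": 4, "PV_LIKE": 4, "NULL": 4},
            "layer": "L2/3",
            "bout": {},
            "kernel_decay_s": 0.7,
            "kernel_amp": 0.2,
            "offset": 100.0,
            "noise_sd": 2.0,
            "rate_sigma": 0.3,
            "alpha_range": [0.05, 0.15],
        },
        "process": {
            "cutoff_hz": 1.0,
            "filter_order": 60,
            "percentile": 5.0,
            "demix": {"enabled": False, "rank": 2, "n_iter": 200, "tol": 1e-10},
        },
        "segment": {
            "v_thresh": 0.1,
            "lp_cutoff_hz": 0.25,
            "lp_order": 60,
            "window_s": 2.0,
            "merge_gap_s": 0.5,
            "excl_after_s": 3.0,
            "excl_before_s": 0.2,
        },
        "analyze": {
            "n_boot": 10000,
            "inter_sample_corr": 0.35,
            "ci_level": 0.95,
            "lmi_thresh": 0.2,
            "min_samples": 5,
            "min_state_s": 5.0,
            "bin_s": 1.0,
            "spacing_s": 2.0,
            "contexts": ["dark", "grey", "stim"],
            "xcorr": False,
            "max_lag_s": 10.0,
        },
        "classify": {
            "variability_pct": 95.0,
            "variability_scope": "neuron",  # "neuron": top 5% of neurons by max
            # across-context variability; "context": 5% per context separately
            "delta_band": 0.2,
            "ci_requires_both": False,
            "group_by_cell_type": True,
            "min_group_n": 20,
        },
        "report": {"min_animals": 3},
    }


def demo_config() -> dict:
    """Small, fast demonstration configuration (the packaged demo)."""
    cfg = default_config()
    cfg["simulate"].update(n_animals=2, n_trials_dark=4, n_trials_stim=6)
    cfg["analyze"].update(n_boot=300)
    cfg["classify"].update(min_group_n=4)
    cfg["report"].update(min_animals=2)
    return cfg


# keys whose dict values are replaced wholesale rather than deep-merged
# (a population spec is a complete enumeration, not a set of overrides)
_REPLACE_KEYS = {"population"}


def merge_config(base: dict, override: dict | None) -> dict:
    """Recursive dict merge; override wins, base is not mutated."""
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if (
            isinstance(val, dict)
            and isinstance(out.get(key), dict)
            and key not in _REPLACE_KEYS
        ):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None, base: dict | None = None) -> dict:
    """Defaults merged with a YAML (or JSON) override file, if given."""
    cfg = base if base is not None else default_config()
    if path is None:
        return copy.deepcopy(cfg)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    return merge_config(cfg, override)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration for provenance records."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
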