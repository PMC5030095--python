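"""Context-dependence classification of locomotion responses.

A neuron is context-dependent (CD) when its locomotion modulation differs
significantly between darkness and visual stimulation — operationalized
as a bootstrap confidence interval of LMI_stim - LMI_dark that excludes
0 — and its within-context responses are reliable.  Reliability comes
from an odd/even split: locomotion and stationary epochs of each context
are numbered in time order and separate LMIs are computed from the odd
and from the even epochs; the 5% of neurons with the largest
|LMI_odd - LMI_even| in a population are flagged unreliable and barred
from the CD label.  A context-independent (CI) neuron is responsive in at
least one context with |LMI_stim - LMI_dark| < 0.2; everything else
(non-responsive or unreliable) is OTHER.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import State, runs_of
from .modulation import BootstrapConfig, LmiResult, _lmi

__all__ = [
    "EpochSplitResult",
    "ContextClass",
    "split_odd_even",
    "flag_high_variability",
    "flag_high_variability_neurons",
    "classify_context",
]


@dataclass
class EpochSplitResult:
    """Odd/even epoch LMIs of one neuron in one context."""

    neuron_id: str | None
    context: str | None
    lmi_odd: float
    lmi_even: float
    variability: float  # |lmi_odd - lmi_even|, NaN when invalid
    valid: bool


def split_odd_even(
    dff: np.ndarray,
    labels: np.ndarray,
    context_mask: np.ndarray | None = None,
    neuron_id: str | None = None,
    context: str | None = None,
) -> EpochSplitResult:
    """Separate LMIs from odd- and even-numbered epochs of one context.

    Locomotion epochs within the context are numbered 1..K in time order,
    stationary epochs independently 1..M.  LMI_odd uses the frames of the
    odd-numbered locomotion and stationary epochs, LMI_even the even ones.
    Fewer than two epochs of either state — or a nonpositive mean-sum in
    either half — makes the split invalid (the neuron is treated as
    unreliable downstream).
    """
    dff = np.asarray(dff, dtype=float)
    labels = np.asarray(labels)
    mask = np.ones_like(labels, dtype=bool) if context_mask is None else np.asarray(context_mask, bool)
    lab = np.where(mask, labels, State.EXCLUDED)
    loco_runs = runs_of(lab == State.LOCOMOTION)
    stat_runs = runs_of(lab == State.STATIONARY)

    invalid = EpochSplitResult(neuron_id, context, np.nan, np.nan, np.nan, valid=False)
    if len(loco_runs) < 2 or len(stat_runs) < 2:
        return invalid

    def mean_over(runs: list[tuple[int, int]]) -> float:
        chunks = [dff[s:e] for s, e in runs]
        return float(np.concatenate(chunks).mean()) if chunks else np.nan

    halves = []
    for parity in (0, 1):  # 0 -> odd-numbered (1st, 3rd, ...), 1 -> even-numbered
        r_l = mean_over(loco_runs[parity::2])
        r_s = mean_over(stat_runs[parity::2])
        halves.append(_lmi(r_l, r_s))
    lmi_odd, lmi_even = halves
    if not (np.isfinite(lmi_odd) and np.isfinite(lmi_even)):
        return invalid
    return EpochSplitResult(
        neuron_id, context, float(lmi_odd), float(lmi_even),
        float(abs(lmi_odd - lmi_even)), valid=True,
    )


def flag_high_variability(
    splits: pd.DataFrame,
    pct: float = 95.0,
    group_cols: tuple[str, ...] = ("cell_type", "context"),
    min_n: int = 20,
) -> pd.Series:
    """Flag the most variable neurons within each population.

    ``splits`` needs columns ``variability``, ``valid`` and the grouping
    columns (by default cell type x context, matching how reliability is
    assessed per population).  A neuron-context is flagged when its
    variability strictly exceeds the ``pct``-th percentile (linear
    interpolation) of the valid variabilities of its group; invalid rows
    are flagged by definition.  Groups with fewer than ``min_n`` valid
    members are too small for a meaningful tail percentile and get no
    flags beyond the invalid ones (with a warning).
    """
    if len(splits) == 0:
        raise ValueError("empty population")
    group_cols = [c for c in group_cols if c in splits.columns]
    flags = pd.Series(False, index=splits.index)
    grouped = splits.groupby(list(group_cols)) if group_cols else [(None, splits)]
    for key, grp in grouped:
        valid = grp[grp["valid"] & np.isfinite(grp["variability"])]
        flags.loc[grp.index[~grp["valid"]]] = True
        if len(valid) < min_n:
            if len(valid):
                warnings.warn(
                    f"population {key!r} has only {len(valid)} valid neurons "
                    f"(< {min_n}); skipping variability flagging",
                    stacklevel=2,
                )
            continue
        thresh = np.percentile(valid["variability"], pct)
        flags.loc[valid.index[valid["variability"] > thresh]] = True
    return flags


def flag_high_variability_neurons(
    splits: pd.DataFrame,
    pct: float = 95.0,
    group_cols: tuple[str, ...] = ("cell_type",),
    min_n: int = 20,
) -> pd.Series:
    """Flag the ``100 - pct`` % most variable *neurons* of each population.

    A neuron's variability is its largest odd/even LMI difference across
    the analyzed contexts, so the excluded set is a fixed fraction of
    neurons (a neuron over the line in either context counts once).
    Neurons with an invalid split in any context are flagged as
    unreliable outright.  Returns a boolean Series indexed by neuron_id.
    """
    if len(splits) == 0:
        raise ValueError("empty population")
    group_cols = [c for c in group_cols if c in splits.columns]
    agg = {"variability": ("variability", "max"), "valid": ("valid", "all")}
    per_neuron = splits.groupby(["neuron_id"] + group_cols, as_index=False).agg(**agg)
    flags = pd.Series(False, index=per_neuron["neuron_id"])
    grouped = per_neuron.groupby(group_cols) if group_cols else [(None, per_neuron)]
    for key, grp in grouped:
        invalid = grp[~grp["valid"] | ~np.isfinite(grp["variability"])]
        flags.loc[invalid["neuron_id"]] = True
        valid = grp.drop(invalid.index)
        if len(valid) < min_n:
            if len(valid):
                warnings.warn(
                    f"population {key!r} has only {len(valid)} valid neurons "
                    f"(< {min_n}); skipping variability flagging",
                    stacklevel=2,
                )
            continue
        thresh = np.percentile(valid["variability"], pct)
        flags.loc[valid.loc[valid["variability"] > thresh, "neuron_id"]] = True
    return flags


@dataclass
class ContextClass:
    """Across-context classification of one neuron."""

    neuron_id: str | None
    delta_lmi: float  # lmi_stim - lmi_dark
    diff_ci_low: float
    diff_ci_high: float
    significant_diff: bool
    high_variability: bool
    label: str  # CD | CI | OTHER
    valid: bool


def classify_context(
    res_dark: LmiResult,
    res_stim: LmiResult,
    boot_dark: np.ndarray,
    boot_stim: np.ndarray,
    high_var_dark: bool,
    high_var_stim: bool,
    cfg: BootstrapConfig | None = None,
    delta_band: float = 0.2,
    ci_requires_both: bool = False,
) -> ContextClass:
    """Label a neuron CD, CI, or OTHER from its two context results.

    ``boot_dark`` / ``boot_stim`` are bootstrap LMI distributions obtained
    by resampling each context's sample pool independently; their
    iteration-wise difference gives the equal-tailed CI of
    LMI_stim - LMI_dark.  CD requires that CI to exclude 0 and reliability
    in both contexts (high-variability neurons are excluded from the CD
    definition only).  CI requires a non-CD neuron with
    |LMI_stim - LMI_dark| < ``delta_band`` that is locomotion responsive
    in at least one context (both, if ``ci_requires_both``).
    """
    cfg = cfg or BootstrapConfig()
    neuron_id = res_dark.neuron_id or res_stim.neuron_id
    high_var = bool(high_var_dark or high_var_stim)
    if not (res_dark.valid and res_stim.valid):
        return ContextClass(neuron_id, np.nan, np.nan, np.nan, False, high_var, "OTHER", valid=False)

    delta = float(res_stim.lmi - res_dark.lmi)
    diff = np.asarray(boot_stim, dtype=float) - np.asarray(boot_dark, dtype=float)
    ok = np.isfinite(diff)
    if ok.sum() == 0:
        return ContextClass(neuron_id, delta, np.nan, np.nan, False, high_var, "OTHER", valid=False)
    alpha = (1.0 - cfg.ci_level) / 2.0
    lo, hi = np.percentile(diff[ok], [100 * alpha, 100 * (1 - alpha)])
    significant = bool(lo > 0 or hi < 0)

    responsive_dark = res_dark.responsive_class != "NONE"
    responsive_stim = res_stim.responsive_class != "NONE"
    responsive = (responsive_dark and responsive_stim) if ci_requires_both else (
        responsive_dark or responsive_stim
    )

    if significant and not high_var:
        label = "CD"
    elif abs(delta) < delta_band and responsive:
        label = "CI"
    else:
        label = "OTHER"
    return ContextClass(
        neuron_id, delta, float(lo), float(hi), significant, high_var, label, valid=True
    )
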