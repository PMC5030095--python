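"""Per-animal aggregation and population statistics.

Animals, not neurons, are the statistical sample: neuron-level results
are collapsed to one summary per animal x cell type x layer x context
(median LMI, mean dF/F0 per state, responsive fractions), and all
population tests run on those per-animal values — Wilcoxon signed-rank
for paired comparisons (locomotion vs stationary, dark vs stimulation),
Kruskal-Wallis for LMI context comparisons, Mann-Whitney U for layer
comparisons, all two-tailed.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["aggregate_per_animal", "run_population_tests"]

_GROUP = ["animal_id", "cell_type", "layer", "context"]


def aggregate_per_animal(neuron_results: pd.DataFrame) -> pd.DataFrame:
    """One summary row per animal x cell type x layer x context.

    ``neuron_results`` must carry per neuron-context rows with columns
    ``animal_id, cell_type, layer, context, r_l, r_s, lmi, responsive_class,
    valid``.  Invalid rows are excluded; an animal group with zero valid
    neurons is omitted with a warning.
    """
    for col in _GROUP + ["lmi", "r_l", "r_s", "responsive_class", "valid"]:
        if col not in neuron_results.columns:
            raise ValueError(f"neuron results missing column {col!r}")
    rows = []
    for key, grp in neuron_results.groupby(_GROUP, sort=True):
        valid = grp[grp["valid"].astype(bool)]
        if len(valid) == 0:
            warnings.warn(f"group {key!r} has no valid neurons; omitted", stacklevel=2)
            continue
        rows.append(
            dict(
                zip(_GROUP, key),
                median_lmi=float(valid["lmi"].median()),
                mean_dff_locomotion=float(valid["r_l"].mean()),
                mean_dff_stationary=float(valid["r_s"].mean()),
                frac_responsive_positive=float((valid["responsive_class"] == "POSITIVE").mean()),
                frac_responsive_negative=float((valid["responsive_class"] == "NEGATIVE").mean()),
                n_neurons=int(len(valid)),
            )
        )
    return pd.DataFrame(rows)


def _record(rows: list, test: str, cell_type: str, context: str, comparison: str,
            stat: float, p: float, direction: str, n: int) -> None:
    rows.append(
        dict(test=test, cell_type=cell_type, context=context, comparison=comparison,
             statistic=float(stat), p_value=float(p), direction=direction, n_animals=n)
    )


def run_population_tests(summaries: pd.DataFrame, min_animals: int = 3) -> pd.DataFrame:
    """The three rank tests over per-animal summaries.

    * signed-rank: mean dF/F0 locomotion vs stationary within cell type and
      context, paired per animal;
    * Kruskal-Wallis: per-animal median LMI, dark vs stimulation, within
      cell type (and layer);
    * Mann-Whitney U: median LMI layer 2/3 vs layer 4 within cell type and
      context, when both layers are present.

    Groups with fewer than ``min_animals`` animals are skipped with a
    warning.  Two-tailed p-values, reported with the effect direction.
    """
    rows: list[dict] = []

    def _skip(what: str, n: int) -> bool:
        if n < min_animals:
            warnings.warn(f"{what}: only {n} animals (< {min_animals}); test skipped",
                          stacklevel=3)
            return True
        return False

    for (cell_type, layer, ctx), grp in summaries.groupby(["cell_type", "layer", "context"]):
        n = len(grp)
        if _skip(f"signed-rank {cell_type}/{layer}/{ctx}", n):
            continue
        x = grp["mean_dff_locomotion"].to_numpy()
        y = grp["mean_dff_stationary"].to_numpy()
        if np.allclose(x, y):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(x, y, alternative="two-sided")
        direction = "locomotion>stationary" if np.median(x - y) > 0 else "locomotion<=stationary"
        _record(rows, "wilcoxon_signed_rank", cell_type, ctx,
                f"loco_vs_stat[{layer}]", stat, p, direction, n)

    for (cell_type, layer), grp in summaries.groupby(["cell_type", "layer"]):
        piv = grp.pivot_table(index="animal_id", columns="context", values="median_lmi")
        if not {"dark", "stim"}.issubset(piv.columns):
            continue
        piv = piv.dropna(subset=["dark", "stim"])
        if _skip(f"kruskal {cell_type}/{layer}", len(piv)):
            continue
        d, s = piv["dark"].to_numpy(), piv["stim"].to_numpy()
        if np.allclose(d, s):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(d, s)
        direction = "stim>dark" if np.median(s) > np.median(d) else "stim<=dark"
        _record(rows, "kruskal_wallis", cell_type, "dark_vs_stim",
                f"median_lmi[{layer}]", stat, p, direction, len(piv))

    for (cell_type, ctx), grp in summaries.groupby(["cell_type", "context"]):
        layers = sorted(grp["layer"].unique())
        if len(layers) < 2:
            continue
        a = grp.loc[grp["layer"] == layers[0], "median_lmi"].to_numpy()
        b = grp.loc[grp["layer"] == layers[1], "median_lmi"].to_numpy()
        if _skip(f"mannwhitney {cell_type}/{ctx}", min(len(a), len(b))):
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        direction = f"{layers[0]}>{layers[1]}" if np.median(a) > np.median(b) else f"{layers[0]}<={layers[1]}"
        _record(rows, "mann_whitney_u", cell_type, ctx,
                f"median_lmi[{layers[0]}_vs_{layers[1]}]", stat, p, direction,
                min(len(a), len(b)))

    df = pd.DataFrame(rows, columns=["test", "cell_type", "context", "comparison",
                                     "statistic", "p_value", "direction", "n_animals"])
    if len(df):
        # report p to 3 significant figures; raw statistic kept as-is
        df["p_value"] = df["p_value"].map(lambda p: float(f"{p:.3g}"))
    return df
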