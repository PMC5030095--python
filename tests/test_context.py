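"""Odd/even reliability splits and context-dependence classification."""

import numpy as np
import pandas as pd
import pytest

from locomod.behavior import State
from locomod.context import (
    classify_context,
    flag_high_variability,
    flag_high_variability_neurons,
    split_odd_even,
)
from locomod.modulation import BootstrapConfig, LmiResult

L, S = State.LOCOMOTION, State.STATIONARY


def _alternating_labels(n_pairs=6, frames=80):
    pattern = np.concatenate([np.full(frames, L), np.full(frames, S)])
    return np.tile(pattern, n_pairs).astype(np.int8)


class TestSplitOddEven:
    def test_state_deterministic_signal_has_zero_variability(self):
        labels = _alternating_labels()
        dff = np.where(labels == L, 2.0, 1.0)
        res = split_odd_even(dff, labels)
        assert res.valid
        assert res.lmi_odd == pytest.approx(res.lmi_even)
        assert res.variability == pytest.approx(0.0)

    def test_odd_only_modulation_detected(self):
        """Gain 3 during odd locomotion epochs only: LMI_odd = 0.5, LMI_even = 0."""
        labels = _alternating_labels(n_pairs=6)
        dff = np.ones(labels.size)
        loco_starts = np.flatnonzero(np.diff(np.concatenate(
            ([0], (labels == L).astype(int)))) == 1)
        for k, start in enumerate(loco_starts):
            if k % 2 == 0:  # 1st, 3rd, ... epochs
                dff[start : start + 80] = 3.0
        res = split_odd_even(dff, labels)
        assert res.lmi_odd == pytest.approx(0.5)
        assert res.lmi_even == pytest.approx(0.0)
        assert res.variability == pytest.approx(0.5)

    def test_single_epoch_invalid(self):
        labels = np.concatenate([np.full(200, L), np.full(200, S),
                                 np.full(200, S)]).astype(np.int8)
        res = split_odd_even(np.ones(600), labels)
        assert not res.valid

    def test_context_mask_restricts_epochs(self):
        labels = _alternating_labels(n_pairs=4)
        mask = np.zeros(labels.size, dtype=bool)
        mask[: labels.size // 2] = True
        dff = np.where(labels == L, 2.0, 1.0)
        res = split_odd_even(dff, labels, mask)
        assert res.valid  # two L and two S epochs remain in the masked half


class TestFlagHighVariability:
    def _pop(self, variabilities, cell_type="VIP_LIKE", context="dark"):
        return pd.DataFrame(
            {"neuron_id": [f"n{i}" for i in range(len(variabilities))],
             "cell_type": cell_type, "context": context,
             "variability": variabilities, "valid": True}
        )

    def test_single_outlier_flagged(self):
        df = self._pop([0.1] * 19 + [0.9])
        flags = flag_high_variability(df, pct=95.0)
        assert flags.sum() == 1
        assert bool(flags.iloc[-1])

    def test_all_equal_none_flagged(self):
        flags = flag_high_variability(self._pop([0.2] * 25), pct=95.0)
        assert flags.sum() == 0

    def test_pct_100_none_flagged(self):
        rng = np.random.default_rng(0)
        flags = flag_high_variability(self._pop(rng.random(40)), pct=100.0)
        assert flags.sum() == 0

    def test_small_group_warns_and_skips(self):
        with pytest.warns(UserWarning, match="valid neurons"):
            flags = flag_high_variability(self._pop([0.1] * 5 + [0.9]), pct=95.0)
        assert flags.sum() == 0

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            flag_high_variability(pd.DataFrame())

    def test_neuron_scope_flags_five_percent_of_neurons(self):
        """Per-neuron rule: 100 neurons x 2 contexts -> exactly 5 flagged."""
        rng = np.random.default_rng(1)
        rows = []
        for i in range(100):
            for ctx in ("dark", "stim"):
                rows.append(dict(neuron_id=f"n{i:03d}", cell_type="SST_LIKE",
                                 context=ctx, variability=rng.random(), valid=True))
        flags = flag_high_variability_neurons(pd.DataFrame(rows), pct=95.0)
        assert flags.sum() == 5

    def test_neuron_scope_invalid_split_flags_neuron(self):
        rows = [dict(neuron_id=f"n{i}", cell_type="X", context=c,
                     variability=0.1, valid=not (i == 0 and c == "dark"))
                for i in range(25) for c in ("dark", "stim")]
        flags = flag_high_variability_neurons(pd.DataFrame(rows), pct=95.0, min_n=5)
        assert bool(flags.loc["n0"])


def test_cd_fraction_monotone_in_context_gap():
    """Widening the simulated dark/stimulation gain gap never lowers the
    fraction of neurons labelled context-dependent.

    Variability flagging is disabled (pct=100) to isolate the
    significance pathway the gain gap acts on.
    """
    import simtools
    from locomod.pipeline import classify_population

    fractions = []
    for g_stim, seed in zip([1.0, 1.75, 2.5, 4.0, 6.0],
                            simtools.child_seeds(77, 5)):
        sessions = [
            simtools.build_session({"SST_LIKE": 50}, f"g{g_stim}_m{k}", s,
                                   gain_override=(1.0, g_stim))
            for k, s in enumerate(simtools.child_seeds(seed, 2))
        ]
        out = simtools.analyze_sessions(
            sessions, {"n_boot": 1000, "contexts": ["dark", "stim"]}, seed=seed)
        cls = classify_population(out["diffs"], out["splits"], out["meta"],
                                  out["boot_cfg"],
                                  {"min_group_n": 20, "variability_pct": 100.0})
        fractions.append((cls["label"] == "CD").mean())
    assert all(b >= a for a, b in zip(fractions, fractions[1:])), fractions


def _res(lmi, lo, hi, cls, context, valid=True):
    return LmiResult(neuron_id="n0", context=context, r_l=np.nan, r_s=np.nan,
                     lmi=lmi, ci_low=lo, ci_high=hi, responsive_class=cls, valid=valid)


class TestClassifyContext:
    def setup_method(self):
        self.rng = np.random.default_rng(2)
        self.cfg = BootstrapConfig(n_boot=2000)

    def _boot(self, center, sd=0.05):
        return self.rng.normal(center, sd, 2000)

    def test_similar_responsive_contexts_are_context_independent(self):
        # VIP-like: strong similar modulation in both contexts
        cc = classify_context(
            _res(0.6, 0.5, 0.7, "POSITIVE", "dark"),
            _res(0.55, 0.45, 0.65, "POSITIVE", "stim"),
            self._boot(0.6), self._boot(0.55), False, False, self.cfg)
        assert cc.label == "CI"
        assert not cc.significant_diff

    def test_gated_modulation_is_context_dependent(self):
        # SST-like: no dark response, clear stimulation response
        cc = classify_context(
            _res(0.0, -0.1, 0.1, "NONE", "dark"),
            _res(0.5, 0.4, 0.6, "POSITIVE", "stim"),
            self._boot(0.0), self._boot(0.5), False, False, self.cfg)
        assert cc.label == "CD"
        assert cc.significant_diff

    def test_high_variability_blocks_cd_only(self):
        cc = classify_context(
            _res(0.0, -0.1, 0.1, "NONE", "dark"),
            _res(0.5, 0.4, 0.6, "POSITIVE", "stim"),
            self._boot(0.0), self._boot(0.5), True, False, self.cfg)
        assert cc.label != "CD"
        # a flagged but responsive neuron with similar LMIs can still be CI
        cc2 = classify_context(
            _res(0.6, 0.5, 0.7, "POSITIVE", "dark"),
            _res(0.55, 0.45, 0.65, "POSITIVE", "stim"),
            self._boot(0.6), self._boot(0.55), True, True, self.cfg)
        assert cc2.label == "CI"

    def test_unresponsive_neuron_is_other(self):
        cc = classify_context(
            _res(0.05, -0.1, 0.2, "NONE", "dark"),
            _res(0.0, -0.15, 0.15, "NONE", "stim"),
            self._boot(0.05), self._boot(0.0), False, False, self.cfg)
        assert cc.label == "OTHER"

    def test_invalid_context_is_other(self):
        cc = classify_context(
            _res(np.nan, np.nan, np.nan, "NONE", "dark", valid=False),
            _res(0.5, 0.4, 0.6, "POSITIVE", "stim"),
            np.full(100, np.nan), self._boot(0.5), False, False, self.cfg)
        assert cc.label == "OTHER" and not cc.valid

    def test_ci_requires_both_flag(self):
        args = (
            _res(0.1, -0.05, 0.25, "NONE", "dark"),
            _res(0.25, 0.21, 0.4, "POSITIVE", "stim"),
            self._boot(0.1, sd=0.15), self._boot(0.25, sd=0.15),
            False, False, self.cfg)
        assert classify_context(*args).label == "CI"
        assert classify_context(*args, ci_requires_both=True).label == "OTHER"

    def test_labels_partition(self):
        for _ in range(50):
            d, s = self.rng.uniform(-0.5, 0.8, 2)
            cc = classify_context(
                _res(d, d - 0.1, d + 0.1, "POSITIVE" if d > 0.2 else "NONE", "dark"),
                _res(s, s - 0.1, s + 0.1, "POSITIVE" if s > 0.2 else "NONE", "stim"),
                self._boot(d), self._boot(s),
                bool(self.rng.random() < 0.1), bool(self.rng.random() < 0.1),
                self.cfg)
            assert cc.label in {"CD", "CI", "OTHER"}
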