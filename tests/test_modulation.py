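"""LMI, sample extraction, bootstrap, responsiveness, xcorr, tuning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locomod.behavior import State
from locomod.modulation import (
    BootstrapConfig,
    bootstrap_lmi,
    classify_responsiveness,
    compute_lmi,
    compute_osi_dsi,
    cross_correlate,
    extract_samples,
    resample_size,
)

FS = 40.0
L, S, X = State.LOCOMOTION, State.STATIONARY, State.EXCLUDED


def _labels(n_loco=400, n_stat=400):
    return np.concatenate([np.full(n_loco, L), np.full(n_stat, S)]).astype(np.int8)


def _dff(r_l, r_s, n_loco=400, n_stat=400):
    return np.concatenate([np.full(n_loco, float(r_l)), np.full(n_stat, float(r_s))])


class TestComputeLmi:
    def test_threefold_increase_is_half(self):
        res = compute_lmi(_dff(0.9, 0.3), _labels())
        assert res.lmi == pytest.approx(0.5)

    def test_no_difference_is_zero(self):
        res = compute_lmi(_dff(0.4, 0.4), _labels())
        assert res.lmi == pytest.approx(0.0)

    def test_fifty_percent_change_is_point_two(self):
        res = compute_lmi(_dff(1.5, 1.0), _labels())
        assert res.lmi == pytest.approx(0.2)

    def test_excluded_frames_ignored(self):
        dff = np.concatenate([_dff(0.9, 0.3), np.full(200, 100.0)])
        labels = np.concatenate([_labels(), np.full(200, X)]).astype(np.int8)
        assert compute_lmi(dff, labels).lmi == pytest.approx(0.5)

    def test_insufficient_state_data_invalid(self):
        res = compute_lmi(_dff(1, 1, n_loco=100), _labels(n_loco=100))
        assert not res.valid and np.isnan(res.lmi)

    def test_nonpositive_denominator_flagged_not_clipped(self):
        res = compute_lmi(_dff(-0.2, -0.3), _labels())
        assert not res.valid and np.isnan(res.lmi)

    @given(r_l=st.floats(0.01, 5.0), r_s=st.floats(0.01, 5.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_antisymmetry_under_state_swap(self, r_l, r_s):
        a = compute_lmi(_dff(r_l, r_s), _labels()).lmi
        b = compute_lmi(_dff(r_s, r_l), _labels()).lmi
        assert a == pytest.approx(-b, abs=1e-12)
        assert -1.0 <= a <= 1.0


class TestExtractSamples:
    def _stim(self, n):
        return np.zeros(n, dtype=np.int64)

    def test_period_shorter_than_bin_yields_nothing(self):
        n = 36  # 0.9 s
        labels = np.full(n, L, dtype=np.int8)
        out = extract_samples(np.ones(n), labels, self._stim(n))
        assert len(out) == 0

    def test_five_second_period_yields_three_bins(self):
        n = 200  # 5.0 s
        labels = np.full(n, L, dtype=np.int8)
        out = extract_samples(np.ones(n), labels, self._stim(n))
        assert list(out["start_frame"]) == [0, 80, 160]

    def test_constant_signal_constant_samples(self):
        n = 120  # 3 s
        labels = np.full(n, S, dtype=np.int8)
        out = extract_samples(np.full(n, 2.5), labels, self._stim(n))
        np.testing.assert_allclose(out["value"], 2.5)

    def test_stimulus_change_breaks_period(self):
        n = 200
        labels = np.full(n, L, dtype=np.int8)
        stim = np.concatenate([np.zeros(100, np.int64), np.ones(100, np.int64)])
        out = extract_samples(np.ones(n), labels, stim)
        # two 2.5 s periods; the second bin of each would cross the period
        # boundary, so each period contributes only its onset bin
        assert list(out["start_frame"]) == [0, 100]

    def test_excluded_frames_break_periods(self):
        n = 200
        labels = np.full(n, L, dtype=np.int8)
        labels[100:104] = X
        out = extract_samples(np.ones(n), labels, self._stim(n))
        assert list(out["start_frame"]) == [0, 104]


class TestBootstrap:
    def test_resample_fraction_identity(self):
        cfg = BootstrapConfig()
        assert cfg.frac == pytest.approx(0.65)
        assert resample_size(100, cfg.frac) == 65
        assert resample_size(40, cfg.frac) == 26

    def test_degenerate_samples_give_point_interval(self):
        cfg = BootstrapConfig(n_boot=500)
        res = bootstrap_lmi(np.full(20, 3.0), np.full(20, 1.0), cfg, rng=0)
        assert res.ci_low == pytest.approx(0.5)
        assert res.ci_high == pytest.approx(0.5)
        np.testing.assert_allclose(res.boot, 0.5)

    def test_deterministic_under_seed(self):
        rng_vals = np.random.default_rng(0).normal(1.0, 0.3, 40)
        cfg = BootstrapConfig(n_boot=200)
        a = bootstrap_lmi(rng_vals[:20], rng_vals[20:], cfg, rng=5)
        b = bootstrap_lmi(rng_vals[:20], rng_vals[20:], cfg, rng=5)
        np.testing.assert_array_equal(a.boot, b.boot)

    def test_null_coverage_near_nominal(self):
        """State-independent samples: the 95% CI contains 0 in ~95% of
        replicates (stratified subsampling makes it conservative)."""
        rng = np.random.default_rng(20)
        cfg = BootstrapConfig(n_boot=400)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            lv = rng.normal(0.2, 0.08, 30)
            sv = rng.normal(0.2, 0.08, 30)
            res = bootstrap_lmi(lv, sv, cfg, rng=rng)
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert hits / n_rep >= 0.90

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(21)
        cfg = BootstrapConfig(n_boot=2000, resample_frac=1.0)
        widths = []
        for n in (20, 80, 320):
            lv = rng.normal(0.6, 0.1, n)
            sv = rng.normal(0.2, 0.1, n)
            res = bootstrap_lmi(lv, sv, cfg, rng=rng)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_too_few_samples_invalid(self):
        res = bootstrap_lmi(np.ones(3), np.ones(30), BootstrapConfig(), rng=0)
        assert not res.valid

    def test_ci_contains_point_estimate_degenerate(self):
        res = bootstrap_lmi(np.full(10, 2.0), np.full(10, 2.0), BootstrapConfig(n_boot=100), rng=0)
        assert res.ci_low <= 0.0 <= res.ci_high


class TestClassifyResponsiveness:
    @pytest.mark.parametrize(
        "lmi, lo, hi, expected",
        [
            (0.5, 0.3, 0.7, "POSITIVE"),
            (0.15, 0.05, 0.25, "NONE"),  # CI excludes 0 but LMI under threshold
            (-0.4, -0.6, -0.2, "NEGATIVE"),
            (0.25, -0.05, 0.55, "NONE"),  # CI straddles 0
            (np.nan, np.nan, np.nan, "NONE"),
        ],
    )
    def test_rule(self, lmi, lo, hi, expected):
        assert classify_responsiveness(lmi, lo, hi) == expected


class TestCrossCorrelate:
    def test_identical_series_unit_correlation(self):
        rng = np.random.default_rng(22)
        v = rng.random(2000)
        _, _, zero = cross_correlate(v, v, max_lag_s=1.0)
        assert zero == pytest.approx(1.0)

    def test_delayed_signal_peaks_at_positive_lag(self):
        rng = np.random.default_rng(23)
        speed = np.convolve(rng.random(4040), np.ones(20) / 20, mode="same")
        dff = np.roll(speed, 40)  # neural signal lags behavior by 1 s
        lags, corr, _ = cross_correlate(dff[80:-80], speed[80:-80], max_lag_s=3.0)
        assert lags[np.nanargmax(corr)] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(24)
        n = 100_000
        _, _, zero = cross_correlate(rng.normal(size=n), np.abs(rng.normal(size=n)),
                                     max_lag_s=0.25)
        assert abs(zero) < 0.02

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cross_correlate(np.ones(100), np.arange(100.0))


class TestOsiDsi:
    def test_single_direction_response_fully_selective(self):
        r = np.zeros(8)
        r[2] = 1.0
        res = compute_osi_dsi(r)
        assert res.osi == pytest.approx(1.0)
        assert res.dsi == pytest.approx(1.0)
        assert res.pref_direction_deg == pytest.approx(90.0)

    def test_uniform_response_unselective(self):
        res = compute_osi_dsi(np.full(8, 0.5))
        assert res.osi == pytest.approx(0.0)
        assert res.dsi == pytest.approx(0.0)

    def test_ratio_convention(self):
        r = np.full(8, 1.0)
        r[0] = 2.0  # pref 2, opposite 1, orthogonal 1
        res = compute_osi_dsi(r)
        assert res.dsi == pytest.approx(1.0 / 3.0)
        assert res.osi == pytest.approx(1.0 / 3.0)

    def test_all_zero_flagged(self):
        res = compute_osi_dsi(np.zeros(8))
        assert not res.valid and np.isnan(res.osi)

    def test_indices_bounded(self):
        rng = np.random.default_rng(25)
        for _ in range(20):
            res = compute_osi_dsi(rng.random(8))
            assert 0.0 <= res.osi <= 1.0
            assert 0.0 <= res.dsi <= 1.0
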