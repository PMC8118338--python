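"""Aligned spectrograms and the three transition-speed metrics."""

import numpy as np
import pytest

import ovitrans as ot
from ovitrans.dynamics import AlignedSpectrogram


def _spectra(power, epoch_len=10.0, normalised=True):
    power = np.asarray(power, dtype=float)
    n_ch, n_ep, n_bins = power.shape
    return ot.PowerSpectra(
        epoch_len_s=epoch_len,
        freqs=np.arange(n_bins) * 0.1,
        power=power,
        artefact_mask=np.zeros((n_ch, n_ep), bool),
        channels=[f"ch{i}" for i in range(n_ch)],
        normalised=normalised,
    )


def _aligned(values, mask=None, epoch_len=10.0):
    values = np.asarray(values, dtype=float)
    n_ep, n_bins = values.shape
    rel = (np.arange(n_ep) - n_ep // 2) * epoch_len
    return AlignedSpectrogram(
        rel_times=rel,
        freqs=np.arange(n_bins) * 0.1,
        values=values,
        mask=np.zeros(n_ep, bool) if mask is None else mask,
        epoch_len_s=epoch_len,
    )


class TestAlign:
    def test_epoch_starting_at_centre_maps_to_zero(self):
        ps = _spectra(np.ones((1, 100, 5)))
        a = ot.align_spectrogram(ps, centre_s=500.0, T_s=300.0)
        assert a.values.shape == (60, 5)
        i0 = np.argmin(np.abs(a.rel_times))
        assert a.rel_times[i0] == pytest.approx(0.0)

    def test_constant_night_gives_constant_window(self):
        ps = _spectra(np.full((1, 100, 4), 2.5))
        a = ot.align_spectrogram(ps, 500.0, 300.0)
        assert np.all(a.values == 2.5)

    def test_mean_of_identical_transitions_equals_any_single_one(self, rng):
        """Averaging aligned spectrograms over identical events is an identity."""
        block = rng.uniform(1, 2, size=(60, 8))
        night = np.tile(block, (10, 1))[None, :, :]
        ps = _spectra(night)
        windows = [
            ot.align_spectrogram(ps, 300.0 + k * 600.0, 300.0).values
            for k in range(9)
        ]
        np.testing.assert_allclose(np.mean(windows, axis=0), windows[0])

    def test_edge_transition_raises(self):
        ps = _spectra(np.ones((1, 50, 4)))
        with pytest.raises(ValueError, match="edge"):
            ot.align_spectrogram(ps, 100.0, 300.0)

    def test_requires_normalised_spectra(self):
        ps = _spectra(np.ones((1, 100, 4)), normalised=False)
        with pytest.raises(ValueError, match="normalised"):
            ot.align_spectrogram(ps, 500.0, 300.0)


class TestMinMax:
    def test_linear_ramp_maps_to_unit_ramp(self):
        vals = np.linspace(2, 6, 20)[:, None]
        out = ot.minmax_normalise_bins(_aligned(vals))
        np.testing.assert_allclose(out.values[:, 0], np.linspace(0, 1, 20))

    def test_constant_bin_set_to_zero_with_warning(self):
        vals = np.ones((20, 2))
        vals[:, 1] = np.linspace(0, 1, 20)
        with pytest.warns(UserWarning, match="flat"):
            out = ot.minmax_normalise_bins(_aligned(vals))
        assert np.all(out.values[:, 0] == 0.0)

    def test_per_bin_min_zero_max_one(self, rng):
        out = ot.minmax_normalise_bins(_aligned(rng.uniform(3, 9, (40, 6))))
        np.testing.assert_allclose(out.values.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.max(axis=0), 1.0, atol=1e-12)

    def test_invariant_to_per_bin_affine_rescaling(self, rng):
        vals = rng.uniform(1, 2, (40, 4))
        base = ot.minmax_normalise_bins(_aligned(vals)).values
        scaled = vals * np.array([2.0, 5.0, 0.3, 11.0]) + np.array([1, 0, 4, 2])
        out = ot.minmax_normalise_bins(_aligned(scaled)).values
        np.testing.assert_allclose(out, base, rtol=1e-9)


class TestVariancePeak:
    def test_constant_spectrogram_peaks_at_zero(self):
        a = _aligned(np.ones((60, 5)))
        a.minmax_normalised = True
        peak, _ = ot.speed_variance_peak(a)
        assert peak == 0.0

    def test_step_gives_quarter_variance_at_step_time(self):
        vals = np.r_[np.zeros((30, 5)), np.ones((30, 5))]
        a = _aligned(vals)
        a.minmax_normalised = True
        peak, t_peak = ot.speed_variance_peak(a, win_s=60.0)
        assert peak == pytest.approx(0.25)
        assert abs(t_peak) <= 10.0

    def test_abrupt_step_beats_ramp_at_equal_endpoints(self):
        step = np.r_[np.zeros((30, 5)), np.ones((30, 5))]
        ramp = np.clip(np.linspace(-2.5, 3.5, 60), 0, 1)[:, None] * np.ones((1, 5))
        for per_bin in (True, False):
            p_step, _ = ot.speed_variance_peak(
                _aligned(step), per_bin=per_bin
            )
            p_ramp, _ = ot.speed_variance_peak(
                _aligned(ramp), per_bin=per_bin
            )
            assert p_step > p_ramp

    def test_all_masked_windows_skipped(self):
        a = _aligned(np.ones((60, 3)), mask=np.ones(60, bool))
        a.minmax_normalised = True
        peak, t_peak = ot.speed_variance_peak(a)
        assert np.isnan(peak) and np.isnan(t_peak)


def _band_series(rel_times, values):
    return np.asarray(rel_times, float), np.asarray(values, float)


def _ramp_series(tau_s, lo=0.2, hi=1.0, epoch=10.0, half_window=300.0):
    """Noiseless series: hi until -tau/2, linear to lo at +tau/2, then flat."""
    t = np.arange(-half_window, half_window, epoch)
    v = np.where(
        t < -tau_s / 2,
        hi,
        np.where(t >= tau_s / 2, lo, hi + (lo - hi) * (t + tau_s / 2) / tau_s),
    )
    return t, v


class TestSpeedDuration:
    def test_noiseless_step_takes_one_epoch(self):
        t = np.arange(-300, 300, 10.0)
        v = np.where(t < 0, 1.0, 0.2)
        sd = ot.speed_duration(t, v)
        assert sd.valid
        assert sd.duration_min == pytest.approx(1 / 6)
        assert sd.start_s == -10.0 and sd.end_s == 0.0

    def test_noiseless_60s_ramp_measures_one_minute(self):
        t, v = _ramp_series(60.0)
        sd = ot.speed_duration(t, v)
        assert sd.valid
        assert sd.duration_min == pytest.approx(1.0, abs=1 / 6)

    def test_flat_series_flagged_never_leaves(self):
        t = np.arange(-300, 300, 10.0)
        sd = ot.speed_duration(t, np.ones_like(t))
        assert not sd.valid
        assert "never leaves" in sd.reason

    def test_duration_increases_with_ramp_length(self):
        durations = []
        for tau in (30.0, 60.0, 120.0, 240.0):
            t, v = _ramp_series(tau)
            sd = ot.speed_duration(t, v)
            assert sd.valid
            durations.append(sd.duration_min)
        assert durations == sorted(durations)

    def test_method_b_endpoints_match_analytic_ramp_within_one_epoch(self):
        """With baselines placed outside the ramp, the SD-band crossings sit
        at the analytic ramp endpoints to epoch resolution."""
        for tau in (60.0, 120.0):
            t, v = _ramp_series(tau)
            sd = ot.speed_duration(t, v, baseline_len_s=200.0, baseline_gap_s=tau / 2)
            assert abs(sd.start_s - (-tau / 2)) <= 10.0 + 1e-9
            assert abs(sd.end_s - tau / 2) <= 10.0 + 1e-9

    def test_duration_invariant_to_positive_scaling(self):
        t, v = _ramp_series(120.0)
        base = ot.speed_duration(t, v)
        scaled = ot.speed_duration(t, 7.5 * v)
        assert scaled.duration_min == pytest.approx(base.duration_min)


class TestGradient:
    def test_fall_of_08_over_a_minute(self):
        sd = ot.SpeedDuration(1.0, -30.0, 30.0, 1.0, 0.2, True)
        assert ot.speed_gradient(sd) == pytest.approx(-0.8)

    def test_equal_endpoints_give_zero(self):
        sd = ot.SpeedDuration(1.0, -30.0, 30.0, 0.7, 0.7, True)
        assert ot.speed_gradient(sd) == 0.0

    def test_zero_length_errors(self):
        sd = ot.SpeedDuration(0.0, 0.0, 0.0, 1.0, 0.2, True)
        with pytest.raises(ValueError, match="zero-length"):
            ot.speed_gradient(sd)

    def test_invalid_duration_errors(self):
        sd = ot.SpeedDuration(np.nan, np.nan, np.nan, np.nan, np.nan, False)
        with pytest.raises(ValueError, match="invalid"):
            ot.speed_gradient(sd)

    def test_gradient_scales_with_the_series(self):
        t, v = _ramp_series(60.0)
        g1 = ot.speed_gradient(ot.speed_duration(t, v))
        g2 = ot.speed_gradient(ot.speed_duration(t, 3.0 * v))
        assert g2 == pytest.approx(3.0 * g1, rel=1e-9)

    def test_halving_ramp_time_roughly_doubles_gradient(self):
        t1, v1 = _ramp_series(120.0)
        t2, v2 = _ramp_series(60.0)
        g1 = abs(ot.speed_gradient(ot.speed_duration(t1, v1)))
        g2 = abs(ot.speed_gradient(ot.speed_duration(t2, v2)))
        assert g2 / g1 == pytest.approx(2.0, rel=0.15)


class TestPrePost:
    def test_constant_at_nrem_level_gives_unit_proportions(self):
        t = np.arange(-300, 300, 10.0)
        pp = ot.prepost_power(t, np.full_like(t, 4.2), 4.2, 1.0, band="delta")
        assert pp.pre_prop_nrem == pytest.approx(1.0)
        assert pp.post_prop_nrem == pytest.approx(1.0)

    def test_programmed_half_and_tenth_levels(self):
        t = np.arange(-300, 300, 10.0)
        v = np.where(t < 0, 0.5 * 4.0, 0.1 * 4.0)
        pp = ot.prepost_power(t, v, mean_nrem_power=4.0, mean_wake_power=2.0)
        assert pp.pre_prop_nrem == pytest.approx(0.5)
        assert pp.post_prop_nrem == pytest.approx(0.1)
        assert pp.pre_prop_wake == pytest.approx(1.0)

    def test_empty_window_flagged(self):
        t = np.arange(-300, 300, 10.0)
        mask = (t >= -240) & (t < -120)
        pp = ot.prepost_power(t, np.ones_like(t), 1.0, 1.0, mask=mask)
        assert not pp.valid
        assert np.isnan(pp.pre)
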