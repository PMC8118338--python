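"""Spectral front end: periodograms, artefact rule, band powers, normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ovitrans as ot
from ovitrans.spectral import MAINS_OMIT_HZ, epoch_total_power


def _rec(signals, fs=250.0):
    return ot.Recording(signals=np.asarray(signals, dtype=float), fs=fs)


def _flat_spectra(n_bins=1251, n_epochs=5, n_channels=1, value=1.0):
    """PowerSpectra with `value` in every 0.1 Hz bin (epoch_len 10 s)."""
    freqs = np.arange(n_bins) * 0.1
    power = np.full((n_channels, n_epochs, n_bins), value)
    return ot.PowerSpectra(
        epoch_len_s=10.0,
        freqs=freqs,
        power=power,
        artefact_mask=np.zeros((n_channels, n_epochs), bool),
        channels=[f"ch{i}" for i in range(n_channels)],
    )


class TestRereference:
    def test_mean_zero_signals_are_fixed_point(self):
        rec = _rec([[1.0] * 100, [-1.0] * 100])
        out = ot.rereference_common_average(rec)
        np.testing.assert_allclose(out.signals, rec.signals)

    def test_subtracts_channel_mean(self):
        rec = _rec([[2.0] * 50, [0.0] * 50])
        out = ot.rereference_common_average(rec)
        np.testing.assert_allclose(out.signals[0], 1.0)
        np.testing.assert_allclose(out.signals[1], -1.0)

    def test_eight_channel_mean_is_zero_at_every_sample(self, rng):
        rec = _rec(rng.standard_normal((8, 2500)))
        out = ot.rereference_common_average(rec)
        np.testing.assert_allclose(out.signals.mean(axis=0), 0.0, atol=1e-12)
        assert out.channels == rec.channels

    def test_single_channel_errors(self):
        with pytest.raises(ValueError, match="cannot re-reference"):
            ot.rereference_common_average(_rec([[1.0] * 10]))


class TestEpochPsd:
    def test_pure_tone_power_concentrates_in_its_bin(self):
        fs, f0 = 250.0, 10.0
        t = np.arange(2500 * 3) / fs
        rec = _rec([np.sin(2 * np.pi * f0 * t)], fs)
        ps = ot.epoch_psd(rec, 10.0)
        assert ps.freqs[1] - ps.freqs[0] == pytest.approx(0.1)
        i0 = np.argmin(np.abs(ps.freqs - f0))
        spectrum = ps.power[0, 0]
        assert spectrum[i0] / spectrum[1:].sum() > 0.99

    def test_zero_signal_gives_zero_power(self):
        ps = ot.epoch_psd(_rec([np.zeros(5000)]), 10.0)
        assert np.all(ps.power == 0)

    def test_trailing_partial_epoch_dropped(self):
        ps = ot.epoch_psd(_rec([np.ones(6200)]), 10.0)
        assert ps.n_epochs == 2

    def test_epoch_longer_than_recording_errors(self):
        with pytest.raises(ValueError):
            ot.epoch_psd(_rec([np.zeros(100)]), 10.0)

    def test_non_integer_epoch_sample_count_errors(self):
        with pytest.raises(ValueError, match="integer sample count"):
            ot.epoch_psd(_rec([np.zeros(1000)], fs=250.0), epoch_len_s=0.75 / 250)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_parseval_bin_sum_equals_variance(self, seed):
        """Sum of one-sided bin powers equals the mean-removed epoch variance."""
        x = np.random.default_rng(seed).standard_normal((1, 2500))
        ps = ot.epoch_psd(_rec(x), 10.0)
        var = (x[0] - x[0].mean()).var()
        np.testing.assert_allclose(ps.power[0, 0].sum(), var, rtol=1e-9)


class TestFlagArtefacts:
    def test_identical_powers_flag_nothing(self):
        ps = _flat_spectra(n_epochs=100)
        out = ot.flag_artefacts(ps)
        assert not out.artefact_mask.any()

    def test_single_outlier_is_the_only_flag(self):
        ps = _flat_spectra(n_bins=10, n_epochs=100, value=0.1)
        ps.power[0, 42] = 10.0  # epoch total 100 vs 1.0 elsewhere
        out = ot.flag_artefacts(ps)
        expected = np.zeros(100, bool)
        expected[42] = True
        np.testing.assert_array_equal(out.artefact_mask[0], expected)

    def test_huge_k_flags_nothing(self, rng):
        ps = _flat_spectra(n_bins=10, n_epochs=50)
        ps.power *= rng.uniform(0.5, 2.0, size=(1, 50, 1))
        out = ot.flag_artefacts(ps, ot.ArtefactRule(k=1e9))
        assert not out.artefact_mask.any()

    def test_idempotent_and_permutation_invariant(self, rng):
        ps = _flat_spectra(n_bins=10, n_epochs=60)
        ps.power *= rng.lognormal(0, 0.5, size=(1, 60, 1))
        once = ot.flag_artefacts(ps)
        twice = ot.flag_artefacts(once)
        np.testing.assert_array_equal(once.artefact_mask, twice.artefact_mask)
        perm = rng.permutation(60)
        ps_p = _flat_spectra(n_bins=10, n_epochs=60)
        ps_p.power = ps.power[:, perm]
        out_p = ot.flag_artefacts(ps_p)
        np.testing.assert_array_equal(out_p.artefact_mask[0], once.artefact_mask[0][perm])

    def test_upper_sided_ignores_low_outliers(self):
        ps = _flat_spectra(n_bins=10, n_epochs=100, value=0.1)
        ps.power[0, 3] = 0.0
        out = ot.flag_artefacts(ps, ot.ArtefactRule(sided="upper"))
        assert not out.artefact_mask.any()


class TestBandPower:
    def test_flat_delta_is_35_units(self):
        ps = _flat_spectra()
        bp = ot.band_power(ps, ot.BandDefinition("delta", 0.5, 4.0))
        np.testing.assert_allclose(bp, 35.0)

    def test_flat_gamma_with_mains_omission_is_890_units(self):
        ps = _flat_spectra()
        band = ot.BandDefinition("gamma", 35.0, 125.0, [MAINS_OMIT_HZ])
        np.testing.assert_allclose(ot.band_power(ps, band), 890.0)

    def test_zero_spectrum_gives_zero_in_every_band(self):
        ps = _flat_spectra(value=0.0)
        for band in ot.DEFAULT_BANDS.values():
            np.testing.assert_allclose(ot.band_power(ps, band), 0.0)

    def test_band_outside_range_errors(self):
        ps = _flat_spectra(n_bins=100)  # covers 0-9.9 Hz
        with pytest.raises(ValueError, match="outside the spectral range"):
            ot.band_power(ps, ot.BandDefinition("gamma", 35.0, 125.0))

    def test_band_partition_sums_to_total(self, rng):
        ps = _flat_spectra()
        ps.power = rng.uniform(size=ps.power.shape)
        edges = [0.5, 4.0, 9.0, 14.0, 35.0, 125.0]
        total = sum(
            ot.band_power(ps, ot.BandDefinition("b", lo, hi))
            for lo, hi in zip(edges[:-1], edges[1:])
        )
        whole = ot.band_power(ps, ot.BandDefinition("all", 0.5, 125.0))
        np.testing.assert_allclose(total, whole, rtol=1e-12)


class TestBandPowerTable:
    def test_long_format_columns_and_values(self):
        ps = _flat_spectra(n_epochs=3, n_channels=2)
        ps.artefact_mask[1, 2] = True
        df = ot.band_power_table(ps)
        assert list(df.columns) == [
            "epoch_index", "t_start_s", "channel", "band", "power", "artefact",
        ]
        assert len(df) == 3 * 2 * len(ot.DEFAULT_BANDS)
        row = df[(df.channel == "ch0") & (df.band == "delta") & (df.epoch_index == 1)]
        assert row["power"].iloc[0] == pytest.approx(35.0)
        assert row["t_start_s"].iloc[0] == pytest.approx(10.0)
        flagged = df[(df.channel == "ch1") & (df.epoch_index == 2)]
        assert (flagged["artefact"] == 1).all()


class TestNormaliseNight:
    def test_identical_epochs_normalise_to_unit_total(self):
        ps = _flat_spectra(n_epochs=7)
        out = ot.normalise_night(ps)
        np.testing.assert_allclose(epoch_total_power(out), 1.0)

    def test_two_epoch_example(self):
        ps = _flat_spectra(n_bins=4, n_epochs=2, value=0.5)
        ps.power[0, 0] = 0.5  # total 2
        ps.power[0, 1] = 1.0  # total 4
        out = ot.normalise_night(ps)
        np.testing.assert_allclose(epoch_total_power(out)[0], [2 / 3, 4 / 3])

    def test_mean_total_is_one_and_idempotent(self, rng):
        ps = _flat_spectra(n_epochs=50)
        ps.power *= rng.lognormal(0, 0.3, size=(1, 50, 1))
        out = ot.normalise_night(ps)
        assert out.normalised
        assert epoch_total_power(out)[0].mean() == pytest.approx(1.0, abs=1e-9)
        again = ot.normalise_night(out)
        np.testing.assert_allclose(again.power, out.power, rtol=1e-12)

    def test_artefact_epochs_excluded_from_the_reference(self):
        ps = _flat_spectra(n_bins=4, n_epochs=3, value=1.0)
        ps.power[0, 2] = 100.0
        ps.artefact_mask[0, 2] = True
        out = ot.normalise_night(ps)
        np.testing.assert_allclose(epoch_total_power(out)[0][:2], 1.0)

    def test_all_artefact_errors(self):
        ps = _flat_spectra(n_epochs=3)
        ps.artefact_mask[:] = True
        with pytest.raises(ValueError, match="no artefact-free"):
            ot.normalise_night(ps)
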