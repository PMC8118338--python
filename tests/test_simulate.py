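"""Synthetic night generator: determinism, scripted features, spectral truth."""

import dataclasses

import numpy as np
import pytest

import ovitrans as ot
from ovitrans.spectral import DEFAULT_BANDS, band_power, epoch_psd


QUICK = dict(night_len_h=1.0, n_channels=2, rem_prob=0.0, prewake_delta_frac=1.0,
             artefact_rate_per_h=0.0)


class TestDeterminism:
    def test_same_seed_gives_bit_identical_signals(self):
        cfg = ot.SimConfig(seed=13, **QUICK)
        rec1, gt1 = ot.generate_recording(cfg)
        rec2, gt2 = ot.generate_recording(dataclasses.replace(cfg))
        np.testing.assert_array_equal(rec1.signals, rec2.signals)
        assert list(gt1.hypnogram) == list(gt2.hypnogram)

    def test_different_seeds_differ(self):
        rec1, _ = ot.generate_recording(ot.SimConfig(seed=1, **QUICK))
        rec2, _ = ot.generate_recording(ot.SimConfig(seed=2, **QUICK))
        assert not np.array_equal(rec1.signals, rec2.signals)


class TestScheduleAndGroundTruth:
    def test_explicit_schedule_is_respected(self):
        sched = [("WAKE", 600.0), ("NREM", 900.0), ("WAKE", 600.0)]
        cfg = ot.SimConfig(schedule=sched, seed=0, **QUICK)
        rec, gt = ot.generate_recording(cfg)
        assert rec.duration_s == pytest.approx(2100.0)
        assert list(gt.switches["direction"]) == ["TO_SLEEP", "TO_WAKE"]
        np.testing.assert_allclose(gt.switches["t_s"], [600.0, 1500.0])
        assert list(gt.hypnogram[:60]) == ["WAKE"] * 60
        assert list(gt.hypnogram[60:150]) == ["NREM"] * 90

    def test_zero_ramp_band_power_steps_at_the_switch(self):
        sched = [("WAKE", 600.0), ("NREM", 600.0)]
        cfg = ot.SimConfig(schedule=sched, ramp_sleep_s=0.0, seed=3, **QUICK)
        rec, gt = ot.generate_recording(cfg)
        delta = band_power(epoch_psd(rec), DEFAULT_BANDS["delta"])[0]
        wake_level = delta[:59].mean()
        nrem_level = delta[61:].mean()
        # every epoch strictly before/after the switch sits at its state level
        assert delta[58] < (wake_level + nrem_level) / 2
        assert delta[61] > (wake_level + nrem_level) / 2

    def test_hypnogram_matches_switch_times(self):
        cfg = ot.SimConfig(night_len_h=3.0, n_channels=2, seed=8,
                           prewake_delta_frac=1.0, artefact_rate_per_h=0.0)
        _, gt = ot.generate_recording(cfg)
        for _, sw in gt.switches.iterrows():
            e = int(sw.t_s / 10)
            before, after = gt.hypnogram[e - 1], gt.hypnogram[e]
            if sw.direction == "TO_WAKE":
                assert after == "WAKE" and before in ("NREM", "REM")
            else:
                assert before == "WAKE" and after in ("NREM", "REM")

    def test_night_shorter_than_one_bout_errors(self):
        with pytest.raises(ValueError, match="shorter than one bout"):
            ot.generate_recording(ot.SimConfig(night_len_h=0.01))

    def test_rem_segments_recorded_in_hypnogram(self):
        cfg = ot.SimConfig(night_len_h=4.0, n_channels=2, rem_prob=1.0, seed=4,
                           prewake_delta_frac=1.0, artefact_rate_per_h=0.0)
        _, gt = ot.generate_recording(cfg)
        assert (gt.hypnogram == "REM").sum() > 0
        assert (gt.switches["from_state"] == "REM").any()


class TestSpectralGroundTruth:
    def test_nrem_to_wake_delta_power_ratio_matches_profiles(self):
        """Measured epoch delta power ratio equals the programmed profile ratio."""
        cfg = ot.SimConfig(night_len_h=3.0, n_channels=2, seed=6, **{
            k: v for k, v in QUICK.items() if k != "night_len_h" and k != "n_channels"
        })
        rec, gt = ot.generate_recording(cfg)
        delta = band_power(epoch_psd(rec), DEFAULT_BANDS["delta"])[0]
        sw = gt.switches["t_s"].to_numpy()
        t_mid = np.arange(len(gt.hypnogram)) * 10 + 5
        far = np.min(np.abs(t_mid[:, None] - sw[None, :]), axis=1) > 150
        nrem = delta[(gt.hypnogram == "NREM") & far].mean()
        wake = delta[(gt.hypnogram == "WAKE") & far].mean()
        programmed = (
            gt.expected_band_power["NREM"]["delta"]
            / gt.expected_band_power["WAKE"]["delta"]
        )
        assert nrem / wake == pytest.approx(programmed, rel=0.1)

    def test_measured_ssr2_matches_analytic_expectation(self):
        cfg = ot.SimConfig(night_len_h=2.0, n_channels=2, seed=10, **{
            k: v for k, v in QUICK.items() if k not in ("night_len_h", "n_channels")
        })
        rec, gt = ot.generate_recording(cfg)
        ssr = ot.compute_ssr(epoch_psd(rec))
        sw = gt.switches["t_s"].to_numpy()
        t_mid = np.arange(len(gt.hypnogram)) * 10 + 5
        far = np.min(np.abs(t_mid[:, None] - sw[None, :]), axis=1) > 150
        for state in ("WAKE", "NREM"):
            got = ssr.ssr2[0, (gt.hypnogram == state) & far].mean()
            assert got == pytest.approx(gt.expected_ssr2[state], abs=0.01)

    def test_artefact_epochs_are_large_outliers(self):
        cfg = ot.SimConfig(night_len_h=1.0, n_channels=2, seed=12,
                           rem_prob=0.0, prewake_delta_frac=1.0,
                           artefact_rate_per_h=10.0)
        rec, gt = ot.generate_recording(cfg)
        ps = epoch_psd(rec)
        tot = ps.power.sum(axis=2)
        for c, ch in enumerate(rec.channels):
            eps = gt.artefact_epochs[ch]
            if eps:
                clean = np.delete(tot[c], eps)
                assert tot[c, eps].min() > 10 * np.median(clean)

    def test_prewake_decline_solved_against_schedule(self):
        cfg = ot.SimConfig(night_len_h=4.0, n_channels=2, seed=42, rem_prob=0.0,
                           prewake_delta_frac=0.5, artefact_rate_per_h=0.0)
        rec, gt = ot.generate_recording(cfg)
        assert gt.prewake_delta_power is not None
        delta = band_power(epoch_psd(rec), DEFAULT_BANDS["delta"])[0]
        # crossfade epochs at the switches sit between state levels; keep the
        # oracle mean to NREM plateau epochs (declined plateau included)
        sw = gt.switches["t_s"].to_numpy()
        t_mid = np.arange(len(gt.hypnogram)) * 10 + 5
        far = np.min(np.abs(t_mid[:, None] - sw[None, :]), axis=1) > 60
        mean_nrem = delta[(gt.hypnogram == "NREM") & far].mean()
        assert gt.prewake_delta_power / mean_nrem == pytest.approx(0.5, abs=0.03)
        # staging is unaffected: declined epochs keep the NREM SSR2
        assert gt.expected_ssr2["NREM_PRE"] == pytest.approx(
            gt.expected_ssr2["NREM"], abs=1e-9
        )


class TestCohort:
    def test_two_groups_times_five_gives_ten_members(self):
        cfgs = {"a": ot.SimConfig(**QUICK), "b": ot.SimConfig(**QUICK)}
        members, manifest = ot.generate_cohort(cfgs, n_per_group=5)
        assert len(members) == 10
        assert len(manifest) == 10
        assert set(manifest["group"]) == {"a", "b"}
        assert manifest["seed"].is_unique

    def test_group_parameters_propagate(self):
        cfgs = {
            "slow": ot.SimConfig(ramp_wake_s=120.0, **QUICK),
            "fast": ot.SimConfig(ramp_wake_s=30.0, **QUICK),
        }
        _, manifest = ot.generate_cohort(cfgs, n_per_group=2)
        ramps = manifest.groupby("group")["ramp_wake_s"].unique()
        assert ramps["slow"] == [120.0] and ramps["fast"] == [30.0]

    def test_duplicate_seeds_error(self):
        cfgs = {"a": ot.SimConfig(**QUICK), "b": ot.SimConfig(**QUICK)}
        with pytest.raises(ValueError, match="duplicate seed"):
            ot.generate_cohort(cfgs, n_per_group=2,
                               seeds={"a": [1, 2], "b": [2, 3]})

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            ot.generate_cohort({"a": ot.SimConfig(**QUICK)}, n_per_group=0)
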