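"""Shared fixtures: synthetic nights and cohorts reused across test modules.

Expensive end-to-end objects are session-scoped so the full default night and
the two cohorts are generated and analysed exactly once per test run.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

import ovitrans as ot


@pytest.fixture(scope="session")
def default_night():
    """Full-scale default synthetic night (10.6 h, 8 channels) + analysis."""
    cfg = ot.SimConfig(seed=7)
    t0 = time.process_time()
    rec, gt = ot.generate_recording(cfg)
    res = ot.analyse_night(rec, hypnogram=gt.hypnogram_df())
    elapsed = time.process_time() - t0
    return {"config": cfg, "ground_truth": gt, "result": res, "elapsed_s": elapsed}


@pytest.fixture(scope="session")
def small_night():
    """Quick night (1.5 h, 2 channels) for pipeline-level unit tests."""
    cfg = ot.SimConfig(night_len_h=1.5, n_channels=2, seed=21)
    rec, gt = ot.generate_recording(cfg)
    return rec, gt


def twelve_switch_schedule() -> list[tuple[str, float]]:
    """Hand-built schedule with 12 NREM->WAKE switches, 3 preceded by REM."""
    segs = [("WAKE", 660.0)]
    for k in range(12):
        if k in (2, 6, 9):
            segs += [("NREM", 600.0), ("REM", 120.0)]
        else:
            segs += [("NREM", 720.0)]
        segs += [("WAKE", 660.0)]
    return segs


@pytest.fixture(scope="session")
def twelve_switch_night():
    """Scripted night with 12 programmed awakenings at abrupt (30 s) ramps."""
    cfg = ot.SimConfig(
        schedule=twelve_switch_schedule(),
        ramp_wake_s=30.0,
        ramp_sleep_s=30.0,
        prewake_delta_frac=1.0,
        rem_prob=0.0,
        seed=5,
    )
    t0 = time.process_time()
    rec, gt = ot.generate_recording(cfg)
    res = ot.analyse_night(rec, hypnogram=gt.hypnogram_df())
    elapsed = time.process_time() - t0
    return {"config": cfg, "ground_truth": gt, "result": res, "elapsed_s": elapsed}


def speed_cohort_configs() -> dict[str, ot.SimConfig]:
    """Ramp-contrast cohort: groups differ only in crossfade duration."""
    base = dict(night_len_h=4.0, n_channels=8, rem_prob=0.0, prewake_delta_frac=1.0)
    return {
        "gradual": ot.SimConfig(ramp_wake_s=120.0, ramp_sleep_s=120.0, **base),
        "abrupt": ot.SimConfig(ramp_wake_s=30.0, ramp_sleep_s=30.0, **base),
    }


def prepost_cohort_configs() -> dict[str, ot.SimConfig]:
    """Pre-waking delta contrast cohort: groups differ only in the decline."""
    base = dict(
        night_len_h=4.0, n_channels=8, rem_prob=0.0,
        ramp_wake_s=60.0, ramp_sleep_s=60.0,
    )
    return {
        "normal_like": ot.SimConfig(prewake_delta_frac=0.5, **base),
        "hd_like": ot.SimConfig(prewake_delta_frac=0.75, **base),
    }


def null_cohort_configs() -> dict[str, ot.SimConfig]:
    """Two groups with identical generator parameters (null for calibration)."""
    cfg = ot.SimConfig(
        night_len_h=3.0, n_channels=4, rem_prob=0.0, prewake_delta_frac=1.0
    )
    return {"g1": cfg, "g2": cfg}


@pytest.fixture(scope="session")
def speed_cohort():
    members, manifest = ot.generate_cohort(speed_cohort_configs(), n_per_group=5,
                                           base_seed=100)
    t0 = time.process_time()
    out = ot.analyse_cohort(members)
    out["manifest"] = manifest
    out["elapsed_s"] = time.process_time() - t0
    return out


@pytest.fixture(scope="session")
def prepost_cohort():
    members, manifest = ot.generate_cohort(prepost_cohort_configs(), n_per_group=5,
                                           base_seed=200)
    t0 = time.process_time()
    out = ot.analyse_cohort(members)
    out["manifest"] = manifest
    out["elapsed_s"] = time.process_time() - t0
    return out


@pytest.fixture(scope="session")
def null_cohort():
    members, manifest = ot.generate_cohort(null_cohort_configs(), n_per_group=4,
                                           base_seed=300)
    out = ot.analyse_cohort(members)
    out["manifest"] = manifest
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
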