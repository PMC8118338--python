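"""NREM/wake transition detection, REM exclusion, and bout statistics.

A transition is declared where the *consensus wake fraction* — the share of
non-artefact channel-epochs automatically labelled wake within a rolling
5-minute window pooled over all channels — crosses 50% and stays on the new
side for a minimum dwell time.  The transition centre (the mid-point on the
slope between the two states) is the linearly interpolated time of the 0.5
crossing.  Transitions whose neighbourhood overlaps manually scored REM
epochs are excluded from the dynamics analysis.  Bouts of wake or NREM sleep
span consecutive transition centres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .state_space import ARTEFACT, NREM, WAKE, labels_to_names

__all__ = [
    "TO_WAKE",
    "TO_SLEEP",
    "WakeFractionSeries",
    "Transition",
    "Bout",
    "consensus_wake_fraction",
    "state_balance_fraction",
    "detect_transitions",
    "refine_centres",
    "exclude_rem",
    "compute_bouts",
    "crosscheck_manual",
    "transitions_table",
    "bouts_table",
]

TO_WAKE = "TO_WAKE"
TO_SLEEP = "TO_SLEEP"


@dataclass
class WakeFractionSeries:
    """Rolling-window consensus wake fraction.

    ``times`` are window-centre times in seconds (strictly increasing, one
    window position per epoch step); ``fraction`` is the share of non-artefact
    channel-epochs labelled WAKE in each window, in [0, 1], NaN where a window
    contains only artefact epochs.
    """

    times: np.ndarray
    fraction: np.ndarray
    window_len_s: float = 300.0
    step_s: float = 10.0


@dataclass
class Transition:
    """One detected sleep-to-wake or wake-to-sleep switch."""

    direction: str  # TO_WAKE or TO_SLEEP
    centre_s: float
    window_bounds: tuple[float, float] = (0.0, 0.0)
    rem_contaminated: bool = False
    excluded: bool = False
    reason: str = ""


@dataclass
class Bout:
    """Maximal contiguous period in one state, delimited by transition centres."""

    state: str  # "WAKE" or "NREM"
    start_s: float
    end_s: float

    @property
    def duration_min(self) -> float:
        return (self.end_s - self.start_s) / 60.0


def consensus_wake_fraction(
    labels: np.ndarray,
    epoch_len_s: float = 10.0,
    window_len_s: float = 300.0,
) -> WakeFractionSeries:
    """Pool per-channel labels into a rolling wake fraction.

    ``labels`` is ``(n_channels, n_epochs)`` of integer label codes on a
    common epoch grid.  The window advances one epoch at a time; at each
    position the fraction is (# channel-epochs labelled WAKE) / (# not
    ARTEFACT) over all channels in the window.  All-artefact windows yield
    NaN (a gap).
    """
    labels = np.atleast_2d(labels)
    n_ep = labels.shape[1]
    w = int(round(window_len_s / epoch_len_s))
    w = max(1, min(w, n_ep))
    wake = (labels == WAKE).sum(axis=0).astype(float)
    valid = (labels != ARTEFACT).sum(axis=0).astype(float)
    kern = np.ones(w)
    wake_w = np.convolve(wake, kern, mode="valid")
    valid_w = np.convolve(valid, kern, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(valid_w > 0, wake_w / np.where(valid_w > 0, valid_w, 1), np.nan)
    times = (np.arange(frac.size) + w / 2.0) * epoch_len_s
    return WakeFractionSeries(
        times=times, fraction=frac, window_len_s=w * epoch_len_s, step_s=epoch_len_s
    )


def state_balance_fraction(
    labels: np.ndarray,
    epoch_len_s: float = 10.0,
    window_len_s: float = 300.0,
) -> WakeFractionSeries:
    """Rolling share of wake among *classified* (wake or NREM) channel-epochs.

    Unlike :func:`consensus_wake_fraction`, inter-state epochs are excluded
    from the denominator, so the 0.5 crossing sits symmetrically between the
    loss of NREM and the onset of wake classifications.  Used to place
    transition centres without the systematic shift that the inter-state
    buffer induces in the detection fraction.
    """
    labels = np.atleast_2d(labels)
    n_ep = labels.shape[1]
    w = int(round(window_len_s / epoch_len_s))
    w = max(1, min(w, n_ep))
    wake = (labels == WAKE).sum(axis=0).astype(float)
    staged = ((labels == WAKE) | (labels == NREM)).sum(axis=0).astype(float)
    kern = np.ones(w)
    wake_w = np.convolve(wake, kern, mode="valid")
    staged_w = np.convolve(staged, kern, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(staged_w > 0, wake_w / np.where(staged_w > 0, staged_w, 1), np.nan)
    times = (np.arange(frac.size) + w / 2.0) * epoch_len_s
    return WakeFractionSeries(
        times=times, fraction=frac, window_len_s=w * epoch_len_s, step_s=epoch_len_s
    )


def refine_centres(
    transitions: list[Transition],
    balance: WakeFractionSeries,
    search_s: float = 150.0,
) -> list[Transition]:
    """Move each centre to the nearest 0.5 crossing of the state balance.

    The detection fraction counts inter-state epochs against wake, which
    shifts its 0.5 crossing toward the wake side of a gradual switch; the
    state-balance crossing is symmetric in the two staged states and so marks
    the mid-point on the slope.  Each centre moves to the balance crossing (in
    the matching direction) closest to it within ``search_s``; centres with no
    such crossing are left unchanged.
    """
    f = _fill_gaps(np.asarray(balance.fraction, dtype=float))
    t = np.asarray(balance.times, dtype=float)
    if f.size < 2:
        return [replace(tr) for tr in transitions]
    out = []
    sign = np.sign(f - 0.5)
    for tr in transitions:
        want_up = tr.direction == TO_WAKE
        best = None
        for i in range(1, f.size):
            if sign[i] == sign[i - 1] or sign[i] == 0:
                continue
            rising = f[i] > f[i - 1]
            if rising != want_up:
                continue
            c = _interp_crossing(t, f, i)
            if abs(c - tr.centre_s) <= search_s and (
                best is None or abs(c - tr.centre_s) < abs(best - tr.centre_s)
            ):
                best = c
        out.append(replace(tr, centre_s=best) if best is not None else replace(tr))
    return out


def _fill_gaps(f: np.ndarray) -> np.ndarray:
    """Carry the last finite value across NaN gaps (backfill at the start)."""
    f = f.copy()
    isnan = ~np.isfinite(f)
    if isnan.all():
        return f
    idx = np.where(~isnan, np.arange(f.size), -1)
    np.maximum.accumulate(idx, out=idx)
    first = np.argmax(~isnan)
    idx[idx < 0] = np.argmax(~isnan[first:]) + first
    return f[np.maximum(idx, first)]


def detect_transitions(
    wf: WakeFractionSeries, min_dwell_s: float = 300.0
) -> list[Transition]:
    """Find sustained 0.5 crossings of the consensus wake fraction.

    An upward crossing preceded and followed by at least ``min_dwell_s`` on
    the respective side becomes a TO_WAKE event (TO_SLEEP symmetric); brief
    re-crossings shorter than the dwell are ignored (hysteresis).  The centre
    is the linear interpolation of the 0.5 crossing between the bracketing
    window-centre times.  Events alternate in direction by construction.
    An empty or constant series yields an empty list.
    """
    f = np.asarray(wf.fraction, dtype=float)
    t = np.asarray(wf.times, dtype=float)
    if f.size < 2 or not np.isfinite(f).any():
        return []
    f = _fill_gaps(f)
    above = f > 0.5
    dwell = max(1, int(round(min_dwell_s / wf.step_s)))

    # Run-length debouncing: repeatedly flip the shortest run below the dwell
    # into its neighbours' state, so only crossings with a sustained period on
    # both sides survive.  Runs alternate in value, hence so do transitions.
    runs = _runs(above)
    while len(runs) > 1:
        lengths = [ln for _, _, ln in runs]
        short = [k for k, ln in enumerate(lengths) if ln < dwell]
        if not short:
            break
        k = min(short, key=lambda j: lengths[j])
        val, start, ln = runs[k]
        runs[k] = (not val, start, ln)
        runs = _merge_runs(runs)

    out: list[Transition] = []
    for (prev, _, _), (cur, start, _) in zip(runs, runs[1:]):
        out.append(
            Transition(
                direction=TO_WAKE if cur else TO_SLEEP,
                centre_s=_interp_crossing(t, f, start),
            )
        )
    return out


def _runs(b: np.ndarray) -> list[tuple[bool, int, int]]:
    """Run-length encode a boolean array as (value, start, length) triples."""
    starts = np.flatnonzero(np.diff(b.astype(np.int8)) != 0) + 1
    bounds = np.concatenate(([0], starts, [b.size]))
    return [
        (bool(b[s]), int(s), int(e - s)) for s, e in zip(bounds[:-1], bounds[1:])
    ]


def _merge_runs(runs: list[tuple[bool, int, int]]) -> list[tuple[bool, int, int]]:
    merged: list[tuple[bool, int, int]] = []
    for val, start, ln in runs:
        if merged and merged[-1][0] == val:
            pval, pstart, pln = merged[-1]
            merged[-1] = (pval, pstart, pln + ln)
        else:
            merged.append((val, start, ln))
    return merged


def _interp_crossing(t: np.ndarray, f: np.ndarray, i: int) -> float:
    """Interpolated time where f crosses 0.5 between samples i-1 and i."""
    f0, f1 = f[i - 1], f[i]
    if (f0 - 0.5) * (f1 - 0.5) > 0 or f1 == f0:
        return float((t[i - 1] + t[i]) / 2.0)
    return float(t[i - 1] + (0.5 - f0) * (t[i] - t[i - 1]) / (f1 - f0))


def exclude_rem(
    transitions: list[Transition],
    hypnogram: pd.DataFrame | None,
    epoch_len_s: float = 10.0,
    extent_s: float = 300.0,
) -> list[Transition]:
    """Flag transitions whose neighbourhood contains manually scored REM.

    Any transition whose analysis extent (``centre +/- extent_s``) overlaps at
    least one REM epoch of the hypnogram is flagged ``rem_contaminated`` and
    excluded from downstream dynamics.  A missing hypnogram produces a warning
    and no exclusions.
    """
    if hypnogram is None:
        warnings.warn("no hypnogram supplied: REM-contaminated transitions not excluded")
        return [replace(tr) for tr in transitions]
    rem_idx = hypnogram.loc[hypnogram["label"] == "REM", "epoch_index"].to_numpy()
    rem_starts = rem_idx * epoch_len_s
    out = []
    for tr in transitions:
        lo, hi = tr.centre_s - extent_s, tr.centre_s + extent_s
        # epoch [s, s + L) overlaps [lo, hi]
        hit = np.any((rem_starts < hi) & (rem_starts + epoch_len_s > lo))
        if hit:
            out.append(
                replace(
                    tr,
                    rem_contaminated=True,
                    excluded=True,
                    reason="REM epoch within analysis extent",
                    window_bounds=(lo, hi),
                )
            )
        else:
            out.append(replace(tr, window_bounds=(lo, hi)))
    return out


def compute_bouts(
    transitions: list[Transition],
    night_bounds: tuple[float, float] | None = None,
) -> tuple[list[Bout], dict]:
    """Derive wake/NREM bouts and the fragmentation summary.

    Bout ``k`` spans consecutive transition centres; the bout state is the
    state entered by the transition that starts it.  Partial segments before
    the first and after the last centre are not turned into bouts, so edge
    effects never bias the means.  The summary reports the number of
    (non-excluded) transitions to wake and to sleep and the mean wake and
    NREM bout lengths in minutes.
    """
    for a, b in zip(transitions, transitions[1:]):
        if a.direction == b.direction:
            raise ValueError("transitions must alternate in direction")
    bouts = [
        Bout(
            state="WAKE" if a.direction == TO_WAKE else "NREM",
            start_s=a.centre_s,
            end_s=b.centre_s,
        )
        for a, b in zip(transitions, transitions[1:])
    ]
    wake_d = [b.duration_min for b in bouts if b.state == "WAKE"]
    nrem_d = [b.duration_min for b in bouts if b.state == "NREM"]
    kept = [tr for tr in transitions if not tr.excluded]
    summary = {
        "n_transitions_to_wake": sum(tr.direction == TO_WAKE for tr in kept),
        "n_transitions_to_sleep": sum(tr.direction == TO_SLEEP for tr in kept),
        "mean_wake_bout_min": float(np.mean(wake_d)) if wake_d else float("nan"),
        "mean_nrem_bout_min": float(np.mean(nrem_d)) if nrem_d else float("nan"),
    }
    return bouts, summary


def crosscheck_manual(
    auto_labels: np.ndarray,
    manual_labels: np.ndarray,
) -> dict:
    """Concordance between automatic and manual staging.

    ``auto_labels`` is 1-D or ``(n_channels, n_epochs)`` integer codes;
    ``manual_labels`` is a 1-D array of strings in {WAKE, NREM, REM} on the
    same epoch grid.  Agreement is restricted to epochs automatically labelled
    WAKE or NREM (INTER and ARTEFACT excluded); manual REM inside that set
    counts as disagreement.  Returns confusion counts and percent agreement.
    """
    auto = np.atleast_2d(np.asarray(auto_labels))
    manual = np.asarray(manual_labels, dtype=object)
    if auto.shape[1] != manual.size:
        raise ValueError(
            f"epoch grid mismatch: {auto.shape[1]} automatic vs "
            f"{manual.size} manual epochs"
        )
    manual2 = np.broadcast_to(manual, auto.shape)
    sel = (auto == WAKE) | (auto == NREM)
    auto_names = labels_to_names(auto[sel])
    man_sel = manual2[sel]
    confusion = (
        pd.crosstab(
            pd.Series(auto_names, name="auto"),
            pd.Series(man_sel, name="manual"),
        )
        if sel.any()
        else pd.DataFrame()
    )
    agree = float(np.mean(auto_names == man_sel)) * 100.0 if sel.any() else float("nan")
    return {
        "confusion": confusion,
        "percent_agreement": agree,
        "n_compared": int(sel.sum()),
    }


def transitions_table(transitions: list[Transition]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "direction": [tr.direction for tr in transitions],
            "centre_s": [tr.centre_s for tr in transitions],
            "rem_contaminated": [tr.rem_contaminated for tr in transitions],
            "excluded": [tr.excluded for tr in transitions],
            "reason": [tr.reason for tr in transitions],
        }
    )


def bouts_table(bouts: list[Bout]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "state": [b.state for b in bouts],
            "start_s": [b.start_s for b in bouts],
            "end_s": [b.end_s for b in bouts],
            "duration_min": [b.duration_min for b in bouts],
        }
    )
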