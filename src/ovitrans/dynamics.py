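"""Spectral dynamics of individual transitions.

Given night-normalised epoch spectra and a transition centre, this module
re-indexes epochs to time-from-centre and quantifies how fast and how far the
spectrum moves:

* **method A** — peak of the pooled moving variance (1-minute window) of
  per-bin min-max-normalised power, searched within +/-2 minutes of the
  centre: abrupt switches concentrate spectral change into few epochs and
  give large peaks;
* **method B** — the time from when a band's power leaves the mean +/- SD
  envelope of its 5-minute pre-transition baseline to when it settles inside
  the envelope of the 5-minute post-transition baseline;
* **method C** — the straight-line gradient of band power between the method-B
  start and end points, in power per minute;
* **pre/post contrasts** — mean band power in the [-4, -2] and [+2, +4] minute
  windows expressed as proportions of the night's mean NREM and wake power in
  that band (transitions have either not yet begun or already finished there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .spectral import PowerSpectra

__all__ = [
    "AlignedSpectrogram",
    "SpeedDuration",
    "PrePostPower",
    "align_spectrogram",
    "rebin_frequencies",
    "minmax_normalise_bins",
    "speed_variance_peak",
    "speed_duration",
    "speed_gradient",
    "prepost_power",
]


@dataclass
class AlignedSpectrogram:
    """Epoch spectra of one channel re-indexed to time from a transition centre.

    ``rel_times`` are epoch start times minus the centre, spanning
    approximately [-T, +T); ``values`` has shape ``(n_epochs, n_bins)``;
    ``mask`` marks artefact epochs.
    """

    rel_times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    epoch_len_s: float
    channel: str = ""
    minmax_normalised: bool = False


@dataclass
class SpeedDuration:
    """Method-B result for one band of one transition."""

    duration_min: float
    start_s: float
    end_s: float
    start_power: float
    end_power: float
    valid: bool
    reason: str = ""


@dataclass
class PrePostPower:
    """Band power before/after a transition, absolute and as state proportions."""

    band: str
    pre: float
    post: float
    pre_prop_nrem: float
    post_prop_nrem: float
    pre_prop_wake: float
    post_prop_wake: float
    valid: bool = True


def align_spectrogram(
    ps: PowerSpectra,
    centre_s: float,
    T_s: float = 300.0,
    channel: int = 0,
) -> AlignedSpectrogram:
    """Extract the +/-T window of one channel's spectra around a centre.

    The epoch whose start time equals the centre maps to relative time in
    [0, epoch_len).  Requires night-normalised spectra.

    Raises
    ------
    ValueError
        If the window does not fit inside the night (the caller should skip
        the transition with a reason).
    """
    if not ps.normalised:
        raise ValueError("align_spectrogram expects night-normalised spectra")
    ep = ps.epoch_len_s
    half = int(round(T_s / ep))
    i_c = int(np.floor(centre_s / ep))
    i0, i1 = i_c - half, i_c + half
    if i0 < 0 or i1 > ps.n_epochs:
        raise ValueError(
            f"transition at {centre_s:.0f} s too close to the recording edge"
        )
    idx = np.arange(i0, i1)
    return AlignedSpectrogram(
        rel_times=idx * ep - centre_s,
        freqs=ps.freqs,
        values=ps.power[channel, i0:i1, :],
        mask=ps.artefact_mask[channel, i0:i1],
        epoch_len_s=ep,
        channel=ps.channels[channel],
    )


def rebin_frequencies(a: AlignedSpectrogram, width_hz: float = 1.0) -> AlignedSpectrogram:
    """Aggregate the spectrogram into coarser frequency bins.

    Power is summed over consecutive groups of native bins spanning
    ``width_hz``; the new bin frequency is the group centre.  Coarser bins
    average out the large sampling variability of single-periodogram bins, so
    moving-variance measures respond to spectral change rather than to
    per-bin estimation noise.  A ``width_hz`` at or below the native
    resolution returns the input unchanged.
    """
    native = float(np.median(np.diff(a.freqs)))
    group = int(round(width_hz / native))
    if group <= 1:
        return a
    n_groups = a.freqs.size // group
    if n_groups < 1:
        raise ValueError("rebin width exceeds the spectral range")
    trimmed = a.values[:, : n_groups * group]
    vals = trimmed.reshape(a.values.shape[0], n_groups, group).sum(axis=2)
    freqs = a.freqs[: n_groups * group].reshape(n_groups, group).mean(axis=1)
    return replace(a, values=vals, freqs=freqs, minmax_normalised=False)


def minmax_normalise_bins(a: AlignedSpectrogram) -> AlignedSpectrogram:
    """Scale every frequency bin to [0, 1] over the aligned window.

    Each bin is mapped to ``(v - min) / (max - min)`` using unmasked epochs,
    so 0 is the minimum and 1 the maximum power at that frequency during the
    transition.  Flat bins (max == min) are set to 0 with a warning.
    """
    keep = ~a.mask
    if not keep.any():
        raise ValueError("aligned window contains only artefact epochs")
    sub = a.values[keep]
    lo = sub.min(axis=0)
    hi = sub.max(axis=0)
    span = hi - lo
    flat = span <= 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} flat frequency bins set to 0")
    safe = np.where(flat, 1.0, span)
    vals = (a.values - lo) / safe
    vals[:, flat] = 0.0
    return replace(a, values=vals, minmax_normalised=True)


def speed_variance_peak(
    a: AlignedSpectrogram,
    win_s: float = 60.0,
    search_s: float = 120.0,
    per_bin: bool = False,
) -> tuple[float, float]:
    """Method A: peak of the moving variance of normalised power.

    At each 1-minute window position the variance of all (bin x epoch) values
    in the window is pooled into one number (``per_bin=True`` instead averages
    per-bin variances); the maximum over window centres within
    ``+/-search_s`` of the transition centre is returned with its time.
    Windows whose epochs are all masked are skipped.
    """
    if not a.minmax_normalised:
        a = minmax_normalise_bins(a)
    ep = a.epoch_len_s
    w = max(2, int(round(win_s / ep)))
    best, best_t = -np.inf, np.nan
    for j in range(a.values.shape[0] - w + 1):
        t_centre = a.rel_times[j] + w * ep / 2.0
        if not (-search_s <= t_centre <= search_s):
            continue
        keep = ~a.mask[j : j + w]
        if not keep.any():
            continue
        block = a.values[j : j + w][keep]
        v = float(block.var(axis=0).mean()) if per_bin else float(block.var())
        if v > best:
            best, best_t = v, t_centre
    if not np.isfinite(best):
        return float("nan"), float("nan")
    return best, float(best_t)


def speed_duration(
    rel_times: np.ndarray,
    values: np.ndarray,
    mask: np.ndarray | None = None,
    baseline_len_s: float = 300.0,
    dwell_epochs: int = 2,
    baseline_gap_s: float = 0.0,
) -> SpeedDuration:
    """Method B: SD-band crossing duration for one band series.

    ``values`` is the band power of consecutive epochs at ``rel_times``
    (seconds from the transition centre).  The pre-baseline is the
    ``baseline_len_s`` before the centre and the post-baseline the same length
    after it; ``baseline_gap_s`` pushes both windows away from the centre (a
    gap of half the expected ramp keeps a known ramp out of the baselines,
    whose SD it would otherwise inflate).  The transition *start* is the last moment the power is still
    inside the pre-baseline mean +/- SD envelope before leaving it for good,
    and the *end* is the first moment it is back inside the post-baseline
    envelope for at least ``dwell_epochs`` consecutive epochs.  Both are
    epoch-resolution times; the duration is their difference in minutes.

    If the power never leaves the pre-envelope, or never settles in the
    post-envelope, the result is flagged invalid.
    """
    t = np.asarray(rel_times, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.ones(t.size, dtype=bool) if mask is None else ~np.asarray(mask)
    g = baseline_gap_s
    pre_sel = keep & (t >= -g - baseline_len_s) & (t < -g)
    post_sel = keep & (t >= g) & (t < g + baseline_len_s)
    if pre_sel.sum() < 6 or post_sel.sum() < 6:
        return SpeedDuration(
            np.nan, np.nan, np.nan, np.nan, np.nan, False, "baseline too sparse"
        )
    pre_m, pre_sd = v[pre_sel].mean(), v[pre_sel].std(ddof=1)
    post_m, post_sd = v[post_sel].mean(), v[post_sel].std(ddof=1)

    in_pre = keep & (np.abs(v - pre_m) <= pre_sd)
    in_post = keep & (np.abs(v - post_m) <= post_sd)

    pre_idx = np.flatnonzero(in_pre)
    if pre_idx.size == 0 or in_pre[keep][-1]:
        return SpeedDuration(
            np.nan, np.nan, np.nan, np.nan, np.nan, False,
            "power never leaves the pre-transition envelope",
        )
    i_start = pre_idx[-1]  # last sample still inside before the final departure

    dwell = max(1, dwell_epochs)
    j = i_start + 1
    i_end = -1
    idx_after = np.flatnonzero(keep & (np.arange(t.size) > i_start))
    for k, jj in enumerate(idx_after):
        if in_post[jj] and k + dwell <= idx_after.size:
            if all(in_post[idx_after[k + d]] for d in range(dwell) if k + d < idx_after.size):
                i_end = jj
                break
    if i_end < 0:
        return SpeedDuration(
            np.nan, float(t[i_start]), np.nan, float(v[i_start]), np.nan, False,
            "power never settles in the post-transition envelope",
        )
    return SpeedDuration(
        duration_min=float((t[i_end] - t[i_start]) / 60.0),
        start_s=float(t[i_start]),
        end_s=float(t[i_end]),
        start_power=float(v[i_start]),
        end_power=float(v[i_end]),
        valid=True,
    )


def speed_gradient(sd: SpeedDuration) -> float:
    """Method C: straight-line power gradient between the method-B endpoints.

    Returns (power at end - power at start) / (duration in minutes); negative
    for falling bands (delta during waking), positive for rising ones.

    Raises
    ------
    ValueError
        If the method-B result is invalid or has zero length.
    """
    if not sd.valid:
        raise ValueError("method-B endpoints are invalid; gradient undefined")
    dt_min = (sd.end_s - sd.start_s) / 60.0
    if dt_min <= 0:
        raise ValueError("zero-length transition: gradient undefined")
    return (sd.end_power - sd.start_power) / dt_min


def prepost_power(
    rel_times: np.ndarray,
    values: np.ndarray,
    mean_nrem_power: float,
    mean_wake_power: float,
    mask: np.ndarray | None = None,
    band: str = "",
    pre_window_s: tuple[float, float] = (-240.0, -120.0),
    post_window_s: tuple[float, float] = (120.0, 240.0),
) -> PrePostPower:
    """Mean band power in the pre/post windows, as proportions of state means.

    The windows default to [-4, -2] and [+2, +4] minutes from the centre.  The
    state reference means are the night averages of this band's power over
    artefact-free epochs automatically labelled NREM or wake.  An empty window
    after masking flags the result invalid.
    """
    t = np.asarray(rel_times, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.ones(t.size, dtype=bool) if mask is None else ~np.asarray(mask)
    pre_sel = keep & (t >= pre_window_s[0]) & (t < pre_window_s[1])
    post_sel = keep & (t >= post_window_s[0]) & (t < post_window_s[1])
    valid = bool(pre_sel.any() and post_sel.any())
    pre = float(v[pre_sel].mean()) if pre_sel.any() else float("nan")
    post = float(v[post_sel].mean()) if post_sel.any() else float("nan")

    def _prop(x: float, ref: float) -> float:
        return x / ref if ref > 0 else float("nan")

    return PrePostPower(
        band=band,
        pre=pre,
        post=post,
        pre_prop_nrem=_prop(pre, mean_nrem_power),
        post_prop_nrem=_prop(post, mean_nrem_power),
        pre_prop_wake=_prop(pre, mean_wake_power),
        post_prop_wake=_prop(post, mean_wake_power),
        valid=valid,
    )
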