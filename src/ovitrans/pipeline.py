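"""End-to-end night and cohort analysis.

:func:`analyse_night` runs the full chain on one recording: common-average
re-referencing, epoch PSDs, MAD artefact rejection, night normalisation,
SSR staging with per-channel relative thresholds, consensus transition
detection, REM exclusion against a hypnogram, bout statistics, and the
per-transition dynamics metrics (methods A/B/C and the pre/post band-power
contrasts).  :func:`analyse_cohort` maps it over synthetic cohort members one
animal at a time and stacks tidy metric tables for the group statistics.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics as dyn
from .recording import Recording, rereference_common_average
from .simulate import CohortMember
from .spectral import (
    DEFAULT_BANDS,
    ArtefactRule,
    BandDefinition,
    PowerSpectra,
    _band_bins,
    band_power,
    epoch_psd,
    flag_artefacts,
    normalise_night,
)
from .state_space import (
    NREM,
    WAKE,
    SSRSeries,
    StateThresholds,
    classify_epochs,
    compute_ssr,
    fit_state_thresholds,
)
from .transitions import (
    Bout,
    Transition,
    WakeFractionSeries,
    compute_bouts,
    consensus_wake_fraction,
    crosscheck_manual,
    detect_transitions,
    exclude_rem,
    refine_centres,
    state_balance_fraction,
)

__all__ = ["AnalysisConfig", "NightResult", "analyse_night", "analyse_cohort"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full pipeline (defaults follow the method)."""

    epoch_len_s: float = 10.0
    rereference: bool = True
    artefact_rule: ArtefactRule = field(default_factory=ArtefactRule)
    #: With common-average re-referencing an artefact on one channel leaks
    #: into every channel, so an epoch flagged anywhere is masked everywhere.
    artefact_mask_union: bool = True
    bands: dict[str, BandDefinition] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    y_frac: float = 0.20
    ssr_bin_width: float = 0.01
    min_stage_epochs: int = 200
    window_len_s: float = 300.0
    min_dwell_s: float = 300.0
    #: Re-place each detected centre at the 0.5 crossing of the symmetric
    #: wake/NREM state-balance fraction (mid-point on the slope).
    refine_centres: bool = True
    rem_extent_s: float = 300.0
    align_T_s: float = 300.0
    variance_win_s: float = 60.0
    variance_search_s: float = 120.0
    #: Spectrogram bin width (Hz) for the moving-variance metric; coarser
    #: bins suppress single-bin periodogram noise.
    variance_bin_hz: float = 1.0
    #: Average per-bin variances over bins (True) instead of pooling all
    #: bin x epoch values into one variance; the per-bin form responds to
    #: temporal change only, not to the static spread between bins.
    variance_per_bin: bool = True
    baseline_len_s: float = 300.0


@dataclass
class NightResult:
    """All outputs of one night's analysis."""

    spectra: PowerSpectra  # night-normalised
    ssr: SSRSeries
    thresholds: list[StateThresholds]
    labels: np.ndarray  # (n_channels, n_epochs) integer codes
    wake_fraction: WakeFractionSeries
    transitions: list[Transition]
    bouts: list[Bout]
    summary: dict
    state_band_means: pd.DataFrame  # channel x band x state reference powers
    #: Methods B/C and pre/post contrasts, one row per transition x channel x
    #: band; channel "mean" rows carry the cross-channel-average band series
    #: (the primary per-transition metric, less noisy than any single channel).
    speed: pd.DataFrame
    #: Method A, one row per transition x channel (+ channel "mean").
    variance_peaks: pd.DataFrame
    concordance: dict | None = None
    skipped_transitions: list[tuple[int, str]] = field(default_factory=list)


def _state_band_means(
    ps: PowerSpectra, labels: np.ndarray, bands: dict[str, BandDefinition]
) -> tuple[pd.DataFrame, dict]:
    """Night-mean band power per channel for auto-labelled wake and NREM epochs."""
    rows = []
    lookup: dict[tuple[int, str, str], float] = {}
    bp = {name: band_power(ps, band) for name, band in bands.items()}
    for c in range(ps.n_channels):
        for name in bands:
            for state, code in (("WAKE", WAKE), ("NREM", NREM)):
                sel = (labels[c] == code) & ~ps.artefact_mask[c]
                mean = float(bp[name][c, sel].mean()) if sel.any() else float("nan")
                rows.append(
                    {
                        "channel": ps.channels[c],
                        "band": name,
                        "state": state,
                        "mean_power": mean,
                    }
                )
                lookup[(c, name, state)] = mean
    return pd.DataFrame(rows), lookup


def analyse_night(
    rec: Recording,
    hypnogram: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> NightResult:
    """Run the complete staging + transition-dynamics analysis on one night.

    ``hypnogram`` (epoch_index/label, labels WAKE/NREM/REM) is used for REM
    exclusion and the manual cross-check; without it no transitions are
    excluded (a warning is emitted by the exclusion step).
    """
    cfg = config or AnalysisConfig()
    if cfg.rereference and rec.n_channels >= 2:
        rec = rereference_common_average(rec)
    ps = epoch_psd(rec, cfg.epoch_len_s)
    ps = flag_artefacts(ps, cfg.artefact_rule)
    if cfg.artefact_mask_union and ps.n_channels > 1:
        union = ps.artefact_mask.any(axis=0)
        ps = dataclasses.replace(
            ps, artefact_mask=np.broadcast_to(union, ps.artefact_mask.shape).copy()
        )
    ps = normalise_night(ps)

    ssr = compute_ssr(ps)
    thresholds = []
    for c, ch in enumerate(ps.channels):
        vals = ssr.ssr2[c][~ssr.mask[c]]
        thresholds.append(
            fit_state_thresholds(
                vals,
                y_frac=cfg.y_frac,
                bin_width=cfg.ssr_bin_width,
                min_epochs=cfg.min_stage_epochs,
                channel=ch,
            )
        )
    labels = classify_epochs(ssr, thresholds)

    wf = consensus_wake_fraction(labels, cfg.epoch_len_s, cfg.window_len_s)
    trans = detect_transitions(wf, cfg.min_dwell_s)
    if cfg.refine_centres:
        balance = state_balance_fraction(labels, cfg.epoch_len_s, cfg.window_len_s)
        trans = refine_centres(trans, balance)
    if hypnogram is not None:
        trans = exclude_rem(trans, hypnogram, cfg.epoch_len_s, cfg.rem_extent_s)
    bouts, summary = compute_bouts(trans)

    state_means_df, state_means = _state_band_means(ps, labels, cfg.bands)
    band_bins = {name: _band_bins(ps, band) for name, band in cfg.bands.items()}

    speed_rows = []
    var_rows = []
    skipped: list[tuple[int, str]] = []
    for ti, tr in enumerate(trans):
        if tr.excluded:
            continue
        try:
            per_ch = [
                dyn.align_spectrogram(ps, tr.centre_s, cfg.align_T_s, channel=c)
                for c in range(ps.n_channels)
            ]
        except ValueError as err:
            skipped.append((ti, str(err)))
            continue
        # channel set: per-channel rows for the mixed models, plus a
        # cross-channel mean (channel="mean") carrying the primary metrics
        mean_aligned = dataclasses.replace(
            per_ch[0],
            values=np.mean([a.values for a in per_ch], axis=0),
            mask=np.logical_and.reduce([a.mask for a in per_ch]),
            channel="mean",
        )
        for c, aligned in enumerate(per_ch + [mean_aligned]):
            is_mean = aligned.channel == "mean"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coarse = dyn.rebin_frequencies(aligned, cfg.variance_bin_hz)
                mm = dyn.minmax_normalise_bins(coarse)
            vpeak, vtime = dyn.speed_variance_peak(
                mm, cfg.variance_win_s, cfg.variance_search_s,
                per_bin=cfg.variance_per_bin,
            )
            var_rows.append(
                {
                    "transition": ti,
                    "direction": tr.direction,
                    "centre_s": tr.centre_s,
                    "channel": aligned.channel,
                    "variance_peak": vpeak,
                    "variance_peak_t_s": vtime,
                }
            )
            for name in cfg.bands:
                series = aligned.values[:, band_bins[name]].sum(axis=1)
                sd = dyn.speed_duration(
                    aligned.rel_times,
                    series,
                    aligned.mask,
                    baseline_len_s=cfg.baseline_len_s,
                )
                grad = dyn.speed_gradient(sd) if sd.valid else float("nan")
                if is_mean:
                    m_nrem = float(
                        np.mean([state_means[(k, name, "NREM")] for k in range(ps.n_channels)])
                    )
                    m_wake = float(
                        np.mean([state_means[(k, name, "WAKE")] for k in range(ps.n_channels)])
                    )
                else:
                    m_nrem = state_means[(c, name, "NREM")]
                    m_wake = state_means[(c, name, "WAKE")]
                pp = dyn.prepost_power(
                    aligned.rel_times,
                    series,
                    m_nrem,
                    m_wake,
                    aligned.mask,
                    band=name,
                )
                speed_rows.append(
                    {
                        "transition": ti,
                        "direction": tr.direction,
                        "centre_s": tr.centre_s,
                        "channel": aligned.channel,
                        "band": name,
                        "duration_min": sd.duration_min,
                        "start_s": sd.start_s,
                        "end_s": sd.end_s,
                        "gradient_power_per_min": grad,
                        "speed_valid": sd.valid,
                        "pre_power": pp.pre,
                        "post_power": pp.post,
                        "pre_prop_nrem": pp.pre_prop_nrem,
                        "post_prop_nrem": pp.post_prop_nrem,
                        "pre_prop_wake": pp.pre_prop_wake,
                        "post_prop_wake": pp.post_prop_wake,
                    }
                )

    concordance = None
    if hypnogram is not None and len(hypnogram) == labels.shape[1]:
        concordance = crosscheck_manual(labels, hypnogram["label"].to_numpy())

    speed_cols = [
        "transition", "direction", "centre_s", "channel", "band", "duration_min",
        "start_s", "end_s", "gradient_power_per_min", "speed_valid", "pre_power",
        "post_power", "pre_prop_nrem", "post_prop_nrem", "pre_prop_wake",
        "post_prop_wake",
    ]
    var_cols = [
        "transition", "direction", "centre_s", "channel", "variance_peak",
        "variance_peak_t_s",
    ]
    return NightResult(
        spectra=ps,
        ssr=ssr,
        thresholds=thresholds,
        labels=labels,
        wake_fraction=wf,
        transitions=trans,
        bouts=bouts,
        summary=summary,
        state_band_means=state_means_df,
        speed=pd.DataFrame(speed_rows, columns=speed_cols),
        variance_peaks=pd.DataFrame(var_rows, columns=var_cols),
        concordance=concordance,
        skipped_transitions=skipped,
    )


def analyse_cohort(
    members: list[CohortMember],
    config: AnalysisConfig | None = None,
    keep_results: bool = False,
) -> dict:
    """Analyse every cohort member against its own scripted hypnogram.

    Recordings are generated and discarded one at a time to bound memory.
    Returns tidy tables: ``summaries`` (one row per animal: fragmentation
    quartet), ``speed`` and ``variance_peaks`` (per transition x channel
    metrics with group/animal columns), and optionally the full per-night
    results.
    """
    cfg = config or AnalysisConfig()
    summaries = []
    speed_frames = []
    var_frames = []
    results = {}
    for m in members:
        rec, gt = m.generate()
        res = analyse_night(rec, hypnogram=gt.hypnogram_df(), config=cfg)
        del rec
        row = {"group": m.group, "animal": m.animal, **res.summary}
        summaries.append(row)
        for frame, store in ((res.speed, speed_frames), (res.variance_peaks, var_frames)):
            f = frame.copy()
            f.insert(0, "group", m.group)
            f.insert(1, "animal", m.animal)
            store.append(f)
        if keep_results:
            results[m.animal] = res
    out = {
        "summaries": pd.DataFrame(summaries),
        "speed": pd.concat(speed_frames, ignore_index=True)
        if speed_frames
        else pd.DataFrame(),
        "variance_peaks": pd.concat(var_frames, ignore_index=True)
        if var_frames
        else pd.DataFrame(),
    }
    if keep_results:
        out["results"] = results
    return out
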