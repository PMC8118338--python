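"""State-space ratios and relative-threshold wake/NREM staging.

Each epoch is reduced to two dimensionless spectral ratios:

* ``SSR1 = power(6.5-9 Hz) / power(0.5-9 Hz)`` — used for visualisation;
* ``SSR2 = power(0.5-20 Hz) / power(0.5-100 Hz)`` — the staging axis.  Slow
  activity dominates NREM sleep, so NREM epochs sit near 1 and wake epochs
  lower, producing a bimodal SSR2 histogram over a night.

Staging thresholds are *relative*: the distance ``x`` between the two highest
histogram peaks defines a margin ``y = y_frac * x`` (20% by default).  Epochs
above ``upper_peak - y`` are NREM, below ``lower_peak + y`` are wake, and the
gap between the two boundaries is an inter-state buffer, so the wake and NREM
regions can never overlap for ``y_frac < 0.5``.  Thresholds are fitted per
channel because the SSR2 distribution differs between animals and channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .spectral import BandDefinition, PowerSpectra, band_power

__all__ = [
    "WAKE",
    "NREM",
    "INTER",
    "ARTEFACT",
    "LABEL_NAMES",
    "SSRSeries",
    "StateThresholds",
    "compute_ssr",
    "fit_state_thresholds",
    "classify_epochs",
    "labels_to_names",
    "thresholds_to_json",
    "labels_table",
]

# Integer label codes used throughout the pipeline.
WAKE, NREM, INTER, ARTEFACT = 0, 1, 2, 3
LABEL_NAMES = {WAKE: "WAKE", NREM: "NREM", INTER: "INTER", ARTEFACT: "ARTEFACT"}

_SSR1_NUM = BandDefinition("ssr1_num", 6.5, 9.0)
_SSR1_DEN = BandDefinition("ssr1_den", 0.5, 9.0)
_SSR2_NUM = BandDefinition("ssr2_num", 0.5, 20.0)
_SSR2_DEN = BandDefinition("ssr2_den", 0.5, 100.0)


@dataclass
class SSRSeries:
    """Per-epoch state-space ratios for every channel.

    ``ssr1`` and ``ssr2`` have shape ``(n_channels, n_epochs)``; both lie in
    [0, 1] wherever the denominator is positive because the numerator band is
    a subset of the denominator band.  ``mask`` marks artefact or invalid
    (zero-denominator) epochs; masked entries are NaN.
    """

    ssr1: np.ndarray
    ssr2: np.ndarray
    mask: np.ndarray
    channels: list[str]
    epoch_len_s: float = 10.0

    @property
    def n_epochs(self) -> int:
        return self.ssr2.shape[1]


@dataclass
class StateThresholds:
    """Histogram-derived staging bounds for one channel.

    ``lower_peak``/``upper_peak`` are the SSR2 bin centres of the wake and
    NREM histogram modes; ``x = upper_peak - lower_peak``; ``y = y_frac * x``;
    ``wake_max = lower_peak + y``; ``nrem_min = upper_peak - y``.  The
    histogram itself is retained for audit.
    """

    lower_peak: float
    upper_peak: float
    y_frac: float = 0.20
    bin_width: float = 0.01
    hist_counts: np.ndarray | None = field(default=None, repr=False)
    hist_edges: np.ndarray | None = field(default=None, repr=False)
    channel: str = ""

    def __post_init__(self) -> None:
        if not self.lower_peak < self.upper_peak:
            raise ValueError("lower_peak must be below upper_peak")

    @property
    def x(self) -> float:
        return self.upper_peak - self.lower_peak

    @property
    def y(self) -> float:
        return self.y_frac * self.x

    @property
    def wake_max(self) -> float:
        return self.lower_peak + self.y

    @property
    def nrem_min(self) -> float:
        return self.upper_peak - self.y


def compute_ssr(ps: PowerSpectra) -> SSRSeries:
    """Compute SSR1 and SSR2 for every epoch and channel.

    Requires spectra covering 0.5-100 Hz.  Epochs with a zero denominator are
    marked invalid (merged into the mask) rather than raising.
    """
    if ps.freqs[-1] < 100.0 - 1e-9:
        raise ValueError("spectra must cover 0.5-100 Hz to compute SSRs")
    num2 = band_power(ps, _SSR2_NUM)
    den2 = band_power(ps, _SSR2_DEN)
    num1 = band_power(ps, _SSR1_NUM)
    den1 = band_power(ps, _SSR1_DEN)
    # only the staging ratio's denominator invalidates an epoch; SSR1 is
    # plot-only and simply NaN where its own denominator vanishes
    mask = ps.artefact_mask | (den2 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ssr2 = np.where(den2 > 0, num2 / np.where(den2 > 0, den2, 1.0), np.nan)
        ssr1 = np.where(den1 > 0, num1 / np.where(den1 > 0, den1, 1.0), np.nan)
    ssr2[mask] = np.nan
    ssr1[ps.artefact_mask] = np.nan
    return SSRSeries(
        ssr1=ssr1,
        ssr2=ssr2,
        mask=mask,
        channels=list(ps.channels),
        epoch_len_s=ps.epoch_len_s,
    )


def fit_state_thresholds(
    ssr2_values: np.ndarray,
    y_frac: float = 0.20,
    bin_width: float = 0.01,
    smooth: bool = True,
    min_peak_separation: float = 0.05,
    min_epochs: int = 200,
    channel: str = "",
) -> StateThresholds:
    """Locate the two SSR2 histogram modes and derive staging thresholds.

    The SSR2 values (artefact-free, one channel) are histogrammed over [0, 1];
    counts are optionally smoothed with a 3-bin moving average; local maxima
    at least ``min_peak_separation`` apart are ranked by height and the two
    highest become the wake (lower) and NREM (upper) peaks, reported as bin
    centres.

    Raises
    ------
    ValueError
        If fewer than ``min_epochs`` values are supplied, or fewer than two
        qualifying peaks exist ("no bimodal structure"); callers may fall
        back to manual scoring in that case.
    """
    vals = np.asarray(ssr2_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < min_epochs:
        raise ValueError(
            f"need >= {min_epochs} artefact-free epochs, got {vals.size}"
        )
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.clip(vals, 0.0, 1.0 - 1e-12), bins=edges)
    ranked = counts.astype(float)
    if smooth:
        ranked = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    distance = max(1, int(np.ceil(min_peak_separation / bin_width)))
    peaks, _ = find_peaks(ranked, distance=distance)
    if peaks.size < 2:
        raise ValueError("no bimodal structure in the SSR2 histogram")
    top2 = peaks[np.argsort(ranked[peaks])[-2:]]
    centres = (edges[top2] + edges[top2 + 1]) / 2.0
    lo, hi = float(centres.min()), float(centres.max())
    return StateThresholds(
        lower_peak=lo,
        upper_peak=hi,
        y_frac=y_frac,
        bin_width=bin_width,
        hist_counts=counts,
        hist_edges=edges,
        channel=channel,
    )


def classify_epochs(ssr: SSRSeries, thresholds: list[StateThresholds]) -> np.ndarray:
    """Label every epoch WAKE / NREM / INTER / ARTEFACT, per channel.

    ``ssr2 >= nrem_min`` is NREM, ``ssr2 < wake_max`` is wake, anything in
    between is inter-state, and masked epochs are ARTEFACT (which overrides
    everything).  Thresholds must be supplied per channel, fitted on the same
    channel's SSR2 distribution.
    """
    if len(thresholds) != len(ssr.channels):
        raise ValueError("one StateThresholds per channel required")
    labels = np.full(ssr.ssr2.shape, INTER, dtype=np.int8)
    for c, th in enumerate(thresholds):
        s = ssr.ssr2[c]
        with np.errstate(invalid="ignore"):
            labels[c, s >= th.nrem_min] = NREM
            labels[c, s < th.wake_max] = WAKE
    labels[ssr.mask] = ARTEFACT
    return labels


def labels_to_names(labels: np.ndarray) -> np.ndarray:
    """Map integer label codes to their string names."""
    return np.vectorize(LABEL_NAMES.get)(labels)


def thresholds_to_json(thresholds: list[StateThresholds], path=None) -> str:
    """Dump fitted thresholds (per channel) as JSON for audit."""
    payload = [
        {
            "channel": th.channel,
            "lower_peak": th.lower_peak,
            "upper_peak": th.upper_peak,
            "x": th.x,
            "y": th.y,
            "y_frac": th.y_frac,
            "wake_max": th.wake_max,
            "nrem_min": th.nrem_min,
            "bin_width": th.bin_width,
        }
        for th in thresholds
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def labels_table(ssr: SSRSeries, labels: np.ndarray) -> pd.DataFrame:
    """Long-format per-epoch label table (one row per channel-epoch)."""
    n_ch, n_ep = labels.shape
    idx = np.tile(np.arange(n_ep), n_ch)
    return pd.DataFrame(
        {
            "epoch_index": idx,
            "t_start_s": idx * ssr.epoch_len_s,
            "channel": np.repeat(ssr.channels, n_ep),
            "ssr1": ssr.ssr1.ravel(),
            "ssr2": ssr.ssr2.ravel(),
            "label": labels_to_names(labels).ravel(),
        }
    )
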