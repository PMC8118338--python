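"""Epoch power spectra, artefact rejection, band powers and night normalisation.

The spectral front end of the pipeline: the night is cut into fixed-length
epochs (10 s by default), each epoch gets a one-sided FFT periodogram with the
mean removed and power scaled so that the sum over frequency bins equals the
epoch's signal variance (Parseval).  Epochs whose total power deviates from
the night mean by more than ``k`` times the median absolute deviation are
masked as artefacts, and all surviving spectra are normalised per channel to
the night's mean epoch total power over the whole spectrum (0-125 Hz at a
250 Hz sampling rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .recording import Recording

__all__ = [
    "PowerSpectra",
    "BandDefinition",
    "ArtefactRule",
    "DEFAULT_BANDS",
    "MAINS_OMIT_HZ",
    "epoch_psd",
    "flag_artefacts",
    "band_power",
    "normalise_night",
    "epoch_total_power",
    "band_power_table",
]

#: Mains interference guard band excluded from band powers (Hz).
MAINS_OMIT_HZ: tuple[float, float] = (49.5, 50.5)


@dataclass
class BandDefinition:
    """A half-open frequency band ``[lo_hz, hi_hz)`` on bin centres.

    ``omit_ranges`` lists half-open sub-intervals excluded from the band, e.g.
    a guard band around 50 Hz mains interference.
    """

    name: str
    lo_hz: float
    hi_hz: float
    omit_ranges: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: lo must be < hi")
        for lo, hi in self.omit_ranges:
            if not (self.lo_hz <= lo < hi <= self.hi_hz):
                raise ValueError(
                    f"band {self.name}: omit range ({lo}, {hi}) outside band"
                )


#: Canonical EEG bands.  Half-open intervals prevent double counting at the
#: shared edges (4, 9, 14, 35 Hz); gamma omits a 1 Hz guard band around the
#: 50 Hz mains frequency.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 9.0),
    "alpha": BandDefinition("alpha", 9.0, 14.0),
    "beta": BandDefinition("beta", 14.0, 35.0),
    "gamma": BandDefinition("gamma", 35.0, 125.0, [MAINS_OMIT_HZ]),
}


@dataclass
class ArtefactRule:
    """Robust outlier rule for epoch total power.

    An epoch is flagged when its total power deviates from the night mean by
    more than ``k`` times the median absolute deviation about that mean.
    ``sided`` is ``"two_sided"`` (default; also catches flatline signal loss)
    or ``"upper"`` (only high-power epochs flagged).
    """

    k: float = 3.0
    sided: str = "two_sided"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("MAD multiplier k must be positive")
        if self.sided not in ("two_sided", "upper"):
            raise ValueError("sided must be 'two_sided' or 'upper'")


@dataclass
class PowerSpectra:
    """Per-channel epoch-by-frequency power grid with an artefact mask.

    ``power`` has shape ``(n_channels, n_epochs, n_bins)`` and is nonnegative;
    ``artefact_mask`` has shape ``(n_channels, n_epochs)`` with ``True``
    marking epochs excluded from all downstream statistics.
    """

    epoch_len_s: float
    freqs: np.ndarray
    power: np.ndarray
    artefact_mask: np.ndarray
    channels: list[str]
    normalised: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        self.artefact_mask = np.asarray(self.artefact_mask, dtype=bool)
        if self.power.ndim != 3:
            raise ValueError("power must be (n_channels, n_epochs, n_bins)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.artefact_mask.shape != self.power.shape[:2]:
            raise ValueError("artefact_mask shape must match (channels, epochs)")

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.power.shape[1]

    @property
    def epoch_starts_s(self) -> np.ndarray:
        """Start time of each epoch in seconds (epoch i covers [Li, L(i+1)))."""
        return np.arange(self.n_epochs) * self.epoch_len_s


def epoch_psd(rec: Recording, epoch_len_s: float = 10.0) -> PowerSpectra:
    """Compute one periodogram per epoch per channel.

    Rectangular window, per-epoch mean removal, one-sided spectrum scaled so
    the sum over bins equals the epoch's (mean-removed) signal variance.
    Frequency resolution is ``1 / epoch_len_s`` Hz; a trailing partial epoch
    is discarded.

    Raises
    ------
    ValueError
        If ``epoch_len_s * fs`` is not an integer sample count, or the
        recording is shorter than one epoch.
    """
    n = epoch_len_s * rec.fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError("epoch_len_s * fs must be an integer sample count")
    n = int(round(n))
    n_epochs = rec.n_samples // n
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")

    x = rec.signals[:, : n_epochs * n].reshape(rec.n_channels, n_epochs, n)
    x = x - x.mean(axis=2, keepdims=True)
    spec = np.fft.rfft(x, axis=2)
    power = np.abs(spec) ** 2 / n**2
    power[..., 1:] *= 2.0  # one-sided doubling
    if n % 2 == 0:
        power[..., -1] /= 2.0  # Nyquist bin is not duplicated
    return PowerSpectra(
        epoch_len_s=float(epoch_len_s),
        freqs=np.fft.rfftfreq(n, 1.0 / rec.fs),
        power=power,
        artefact_mask=np.zeros((rec.n_channels, n_epochs), dtype=bool),
        channels=list(rec.channels),
    )


def epoch_total_power(ps: PowerSpectra) -> np.ndarray:
    """Total power of each epoch (sum over all frequency bins).

    With the Parseval scaling of :func:`epoch_psd` this equals the epoch's
    mean-removed signal variance.  Shape ``(n_channels, n_epochs)``.
    """
    return ps.power.sum(axis=2)


def flag_artefacts(ps: PowerSpectra, rule: ArtefactRule | None = None) -> PowerSpectra:
    """Mask epochs whose total power is a robust outlier, per channel.

    For each channel the mean ``m`` and the median absolute deviation about
    the mean, ``MAD = median(|p - m|)``, of the epoch total powers are
    computed over *all* epochs, and epoch ``i`` is flagged when
    ``|p_i - m| > k * MAD`` (or ``p_i - m > k * MAD`` for the upper-sided
    rule).  Because the statistics are a deterministic function of the powers
    alone, re-application with the same rule is idempotent; with identical
    powers MAD is 0 and nothing is flagged (all deviations are 0).

    Any pre-existing mask (e.g. invalid epochs) is preserved by OR-ing.
    """
    if rule is None:
        rule = ArtefactRule()
    if ps.n_epochs < 3:
        raise ValueError("need at least 3 epochs to estimate the artefact rule")
    tot = epoch_total_power(ps)
    mean = tot.mean(axis=1, keepdims=True)
    dev = tot - mean
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    if rule.sided == "two_sided":
        flagged = np.abs(dev) > rule.k * mad
    else:
        flagged = dev > rule.k * mad
    return replace(ps, artefact_mask=ps.artefact_mask | flagged)


def _band_bins(ps: PowerSpectra, band: BandDefinition) -> np.ndarray:
    df = 1.0 / ps.epoch_len_s
    if band.lo_hz < ps.freqs[0] - df / 2 or band.hi_hz > ps.freqs[-1] + df:
        raise ValueError(
            f"band {band.name} [{band.lo_hz}, {band.hi_hz}) outside the "
            f"spectral range [{ps.freqs[0]}, {ps.freqs[-1]}]"
        )
    sel = (ps.freqs >= band.lo_hz) & (ps.freqs < band.hi_hz)
    for lo, hi in band.omit_ranges:
        sel &= ~((ps.freqs >= lo) & (ps.freqs < hi))
    if not sel.any():
        raise ValueError(f"band {band.name} selects no frequency bins")
    return sel


def band_power(ps: PowerSpectra, band: BandDefinition) -> np.ndarray:
    """Sum of bin powers with bin centre in ``[lo, hi)`` minus omit ranges.

    Returns shape ``(n_channels, n_epochs)``; artefact epochs are *not*
    blanked here — callers use the mask.
    """
    return ps.power[:, :, _band_bins(ps, band)].sum(axis=2)


def band_power_table(
    ps: PowerSpectra, bands: dict[str, BandDefinition] | None = None
) -> "pd.DataFrame":
    """Long-format epoch x channel x band power table.

    Columns: epoch_index, t_start_s, channel, band, power, artefact (0/1) —
    the interchange format for downstream tools.
    """
    import pandas as pd

    if bands is None:
        bands = DEFAULT_BANDS
    frames = []
    starts = ps.epoch_starts_s
    for name, band in bands.items():
        bp = band_power(ps, band)
        for c, ch in enumerate(ps.channels):
            frames.append(
                pd.DataFrame(
                    {
                        "epoch_index": np.arange(ps.n_epochs),
                        "t_start_s": starts,
                        "channel": ch,
                        "band": name,
                        "power": bp[c],
                        "artefact": ps.artefact_mask[c].astype(int),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True).sort_values(
        ["epoch_index", "channel", "band"], kind="stable", ignore_index=True
    )


def normalise_night(ps: PowerSpectra) -> PowerSpectra:
    """Normalise each channel to its night mean epoch total power.

    Every bin power is divided by the mean, over artefact-free epochs, of the
    epoch total power across the whole spectrum.  After normalisation the mean
    normalised epoch total over artefact-free epochs is exactly 1, and the
    operation is idempotent.  Performed per channel.

    Raises
    ------
    ValueError
        If any channel has no artefact-free epoch.
    """
    keep = ~ps.artefact_mask
    if not keep.any(axis=1).all():
        raise ValueError("a channel has no artefact-free epochs to normalise to")
    tot = epoch_total_power(ps)
    denom = np.array(
        [tot[c, keep[c]].mean() for c in range(ps.n_channels)]
    ).reshape(-1, 1, 1)
    return replace(ps, power=ps.power / denom, normalised=True)
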