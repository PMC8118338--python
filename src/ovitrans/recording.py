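"""Multichannel EEG recordings: container, re-referencing and file I/O.

A :class:`Recording` is the entry point of the pipeline: an ordered set of
equally long channel traces in microvolts sampled at a common rate.  Signals
can be loaded from EDF/EDF+ files (via :mod:`mne`, when installed) or from a
plain delimited numeric matrix with one column per channel, which keeps the
pipeline usable without any binary format dependencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "rereference_common_average",
    "read_delimited",
    "write_delimited",
    "read_edf",
    "read_hypnogram",
    "write_hypnogram",
]


@dataclass
class Recording:
    """Multichannel signal matrix with sampling metadata.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channels
        Ordered channel labels, one per row of ``signals``.
    t0
        Recording start time in seconds (0 by convention; all epoch and
        transition times in the package are relative to it).
    """

    signals: np.ndarray
    fs: float
    channels: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.signals.shape[0])]
        if len(self.channels) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.signals.shape[0]} signal rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def rereference_common_average(rec: Recording) -> Recording:
    """Re-reference every channel to the instantaneous mean across channels.

    After re-referencing, the mean across channels is zero at every sample.
    Channel count and order are unchanged.

    Raises
    ------
    ValueError
        If the recording has a single channel ("cannot re-reference").
    """
    if rec.n_channels < 2:
        raise ValueError("cannot re-reference a single-channel recording")
    car = rec.signals.mean(axis=0, keepdims=True)
    return replace(rec, signals=rec.signals - car)


def read_delimited(path, fs: float, sep: str = ",", t0: float = 0.0) -> Recording:
    """Read a delimited numeric matrix (rows = samples, columns = channels).

    The first row is taken as channel labels.  The sampling rate is not part
    of the matrix format and must be supplied (e.g. from a sidecar config).
    """
    df = pd.read_csv(path, sep=sep)
    return Recording(
        signals=df.to_numpy(dtype=float).T,
        fs=fs,
        channels=[str(c) for c in df.columns],
        t0=t0,
    )


def write_delimited(rec: Recording, path, sep: str = ",") -> None:
    """Write a recording as a delimited matrix (rows = samples)."""
    pd.DataFrame(rec.signals.T, columns=rec.channels).to_csv(
        path, sep=sep, index=False
    )


def read_edf(path, channels: list[str] | None = None) -> Recording:
    """Read an EDF/EDF+ recording.

    Requires :mod:`mne` (install the ``ovitrans[edf]`` extra).  Signal units
    are converted from MNE's volts to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading EDF requires the 'mne' package (pip install ovitrans[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, include=channels, preload=True, verbose="error")
    return Recording(
        signals=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
    )


def read_hypnogram(path, epoch_len_s: float = 10.0) -> pd.DataFrame:
    """Read a manually scored hypnogram.

    Expected CSV columns: ``epoch_index`` and ``label`` with labels in
    {WAKE, NREM, REM}.  Returns a DataFrame indexed by epoch with an added
    ``t_start_s`` column.
    """
    df = pd.read_csv(path)
    if not {"epoch_index", "label"} <= set(df.columns):
        raise ValueError("hypnogram must have columns 'epoch_index' and 'label'")
    bad = set(df["label"].unique()) - {"WAKE", "NREM", "REM"}
    if bad:
        warnings.warn(f"hypnogram contains unexpected labels: {sorted(bad)}")
    df = df.sort_values("epoch_index").reset_index(drop=True)
    df["t_start_s"] = df["epoch_index"] * epoch_len_s
    return df


def write_hypnogram(labels, path, epoch_len_s: float = 10.0) -> None:
    """Write per-epoch labels as a hypnogram CSV."""
    labels = list(labels)
    pd.DataFrame(
        {
            "epoch_index": np.arange(len(labels)),
            "t_start_s": np.arange(len(labels)) * epoch_len_s,
            "label": labels,
        }
    ).to_csv(path, index=False)
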