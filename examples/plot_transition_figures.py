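"""Plot the transition-dynamics figures: aligned spectrograms, moving
variance, and pre/post band-power traces.

Writes three PNGs into ``scratch/`` (created if missing): the min-max
normalised mean spectrogram around awakenings, the moving-variance curve
(method A), and delta power around awakenings as a proportion of the NREM
mean.  Requires matplotlib (``pip install ovitrans[plot]``).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import ovitrans as ot
from ovitrans import dynamics as dyn

out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)

cfg = ot.SimConfig(night_len_h=2.5, n_channels=4, seed=19, ramp_wake_s=90.0)
rec, gt = ot.generate_recording(cfg)
res = ot.analyse_night(rec, hypnogram=gt.hypnogram_df())

kept = [t for t in res.transitions if not t.excluded and t.direction == "TO_WAKE"]
aligned = []
for tr in kept:
    try:
        a = dyn.align_spectrogram(res.spectra, tr.centre_s, 300.0, channel=0)
    except ValueError:
        continue
    aligned.append(dyn.rebin_frequencies(a, 1.0))

# mean spectrogram over awakenings, each bin min-max normalised to itself
mean_vals = np.mean([a.values for a in aligned], axis=0)
mean_a = aligned[0]
mm = dyn.minmax_normalise_bins(
    dyn.AlignedSpectrogram(mean_a.rel_times, mean_a.freqs, mean_vals,
                           np.zeros(mean_vals.shape[0], bool), 10.0)
)
fig, ax = plt.subplots(figsize=(6, 4))
ax.pcolormesh(mm.rel_times / 60.0, mm.freqs, mm.values.T, cmap="gray",
              shading="auto")
ax.set(xlabel="time from transition centre (min)", ylabel="frequency (Hz)",
       title="mean sleep-to-wake spectrogram (per-bin min-max)", ylim=(0, 40))
fig.savefig(out_dir / "mean_transition_spectrogram.png", dpi=120)

# method-A moving variance curve of the mean spectrogram
w = 6
curve_t, curve_v = [], []
for j in range(mm.values.shape[0] - w + 1):
    curve_t.append(mm.rel_times[j] / 60.0 + 0.5)
    curve_v.append(mm.values[j : j + w].var(axis=0).mean())
fig, ax = plt.subplots(figsize=(6, 3))
ax.plot(curve_t, curve_v)
ax.axvline(0, color="k", ls=":")
ax.set(xlabel="time from transition centre (min)",
       ylabel="moving variance (1-min window)",
       title="spectral variance around awakenings")
fig.tight_layout()
fig.savefig(out_dir / "moving_variance.png", dpi=120)

# delta power around awakenings as a proportion of the NREM mean
sp = res.speed
sel = sp[(sp.channel == "mean") & (sp.direction == "TO_WAKE") & (sp.band == "delta")]
delta_bins = (mean_a.freqs >= 0.5) & (mean_a.freqs < 4.0)
traces = np.array([a.values[:, delta_bins].sum(axis=1) for a in aligned])
ref = res.state_band_means
nrem_ref = ref[(ref.band == "delta") & (ref.state == "NREM")]["mean_power"].mean()
fig, ax = plt.subplots(figsize=(6, 3))
t_min = aligned[0].rel_times / 60.0
m = traces.mean(axis=0) / nrem_ref
s = traces.std(axis=0) / np.sqrt(len(traces)) / nrem_ref
ax.plot(t_min, m, color="k")
ax.fill_between(t_min, m - s, m + s, alpha=0.3)
ax.axhline(1.0, color="b", ls="--", label="avg NREM delta")
ax.axvline(0, color="k", ls=":")
ax.set(xlabel="time from awakening (min)",
       ylabel="delta power / avg NREM delta",
       title="slow-wave power collapses across the awakening")
ax.legend()
fig.tight_layout()
fig.savefig(out_dir / "delta_prepost.png", dpi=120)

print(f"wrote 3 figures to {out_dir}/ ; pre-waking delta sits at "
      f"{sel['pre_prop_nrem'].mean():.2f}x the NREM average in [-4, -2] min")
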