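# Methods

This note documents the models and procedures implemented in `ovitrans`, the
choices made where the method leaves latitude, and what the synthetic tests
do and do not establish.

## Spectral estimation

Epochs are fixed 10 s windows (epoch *i* covers `[10i, 10(i+1))`, 0-based,
seconds from recording start).  Each epoch/channel gets a rectangular-window
periodogram with the epoch mean removed; the one-sided spectrum is scaled so
that the sum over frequency bins equals the epoch's signal variance
(Parseval), giving 0.1 Hz resolution at 250 Hz sampling.  No taper or
averaging is applied by default: the downstream quantities are band sums over
tens of bins and minute-scale windows, which average the single-periodogram
variance; a taper would only blur the band edges.  Common-average
re-referencing precedes epoching whenever at least two channels are present.

**Artefact rule.**  Per channel, epoch total powers `p_i` are screened with
`|p_i − mean(p)| > k · median(|p − mean(p)|)`, `k = 3`, two-sided by default
(an upper-only variant exists).  The dispersion is the median absolute
deviation *about the mean*: with that reading a single extreme epoch among
otherwise equal powers is flagged exactly once, whereas the median-centred
MAD would be zero and flag everything that deviates at all.  Statistics are
computed over all epochs, making the rule idempotent and order-invariant.
Because common-average re-referencing injects 1/C of any channel's artefact
into every other channel, the pipeline by default masks an epoch on *all*
channels when any channel flags it (`artefact_mask_union`); on synthetic
nights every residual staging error traced back to exactly this leakage.

**Night normalisation.**  Per channel, every bin power is divided by the mean
over artefact-free epochs of the epoch total power (whole spectrum, 0–125
Hz), so the mean normalised epoch total is exactly 1.  All transition metrics
operate on normalised power; the ratios (SSRs, state proportions) are
unaffected by it.

**Bands.**  delta 0.5–4, theta 4–9, alpha 9–14, beta 14–35, gamma 35–125 Hz,
half-open `[lo, hi)` on bin centres so shared edges are counted once; gamma
omits a 1 Hz guard band `[49.5, 50.5)` around mains.

## Staging

`SSR2 = P(0.5–20)/P(0.5–100)` is computed per epoch and channel (`SSR1 =
P(6.5–9)/P(0.5–9)` is computed for visualisation only).  The SSR2 histogram
(bin width 0.01 over [0, 1], counts smoothed by a 3-bin moving average for
peak ranking) is required to show two local maxima at least 0.05 apart; the
two highest become the wake (lower) and NREM (upper) modes, reported as bin
centres.  With `x = upper − lower` and `y = 0.2x`: `SSR2 ≥ upper − y` ⇒ NREM,
`SSR2 < lower + y` ⇒ wake, else inter-state; artefact epochs override
everything.  Growing `y` recruits inter-state epochs into wake or NREM but can
never convert wake to NREM or back while `y < x/2`.  Thresholds are fitted
per channel because the SSR2 distribution differs between animals and
channels; a unimodal histogram raises an error rather than guessing
(fall back to manual scoring in that case).  At least 200 artefact-free
epochs are required (configurable floor).

## Transition detection

The consensus wake fraction pools all channels: in a rolling 5-minute window
advancing one epoch at a time, it is the number of wake-labelled
channel-epochs over the number of non-artefact channel-epochs.  A transition
is a 0.5 crossing with at least 5 minutes of the old side before and the new
side after (run-length debouncing; shorter excursions are flipped into their
surroundings, so surviving events strictly alternate).

The *centre* is then refined: the detection fraction counts inter-state
epochs in its denominator, so on a gradual switch its 0.5 crossing sits
roughly 30% of the ramp toward the wake side.  The centre is moved to the
nearest matching 0.5 crossing of the wake/(wake+NREM) *state-balance*
fraction, which is symmetric in the two staged states and therefore marks the
mid-point of the slope; on synthetic 120 s ramps this cuts the systematic
centre error from ≈+35 s to under 10 s.  Detection itself still uses the
plain consensus fraction.

Transitions whose ±5 min neighbourhood overlaps a manually scored REM epoch
are flagged and excluded from the dynamics (the extent matches the widest
analysis window; the pre/post windows end at ±4 min).  Bouts span consecutive
transition centres of the full alternating sequence; partial segments at the
night edges never become bouts.  Summary counts report non-excluded
transitions per direction, so REM-rich nights naturally show fewer
transitions to wake than to sleep.

## Transition dynamics

Per kept transition, epoch spectra are re-indexed to time-from-centre over
±5 min; metrics are computed per channel (rows for the mixed models) and on
the cross-channel mean series (`channel == "mean"`), which halves the noise
floor and is the primary per-transition value.

* **Method A (variance peak).**  The aligned spectrogram is aggregated into
  1 Hz bins (single 0.1 Hz periodogram bins are chi-square distributed with
  two degrees of freedom and would dominate the variance), each bin is
  min-max normalised to itself over the window, and a 1-minute moving window
  slides over ±2 min.  The default statistic is the *mean over bins of the
  per-bin temporal variance*: it responds only to change over time.  The
  fully pooled variant (all bin×epoch values in one variance) is available
  behind `variance_per_bin=False` but is dominated by the static spread of
  bin means and, on simulated data, cannot tell a 30 s switch from a 120 s
  one.
* **Method B (duration).**  Baselines are the 5 minutes before and after the
  centre (literal placement; a configurable `baseline_gap_s` can push them
  clear of a known ramp, which otherwise inflates the baseline SD — the
  noise-free oracle tests use that).  The start is the last epoch still
  inside the pre-baseline mean ± SD envelope before the final departure; the
  end is the first epoch back inside the post-envelope for at least 2
  consecutive epochs (resists single-epoch noise).  Results are
  epoch-resolution times; a series that never leaves its pre-envelope, or
  never settles, is flagged invalid rather than given a number.
* **Method C (gradient).**  `(power(end) − power(start)) / duration` in
  power per minute, from the method-B endpoints; negative for falling bands
  on awakening (delta), positive for rising ones (gamma).
* **Pre/post contrasts.**  Mean band power over −4…−2 and +2…+4 min, divided
  by the night mean of that band over automatically labelled, artefact-free
  NREM and wake epochs.

Under the default baseline placement the ramp's tails sit inside both
baselines, so measured durations run ≈25–40% short of the programmed
crossfade and ratios between conditions are compressed; orderings and ratios
(what the group comparisons use) are preserved.  This is the main known bias
of method B.

## Group statistics

Animals are the experimental unit.  The fragmentation quartet (transitions to
wake/sleep, mean wake/NREM bout length) uses the pooled-variance two-sample
t-test, `df = n1 + n2 − 2`; the table reports the second group minus the
first.  Transition durations are strictly positive and right-skewed, so their
group contrast is fit as a gamma-family model with log link; statsmodels has
no gamma-family random-intercept GLMM, so the fit is by generalised
estimating equations with exchangeable within-animal correlation and the
small-sample (bias-reduced) covariance — the same population-level contrast
with clustering handled marginally.  Gradients and variance peaks are fit by
a linear mixed model with a random animal intercept on `sqrt(abs(value))`
(the absolute value first because to-wake gradients are all negative).  In
both cases the group-effect p-value refers the Wald statistic to a t
distribution with `n_animals − 2` degrees of freedom rather than the normal:
with ~10 animals the asymptotic z-test rejected ≈10% of permuted-label nulls
at the 5% level, while the t reference brings both models into the binomial
band around 5% (the LMM slightly conservative at 1–3%).  No multiple-testing
correction is applied across bands by default.  `permutation_calibration`
re-fits any of these models under shuffled animal→group maps and reports the
empirical false-positive rate.

## Synthetic nights

The generator scripts a night as alternating wake/NREM bouts (gamma
distributed, shape 4, means 14.5 and 10.5 min, floored at 6 min so every
programmed bout is long enough for the 5-minute consensus rule to see), with
a configurable chance (default 0.2) that a NREM bout ends in a ~2 min REM
segment known only to the hypnogram.  Each channel is a sum over the five
bands of spectrally flat band-limited noise (synthesised in the frequency
domain, so in-band density is exactly flat and leakage zero), whose amplitude
follows the current state's band-power profile with linear crossfades of
configurable duration at each switch, plus a 50 Hz mains sinusoid and
broadband artefact bursts (10× channel RMS, ~2/h, one epoch long).

The default profiles put the analytic SSR2 (computable in closed form from
the profile, including mains) at 0.549 for wake, 0.878 for NREM and 0.68
(inter-state) for REM, with a clear wake/NREM contrast in every band so all
three speed metrics have a programmed change to recover.  A per-epoch
lognormal modulation of each band's amplitude (σ = 0.06, unit mean power)
reproduces the epoch-to-epoch variability of real band power and sets the
SSR2 mode widths to ≈0.02 (NREM) – 0.035 (wake).

An optional *pre-waking decline* emulates the gentle awakening: over the last
5 minutes of NREM before each awakening, delta power drops to a programmed
fraction of the night's mean NREM delta.  The declined level is solved
exactly against the drawn schedule (the mean it is a fraction *of* includes
the declined time itself), and the removed delta power is added to theta so
the declined epochs keep their NREM SSR2 and stage normally — otherwise the
decline would push its own epochs out of the reference mean and the
programmed fraction would not be recoverable even in principle.

What the generator does **not** emulate: spindles, K-complexes, slow-wave
morphology, 1/f background, EMG/EOG, inter-channel correlation structure, or
movement-artefact morphology.  Passing tests therefore establish that the
pipeline recovers *programmed* spectral state structure, switch times, ramp
contrasts and power contrasts under realistic epoch-level variability — not
that it handles every failure mode of real recordings (e.g. nights whose
SSR2 histogram is not bimodal raise an error by design).

## Problem sizes and determinism

The test suite and the acceptance script use: one full default night (10.6 h,
8 channels, 250 Hz) for staging fidelity; a scripted ~4.8 h night with 12
programmed awakenings (3 REM-preceded) for detection; 5+5 animal cohorts of
4 h nights (8 channels) for the ramp-contrast and pre-waking-delta recovery;
and a 4+4 cohort of 3 h nights (4 channels) with identical group parameters
for the permutation calibration (100 permutations).  Everything is
deterministic given (config, seed); cohort members get consecutive seeds from
a base seed and duplicate seeds are rejected.

## Known limitations

* Method-B durations are compressed by in-baseline ramps (see above); use
  `baseline_gap_s` when the transition extent is known.
* Peak locations in threshold fitting are bin centres (error bounded by the
  0.01 bin width); no sub-bin interpolation.
* REM is consumed from a manual hypnogram only; there is no REM detector.
* The gamma model is marginal (GEE), not a conditional GLMM; with animal-level
  heterogeneity far larger than within-animal noise its effect estimates are
  still unbiased but its working correlation is a convenience, not a model of
  the biology.
* Thresholds do not transfer across nights; each night is staged on its own
  histogram.
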