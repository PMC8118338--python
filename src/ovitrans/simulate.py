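"""Synthetic multichannel EEG nights with known ground truth.

The generator emulates the statistical structure the analysis pipeline is
built for, without attempting physiological detail (no spindles or
K-complexes):

* alternating wake/NREM bouts with gamma-distributed lengths at the scale of
  an ovine night (means 14.5 and 10.5 minutes), occasionally ending in a REM
  segment that only the hypnogram knows about;
* per-state spectral profiles built from flat band-limited noise (delta,
  theta, alpha, beta, gamma), chosen so the SSR2 distribution is bimodal with
  a wake mode near 0.55 and a NREM mode near 0.88;
* linear amplitude crossfades of configurable duration at every switch — the
  programmed transition "ramp" that the speed metrics must recover;
* an optional pre-waking decline of delta power to a programmed fraction of
  the night's mean NREM delta (with a compensating theta increase so the
  declined epochs still stage as NREM), emulating the gentle-awakening
  pattern;
* a mains sinusoid and occasional large artefact bursts.

Everything is deterministic given (config, seed), and every scripted feature
is returned as :class:`GroundTruth` so each pipeline stage can be validated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import Recording

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CohortMember",
    "generate_recording",
    "generate_cohort",
    "default_profiles",
    "expected_ssr",
]

_BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 9.0),
    "alpha": (9.0, 14.0),
    "beta": (14.0, 35.0),
    "gamma": (35.0, 125.0),
}


def default_profiles() -> dict[str, dict[str, float]]:
    """Per-state band power profiles in uV^2.

    Wake is rich in beta/gamma, NREM dominated by delta (with clearly higher
    theta/alpha than wake, as during slow-wave sleep), REM theta-rich with low
    delta.  With these values the analytic SSR2 is ~0.55 in wake, ~0.88 in
    NREM and ~0.68 (inter-state) in REM.
    """
    return {
        "WAKE": {"delta": 54.0, "theta": 20.0, "alpha": 14.0, "beta": 44.0, "gamma": 68.0},
        "NREM": {"delta": 240.0, "theta": 40.0, "alpha": 30.0, "beta": 20.0, "gamma": 38.0},
        "REM": {"delta": 30.0, "theta": 80.0, "alpha": 24.0, "beta": 30.0, "gamma": 60.0},
    }


@dataclass
class SimConfig:
    """Parameters of one synthetic night.

    Bout lengths are drawn from a gamma distribution (``bout_shape``) scaled
    to the target means and floored at ``min_bout_min`` so that every
    programmed bout is long enough to be detectable by a 5-minute consensus
    rule.  ``prewake_delta_frac`` programs the pre-waking delta level as a
    fraction of the night's mean NREM delta power (values >= 1 disable the
    decline).  ``schedule`` may supply an explicit list of ``(state,
    duration_s)`` segments (states WAKE/NREM/REM) instead of the bout model.
    """

    n_channels: int = 8
    fs: float = 250.0
    night_len_h: float = 10.6
    epoch_len_s: float = 10.0
    mean_wake_bout_min: float = 14.5
    mean_nrem_bout_min: float = 10.5
    bout_shape: float = 4.0
    min_bout_min: float = 6.0
    state_profiles: dict[str, dict[str, float]] = field(default_factory=default_profiles)
    ramp_wake_s: float = 120.0  # sleep-to-wake crossfade
    ramp_sleep_s: float = 120.0  # wake-to-sleep crossfade
    minor_fade_s: float = 30.0  # REM boundaries and the pre-waking decline onset
    prewake_delta_frac: float = 0.5
    prewake_lead_s: float = 300.0
    rem_prob: float = 0.2
    rem_len_min: float = 2.0
    artefact_rate_per_h: float = 2.0
    artefact_amp: float = 10.0  # burst amplitude in channel-RMS units
    mains_hz: float = 50.0
    mains_amp_uv: float = 2.0
    band_mod_sigma: float = 0.06  # per-epoch lognormal band-amplitude variability
    seed: int = 0
    schedule: list[tuple[str, float]] | None = None

    def __post_init__(self) -> None:
        for name, val in [
            ("night_len_h", self.night_len_h),
            ("mean_wake_bout_min", self.mean_wake_bout_min),
            ("mean_nrem_bout_min", self.mean_nrem_bout_min),
            ("epoch_len_s", self.epoch_len_s),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        for state, prof in self.state_profiles.items():
            for band, p in prof.items():
                if p < 0:
                    raise ValueError(f"negative power for {state}/{band}")


@dataclass
class GroundTruth:
    """Everything the generator scripted, for validating the pipeline."""

    hypnogram: np.ndarray  # per-epoch labels WAKE/NREM/REM
    switches: pd.DataFrame  # t_s, direction, from_state, ramp_s, declined
    artefact_epochs: dict[str, list[int]]
    expected_ssr2: dict[str, float]
    expected_band_power: dict[str, dict[str, float]]
    prewake_delta_power: float | None
    prewake_fraction_of_nrem_time: float
    epoch_len_s: float
    config: SimConfig

    def hypnogram_df(self) -> pd.DataFrame:
        n = len(self.hypnogram)
        return pd.DataFrame(
            {
                "epoch_index": np.arange(n),
                "t_start_s": np.arange(n) * self.epoch_len_s,
                "label": self.hypnogram,
            }
        )

    def to_json(self, path=None) -> str:
        payload = {
            "switches": self.switches.to_dict(orient="records"),
            "artefact_epochs": self.artefact_epochs,
            "expected_ssr2": self.expected_ssr2,
            "expected_band_power": self.expected_band_power,
            "prewake_delta_power": self.prewake_delta_power,
            "prewake_fraction_of_nrem_time": self.prewake_fraction_of_nrem_time,
            "config": {
                k: v
                for k, v in dataclasses.asdict(self.config).items()
                if k != "state_profiles"
            },
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def expected_ssr(profile: dict[str, float], mains_power: float = 0.0) -> dict[str, float]:
    """Analytic SSR1/SSR2 of a flat-band profile (mains counted at 50 Hz)."""
    d, t, a, b, g = (profile[k] for k in ("delta", "theta", "alpha", "beta", "gamma"))
    num2 = d + t + a + b * (20.0 - 14.0) / (35.0 - 14.0)
    den2 = d + t + a + b + g * (100.0 - 35.0) / (125.0 - 35.0) + mains_power
    num1 = t * (9.0 - 6.5) / (9.0 - 4.0)
    den1 = d + t
    return {"ssr1": num1 / den1, "ssr2": num2 / den2}


# ---------------------------------------------------------------------------
# schedule construction


def _draw_schedule(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, float]]:
    """Alternating WAKE/NREM segments (REM tails on some NREM bouts)."""
    ep = cfg.epoch_len_s
    total = round(cfg.night_len_h * 3600.0 / ep) * ep
    means = {"WAKE": cfg.mean_wake_bout_min, "NREM": cfg.mean_nrem_bout_min}
    segs: list[tuple[str, float]] = []
    state = "WAKE"
    t = 0.0
    while t < total:
        dur_min = rng.gamma(cfg.bout_shape, means[state] / cfg.bout_shape)
        dur = max(dur_min, cfg.min_bout_min) * 60.0
        dur = max(ep, round(dur / ep) * ep)
        dur = min(dur, total - t)
        if state == "NREM" and rng.random() < cfg.rem_prob:
            rem = rng.gamma(cfg.bout_shape, cfg.rem_len_min / cfg.bout_shape) * 60.0
            rem = max(ep, round(rem / ep) * ep)
            # keep a substantial NREM core so the bout still stages as sleep
            if rem < dur - 300.0:
                segs.append((state, dur - rem))
                segs.append(("REM", rem))
                t += dur
                state = "WAKE"
                continue
        segs.append((state, dur))
        t += dur
        state = "WAKE" if state == "NREM" else "NREM"
    return segs


def _normalise_schedule(
    schedule: list[tuple[str, float]], cfg: SimConfig
) -> list[tuple[str, float]]:
    ep = cfg.epoch_len_s
    out = []
    for state, dur in schedule:
        if state not in ("WAKE", "NREM", "REM"):
            raise ValueError(f"unknown schedule state {state!r}")
        d = max(ep, round(float(dur) / ep) * ep)
        out.append((state, d))
    return out


def _apply_prewake(
    segs: list[tuple[str, float]], cfg: SimConfig
) -> tuple[list[tuple[str, float]], float, float | None]:
    """Split NREM segments that run into wake, inserting a declined tail.

    Returns the new segment list, the fraction of NREM time spent declined,
    and the solved pre-waking delta power (None when disabled).  The declined
    delta level ``d_pre`` is solved so that, time-averaged over all NREM-
    labelled epochs of this night, ``d_pre = frac * mean(delta)`` holds
    exactly for the programmed schedule.
    """
    c = cfg.prewake_delta_frac
    lead = cfg.prewake_lead_s
    if c >= 1.0 or lead <= 0:
        return segs, 0.0, None
    # a short stretch of full NREM must survive before the decline sets in
    min_len = lead + cfg.minor_fade_s + 30.0
    out: list[tuple[str, float]] = []
    declined = 0.0
    nrem_total = 0.0
    for k, (state, dur) in enumerate(segs):
        nxt = segs[k + 1][0] if k + 1 < len(segs) else None
        if state == "NREM":
            nrem_total += dur
        if state == "NREM" and nxt == "WAKE" and dur >= min_len:
            out.append(("NREM", dur - lead))
            out.append(("NREM_PRE", lead))
            declined += lead
        else:
            out.append((state, dur))
    if declined == 0.0 or nrem_total == 0.0:
        return out, 0.0, None
    f = declined / nrem_total
    d_main = cfg.state_profiles["NREM"]["delta"]
    d_pre = c * (1.0 - f) * d_main / (1.0 - c * f)
    return out, f, float(d_pre)


# ---------------------------------------------------------------------------
# signal synthesis


def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a flat spectrum strictly inside [lo, hi) Hz."""
    n_f = n // 2 + 1
    df = fs / n
    k0 = max(1, int(np.ceil(lo / df)))
    k1 = min(n_f - 1, int(np.ceil(hi / df)))
    if k1 <= k0:
        raise ValueError(f"band [{lo}, {hi}) empty at this resolution")
    spec = np.zeros(n_f, dtype=complex)
    spec[k0:k1] = rng.standard_normal(k1 - k0) + 1j * rng.standard_normal(k1 - k0)
    x = np.fft.irfft(spec, n)
    x /= x.std()
    return x


def _ramp_for(prev: str, nxt: str, cfg: SimConfig) -> float:
    base = {"NREM_PRE": "NREM"}
    p, q = base.get(prev, prev), base.get(nxt, nxt)
    if q == "WAKE":
        return cfg.ramp_wake_s
    if p == "WAKE":
        return cfg.ramp_sleep_s
    return cfg.minor_fade_s


def _envelopes(
    segs: list[tuple[str, float]],
    profiles: dict[str, dict[str, float]],
    cfg: SimConfig,
    n_samples: int,
) -> dict[str, np.ndarray]:
    """Per-band amplitude envelopes with linear crossfades at boundaries."""
    t_samp = np.arange(n_samples) / cfg.fs
    bounds = np.cumsum([d for _, d in segs])
    envs = {}
    for band in _BAND_EDGES:
        amps = [np.sqrt(profiles[s][band]) for s, _ in segs]
        knot_t = [0.0]
        knot_a = [amps[0]]
        for k in range(len(segs) - 1):
            r = _ramp_for(segs[k][0], segs[k + 1][0], cfg)
            knot_t += [bounds[k] - r / 2.0, bounds[k] + r / 2.0]
            knot_a += [amps[k], amps[k + 1]]
        knot_t.append(bounds[-1])
        knot_a.append(amps[-1])
        kt = np.maximum.accumulate(np.asarray(knot_t))
        envs[band] = np.interp(t_samp, kt, np.asarray(knot_a))
    return envs


def generate_recording(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Synthesize one night and its ground truth.

    The signal of each channel is the sum over bands of flat band-limited
    noise whose amplitude follows the current state's profile, crossfaded
    linearly over the programmed ramp at each switch, plus a mains sinusoid
    and artefact bursts.  Identical (config, seed) pairs give bit-identical
    output.
    """
    ep = cfg.epoch_len_s
    n_total_epochs = int(round(cfg.night_len_h * 3600.0 / ep))
    if n_total_epochs * ep < cfg.min_bout_min * 60.0 and cfg.schedule is None:
        raise ValueError("night shorter than one bout")
    rng = np.random.default_rng(cfg.seed)

    if cfg.schedule is not None:
        segs = _normalise_schedule(cfg.schedule, cfg)
    else:
        segs = _draw_schedule(cfg, rng)
    segs, prewake_f, d_pre = _apply_prewake(segs, cfg)

    profiles = {s: dict(p) for s, p in cfg.state_profiles.items()}
    if d_pre is not None:
        nrem = profiles["NREM"]
        profiles["NREM_PRE"] = dict(
            nrem,
            delta=d_pre,
            theta=nrem["theta"] + (nrem["delta"] - d_pre),
        )

    total_s = sum(d for _, d in segs)
    n_samples = int(round(total_s * cfg.fs))
    n_epochs = int(total_s / ep)

    # hypnogram: state of the segment containing each epoch midpoint
    bounds = np.cumsum([d for _, d in segs])
    mids = (np.arange(n_epochs) + 0.5) * ep
    seg_of = np.searchsorted(bounds, mids, side="right")
    label_of_seg = np.array(
        ["NREM" if s == "NREM_PRE" else s for s, _ in segs], dtype=object
    )
    hypnogram = label_of_seg[np.clip(seg_of, 0, len(segs) - 1)]

    # programmed switches (WAKE <-> sleep boundaries only)
    rows = []
    for k in range(len(segs) - 1):
        prev, nxt = segs[k][0], segs[k + 1][0]
        p_w, n_w = prev == "WAKE", nxt == "WAKE"
        if p_w == n_w:
            continue
        rows.append(
            {
                "t_s": float(bounds[k]),
                "direction": "TO_WAKE" if n_w else "TO_SLEEP",
                "from_state": "REM" if prev == "REM" else ("WAKE" if p_w else "NREM"),
                "ramp_s": _ramp_for(prev, nxt, cfg),
                "declined": prev == "NREM_PRE",
            }
        )
    switches = pd.DataFrame(rows, columns=["t_s", "direction", "from_state", "ramp_s", "declined"])

    envs = _envelopes(segs, profiles, cfg, n_samples)
    ep_samples = int(round(ep * cfg.fs))
    t_samp = np.arange(n_samples) / cfg.fs

    signals = np.empty((cfg.n_channels, n_samples))
    sigma = cfg.band_mod_sigma
    for ch in range(cfg.n_channels):
        x = np.zeros(n_samples)
        for band, (lo, hi) in _BAND_EDGES.items():
            noise = _band_noise(n_samples, cfg.fs, lo, hi, rng)
            if sigma > 0:
                m = np.exp(sigma * rng.standard_normal(n_epochs + 1) - sigma**2)
                mod = np.repeat(m, ep_samples)[:n_samples]
                noise *= mod
            x += envs[band] * noise
        if cfg.mains_amp_uv > 0:
            x += cfg.mains_amp_uv * np.sin(
                2 * np.pi * cfg.mains_hz * t_samp + rng.uniform(0, 2 * np.pi)
            )
        signals[ch] = x

    # artefact bursts: broadband noise >= artefact_amp x channel RMS, one epoch each
    artefact_epochs: dict[str, list[int]] = {}
    channels = [f"ch{i}" for i in range(cfg.n_channels)]
    for ch in range(cfg.n_channels):
        n_art = rng.poisson(cfg.artefact_rate_per_h * total_s / 3600.0)
        n_art = min(n_art, n_epochs)
        eps = sorted(rng.choice(n_epochs, size=n_art, replace=False).tolist())
        rms = signals[ch].std()
        for e in eps:
            s0 = e * ep_samples
            signals[ch, s0 : s0 + ep_samples] += (
                cfg.artefact_amp * rms * rng.standard_normal(ep_samples)
            )
        artefact_epochs[channels[ch]] = [int(e) for e in eps]

    mains_power = cfg.mains_amp_uv**2 / 2.0
    expected_ssr2 = {
        s: expected_ssr(p, mains_power)["ssr2"] for s, p in profiles.items()
    }
    gt = GroundTruth(
        hypnogram=hypnogram,
        switches=switches,
        artefact_epochs=artefact_epochs,
        expected_ssr2=expected_ssr2,
        expected_band_power=profiles,
        prewake_delta_power=d_pre,
        prewake_fraction_of_nrem_time=prewake_f,
        epoch_len_s=ep,
        config=cfg,
    )
    rec = Recording(signals=signals, fs=cfg.fs, channels=channels)
    return rec, gt


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortMember:
    """Lazy handle on one synthetic animal (recordings are generated on demand)."""

    group: str
    animal: str
    config: SimConfig

    def generate(self) -> tuple[Recording, GroundTruth]:
        return generate_recording(self.config)


def generate_cohort(
    cfg_by_group: dict[str, SimConfig],
    n_per_group: int | dict[str, int] = 5,
    seeds: dict[str, list[int]] | None = None,
    base_seed: int = 0,
) -> tuple[list[CohortMember], pd.DataFrame]:
    """Plan a multi-animal cohort with group-specific generator parameters.

    Recordings are multi-hundred-megabyte arrays, so members are returned as
    lazy handles; call :meth:`CohortMember.generate` one animal at a time.
    Per-animal seeds default to ``base_seed + i`` in enumeration order and
    must be unique across the cohort.

    Returns the member list and a manifest recording group, animal, seed and
    the group parameters that differ between groups.
    """
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in cfg_by_group}
    members: list[CohortMember] = []
    rows = []
    used: set[int] = set()
    idx = 0
    for group, cfg in cfg_by_group.items():
        n = n_per_group[group]
        if n < 1:
            raise ValueError(f"group {group!r} needs at least one animal")
        for a in range(n):
            seed = (
                seeds[group][a] if seeds is not None else base_seed + idx
            )
            if seed in used:
                raise ValueError(f"duplicate seed {seed} across animals")
            used.add(seed)
            mcfg = dataclasses.replace(cfg, seed=seed)
            animal = f"{group}_{a}"
            members.append(CohortMember(group=group, animal=animal, config=mcfg))
            rows.append(
                {
                    "group": group,
                    "animal": animal,
                    "seed": seed,
                    "ramp_wake_s": mcfg.ramp_wake_s,
                    "ramp_sleep_s": mcfg.ramp_sleep_s,
                    "prewake_delta_frac": mcfg.prewake_delta_frac,
                    "night_len_h": mcfg.night_len_h,
                    "n_channels": mcfg.n_channels,
                }
            )
            idx += 1
    return members, pd.DataFrame(rows)
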