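"""Synthetic epoched data with known ground truth.

The generator emulates the structure of evoked MEG/EEG responses that the
downstream analyses assume: every trial is the sum of

* a slow non-oscillatory trend (half-Gaussian rise from a configurable
  onset, slow decay), with class-dependent amplitude,
* a transient theta-band oscillation (carrier ~7 Hz) confined to a
  post-onset window by a Tukey taper,
* i.i.d. Gaussian sensor noise (optionally AR(1) in time).

Stimulus classes can differ in four dissociable ways, mirroring the effect
taxonomy the analyses are built to tease apart:

``global_shift``
    a latency shift of the oscillation common to all channels (processing
    speed);
``relative_phase``
    per-channel phase offsets that by default sum to ~0 across channels,
    i.e. a multichannel phase configuration with no net latency change;
``power_ratio``
    a multiplicative change of oscillation amplitude;
``additive_shift``
    an additive offset during the stimulus window.

Every injected quantity is recorded in :class:`GroundTruth`, and
``trend + oscillation + noise`` reconstructs the emitted data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "EpochSet",
    "GroundTruth",
    "generate_trials",
    "generate_cohort",
    "generate_switching_trials",
    "default_attribute_map",
]


def default_attribute_map(n_categories: int) -> dict[int, dict[str, int]]:
    """Assign animacy (0/1) and size (1/2/3) to each category.

    Animacy and size are assigned on independent cycles so the two
    attributes are (nearly) orthogonal across categories.
    """
    return {
        c: {"animacy": c % 2, "size": (c // 2) % 3 + 1} for c in range(n_categories)
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic evoked-response generator.

    Effect amplitudes are expressed per contrast on the animacy attribute:
    animate trials (animacy == 1) receive the effect, inanimate trials are
    the reference class.
    """

    n_trials: int = 120
    n_channels: int = 10
    fs: float = 250.0
    trial_dur: float = 1.0
    carrier_freq: float = 7.0
    # 6 categories give a full animacy (2) x size (3) attribute crossing
    n_categories: int = 6
    attribute_map: dict[int, dict[str, int]] | None = None
    # class effects (animate minus inanimate)
    global_shift: float = 0.0  # s
    relative_phase: np.ndarray | Sequence[float] | None = None  # rad, per channel
    power_ratio: float = 1.0
    additive_shift: float = 0.0  # signal units
    # channel weights of the additive effect; None -> uniform. A zero-sum
    # topography keeps the class effect orthogonal to the trend's overall
    # level, as real slow category effects are topographic patterns rather
    # than global field shifts
    additive_pattern: np.ndarray | Sequence[float] | None = None
    # slow-trend shape
    trend_onset: float = 0.05  # s
    trend_rise: float = 0.15  # s, rise time to peak
    trend_decay: float = 0.35  # s, sd of the decaying half
    trend_amplitude: float = 1.0
    trend_class_gain: float = 0.0  # fractional amplitude change for animate
    # oscillation
    osc_amplitude: float = 1.0
    osc_window: tuple[float, float] = (0.05, 0.7)  # s, Tukey-tapered support
    # support of the additive class offset; None -> osc_window. A sustained
    # offset (e.g. (0.05, 1.0)) survives per-trial standardization with a
    # sign-consistent class difference across the response period
    additive_window: tuple[float, float] | None = None
    latency_jitter_sd: float = 0.04  # s, per-trial zero-mean jitter
    # truncated so total per-trial latency stays inside +-half a carrier
    # period: latency beyond that is not identifiable in a band-limited
    # response (the trial could equally have skipped a cycle)
    latency_jitter_max: float = 0.06  # s
    noise_sd: float = 0.5
    ar1_coef: float = 0.0  # 0 -> white noise
    # center the per-channel phase offsets so they sum to ~0 across channels
    # (a pure relative configuration); disable to inject e.g. a uniform
    # phase opposition common to all channels
    center_relative_phase: bool = True
    # number of quasi-stationary processing stages across the trial: with
    # more than one, the relative-phase configuration is re-drawn (seeded
    # permutation of the base pattern) per stage, so the oscillatory class
    # code evolves over the trial instead of persisting unrealistically
    phase_stages: int = 1
    seed: int = 0

    @property
    def n_time(self) -> int:
        return int(round(self.fs * self.trial_dur))

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_channels < 1 or self.n_time < 1:
            raise ValueError("n_trials, n_channels and n_time must be positive")
        if self.attribute_map is None:
            self.attribute_map = default_attribute_map(self.n_categories)
        if set(self.attribute_map) != set(range(self.n_categories)):
            raise ValueError("attribute_map must cover every category exactly once")
        if self.relative_phase is None:
            self.relative_phase = np.zeros(self.n_channels)
        self.relative_phase = np.asarray(self.relative_phase, dtype=float)
        if self.relative_phase.shape != (self.n_channels,):
            raise ValueError(
                f"relative_phase must have length n_channels={self.n_channels}, "
                f"got {self.relative_phase.shape}"
            )
        for name in ("global_shift", "power_ratio", "additive_shift", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not np.all(np.isfinite(self.relative_phase)):
            raise ValueError("relative_phase must be finite")
        if self.power_ratio <= 0:
            raise ValueError("power_ratio must be > 0")


@dataclass
class EpochSet:
    """Epoched multichannel data: trials x channels x time."""

    data: np.ndarray  # (N, C, T)
    fs: float
    labels: np.ndarray  # (N,) category ids
    attributes: dict[str, np.ndarray] = field(default_factory=dict)
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        n, c, t = self.data.shape
        if min(n, c, t) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN/Inf")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (n,):
            raise ValueError(f"labels must have length {n}")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(c)]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_time) / self.fs

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=data,
            fs=self.fs,
            labels=self.labels.copy(),
            attributes={k: v.copy() for k, v in self.attributes.items()},
            channel_ids=list(self.channel_ids),
        )


@dataclass
class GroundTruth:
    """Record of every quantity injected by the generator."""

    trend: np.ndarray  # (N, C, T)
    oscillation: np.ndarray  # (N, C, T)
    noise: np.ndarray  # (N, C, T)
    latency_shift: np.ndarray  # (N,) s, per-trial total shift
    phase_offsets: np.ndarray  # (2, C) rad, per class per channel
    labels: np.ndarray  # (N,)
    config: SimConfig | None = None


def _tukey_window(t: np.ndarray, start: float, stop: float, taper_frac: float = 0.25) -> np.ndarray:
    """Tukey taper on [start, stop] seconds, zero outside."""
    w = np.zeros_like(t)
    span = stop - start
    inside = (t >= start) & (t <= stop)
    u = (t[inside] - start) / span  # in [0, 1]
    taper = np.ones_like(u)
    a = taper_frac
    lo = u < a
    hi = u > 1 - a
    taper[lo] = 0.5 * (1 - np.cos(np.pi * u[lo] / a))
    taper[hi] = 0.5 * (1 - np.cos(np.pi * (1 - u[hi]) / a))
    w[inside] = taper
    return w


def _trend_shape(t: np.ndarray, onset: float, rise: float, decay: float) -> np.ndarray:
    """Half-Gaussian rise from `onset` peaking at onset+rise, slow Gaussian decay."""
    peak = onset + rise
    shape = np.zeros_like(t)
    sig_r = max(rise / 2.0, 1e-6)
    rising = (t >= onset) & (t < peak)
    shape[rising] = np.exp(-0.5 * ((t[rising] - peak) / sig_r) ** 2)
    falling = t >= peak
    shape[falling] = np.exp(-0.5 * ((t[falling] - peak) / max(decay, 1e-6)) ** 2)
    return shape


def generate_trials(config: SimConfig, rng: np.random.Generator | None = None) -> tuple[EpochSet, GroundTruth]:
    """Generate one subject's epochs plus the full ground-truth record.

    Deterministic given ``config.seed`` (or the supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, c, t_n = config.n_trials, config.n_channels, config.n_time
    t = np.arange(t_n) / config.fs

    labels = rng.integers(0, config.n_categories, size=n)
    animacy = np.array([config.attribute_map[int(l)]["animacy"] for l in labels])
    size = np.array([config.attribute_map[int(l)]["size"] for l in labels])

    # latency: class shift + truncated per-trial jitter
    jitter = np.zeros(n)
    if config.latency_jitter_sd > 0:
        jitter = rng.normal(0.0, config.latency_jitter_sd, size=n)
        np.clip(jitter, -config.latency_jitter_max, config.latency_jitter_max, out=jitter)
    shift = config.global_shift * animacy + jitter  # s

    # phase offsets: class 0 -> none; class 1 -> configured per-channel offsets,
    # centered so they sum to ~0 across channels (pure relative effect)
    rel = np.asarray(config.relative_phase, dtype=float)
    if config.center_relative_phase and np.any(rel):
        rel = rel - rel.mean()
    n_stages = max(int(config.phase_stages), 1)
    base_rms = float(np.sqrt(np.mean(rel**2))) if np.any(rel) else 0.0
    stage_rel = [rel]
    for _ in range(n_stages - 1):
        fresh = rng.normal(size=c)
        fresh -= fresh.mean()
        rms = np.sqrt(np.mean(fresh**2))
        stage_rel.append(fresh * (base_rms / rms if rms > 0 else 0.0))
    stage_rel = np.stack(stage_rel)  # (S, C), each zero-mean, same RMS as base
    phase_offsets = np.stack([np.zeros(c), rel])  # (2, C), first-stage view
    stage_of_t = np.minimum((np.arange(t_n) * n_stages) // t_n, n_stages - 1)

    # all channels share the same evoked shape (uniform amplitude topography,
    # the schematic multichannel premise): class information lives purely in
    # the injected phase/amplitude/latency/trend modulations. A per-channel
    # gain would let the fixed-position trend leak channel-specific phase
    # structure into the detrended oscillation, confounding the relative-phase
    # effects the generator is supposed to isolate.
    win = _tukey_window(t, *config.osc_window)
    tr_shape = _trend_shape(t, config.trend_onset, config.trend_rise, config.trend_decay)

    amp = config.osc_amplitude * np.where(animacy == 1, np.sqrt(config.power_ratio), 1.0)
    # (N, C, T) phase argument: carrier shifted per trial, offset per channel/class.
    # The Tukey envelope shifts with the trial's latency: a latency-of-processing
    # difference delays the whole evoked response, not just the carrier phase
    # (a fixed envelope would make latency ambiguous modulo the carrier period).
    offsets_t = np.where(
        animacy[:, None, None] == 1, stage_rel[stage_of_t].T[None, :, :], 0.0
    )  # (N, C, T)
    arg = (
        2 * np.pi * config.carrier_freq * (t[None, None, :] - shift[:, None, None])
        + offsets_t
    )
    win_shifted = np.stack([_tukey_window(t - s, *config.osc_window) for s in shift])
    oscillation = amp[:, None, None] * np.cos(arg) * win_shifted[:, None, :]

    trend_amp = config.trend_amplitude * (1.0 + config.trend_class_gain * animacy)
    trend = np.broadcast_to(
        trend_amp[:, None, None] * tr_shape[None, None, :], (n, c, t_n)
    ).copy()
    if config.additive_shift:
        add_win = win if config.additive_window is None else _tukey_window(
            t, *config.additive_window
        )
        pat = (np.ones(c) if config.additive_pattern is None
               else np.asarray(config.additive_pattern, dtype=float))
        if pat.shape != (c,):
            raise ValueError(f"additive_pattern must have length n_channels={c}")
        trend = trend + (
            (config.additive_shift * animacy)[:, None, None]
            * pat[None, :, None] * add_win[None, None, :]
        )

    noise = rng.normal(0.0, config.noise_sd, size=(n, c, t_n))
    if config.ar1_coef:
        # AR(1) along time, stationary variance kept at noise_sd**2
        a = config.ar1_coef
        noise *= np.sqrt(1 - a**2)
        for i in range(1, t_n):
            noise[:, :, i] += a * noise[:, :, i - 1]

    data = trend + oscillation + noise
    epochs = EpochSet(
        data=data,
        fs=config.fs,
        labels=labels,
        attributes={"animacy": animacy, "size": size},
    )
    gt = GroundTruth(
        trend=trend,
        oscillation=oscillation,
        noise=noise,
        latency_shift=shift,
        phase_offsets=phase_offsets,
        labels=labels,
        config=config,
    )
    return epochs, gt


def generate_cohort(
    config: SimConfig,
    n_subjects: int,
    seed: int | None = None,
    amplitude_spread: float = 0.0,
) -> list[tuple[EpochSet, GroundTruth]]:
    """Generate a cohort of subjects with deterministic per-subject seeds.

    ``amplitude_spread`` applies multiplicative log-normal jitter (sd of the
    underlying normal) to the effect amplitudes between subjects; 0 means
    every subject shares the configured amplitudes exactly.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    subject_seeds = [int(s) for s in ss.generate_state(n_subjects) % (2**31 - 1)]
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    cohort = []
    for s in range(n_subjects):
        cfg = replace(config, seed=subject_seeds[s])
        if amplitude_spread > 0:
            g = jitter_rng.lognormal(0.0, amplitude_spread, size=3)
            cfg = replace(
                cfg,
                global_shift=config.global_shift * g[0],
                relative_phase=np.asarray(config.relative_phase) * g[1],
                additive_shift=config.additive_shift * g[2],
            )
        cohort.append(generate_trials(cfg))
    return cohort


def generate_switching_trials(
    n_trials: int = 120,
    n_channels: int = 20,
    n_time: int = 100,
    n_states: int = 4,
    fs: float = 250.0,
    signal_scale: float = 1.0,
    noise_sd: float = 1.0,
    boundary_jitter: float = 0.08,
    seed: int = 0,
) -> tuple[EpochSet, dict]:
    """Piecewise-stationary decoder-sequence data for state-recovery tests.

    Each trial traverses ``n_states`` stages in order; stage k couples the
    label into the channels through a state-specific zero-sum pattern w_k,
    so x_t = y * w_k(t) * signal_scale + noise. Stage boundaries are jittered
    per trial (sd = ``boundary_jitter`` as a fraction of the trial) around
    their nominal positions k*T/K, mimicking trial-varying processing speed.

    Returns the epochs (labels ±1 stored as categories 0/1) and a ground
    truth dict with per-trial state boundaries and the true patterns.
    """
    rng = np.random.default_rng(seed)
    K, T, C, N = n_states, n_time, n_channels, n_trials
    # zero-sum, orthonormal state patterns
    w = rng.normal(size=(K, C))
    w -= w.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(w.T)  # (C, K) orthonormal
    w = q.T
    w -= w.mean(axis=1, keepdims=True)
    w /= np.linalg.norm(w, axis=1, keepdims=True)

    y = rng.choice([-1.0, 1.0], size=N)
    nominal = np.arange(1, K) * T / K
    jit = rng.normal(0.0, boundary_jitter * T, size=(N, K - 1))
    bounds = np.clip(np.sort(nominal[None, :] + jit, axis=1), 1, T - 1).astype(int)
    # enforce strictly increasing boundaries
    for i in range(N):
        for k in range(1, K - 1):
            bounds[i, k] = max(bounds[i, k], bounds[i, k - 1] + 1)

    state_seq = np.zeros((N, T), dtype=int)
    for i in range(N):
        edges = np.concatenate([[0], bounds[i], [T]])
        for k in range(K):
            state_seq[i, edges[k]:edges[k + 1]] = k

    data = rng.normal(0.0, noise_sd, size=(N, C, T))
    data += signal_scale * y[:, None, None] * np.transpose(w[state_seq], (0, 2, 1))

    epochs = EpochSet(
        data=data,
        fs=fs,
        labels=((y + 1) // 2).astype(int),
        attributes={"animacy": ((y + 1) // 2).astype(int)},
    )
    truth = {
        "patterns": w,
        "boundaries": bounds,  # (N, K-1) first sample of states 2..K
        "state_seq": state_seq,
        "y": y,
    }
    return epochs, truth


def config_to_dict(config: SimConfig) -> dict:
    """Serializable view of a SimConfig (arrays to lists)."""
    d = asdict(config)
    d["relative_phase"] = np.asarray(config.relative_phase).tolist()
    d["attribute_map"] = {str(k): v for k, v in config.attribute_map.items()}
    return d
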