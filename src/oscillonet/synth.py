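"""Synthetic multichannel LFP generator with ground truth.

Emulates the statistical structure of anesthetized amygdalo-hippocampal
recordings that the analysis stack assumes: a slow-wave-dominated baseline
(≈1 Hz), a drug state with sustained 2.5–5 Hz low theta plus delta and beta
components, phase–amplitude-coupled gamma, inter-channel shared band
components with fixed phase lags, and 1/f^α background noise.

Band components are narrow-band oscillators with Wiener (random-walk) phase
drift rather than pure tones: pure tones make phase-coupling estimators
degenerate, and mean-reverting drift would leave *independent* channels
spuriously phase-locked at a random offset.  With random-walk drift the
phase difference of two independent channels decorrelates within seconds,
while a shared component keeps its configured lag exactly.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .recording import CANONICAL_CHANNELS, EpochSchedule, Recording

#: Default oscillator center frequencies (Hz) per band component.
DEFAULT_BAND_FREQS = {
    "slow": 1.0, "delta": 2.0, "low_theta": 4.0, "high_theta": 7.0,
    "beta": 20.0, "low_gamma": 45.0, "mid_gamma": 75.0, "high_gamma": 105.0,
}

_BAND_ORDER = tuple(DEFAULT_BAND_FREQS)


@dataclass
class ChannelStateConfig:
    """Generative parameters for one channel in one protocol state.

    ``pac_kappa`` modulates the ``pac_amp_band`` oscillator's amplitude as
    ``1 + κ·cos(φ)`` against the ``pac_phase_band`` oscillator's phase —
    exactly the construction the modulation index detects.
    ``theta_occupancy`` gates the ``low_theta`` component with exponential
    on/off dwell times (mean on-run 2 s).
    """

    band_amps: dict = field(default_factory=dict)
    band_freqs: dict = field(default_factory=dict)
    theta_occupancy: float = 1.0
    pac_kappa: float = 0.0
    pac_phase_band: str = "slow"
    pac_amp_band: str = "mid_gamma"
    noise_alpha: float = 1.0
    noise_amp: float = 0.3
    phase_diffusion: float = 1.0   # rad²/s of the oscillators' Wiener drift
    mean_theta_on_s: float = 2.0

    def __post_init__(self):
        for b, a in self.band_amps.items():
            if a < 0:
                raise ValueError(f"negative amplitude for band {b!r}")
        if not 0.0 <= self.theta_occupancy <= 1.0:
            raise ValueError("theta_occupancy must lie in [0, 1]")
        if not 0.0 <= self.pac_kappa <= 1.0:
            raise ValueError("pac_kappa must lie in [0, 1]")

    def freq(self, band: str) -> float:
        return self.band_freqs.get(band, DEFAULT_BAND_FREQS[band])


@dataclass
class NetworkConfig:
    """Multichannel configuration: per-channel states plus coupling.

    ``shared_fraction[(a, b), band]`` is the fraction of that band's
    component power common to channels a and b; ``pair_lag_rad[(a, b)]`` is
    the phase of b minus the phase of a on shared components.
    """

    channels: dict = field(default_factory=dict)       # label -> ChannelStateConfig
    pair_lag_rad: dict = field(default_factory=dict)   # (a, b) -> lag
    shared_fraction: dict = field(default_factory=dict)  # ((a, b), band) -> frac
    seed: int = 0

    def __post_init__(self):
        labels = set(self.channels)
        for (a, b), lag in self.pair_lag_rad.items():
            if a not in labels or b not in labels:
                raise ValueError(f"pair ({a}, {b}) names an unknown channel")
            if not -np.pi < lag <= np.pi:
                raise ValueError("pair lags must lie in (-pi, pi]")
        for ((a, b), band), f in self.shared_fraction.items():
            if a not in labels or b not in labels:
                raise ValueError(f"pair ({a}, {b}) names an unknown channel")
            if not 0.0 <= f <= 1.0:
                raise ValueError("shared fractions must lie in [0, 1]")


@dataclass
class ProtocolPreset:
    """Per-epoch network configurations for one simulated cohort sex."""

    name: str
    epoch_configs: dict   # epoch name -> NetworkConfig

    def __post_init__(self):
        missing = [e for e, _, _ in _canonical_entries() if e not in self.epoch_configs]
        if missing:
            raise ValueError(f"preset lacks configs for epochs {missing}")


def _canonical_entries():
    return list(EpochSchedule.canonical())


# ---------------------------------------------------------------------------
# Primitive processes
# ---------------------------------------------------------------------------

def _wiener_phase(rng, f0, n, fs, diffusion):
    """Oscillator phase: 2π f0 t + random-walk drift + random start phase."""
    t = np.arange(n) / fs
    drift = np.cumsum(rng.standard_normal(n)) * np.sqrt(diffusion / fs)
    return 2 * np.pi * f0 * t + drift + rng.uniform(0, 2 * np.pi)


def _occupancy_gate(rng, n, fs, occupancy, mean_on_s=2.0, smooth_s=0.25):
    """0/1 gate from alternating exponential on/off runs, edge-smoothed."""
    if occupancy >= 1.0:
        return np.ones(n)
    if occupancy <= 0.0:
        return np.zeros(n)
    mean_off_s = mean_on_s * (1.0 - occupancy) / occupancy
    gate = np.zeros(n)
    pos = 0
    on = rng.uniform() < occupancy  # start state per stationary distribution
    while pos < n:
        dur = rng.exponential(mean_on_s if on else mean_off_s)
        length = max(1, int(round(dur * fs)))
        if on:
            gate[pos:pos + length] = 1.0
        pos += length
        on = not on
    win = np.hanning(max(3, int(smooth_s * fs)))
    return np.convolve(gate, win / win.sum(), mode="same")


def _one_over_f_noise(rng, n, fs, alpha, amp):
    """Gaussian noise with power spectrum ∝ 1/f^α, std scaled to ``amp``."""
    if amp == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (amp / sd) if sd > 0 else x


# ---------------------------------------------------------------------------
# Channel and network synthesis
# ---------------------------------------------------------------------------

def _synth_from_phases(cfg: ChannelStateConfig, phases, gate, noise):
    """Assemble one channel from per-band [(weight, phase)] components."""
    n = len(noise)
    sig = np.zeros(n)
    pac_phase = None
    if cfg.pac_phase_band in phases:
        pac_phase = phases[cfg.pac_phase_band][0][1]
    for band, comps in phases.items():
        amp = cfg.band_amps.get(band, 0.0)
        if amp == 0.0:
            continue
        comp = np.zeros(n)
        for w, ph in comps:
            if w > 0:
                comp += np.sqrt(w) * np.cos(ph)
        comp *= amp
        if band == "low_theta" and cfg.theta_occupancy < 1.0:
            comp *= gate
        if band == cfg.pac_amp_band and cfg.pac_kappa > 0 and pac_phase is not None:
            comp *= 1.0 + cfg.pac_kappa * np.cos(pac_phase)
        sig += comp
    return sig + noise


def generate_channel(cfg: ChannelStateConfig, duration_s, fs, seed) -> np.ndarray:
    """Single-channel synthesis (no inter-channel structure)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    _check_fs(cfg, fs)
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    phases = {}
    for band in _BAND_ORDER:
        # draw every band's oscillator so amplitudes don't alter the stream
        ph = _wiener_phase(rng, cfg.freq(band), n, fs, cfg.phase_diffusion)
        phases[band] = [(1.0, ph)]
    gate = _occupancy_gate(rng, n, fs, cfg.theta_occupancy, cfg.mean_theta_on_s)
    noise = _one_over_f_noise(rng, n, fs, cfg.noise_alpha, cfg.noise_amp)
    return _synth_from_phases(cfg, phases, gate, noise)


def _check_fs(cfg: ChannelStateConfig, fs):
    top = max((cfg.freq(b) for b, a in cfg.band_amps.items() if a > 0),
              default=0.0)
    if fs <= 2 * top:
        raise ValueError(f"fs={fs} too low for a {top} Hz band component")


def _channel_lags(labels, pair_lag_rad, members):
    """Per-channel phase offsets consistent with pairwise lags (lag of a
    pair (a, b) = offset_b − offset_a), resolved over a spanning tree."""
    offset = {}
    for root in members:
        if root in offset:
            continue
        offset[root] = 0.0
        stack = [root]
        while stack:
            u = stack.pop()
            for (a, b), lag in pair_lag_rad.items():
                for x, y, sgn in ((a, b, +1.0), (b, a, -1.0)):
                    if x == u and y in members and y not in offset:
                        offset[y] = offset[x] + sgn * lag
                        stack.append(y)
    return offset


def generate_network(cfg: NetworkConfig, duration_s, fs) -> Recording:
    """Multichannel synthesis with shared, lagged band components.

    For each band, channels connected by a nonzero shared fraction receive a
    common oscillator (applied with the per-channel lag offsets) mixed at
    weight ``shared_fraction`` with an independent oscillator.
    """
    labels = tuple(cfg.channels)
    n = int(round(duration_s * fs))
    ss = np.random.SeedSequence(cfg.seed)
    rng_shared = np.random.default_rng(ss.spawn(1)[0])
    chan_rngs = {lbl: np.random.default_rng(child)
                 for lbl, child in zip(labels, ss.spawn(len(labels)))}

    # shared oscillators per band (one per connected group, resolved lags)
    shared = {}
    for band in _BAND_ORDER:
        members = set()
        for ((a, b), bb), f in cfg.shared_fraction.items():
            if bb == band and f > 0:
                members.update((a, b))
        if not members:
            continue
        f0 = np.mean([cfg.channels[m].freq(band) for m in members])
        any_cfg = cfg.channels[next(iter(members))]
        ph = _wiener_phase(rng_shared, f0, n, fs, any_cfg.phase_diffusion)
        offsets = _channel_lags(labels, cfg.pair_lag_rad, members)
        shared[band] = (ph, offsets)

    def shared_frac(label, band):
        fr = [f for ((a, b), bb), f in cfg.shared_fraction.items()
              if bb == band and label in (a, b)]
        return max(fr) if fr else 0.0

    data = np.empty((len(labels), n))
    for i, lbl in enumerate(labels):
        ccfg = cfg.channels[lbl]
        _check_fs(ccfg, fs)
        rng = chan_rngs[lbl]
        phases = {}
        for band in _BAND_ORDER:
            ph_ind = _wiener_phase(rng, ccfg.freq(band), n, fs,
                                   ccfg.phase_diffusion)
            f = shared_frac(lbl, band)
            comps = [(1.0 - f, ph_ind)]
            if f > 0 and band in shared:
                ph_s, offsets = shared[band]
                comps.insert(0, (f, ph_s + offsets.get(lbl, 0.0)))
            phases[band] = comps
        gate = _occupancy_gate(rng, n, fs, ccfg.theta_occupancy,
                               ccfg.mean_theta_on_s)
        noise = _one_over_f_noise(rng, n, fs, ccfg.noise_alpha, ccfg.noise_amp)
        data[i] = _synth_from_phases(ccfg, phases, gate, noise)
    return Recording(data, fs=fs, channel_labels=labels)


def generate_protocol(preset: ProtocolPreset, fs, seed):
    """Simulate the full protocol (basal … post, 5400 s).

    Returns ``(Recording, EpochSchedule, ground_truth)`` where ground truth
    maps epoch → channel → the generative parameters, for recovery tests.
    Oscillator phases restart at epoch boundaries (states are analyzed
    within epochs, so continuity across them is not required).
    """
    schedule = EpochSchedule.canonical()
    chunks, truth = [], {}
    for k, (name, a, b) in enumerate(schedule):
        epoch_cfg = preset.epoch_configs[name]
        epoch_seed = int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2 ** 31))
        epoch_cfg = replace(epoch_cfg, seed=epoch_seed)
        rec = generate_network(epoch_cfg, b - a, fs)
        chunks.append(rec.data)
        truth[name] = {
            lbl: {
                "band_amps": dict(c.band_amps),
                "band_freqs": {bb: c.freq(bb) for bb in _BAND_ORDER},
                "theta_occupancy": c.theta_occupancy,
                "pac_kappa": c.pac_kappa,
                "pac_phase_band": c.pac_phase_band,
                "pac_amp_band": c.pac_amp_band,
            }
            for lbl, c in epoch_cfg.channels.items()
        }
    data = np.concatenate(chunks, axis=1)
    labels = tuple(preset.epoch_configs["basal"].channels)
    return Recording(data, fs=fs, channel_labels=labels), schedule, truth


# ---------------------------------------------------------------------------
# Protocol presets (male / female)
# ---------------------------------------------------------------------------
# The presets encode the *directions* of the study's findings, not fitted
# magnitudes: they are the test harness for the analysis stack.

_HIPPOCAMPAL_PAIRS = (("HPCd", "HPCi"), ("HPCd", "HPCv"), ("HPCi", "HPCv"))
_ALL_PAIRS = _HIPPOCAMPAL_PAIRS + (("HPCd", "BLA"), ("HPCi", "BLA"), ("HPCv", "BLA"))


def _basal_channel(sex: str, label: str) -> ChannelStateConfig:
    # theta bursts ride above the slow wave while on (they must clear the
    # 30% magnitude threshold to register as segments, as the study's
    # basal temporal ratios ≈ occupancy imply), but at 20% occupancy the
    # slow wave still carries the most total power.
    amps = {"slow": 1.0, "delta": 0.25, "low_theta": 1.6, "high_theta": 0.15,
            "beta": 0.12, "low_gamma": 0.07, "mid_gamma": 0.06, "high_gamma": 0.05}
    if sex == "female":  # markedly higher basal gamma in females, all regions
        for g in ("low_gamma", "mid_gamma", "high_gamma"):
            amps[g] *= 2.5
    return ChannelStateConfig(band_amps=amps, theta_occupancy=0.2,
                              pac_kappa=0.25, pac_phase_band="slow",
                              pac_amp_band="mid_gamma")


def _fg_channel(sex: str, label: str) -> ChannelStateConfig:
    base = _basal_channel(sex, label)
    amps = dict(base.band_amps)
    if sex == "male":
        # sustained low theta at ~3.3 Hz everywhere; delta+beta raised in
        # HPCi/HPCv/BLA; gamma raised in HPCv/BLA; slow suppressed
        amps.update(slow=0.25, low_theta=1.1)
        occ = 0.85
        if label != "HPCd":
            amps.update(delta=0.55, beta=0.30)
        if label in ("HPCv", "BLA"):
            amps["mid_gamma"] = base.band_amps["mid_gamma"] * 2.0
            amps["high_gamma"] = base.band_amps["high_gamma"] * 2.0
        if label == "HPCd":
            amps["high_theta"] = 0.35
        return replace(base, band_amps=amps, theta_occupancy=occ,
                       band_freqs={"low_theta": 3.3}, pac_kappa=0.5,
                       pac_phase_band="low_theta")
    # female: drug effect confined to the dorsal pole; the peak stays in
    # the slow band (≈1.3 Hz), unlike the male shift into low theta
    if label == "HPCd":
        amps.update(slow=0.9, low_theta=1.8)
        return replace(base, band_amps=amps, theta_occupancy=0.45,
                       band_freqs={"slow": 1.3})
    if label == "HPCi":
        amps.update(slow=0.9)
        return replace(base, band_amps=amps, band_freqs={"slow": 1.3})
    return base


def _blend_channel(fg: ChannelStateConfig, basal: ChannelStateConfig,
                   w: float, dbs_gamma: float = 1.0) -> ChannelStateConfig:
    """Linear interpolation from the drug state (w=1) back to basal (w=0)."""
    amps = {b: w * fg.band_amps.get(b, 0.0) + (1 - w) * basal.band_amps.get(b, 0.0)
            for b in set(fg.band_amps) | set(basal.band_amps)}
    for g in ("low_gamma", "mid_gamma", "high_gamma"):
        amps[g] = amps.get(g, 0.0) * dbs_gamma
    freqs = dict(basal.band_freqs)
    if w >= 0.5:
        freqs.update(fg.band_freqs)
    occ = w * fg.theta_occupancy + (1 - w) * basal.theta_occupancy
    kappa = w * fg.pac_kappa + (1 - w) * basal.pac_kappa
    return replace(basal, band_amps=amps, band_freqs=freqs,
                   theta_occupancy=occ, pac_kappa=kappa)


#: Phase potential per channel along the dorsoventral axis; pair lags are
#: potential differences, so the 6 pairwise constraints are realizable.
_PHASE_OFFSETS = {"HPCd": 0.0, "HPCi": 0.5, "HPCv": 1.0, "BLA": 1.5}


def _network(channels, shared=None, seed=0) -> NetworkConfig:
    shared = shared or {}
    lags = {(a, b): _PHASE_OFFSETS[b] - _PHASE_OFFSETS[a] for a, b in _ALL_PAIRS}
    return NetworkConfig(channels=channels, pair_lag_rad=lags,
                         shared_fraction=shared, seed=seed)


def protocol_preset(name: str) -> ProtocolPreset:
    """Build the male or female protocol preset."""
    if name not in ("male", "female"):
        raise ValueError("preset name must be 'male' or 'female'")
    sex = name
    basal_ch = {c: _basal_channel(sex, c) for c in CANONICAL_CHANNELS}
    fg_ch = {c: _fg_channel(sex, c) for c in CANONICAL_CHANNELS}

    basal_shared = {(p, "slow"): (0.6 if sex == "male" else 0.35) for p in _ALL_PAIRS}
    if sex == "female":  # higher basal low-theta coupling in females
        basal_shared.update({(p, "low_theta"): 0.5 for p in _HIPPOCAMPAL_PAIRS})

    if sex == "male":  # drug raises theta (and ventral delta/beta) coupling
        fg_shared = {(p, "low_theta"): 0.8 for p in _ALL_PAIRS}
        for p in (("HPCv", "BLA"), ("HPCi", "BLA"), ("HPCi", "HPCv")):
            fg_shared[(p, "delta")] = 0.7
            fg_shared[(p, "beta")] = 0.7
        fg_shared.update({(p, "slow"): 0.3 for p in _ALL_PAIRS})
    else:
        fg_shared = dict(basal_shared)

    cfgs = {
        "basal": _network(basal_ch, shared=basal_shared),
        "saline": _network(basal_ch, shared=basal_shared),
        "FG": _network(fg_ch, shared=fg_shared),
    }
    dbs_weights = {"DBS1": 0.8, "DBS2": 0.5, "DBS3": 0.25, "DBS4": 0.1, "DBS5": 0.0}
    for epoch, w in dbs_weights.items():
        gamma_boost = 2.0 if sex == "male" else 1.0  # DBS gamma rise, males only
        ch = {c: _blend_channel(fg_ch[c], basal_ch[c], w, dbs_gamma=gamma_boost)
              for c in CANONICAL_CHANNELS}
        sh = {k: w * fg_shared.get(k, 0.0) + (1 - w) * basal_shared.get(k, 0.0)
              for k in set(fg_shared) | set(basal_shared)}
        cfgs[epoch] = _network(ch, shared=sh)
    post_ch = {c: _blend_channel(fg_ch[c], basal_ch[c], 0.0,
                                 dbs_gamma=2.0 if sex == "male" else 1.0)
               for c in CANONICAL_CHANNELS}
    cfgs["post"] = _network(post_ch, shared=basal_shared)
    return ProtocolPreset(name=name, epoch_configs=cfgs)
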