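"""Phase–amplitude coupling via the modulation index, with surrogate
significance testing and comodulograms.

The modulation index (MI) bins the instantaneous phase of a slow band into
``n_bins`` equal bins, averages the fast band's envelope per bin,
normalizes the profile to sum 1, and measures its KL divergence from
uniform, scaled to [0, 1]:

    MI = (log N − H(P)) / log N.

Significance uses a surrogate null: the envelope is circularly time-shifted
by random offsets (≥ 1 s) ``n_perm`` times, and the observed MI counts as
significant when it exceeds the surrogate mean by more than two surrogate
standard deviations.  Circular shifts preserve the envelope's
autocorrelation; ``mode='shuffle'`` gives the cruder sample permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import band_analytic
from .spectral import BandDefinition


@dataclass
class PACResult:
    phase_band: str
    amp_band: str
    n_bins: int
    bin_profile: np.ndarray
    mi: float
    surrogate_mean: float | None = None
    surrogate_sd: float | None = None
    n_perm: int = 0
    significant: bool | None = None
    seed: int | None = None


def _phase_bins(phase, n_bins):
    """Bin index per sample for phase in (−π, π]."""
    idx = np.floor((np.asarray(phase) + np.pi) / (2 * np.pi) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _mi_from_counts(counts, sums):
    profile = sums / counts
    profile = profile / profile.sum()
    p = profile[profile > 0]
    h = -(p * np.log(p)).sum()
    n_bins = len(counts)
    return float((np.log(n_bins) - h) / np.log(n_bins)), profile


def modulation_index(phase, amplitude, n_bins: int = 18,
                     phase_band: str = "", amp_band: str = "") -> PACResult:
    """Tort modulation index of an (instantaneous phase, envelope) pair."""
    phase = np.asarray(phase, float)
    amplitude = np.asarray(amplitude, float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    idx = _phase_bins(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    if (counts == 0).any():
        raise ValueError("empty phase bin: series too short or phase degenerate")
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    if sums.sum() <= 0:
        raise ValueError("zero or negative total amplitude: "
                         "modulation index undefined")
    mi, profile = _mi_from_counts(counts, sums)
    return PACResult(phase_band, amp_band, n_bins, profile, mi)


def pac_surrogates(phase, amplitude, n_bins: int = 18, n_perm: int = 200,
                   seed: int | None = None, fs: float | None = None,
                   min_shift_s: float = 1.0, mode: str = "circular",
                   phase_band: str = "", amp_band: str = "") -> PACResult:
    """Modulation index with a surrogate null and a 2-SD significance rule."""
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    res = modulation_index(phase, amplitude, n_bins, phase_band, amp_band)
    rng = np.random.default_rng(seed)
    amplitude = np.asarray(amplitude, float)
    n = len(amplitude)
    idx = _phase_bins(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    min_shift = int(round((min_shift_s if fs else 0.0) * (fs or 0.0))) or 1
    if min_shift >= n // 2:
        raise ValueError("minimum surrogate shift too large for this series")
    surr = np.empty(n_perm)
    for k in range(n_perm):
        if mode == "circular":
            shift = int(rng.integers(min_shift, n - min_shift))
            amp_s = np.roll(amplitude, shift)
        elif mode == "shuffle":
            amp_s = rng.permutation(amplitude)
        else:
            raise ValueError("mode must be 'circular' or 'shuffle'")
        sums = np.bincount(idx, weights=amp_s, minlength=n_bins)
        surr[k], _ = _mi_from_counts(counts, sums)
    mu, sd = float(surr.mean()), float(surr.std(ddof=1))
    res.surrogate_mean, res.surrogate_sd = mu, sd
    res.n_perm = n_perm
    res.significant = bool(res.mi > mu + 2.0 * sd)
    res.seed = seed
    return res


#: Canonical phase→amplitude pairs: slow-wave phase to theta and gamma
#: amplitudes, delta phase to beta, low-theta phase to the gamma bands.
CANONICAL_PAC_PAIRS = (
    ("slow", "low_theta"),
    ("slow", "low_gamma"), ("slow", "mid_gamma"), ("slow", "high_gamma"),
    ("delta", "beta"),
    ("low_theta", "low_gamma"), ("low_theta", "mid_gamma"),
    ("low_theta", "high_gamma"),
)


def pac_for_bands(signal, fs, phase_band: BandDefinition,
                  amp_band: BandDefinition, n_bins: int = 18,
                  n_perm: int = 200, seed: int | None = None) -> PACResult:
    """Band-pass + Hilbert both bands, then surrogate-tested MI."""
    ph = band_analytic(signal, fs, phase_band)
    am = band_analytic(signal, fs, amp_band)
    return pac_surrogates(ph.phase, am.amplitude, n_bins=n_bins,
                          n_perm=n_perm, seed=seed, fs=fs,
                          phase_band=phase_band.name, amp_band=amp_band.name)


def comodulogram(signal, fs, phase_freqs, amp_freqs, n_bins: int = 18,
                 phase_width_hz: float = 2.0, amp_width_hz: float = 10.0):
    """MI matrix over a grid of (phase, amplitude) center frequencies.

    Phase bands are ``phase_width_hz`` wide, amplitude bands
    ``amp_width_hz`` wide, centered on the grid points.  Returns an array
    of shape (len(phase_freqs), len(amp_freqs)).
    """
    phase_freqs = np.asarray(phase_freqs, float)
    amp_freqs = np.asarray(amp_freqs, float)
    amps, phases = [], []
    for fa in amp_freqs:
        band = BandDefinition(f"amp_{fa:g}", max(fa - amp_width_hz / 2, 0.1),
                              fa + amp_width_hz / 2)
        amps.append(band_analytic(signal, fs, band).amplitude)
    for fp in phase_freqs:
        band = BandDefinition(f"ph_{fp:g}", max(fp - phase_width_hz / 2, 0.1),
                              fp + phase_width_hz / 2)
        phases.append(band_analytic(signal, fs, band).phase)
    out = np.empty((len(phase_freqs), len(amp_freqs)))
    for i, ph in enumerate(phases):
        for j, am in enumerate(amps):
            out[i, j] = modulation_index(ph, am, n_bins).mi
    return out
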