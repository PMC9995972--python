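"""Pairwise phase coupling (PLV, WPLI), wavelet coherograms and normalized
band-envelope mutual information.

PLV is the magnitude of the mean unit phasor of the inter-channel phase
difference in 10-s windows.  WPLI weights phase leads/lags by the imaginary
cross-spectrum magnitude, making it insensitive to zero-lag (volume
conducted) coupling.  Mutual information is computed between band
envelopes, quantile-binned with Miller–Madow bias correction and normalized
by the smaller marginal entropy so identical channels score exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .spectral import BandDefinition

log = logging.getLogger(__name__)


@dataclass
class AnalyticBandSignal:
    """Instantaneous phase and envelope of a band-passed signal."""

    band: BandDefinition
    phase: np.ndarray       # radians in (-pi, pi]
    amplitude: np.ndarray   # envelope >= 0
    fs: float


def band_analytic(signal, fs, band: BandDefinition, order: int = 4) -> AnalyticBandSignal:
    """Zero-phase Butterworth band-pass then Hilbert analytic signal."""
    if band.hi_hz >= fs / 2:
        raise ValueError(f"band {band.name!r} reaches Nyquist at fs={fs}")
    lo = max(band.lo_hz, 1e-3)
    wn = np.array([lo, band.hi_hz]) / (fs / 2)
    if wn[1] - wn[0] < 1e-4:
        raise ValueError(f"band {band.name!r} too narrow for a stable filter at fs={fs}")
    sos = _sig.butter(order, wn, btype="bandpass", output="sos")
    filtered = _sig.sosfiltfilt(sos, np.asarray(signal, float))
    analytic = _sig.hilbert(filtered)
    return AnalyticBandSignal(band=band, phase=np.angle(analytic),
                              amplitude=np.abs(analytic), fs=fs)


# ---------------------------------------------------------------------------
# Phase-locking value
# ---------------------------------------------------------------------------

def plv_windowed(a: AnalyticBandSignal, b: AnalyticBandSignal,
                 window_s: float = 10.0) -> np.ndarray:
    """|mean exp(i(φa − φb))| per non-overlapping window."""
    if len(a.phase) != len(b.phase):
        raise ValueError("signals must have equal length")
    n = int(round(window_s * a.fs))
    n_win = len(a.phase) // n
    if n_win == 0:
        raise ValueError("signal shorter than one PLV window")
    d = np.exp(1j * (a.phase - b.phase))[: n_win * n].reshape(n_win, n)
    return np.abs(d.mean(axis=1))


# ---------------------------------------------------------------------------
# Weighted phase lag index
# ---------------------------------------------------------------------------

def _cross_spectra(x, y, fs, seg_s=1.0, overlap=0.5):
    """Hamming-tapered segment cross-spectra (segments × freq bins)."""
    nper = int(round(seg_s * fs))
    step = max(1, int(round(nper * (1 - overlap))))
    win = np.hamming(nper)
    n_seg = 1 + (len(x) - nper) // step
    idx = np.arange(nper)[None, :] + step * np.arange(n_seg)[:, None]
    X = np.fft.rfft(x[idx] * win, axis=1)
    Y = np.fft.rfft(y[idx] * win, axis=1)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return freqs, X * np.conj(Y)


def wpli_windowed(x, y, fs, band: BandDefinition, window_s: float = 10.0,
                  seg_s: float = 1.0, debias: bool = False) -> np.ndarray:
    """WPLI per non-overlapping window from raw signals.

    Within each window, 1-s Hamming sub-segments (50% overlap) yield
    cross-spectra S; per frequency bin the WPLI is
    |mean Im S| / mean |Im S|, then averaged over the band's bins.
    Windows where every sub-segment has zero imaginary cross-spectrum in a
    bin are reported as NaN (logged).  ``debias=True`` uses the squared
    (Vinck) estimator instead.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("signals must have equal length")
    n = int(round(window_s * fs))
    n_win = len(x) // n
    if n_win == 0:
        raise ValueError("signal shorter than one WPLI window")
    out = np.empty(n_win)
    for w in range(n_win):
        sl = slice(w * n, (w + 1) * n)
        freqs, S = _cross_spectra(x[sl], y[sl], fs, seg_s)
        bins = (freqs >= band.lo_hz) & (freqs < band.hi_hz)
        if not bins.any():
            raise ValueError(f"band {band.name!r} has no bins at {seg_s}-s segments")
        im = S.imag[:, bins]
        denom = np.abs(im).mean(axis=0)
        if np.all(denom == 0):
            log.warning("WPLI undefined (zero imaginary cross-spectrum) in window %d", w)
            out[w] = np.nan
            continue
        ok = denom > 0
        if debias:
            num = (im.mean(axis=0) ** 2 - (im ** 2).mean(axis=0) / im.shape[0])
            den2 = (np.abs(im).mean(axis=0) ** 2)[ok]
            out[w] = float(np.mean(np.clip(num[ok] / den2, 0, 1)))
        else:
            out[w] = float(np.mean(np.abs(im.mean(axis=0))[ok] / denom[ok]))
    return out


def wpli_epoch(x, y, fs, band: BandDefinition, seg_s: float = 1.0) -> float:
    """Single WPLI estimate over a whole epoch (one window spanning it)."""
    v = wpli_windowed(x, y, fs, band, window_s=len(x) / fs, seg_s=seg_s)
    return float(v[0])


# ---------------------------------------------------------------------------
# Wavelet coherogram
# ---------------------------------------------------------------------------

def coherogram(x, y, fs, freqs=None, time_smooth_s: float = 1.0,
               scale_smooth: int = 3):
    """Magnitude-squared wavelet coherence, smoothed over ~1 s × 3 scales."""
    from .theta import _cwt_complex, default_freq_grid

    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, float)
    wx = _cwt_complex(x, fs, freqs)
    wy = _cwt_complex(y, fs, freqs)
    times = np.arange(len(np.asarray(x))) / fs

    def smooth(z):
        nt = max(1, int(round(time_smooth_s * fs)))
        kt = np.ones(nt) / nt
        z = np.apply_along_axis(lambda r: np.convolve(r, kt, mode="same"), 1, z)
        ks = np.ones(scale_smooth) / scale_smooth
        return np.apply_along_axis(lambda c: np.convolve(c, ks, mode="same"), 0, z)

    sxy = smooth(wx * np.conj(wy))
    sxx = smooth(np.abs(wx) ** 2)
    syy = smooth(np.abs(wy) ** 2)
    coh = np.abs(sxy) ** 2 / np.maximum(sxx * syy, 1e-300)
    return freqs, times, np.clip(coh.real, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Normalized mutual information between band envelopes
# ---------------------------------------------------------------------------

def band_mutual_information(a: AnalyticBandSignal, b: AnalyticBandSignal) -> float:
    """Normalized MI between the two band envelopes, in [0, 1].

    Equal-count (quantile) binning with ⌈N^{1/3}⌉ bins per axis, Miller–
    Madow bias correction, normalized by min(H(a), H(b)).  Quantile binning
    makes the estimate invariant under strictly monotone transforms of
    either envelope.
    """
    ea, eb = a.amplitude, b.amplitude
    if len(ea) != len(eb):
        raise ValueError("signals must have equal length")
    n = len(ea)
    if n < 1000:
        raise ValueError("need at least 1000 samples for a stable MI estimate")
    if np.ptp(ea) == 0 or np.ptp(eb) == 0:
        raise ValueError("constant envelope: zero entropy, MI undefined")
    k = int(np.ceil(n ** (1.0 / 3.0)))
    qa = _quantile_bins(ea, k)
    qb = _quantile_bins(eb, k)
    joint = np.zeros((k, k))
    np.add.at(joint, (qa, qb), 1.0)
    pj = joint / n
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)

    def ent(p):
        p = p[p > 0]
        return -(p * np.log(p)).sum(), p.size

    ha, ka = ent(pa)
    hb, kb = ent(pb)
    hab, kab = ent(pj.ravel())
    # Miller–Madow: H_hat + (m-1)/(2N) per entropy term
    mi = (ha + (ka - 1) / (2 * n)) + (hb + (kb - 1) / (2 * n)) \
        - (hab + (kab - 1) / (2 * n))
    denom = min(ha + (ka - 1) / (2 * n), hb + (kb - 1) / (2 * n))
    if denom <= 0:
        raise ValueError("degenerate envelope distribution")
    return float(np.clip(mi / denom, 0.0, 1.0))


def _quantile_bins(x, k):
    """Assign each sample to one of k (near) equal-count bins by rank."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(x))
    return np.minimum((ranks * k) // len(x), k - 1)
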