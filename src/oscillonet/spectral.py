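"""Welch spectral decomposition, band/relative power, peak frequency and
60-s band-power timecourses.

The estimator mirrors the legacy analysis settings: Hamming-tapered 5-s
segments with 50% overlap and ``nfft = 1024``.  Because a 5-s segment at
1 kHz holds more samples than 1024, segments are wrapped modulo ``nfft``
before the FFT (MATLAB ``datawrap`` semantics), giving a bin width of
``fs / 1024`` ≈ 0.977 Hz at 1 kHz.  A ``pad_to_window`` policy using plain
scipy Welch with ``nfft >= nperseg`` is available for new work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band, half-open interval ``[lo_hz, hi_hz)``."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ValueError(f"band {self.name!r}: require 0 <= lo < hi")


#: The eight analyzed bands.  12–16 Hz and 120–250 Hz are intentionally
#: uncovered; relative power is normalized by total power in 0–250 Hz.
CANONICAL_BANDS = (
    BandDefinition("slow", 0.0, 1.5),
    BandDefinition("delta", 1.5, 2.5),
    BandDefinition("low_theta", 2.5, 5.0),
    BandDefinition("high_theta", 5.0, 12.0),
    BandDefinition("beta", 16.0, 30.0),
    BandDefinition("low_gamma", 30.0, 60.0),
    BandDefinition("mid_gamma", 60.0, 90.0),
    BandDefinition("high_gamma", 90.0, 120.0),
)

BAND_MAP = {b.name: b for b in CANONICAL_BANDS}
TOTAL_BAND = BandDefinition("total", 0.0, 250.0)


@dataclass
class Spectrum:
    freqs_hz: np.ndarray
    psd: np.ndarray          # one-sided power density, units²/Hz
    window_s: float
    overlap: float
    nfft: int


def welch_psd(x, fs, window_s: float = 5.0, overlap: float = 0.5,
              nfft: int = 1024, nfft_policy: str = "wrap") -> Spectrum:
    """Welch PSD with Hamming taper and overlapping segments.

    ``nfft_policy='wrap'`` reproduces MATLAB ``pwelch`` when nfft is shorter
    than the segment: each tapered segment is wrapped (summed) modulo nfft
    before the FFT.  ``'pad_to_window'`` uses scipy with
    ``nfft = max(nfft, segment length)``.
    """
    x = np.asarray(x, dtype=float)
    nper = int(round(window_s * fs))
    if x.size < nper:
        raise ValueError("signal shorter than one Welch window")
    step = int(round(nper * (1.0 - overlap)))
    if nfft_policy == "pad_to_window":
        f, p = _sig.welch(x, fs=fs, window="hamming", nperseg=nper,
                          noverlap=nper - step, nfft=max(nfft, nper))
        return Spectrum(f, p, window_s, overlap, max(nfft, nper))
    if nfft_policy != "wrap":
        raise ValueError("nfft_policy must be 'wrap' or 'pad_to_window'")

    win = np.hamming(nper)
    u = (win ** 2).sum()  # window power normalization
    n_seg = 1 + (x.size - nper) // step
    nwrap = int(np.ceil(nper / nfft)) * nfft
    acc = np.zeros(nfft // 2 + 1)
    for k in range(n_seg):
        seg = x[k * step:k * step + nper] * win
        wrapped = np.pad(seg, (0, nwrap - nper)).reshape(-1, nfft).sum(axis=0)
        spec = np.fft.rfft(wrapped)
        acc += (spec.real ** 2 + spec.imag ** 2)
    psd = acc / (n_seg * fs * u)
    psd[1:-1] *= 2.0  # one-sided (DC and Nyquist not doubled)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return Spectrum(freqs, psd, window_s, overlap, nfft)


def band_power(spec: Spectrum, band: BandDefinition) -> float:
    """Integral of the PSD over bins with ``lo <= f < hi``.

    Rectangle rule (bin value × bin width): each PSD bin represents the
    power in its own bin-width slice, so disjoint bands add exactly and a
    band holding a single bin (delta at the legacy 0.977-Hz grid) is still
    well defined.
    """
    dbin = float(spec.freqs_hz[1] - spec.freqs_hz[0])
    hi = min(band.hi_hz, spec.freqs_hz[-1] + 1e-12)
    mask = (spec.freqs_hz >= band.lo_hz) & (spec.freqs_hz < hi)
    if not mask.any():
        raise ValueError(
            f"band {band.name!r} [{band.lo_hz}, {band.hi_hz}) contains no "
            f"PSD bins at bin width {dbin:.4g} Hz")
    return float(spec.psd[mask].sum() * dbin)


def relative_power(spec: Spectrum, band: BandDefinition) -> float:
    """Band power divided by total power in 0–250 Hz (or 0–Nyquist if the
    spectrum stops short of 250 Hz)."""
    hi = TOTAL_BAND.hi_hz
    if spec.freqs_hz[-1] < hi:
        _warn_short_spectrum(spec.freqs_hz[-1])
        hi = spec.freqs_hz[-1] + 1e-12
    total = band_power(spec, BandDefinition("total", 0.0, hi))
    if total <= 0:
        raise ValueError("zero total power: relative power undefined")
    return min(1.0, band_power(spec, band) / total)


_warned_short = set()


def _warn_short_spectrum(top_hz):
    """Warn once per Nyquist value, not once per window."""
    key = round(float(top_hz), 3)
    if key not in _warned_short:
        _warned_short.add(key)
        log.warning("spectrum ends at %.1f Hz < 250 Hz; normalizing "
                    "relative power by [0, fs/2)", top_hz)


def peak_frequency(spec: Spectrum, search_lo: float = 0.5,
                   search_hi: float = 12.0) -> float:
    """Frequency of the maximum PSD bin in ``[search_lo, search_hi)``.

    Ties are broken toward the lowest frequency.  The default search range
    covers the slow-wave-to-theta region where anesthetized LFP peaks live;
    widen it to scan gamma.
    """
    mask = (spec.freqs_hz >= search_lo) & (spec.freqs_hz < search_hi)
    if not mask.any():
        raise ValueError("empty peak search range on this frequency grid")
    f = spec.freqs_hz[mask]
    p = spec.psd[mask]
    return float(f[int(np.argmax(p))])  # argmax returns first (lowest-f) max


def band_timecourse(rec, window_s: float = 60.0, bands=CANONICAL_BANDS,
                    peak_lo: float = 0.5, peak_hi: float = 12.0,
                    **welch_kw) -> pd.DataFrame:
    """Per-channel band powers in consecutive non-overlapping windows.

    Returns a tidy frame with columns channel, window_index, window_start_s,
    band, abs_power, rel_power, peak_freq_hz (peak is window-level, repeated
    across band rows).  A trailing partial window is dropped.
    """
    nwin = int(round(window_s * rec.fs))
    n = rec.n_samples // nwin
    if n == 0:
        raise ValueError("recording shorter than one timecourse window")
    if rec.n_samples % nwin:
        log.info("dropping trailing partial window (%.1f s)",
                 (rec.n_samples % nwin) / rec.fs)
    rows = []
    for ci, label in enumerate(rec.channel_labels):
        for w in range(n):
            seg = rec.data[ci, w * nwin:(w + 1) * nwin]
            spec = welch_psd(seg, rec.fs, **welch_kw)
            pk = peak_frequency(spec, peak_lo, peak_hi)
            for band in bands:
                rows.append((label, w, rec.t0 + w * window_s, band.name,
                             band_power(spec, band), relative_power(spec, band), pk))
    return pd.DataFrame(rows, columns=["channel", "window_index", "window_start_s",
                                       "band", "abs_power", "rel_power",
                                       "peak_freq_hz"])


def epoch_summary(tc: pd.DataFrame, schedule, window_s: float = 60.0,
                  representative_s: float = 300.0) -> pd.DataFrame:
    """Per-epoch summary: mean over the representative 300-s span.

    For epochs longer than 300 s the span is the epoch's *final* 300 s
    (late-epoch windows carry the settled drug/stimulation effect).  Epoch
    boundaries must align with the timecourse window grid.
    """
    rows = []
    for name, a, b in schedule:
        if b - a < representative_s - 1e-9:
            raise ValueError(f"epoch {name!r} shorter than the representative span")
        lo = b - representative_s
        for t in (a, b, lo):
            if abs(t / window_s - round(t / window_s)) > 1e-9:
                raise ValueError(
                    f"epoch {name!r} boundary {t} s not aligned with the "
                    f"{window_s}-s window grid")
        sel = tc[(tc.window_start_s >= lo - 1e-9) & (tc.window_start_s < b - 1e-9)]
        if len(sel) == 0:
            raise ValueError(f"no timecourse windows inside epoch {name!r}")
        g = sel.groupby(["channel", "band"], sort=False).agg(
            abs_power=("abs_power", "mean"), rel_power=("rel_power", "mean"),
            peak_freq_hz=("peak_freq_hz", "mean")).reset_index()
        g.insert(0, "epoch", name)
        rows.append(g)
    return pd.concat(rows, ignore_index=True)
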