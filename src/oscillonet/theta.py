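"""Continuous wavelet transform and theta-segment detection.

A theta segment is a contiguous stretch where the 2.5–5 Hz band carries at
least 30% of the total time–frequency magnitude at each time point.  Per
60-s window we summarize the temporal ratio (fraction of the window inside
segments), the mean segment width (s) and the segment count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

#: Morlet center frequency ω0 = 6 → pywt complex Morlet with bandwidth 2,
#: center frequency 6/(2π).
_MORLET_OMEGA0 = 6.0
_WAVELET = f"cmor2.0-{_MORLET_OMEGA0 / (2 * np.pi):.6f}"

THETA_LO, THETA_HI = 2.5, 5.0


@dataclass
class TFR:
    """Magnitude scalogram with a cone-of-influence mask."""

    freqs_hz: np.ndarray
    times_s: np.ndarray
    magnitude: np.ndarray       # freq x time, >= 0
    coi_mask: np.ndarray        # freq x time, True where edge-contaminated
    omega0: float = _MORLET_OMEGA0


@dataclass
class ThetaSegment:
    start_s: float
    end_s: float

    @property
    def width_s(self):
        return self.end_s - self.start_s


def default_freq_grid(lo=0.5, hi=120.0, n=48):
    """Log-spaced frequency grid covering the analyzed range."""
    return np.geomspace(lo, hi, n)


def _cwt_complex(signal, fs, freqs):
    """Complex Morlet CWT coefficients (freq × time), amplitude-faithful.

    Coefficients are divided by √scale so a unit-amplitude sinusoid yields
    the same magnitude at every analyzed frequency; without this, low
    frequencies would dominate any cross-frequency magnitude ratio.
    """
    fc = pywt.central_frequency(_WAVELET)
    scales = fc * fs / np.asarray(freqs, float)
    coefs, _ = pywt.cwt(np.asarray(signal, float), scales, _WAVELET,
                        sampling_period=1.0 / fs, method="fft")
    return coefs / np.sqrt(scales)[:, None]


def cwt_tfr(signal, fs, freqs=None) -> TFR:
    """Morlet (ω0 = 6) magnitude scalogram.

    The cone of influence marks samples within one wavelet e-folding time
    (√2·ω0 / (2π f) seconds) of either edge.
    """
    signal = np.asarray(signal, dtype=float)
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    duration = signal.size / fs
    if freqs.min() < 2.0 / duration:
        raise ValueError("lowest frequency unresolvable at this duration")
    if freqs.max() >= fs / 2:
        raise ValueError("frequency grid reaches Nyquist")
    mag = np.abs(_cwt_complex(signal, fs, freqs))
    times = np.arange(signal.size) / fs
    efold = np.sqrt(2) * _MORLET_OMEGA0 / (2 * np.pi * freqs)  # seconds
    coi = (times[None, :] < efold[:, None]) | \
          (times[None, :] > duration - efold[:, None])
    return TFR(freqs, times, mag, coi)


def detect_theta_segments(tfr: TFR, threshold: float = 0.30,
                          min_width_s: float = 0.5):
    """Mark time points where theta magnitude ≥ ``threshold`` of the total.

    ratio(t) = Σ magnitude over [2.5, 5) Hz / Σ magnitude over the full
    grid; contiguous runs of marked points at least ``min_width_s`` long
    become :class:`ThetaSegment` s.  Cone-of-influence cells are excluded
    from numerator and denominator; time points with no valid cells are
    never marked.
    """
    theta_rows = (tfr.freqs_hz >= THETA_LO) & (tfr.freqs_hz < THETA_HI)
    if not theta_rows.any():
        raise ValueError("frequency grid does not cover the theta band")
    valid = ~tfr.coi_mask
    mag = tfr.magnitude * valid
    denom = mag.sum(axis=0)
    num = mag[theta_rows].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    marked = ratio >= threshold
    return _runs_to_segments(marked, tfr.times_s, min_width_s)


def _runs_to_segments(marked, times, min_width_s):
    dt = times[1] - times[0] if times.size > 1 else 0.0
    segments = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], marked.view(np.int8), [0]))))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        start, end = times[i0], times[i1 - 1] + dt
        if end - start >= min_width_s:
            segments.append(ThetaSegment(start, end))
    return segments


def theta_summary(segments, total_duration_s, window_s: float = 60.0):
    """Per-window temporal ratio, mean width (s) and segment count.

    Segments are clipped at window boundaries; a straddling segment counts
    once in each window it touches, with the clipped width.  Windows with no
    segments report ratio 0, width 0, count 0.
    """
    n_windows = int(np.ceil(total_duration_s / window_s - 1e-9))
    rows = []
    for w in range(n_windows):
        lo, hi = w * window_s, min((w + 1) * window_s, total_duration_s)
        widths = []
        for seg in segments:
            if seg.end_s <= lo or seg.start_s >= hi:
                continue
            widths.append(min(seg.end_s, hi) - max(seg.start_s, lo))
        total = float(np.sum(widths)) if widths else 0.0
        rows.append({
            "window_index": w,
            "temporal_ratio": total / (hi - lo),
            "mean_width_s": total / len(widths) if widths else 0.0,
            "n_segments": len(widths),
        })
    return rows


def theta_temporal_ratio(signal, fs, freqs=None, threshold=0.30,
                         min_width_s=0.5) -> float:
    """Convenience: overall fraction of a signal inside theta segments."""
    tfr = cwt_tfr(signal, fs, freqs)
    segs = detect_theta_segments(tfr, threshold, min_width_s)
    return float(sum(s.width_s for s in segs) * fs / len(signal))
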