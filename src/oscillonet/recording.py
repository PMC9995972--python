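"""Recording data model, CSV/EDF I/O, epoch schedules and preprocessing.

A :class:`Recording` is a channels × samples array with a sampling rate.
Epoch schedules name half-open time intervals ``[start_s, end_s)`` tied to
the experimental protocol (baseline, saline, anxiogenic drug, five DBS
periods, post-stimulation).  Sample indices are 0-based; slicing an epoch
takes samples ``[start_s * fs, end_s * fs)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CANONICAL_CHANNELS = ("HPCd", "HPCi", "HPCv", "BLA")

#: Canonical protocol epochs and durations (seconds).  The one-hour
#: stimulation block is split into five equal 720-s periods DBS1..DBS5.
CANONICAL_EPOCH_DURATIONS = (
    ("basal", 300.0),
    ("saline", 300.0),
    ("FG", 900.0),
    ("DBS1", 720.0),
    ("DBS2", 720.0),
    ("DBS3", 720.0),
    ("DBS4", 720.0),
    ("DBS5", 720.0),
    ("post", 300.0),
)


@dataclass
class Recording:
    """Multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values in arbitrary voltage units.
    fs : float
        Sampling rate in Hz, > 0.
    channel_labels : tuple of str
        Unique, ordered channel names.
    t0 : float
        Time (s) of the first sample.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None
        return self.data[i]


@dataclass
class EpochSchedule:
    """Ordered, non-overlapping named intervals ``[start_s, end_s)``."""

    entries: list = field(default_factory=list)  # list of (name, start_s, end_s)

    def __post_init__(self):
        self.entries = [(str(n), float(a), float(b)) for n, a, b in self.entries]
        names = [n for n, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("epoch names must be unique")
        prev_end = -np.inf
        for name, a, b in self.entries:
            if b <= a:
                raise ValueError(f"epoch {name!r}: end must exceed start")
            if a < prev_end:
                raise ValueError(f"epoch {name!r} overlaps the previous epoch")
            prev_end = b

    def __iter__(self):
        return iter(self.entries)

    def names(self):
        return [n for n, _, _ in self.entries]

    def interval(self, name: str):
        for n, a, b in self.entries:
            if n == name:
                return a, b
        raise KeyError(f"unknown epoch {name!r}")

    @classmethod
    def canonical(cls, start_s: float = 0.0) -> "EpochSchedule":
        """The full protocol schedule: basal through post, 5400 s total."""
        entries, t = [], float(start_s)
        for name, dur in CANONICAL_EPOCH_DURATIONS:
            entries.append((name, t, t + dur))
            t += dur
        return cls(entries)


@dataclass
class PreprocSpec:
    """Software mirror of the acquisition chain's analog filtering."""

    bandpass_lo_hz: float = 0.3
    bandpass_hi_hz: float = 300.0
    notch_hz: float | None = None
    filter_order: int = 4

    def validate(self, fs: float):
        if not (0 <= self.bandpass_lo_hz < self.bandpass_hi_hz):
            raise ValueError("require 0 <= lo < hi")
        if self.bandpass_hi_hz >= fs / 2:
            raise ValueError("band edge at or above Nyquist")


# ---------------------------------------------------------------------------
# CSV / EDF I/O
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path) -> None:
    """Write a recording as CSV (one column per channel) plus a JSON sidecar
    carrying the sampling rate and time origin."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    # %.17g + round_trip parsing in load_recording gives bit-exact values
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"fs": rec.fs, "t0": rec.t0}))


def load_recording(path, fs: float | None = None, format_hint: str | None = None) -> Recording:
    """Load a CSV or EDF recording.

    CSV: header row of channel labels, one column per channel; ``fs`` from
    the argument or a ``<path>.json`` sidecar.  A column named ``time`` (s)
    is used to infer ``fs`` and ``t0`` instead.  EDF: standard continuous
    signals (values returned in the file's physical units, assumed µV).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return _load_edf(path)
    if fmt != "csv":
        raise ValueError(f"unknown recording format {fmt!r}")

    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError("recording contains NaN/ragged rows")
    t0 = 0.0
    if "time" in df.columns:
        t = df.pop("time").to_numpy()
        if len(t) < 2:
            raise ValueError("time column too short to infer fs")
        fs = 1.0 / float(np.median(np.diff(t)))
        t0 = float(t[0])
    if fs is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fs = float(meta["fs"])
            t0 = float(meta.get("t0", t0))
    if fs is None:
        raise ValueError("sampling rate not given and no sidecar found")
    return Recording(df.to_numpy().T, fs=fs, channel_labels=tuple(df.columns), t0=t0)


def _load_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()  # volts for voltage channel types
    # mne rescales µV-dimensioned channels to V; report back in µV, the
    # conventional unit for LFP work and the unit our writer declares.
    return Recording(data * 1e6, fs=float(raw.info["sfreq"]),
                     channel_labels=tuple(raw.ch_names), t0=0.0)


def save_recording_edf(rec: Recording, path) -> None:
    """Write a 16-bit EDF file (one data record per second).

    The recording must be a whole number of seconds at an integer sampling
    rate; values are declared in µV and quantized to the per-channel
    physical range.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    if rec.n_samples % fs != 0:
        raise ValueError("EDF export requires a whole number of seconds")
    n_rec = rec.n_samples // fs
    ns = rec.n_channels

    phys_min = np.minimum(rec.data.min(axis=1), -1e-6)
    phys_max = np.maximum(rec.data.max(axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767

    def pad(s, n):
        b = str(s)[:n]
        return b + " " * (n - len(b))

    header = (
        pad("0", 8) + pad("X", 80) + pad("X", 80)
        + pad("01.01.00", 8) + pad("00.00.00", 8)
        + pad(256 * (1 + ns), 8) + pad("", 44)
        + pad(n_rec, 8) + pad("1", 8) + pad(ns, 4)
    )
    header += "".join(pad(lbl, 16) for lbl in rec.channel_labels)
    header += "".join(pad("", 80) for _ in range(ns))
    header += "".join(pad("uV", 8) for _ in range(ns))
    header += "".join(pad(f"{phys_min[i]:.6g}"[:8], 8) for i in range(ns))
    header += "".join(pad(f"{phys_max[i]:.6g}"[:8], 8) for i in range(ns))
    header += "".join(pad(dig_min, 8) for _ in range(ns))
    header += "".join(pad(dig_max, 8) for _ in range(ns))
    header += "".join(pad("", 80) for _ in range(ns))
    header += "".join(pad(fs, 8) for _ in range(ns))
    header += "".join(pad("", 32) for _ in range(ns))

    # re-read the truncated physical bounds we actually wrote, so the
    # digital->physical map used by readers matches ours exactly
    pmin = np.array([float(f"{phys_min[i]:.6g}"[:8]) for i in range(ns)])
    pmax = np.array([float(f"{phys_max[i]:.6g}"[:8]) for i in range(ns)])
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.round((rec.data - pmin[:, None]) / gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        for r in range(n_rec):
            for c in range(ns):
                fh.write(digital[c, r * fs:(r + 1) * fs].tobytes())


# ---------------------------------------------------------------------------
# Epoch schedules on disk
# ---------------------------------------------------------------------------

def save_schedule(schedule: EpochSchedule, path) -> None:
    entries = [{"name": n, "start_s": a, "end_s": b} for n, a, b in schedule]
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))


def load_schedule(path) -> EpochSchedule:
    entries = yaml.safe_load(Path(path).read_text())
    return EpochSchedule([(e["name"], e["start_s"], e["end_s"]) for e in entries])


# ---------------------------------------------------------------------------
# Slicing and preprocessing
# ---------------------------------------------------------------------------

def slice_epoch(rec: Recording, schedule: EpochSchedule, name: str) -> Recording:
    """Extract the named epoch as a new Recording (half-open interval)."""
    start_s, end_s = schedule.interval(name)
    i0 = int(round((start_s - rec.t0) * rec.fs))
    i1 = int(round((end_s - rec.t0) * rec.fs))
    if i0 < 0 or i1 > rec.n_samples:
        raise ValueError(f"epoch {name!r} [{start_s}, {end_s}) outside recording")
    return replace(rec, data=rec.data[:, i0:i1], t0=start_s)


def preprocess(rec: Recording, spec: PreprocSpec | None = None) -> Recording:
    """Zero-phase band-pass (and optional notch) per channel.

    Forward–backward (``sosfiltfilt``) filtering so phase metrics downstream
    see no group delay.  Output length equals input length.
    """
    from scipy import signal

    spec = spec or PreprocSpec()
    spec.validate(rec.fs)
    out = rec.data
    if spec.bandpass_lo_hz > 0:
        sos = signal.butter(spec.filter_order, [spec.bandpass_lo_hz, spec.bandpass_hi_hz],
                            btype="bandpass", fs=rec.fs, output="sos")
    else:
        sos = signal.butter(spec.filter_order, spec.bandpass_hi_hz,
                            btype="lowpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, out, axis=1)
    if spec.notch_hz is not None:
        b, a = signal.iirnotch(spec.notch_hz, Q=30.0, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return replace(rec, data=out)
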