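"""Independent brute-force oracles for the core estimators.

Deliberately naive implementations (explicit loops, closed-form counting)
kept separate from the package so estimator tests compare two routes to
the same definition.
"""

import itertools

import numpy as np


def welch_oracle(x, fs, window_s=5.0, overlap=0.5, nfft=1024):
    """Welch PSD by explicit segment loop with modular wrapping."""
    x = np.asarray(x, float)
    nper = int(round(window_s * fs))
    step = int(round(nper * (1 - overlap)))
    win = np.hamming(nper)
    u = float(np.sum(win * win))
    n_seg = 1 + (len(x) - nper) // step
    acc = np.zeros(nfft // 2 + 1)
    for s in range(n_seg):
        seg = x[s * step:s * step + nper] * win
        wrapped = np.zeros(nfft)
        for j in range(nper):
            wrapped[j % nfft] += seg[j]
        spec = np.fft.fft(wrapped)[: nfft // 2 + 1]
        acc += np.abs(spec) ** 2
    psd = acc / (n_seg * fs * u)
    psd[1:-1] *= 2.0
    return np.fft.rfftfreq(nfft, 1.0 / fs), psd


def wpli_oracle(x, y, fs, lo_hz, hi_hz, seg_s=1.0, overlap=0.5):
    """WPLI from raw FFT cross-spectra, one value for the whole signal."""
    nper = int(round(seg_s * fs))
    step = int(round(nper * (1 - overlap)))
    win = np.hamming(nper)
    crosses = []
    s = 0
    while s + nper <= len(x):
        X = np.fft.rfft(x[s:s + nper] * win)
        Y = np.fft.rfft(y[s:s + nper] * win)
        crosses.append(X * np.conj(Y))
        s += step
    crosses = np.array(crosses)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    vals = []
    for b in range(len(freqs)):
        if not (lo_hz <= freqs[b] < hi_hz):
            continue
        im = crosses[:, b].imag
        den = np.mean(np.abs(im))
        if den > 0:
            vals.append(abs(np.mean(im)) / den)
    return float(np.mean(vals))


def modulation_index_oracle(phase, amplitude, n_bins=18):
    """Tort MI by per-sample list accumulation."""
    bins = [[] for _ in range(n_bins)]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    for p, a in zip(phase, amplitude):
        j = int(np.searchsorted(edges, p, side="left")) - 1
        j = min(max(j, 0), n_bins - 1)
        bins[j].append(a)
    means = np.array([np.mean(b) for b in bins])
    prof = means / means.sum()
    h = -sum(p * np.log(p) for p in prof if p > 0)
    return (np.log(n_bins) - h) / np.log(n_bins)


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def friedman_oracle(table):
    """Friedman chi-square from the defining rank-sum formula (tie-free)."""
    table = np.asarray(table, float)
    n, k = table.shape
    rsum = np.zeros(k)
    for row in table:
        r = _midranks(list(row))
        rsum += r
    return 12.0 / (n * k * (k + 1)) * float(np.sum(rsum ** 2)) - 3.0 * n * (k + 1)


def kruskal_oracle(groups):
    """Kruskal–Wallis H from pooled mid-ranks (tie-free closed form)."""
    pooled = [v for g in groups for v in g]
    ranks = _midranks(pooled)
    big_n = len(pooled)
    h = 0.0
    i = 0
    for g in groups:
        rj = sum(ranks[i:i + len(g)])
        h += rj ** 2 / len(g)
        i += len(g)
    return 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)


def mannwhitney_exact_oracle(g1, g2):
    """Exact two-sided Mann–Whitney p by full enumeration (no ties)."""
    g1, g2 = list(g1), list(g2)
    pooled = g1 + g2
    n1 = len(g1)

    def u_of(sel):
        a = [pooled[i] for i in sel]
        b = [pooled[i] for i in range(len(pooled)) if i not in set(sel)]
        u = sum(1 for x in a for y in b if x > y) \
            + 0.5 * sum(1 for x in a for y in b if x == y)
        return u

    u_obs = sum(1 for x in g1 for y in g2 if x > y) \
        + 0.5 * sum(1 for x in g1 for y in g2 if x == y)
    n1n2 = n1 * len(g2)
    d_obs = abs(u_obs - n1n2 / 2.0)
    total = extreme = 0
    for sel in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(sel) - n1n2 / 2.0) >= d_obs - 1e-12:
            extreme += 1
    return u_obs, extreme / total
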