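"""PLV, WPLI, wavelet coherence and normalized envelope MI."""

import numpy as np
import pytest

from oracles import wpli_oracle
from oscillonet import connectivity as conn
from oscillonet import spectral as sp
from oscillonet import synth

FS = 250.0
LT = sp.BAND_MAP["low_theta"]


def tone(f0, dur, fs=FS, phase=0.0):
    return np.sin(2 * np.pi * f0 * np.arange(0, dur, 1 / fs) + phase)


def make_abs(phase, amplitude, fs=FS, band=LT):
    return conn.AnalyticBandSignal(band=band, phase=np.asarray(phase),
                                   amplitude=np.asarray(amplitude), fs=fs)


class TestBandAnalytic:
    def test_sinusoid_envelope_and_phase_rate(self):
        a = conn.band_analytic(tone(4.0, 60), FS, LT)
        core = slice(int(5 * FS), int(-5 * FS))
        assert np.allclose(a.amplitude[core], 1.0, atol=0.02)
        rate = np.diff(np.unwrap(a.phase[core])).mean() * FS / (2 * np.pi)
        assert rate == pytest.approx(4.0, rel=0.01)

    def test_am_envelope_recovered(self):
        t = np.arange(0, 60, 1 / FS)
        modulator = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
        x = modulator * tone(4.0, 60)
        a = conn.band_analytic(x, FS, LT)
        core = slice(int(5 * FS), int(-5 * FS))
        r = np.corrcoef(a.amplitude[core], modulator[core])[0, 1]
        assert r > 0.99

    def test_zero_signal_zero_envelope(self):
        a = conn.band_analytic(np.zeros(int(30 * FS)), FS, LT)
        assert np.allclose(a.amplitude, 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            conn.band_analytic(tone(4, 10), 100.0, sp.BAND_MAP["mid_gamma"])


class TestPLV:
    def test_constant_lag_gives_one(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(-np.pi, np.pi, int(30 * FS)).cumsum() % (2 * np.pi)
        a = make_abs(ph, np.ones_like(ph))
        b = make_abs(ph + 0.7, np.ones_like(ph))
        assert np.allclose(conn.plv_windowed(a, b), 1.0)

    def test_identical_signals_give_one(self):
        x = tone(4.0, 30)
        a = conn.band_analytic(x, FS, LT)
        assert np.allclose(conn.plv_windowed(a, a), 1.0)

    def test_independent_phases_floor(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 10_000
            a = make_abs(rng.uniform(-np.pi, np.pi, n), np.ones(n), fs=1000.0)
            b = make_abs(rng.uniform(-np.pi, np.pi, n), np.ones(n), fs=1000.0)
            means.append(conn.plv_windowed(a, b).mean())
        assert np.mean(means) < 0.05

    def test_length_mismatch_rejected(self):
        a = make_abs(np.zeros(1000), np.ones(1000))
        b = make_abs(np.zeros(999), np.ones(999))
        with pytest.raises(ValueError):
            conn.plv_windowed(a, b)


class TestWPLI:
    def test_matches_brute_force_oracle_small_instances(self):
        fs = 64.0
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.standard_normal(512)
            y = np.roll(x, 3) + 0.5 * rng.standard_normal(512)
            ours = conn.wpli_windowed(x, y, fs, LT, window_s=512 / fs)[0]
            ref = wpli_oracle(x, y, fs, LT.lo_hz, LT.hi_hz)
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_quadrature_lagged_pair_high(self):
        rng = np.random.default_rng(1)
        n = int(300 * FS)
        base = tone(4.0, 300)
        x = base + 0.1 * rng.standard_normal(n)
        y = tone(4.0, 300, phase=np.pi / 2) + 0.1 * rng.standard_normal(n)
        assert conn.wpli_epoch(x, y, FS, LT) > 0.9

    def test_zero_lag_common_signal_suppressed(self):
        rng = np.random.default_rng(2)
        n = int(300 * FS)
        base = tone(4.0, 300)
        x = base + 0.3 * rng.standard_normal(n)
        y = base + 0.3 * rng.standard_normal(n)
        assert conn.wpli_epoch(x, y, FS, LT) < 0.2
        ax, ay = (conn.band_analytic(s, FS, LT) for s in (x, y))
        assert conn.plv_windowed(ax, ay).mean() > 0.8

    def test_independent_noise_floor(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(int(100 * FS))
            y = rng.standard_normal(int(100 * FS))
            vals.append(conn.wpli_epoch(x, y, FS, LT))
        assert np.median(vals) < 0.2

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(60 * FS))
        y = np.roll(x, 5) + rng.standard_normal(int(60 * FS))
        v1 = conn.wpli_windowed(x, y, FS, LT)
        v2 = conn.wpli_windowed(3.7 * x, 0.2 * y, FS, LT)
        assert np.allclose(v1, v2, rtol=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(60 * FS))
        y = np.roll(x, 5) + rng.standard_normal(int(60 * FS))
        assert np.allclose(conn.wpli_windowed(x, y, FS, LT),
                           conn.wpli_windowed(y, x, FS, LT))


class TestCoherogram:
    def test_identical_signals_full_coherence(self):
        x = tone(4.0, 60) + 0.1 * np.random.default_rng(0).standard_normal(int(60 * FS))
        freqs, _, coh = conn.coherogram(x, x, FS)
        assert np.median(coh) > 0.99

    def test_independent_noise_low_coherence(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(60 * FS))
        y = rng.standard_normal(int(60 * FS))
        _, _, coh = conn.coherogram(x, y, FS)
        assert np.median(coh) < 0.3

    def test_shared_tone_coherence_confined_to_band(self):
        rng = np.random.default_rng(2)
        n = int(60 * FS)
        base = tone(4.0, 60)
        x = base + 0.5 * rng.standard_normal(n)
        y = np.roll(base, 10) + 0.5 * rng.standard_normal(n)
        freqs, _, coh = conn.coherogram(x, y, FS)
        near = (freqs > 3) & (freqs < 5.5)
        far = (freqs > 20) & (freqs < 100)
        assert np.median(coh[near]) > 2 * np.median(coh[far])


class TestEnvelopeMI:
    def _analytic_pair(self, n, rho=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ea = np.abs(rng.standard_normal(n)) + 0.1
        eb = np.abs(rho * (ea - ea.mean()) + np.sqrt(max(1 - rho ** 2, 0)) *
                    rng.standard_normal(n)) + 0.1
        return make_abs(np.zeros(n), ea), make_abs(np.zeros(n), eb)

    def test_identical_envelopes_give_one(self):
        a, _ = self._analytic_pair(50_000)
        assert conn.band_mutual_information(a, a) == pytest.approx(1.0)

    def test_independent_envelopes_near_zero(self):
        vals = []
        for seed in range(20):
            a, b = self._analytic_pair(100_000, rho=0.0, seed=seed)
            vals.append(conn.band_mutual_information(a, b))
        assert np.mean(vals) < 0.05

    def test_monotone_transform_invariance(self):
        a, _ = self._analytic_pair(50_000, seed=3)
        b = make_abs(a.phase, np.exp(2.0 * a.amplitude))
        nmi = conn.band_mutual_information(a, b)
        assert nmi > 0.95

    def test_symmetry(self):
        a, b = self._analytic_pair(50_000, rho=0.6, seed=5)
        assert conn.band_mutual_information(a, b) == \
            pytest.approx(conn.band_mutual_information(b, a), abs=1e-12)

    def test_constant_envelope_rejected(self):
        n = 5000
        a = make_abs(np.zeros(n), np.ones(n))
        b = make_abs(np.zeros(n), np.abs(np.random.default_rng(0).standard_normal(n)))
        with pytest.raises(ValueError, match="constant"):
            conn.band_mutual_information(a, b)

    def test_short_series_rejected(self):
        a, b = self._analytic_pair(500)
        with pytest.raises(ValueError, match="1000"):
            conn.band_mutual_information(a, b)


class TestGeneratorCoupling:
    """Network generator meets its documented coupling contracts."""

    def _pair(self, frac, lag, seed=7, dur=300):
        ch = {c: synth.ChannelStateConfig(band_amps={"low_theta": 1.0},
                                          theta_occupancy=1.0)
              for c in ("A", "B")}
        cfg = synth.NetworkConfig(channels=ch, pair_lag_rad={("A", "B"): lag},
                                  shared_fraction={(("A", "B"), "low_theta"): frac},
                                  seed=seed)
        return synth.generate_network(cfg, dur, FS)

    def test_fully_shared_quadrature_pair_high_wpli(self):
        rec = self._pair(1.0, np.pi / 2)
        assert conn.wpli_epoch(rec.data[0], rec.data[1], FS, LT) > 0.95

    def test_independent_channels_low_wpli(self):
        vals = [conn.wpli_epoch(r.data[0], r.data[1], FS, LT)
                for r in (self._pair(0.0, np.pi / 2, seed=s) for s in range(20))]
        assert np.median(vals) < 0.2

    def test_zero_lag_shared_wpli_low_but_plv_high(self):
        rec = self._pair(1.0, 0.0)
        x, y = rec.data
        assert conn.wpli_epoch(x, y, FS, LT) < 0.2
        ax, ay = (conn.band_analytic(s, FS, LT) for s in (x, y))
        assert conn.plv_windowed(ax, ay).mean() > 0.8
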