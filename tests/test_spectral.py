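"""Welch estimator (wrap semantics), band powers and timecourses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import welch_oracle
from oscillonet import recording as rio
from oscillonet import spectral as sp

FS = 1000.0


def tone(f0, dur, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * f0 * np.arange(0, dur, 1 / fs))


class TestWelch:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4096) + tone(7.0, 4096 / 500, fs=500)
        spec = sp.welch_psd(x, 500, window_s=2.0, nfft=512)
        f_o, p_o = welch_oracle(x, 500, window_s=2.0, nfft=512)
        assert np.allclose(spec.freqs_hz, f_o)
        assert np.allclose(spec.psd, p_o, rtol=1e-9, atol=1e-15)

    def test_sinusoid_peak_bin(self):
        spec = sp.welch_psd(tone(4.0, 300), FS)
        f_peak = spec.freqs_hz[np.argmax(spec.psd)]
        assert abs(f_peak - 4.0) <= FS / 1024  # one bin at the wrap grid

    def test_parseval_white_noise(self):
        errs = []
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(60_000)
            spec = sp.welch_psd(x, FS)
            dbin = spec.freqs_hz[1] - spec.freqs_hz[0]
            errs.append(spec.psd.sum() * dbin / x.var())
        assert np.allclose(errs, 1.0, rtol=0.05)

    def test_zero_signal_zero_psd(self):
        spec = sp.welch_psd(np.zeros(10_000), FS)
        assert not spec.psd.any()

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sp.welch_psd(np.zeros(100), FS)

    def test_pad_policy_uses_finer_grid(self):
        spec = sp.welch_psd(tone(4.0, 60), FS, nfft_policy="pad_to_window")
        assert spec.freqs_hz[1] - spec.freqs_hz[0] < FS / 1024


class TestBandPower:
    def test_sinusoid_concentrated_in_band(self):
        spec = sp.welch_psd(tone(4.0, 300), FS)
        total = sp.band_power(spec, sp.BandDefinition("all", 0, 500))
        assert sp.band_power(spec, sp.BAND_MAP["low_theta"]) / total > 0.95

    def test_band_additivity_exact(self):
        rng = np.random.default_rng(5)
        spec = sp.welch_psd(rng.standard_normal(30_000), FS)
        gap = sp.BandDefinition("gap", 12.0, 16.0)
        parts = sum(sp.band_power(spec, b)
                    for b in (*sp.CANONICAL_BANDS, gap))
        whole = sp.band_power(spec, sp.BandDefinition("lowfull", 0.0, 120.0))
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_empty_band_error_names_band(self):
        spec = sp.welch_psd(np.ones(10_000), FS)
        tiny = sp.BandDefinition("sliver", 3.05, 3.10)
        with pytest.raises(ValueError, match="sliver"):
            sp.band_power(spec, tiny)


class TestRelativePower:
    def test_full_range_band_is_one(self):
        rng = np.random.default_rng(0)
        spec = sp.welch_psd(rng.standard_normal(20_000), FS)
        assert sp.relative_power(spec, sp.TOTAL_BAND) == pytest.approx(1.0)

    def test_single_tone_dominates(self):
        spec = sp.welch_psd(tone(4.0, 300) + 1e-3 *
                            np.random.default_rng(1).standard_normal(300_000), FS)
        assert sp.relative_power(spec, sp.BAND_MAP["low_theta"]) > 0.95

    def test_equal_tones_split_evenly(self):
        # bin-centered tones (k*fs/nfft): the wrap grid samples the DTFT at
        # 0.977-Hz steps, so off-grid tones are scalloped by design
        f_theta, f_beta = 4 * FS / 1024, 20 * FS / 1024
        spec = sp.welch_psd(tone(f_theta, 300) + tone(f_beta, 300), FS)
        assert sp.relative_power(spec, sp.BAND_MAP["low_theta"]) == \
            pytest.approx(0.5, abs=0.03)
        assert sp.relative_power(spec, sp.BAND_MAP["beta"]) == \
            pytest.approx(0.5, abs=0.03)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, c):
        x = tone(4.0, 30) + 0.3 * np.random.default_rng(2).standard_normal(30_000)
        s1 = sp.welch_psd(x, FS)
        s2 = sp.welch_psd(c * x, FS)
        for band in ("slow", "low_theta", "beta"):
            r1 = sp.relative_power(s1, sp.BAND_MAP[band])
            r2 = sp.relative_power(s2, sp.BAND_MAP[band])
            assert r2 == pytest.approx(r1, rel=1e-9)
        p1 = sp.band_power(s1, sp.BAND_MAP["low_theta"])
        p2 = sp.band_power(s2, sp.BAND_MAP["low_theta"])
        assert p2 == pytest.approx(c * c * p1, rel=1e-9)

    def test_zero_signal_relative_power_error(self):
        spec = sp.welch_psd(np.zeros(20_000), FS)
        with pytest.raises(ValueError, match="zero total"):
            sp.relative_power(spec, sp.BAND_MAP["slow"])


class TestPeakFrequency:
    def test_finds_dominant_low_frequency(self):
        spec = sp.welch_psd(tone(1.0, 300) + 0.2 * tone(4.0, 300), FS)
        assert abs(sp.peak_frequency(spec) - 1.0) <= FS / 1024

    def test_tie_breaks_to_lowest_frequency(self):
        freqs = np.linspace(0, 125, 513)
        spec = sp.Spectrum(freqs, np.ones_like(freqs), 5.0, 0.5, 1024)
        assert sp.peak_frequency(spec, 0.5, 12.0) == freqs[freqs >= 0.5][0]

    def test_empty_search_range_rejected(self):
        spec = sp.welch_psd(np.ones(10_000), FS)
        with pytest.raises(ValueError):
            sp.peak_frequency(spec, 3.00, 3.01)


class TestTimecourse:
    def test_window_count_and_columns(self):
        rec = rio.Recording(tone(4.0, 300, fs=250)[None, :], 250.0, ("HPCd",))
        tc = sp.band_timecourse(rec)
        assert tc.window_index.nunique() == 5
        assert set(tc.band) == {b.name for b in sp.CANONICAL_BANDS}

    def test_recording_shorter_than_window_rejected(self):
        rec = rio.Recording(np.zeros((1, 59 * 250)), 250.0, ("a",))
        with pytest.raises(ValueError, match="shorter"):
            sp.band_timecourse(rec)

    def test_stationary_signal_low_window_variance(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = tone(4.0, 300, fs=250) + 0.5 * rng.standard_normal(75_000)
            rec = rio.Recording(x[None, :], 250.0, ("a",))
            tc = sp.band_timecourse(rec)
            rel = tc[tc.band == "low_theta"].rel_power
            assert rel.std() / rel.mean() < 0.10

    def test_epoch_summary_means_windows(self):
        rec = rio.Recording(tone(4.0, 600, fs=250)[None, :], 250.0, ("a",))
        tc = sp.band_timecourse(rec)
        sched = rio.EpochSchedule([("one", 0, 300), ("two", 300, 600)])
        summ = sp.epoch_summary(tc, sched)
        one = summ[(summ.epoch == "one") & (summ.band == "low_theta")]
        w0 = tc[(tc.band == "low_theta") & (tc.window_index == 0)]
        assert one.rel_power.iloc[0] == pytest.approx(
            float(w0.rel_power.iloc[0]), rel=1e-6)

    def test_epoch_summary_uses_final_span_of_long_epochs(self):
        # 4 Hz in the first 300 s, 1 Hz in the final 300 s of one epoch
        x = np.concatenate([tone(4.0, 300, fs=250), tone(1.0, 300, fs=250)])
        rec = rio.Recording(x[None, :], 250.0, ("a",))
        tc = sp.band_timecourse(rec)
        sched = rio.EpochSchedule([("long", 0, 600)])
        summ = sp.epoch_summary(tc, sched)
        slow = summ[(summ.epoch == "long") & (summ.band == "slow")]
        assert slow.rel_power.iloc[0] > 0.9

    def test_misaligned_schedule_rejected(self):
        rec = rio.Recording(np.zeros((1, 330 * 250)) + tone(4, 330, 250), 250.0,
                            ("a",))
        tc = sp.band_timecourse(rec)
        with pytest.raises(ValueError, match="aligned"):
            sp.epoch_summary(tc, rio.EpochSchedule([("off", 30, 330)]))

    def test_short_epoch_rejected(self):
        rec = rio.Recording(tone(4, 300, 250)[None, :], 250.0, ("a",))
        tc = sp.band_timecourse(rec)
        with pytest.raises(ValueError, match="shorter"):
            sp.epoch_summary(tc, rio.EpochSchedule([("tiny", 0, 120)]))
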