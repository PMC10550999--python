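"""Ping band-pass, rms-fast RL, SEL and cumulative-dose behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahdtag import acoustics
from ahdtag.acoustics import (
    PingDetection,
    bandpass_ahd,
    cumulate_sel,
    detect_pings,
    measure_rl_rms_fast,
    measure_snr,
    ping_sel,
)
from ahdtag.tag_io import TimeSeries, ValidationError


def _tone(freq, fs, duration, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _band_gain_db(freq, fs=300_000.0):
    ts = TimeSeries(_tone(freq, fs, 0.5), fs)
    out = bandpass_ahd(ts)
    mid = out.data[len(out.data) // 4 : -len(out.data) // 4]
    ref = ts.data[len(ts.data) // 4 : -len(ts.data) // 4]
    return 20 * np.log10(np.sqrt(np.mean(mid**2)) / np.sqrt(np.mean(ref**2)))


class TestBandpass:
    def test_fundamental_preserved(self):
        assert abs(_band_gain_db(14_000.0)) < 1.0

    def test_low_frequency_rejected(self):
        assert _band_gain_db(5_000.0) < -30.0

    def test_click_band_rejected(self):
        assert _band_gain_db(130_000.0) < -40.0

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError):
            bandpass_ahd(TimeSeries(np.zeros(1000), 48_000.0))


class TestRmsFast:
    def test_unit_tone_level(self):
        """1 Pa amplitude tone: rms = 1/sqrt(2) Pa = 116.99 dB re 1 uPa."""
        fs = 120_000.0
        data = np.zeros(int(fs))
        data[int(0.2 * fs) : int(0.8 * fs)] = _tone(14_000.0, fs, 0.6)
        rl = measure_rl_rms_fast(TimeSeries(data, fs), 0.2)
        assert rl == pytest.approx(116.99, abs=0.02)

    def test_window_outside_recording_raises(self):
        with pytest.raises(ValueError):
            measure_rl_rms_fast(TimeSeries(np.zeros(100), 120_000.0), 0.0)

    def test_rectangular_ping_sel_equals_rl_plus_duration_term(self):
        """For a rectangular in-band ping: SEL = RL + 10 log10(d) +/- 0.2."""
        fs = 120_000.0
        data = np.zeros(int(fs))
        data[int(0.2 * fs) : int(0.7 * fs)] = _tone(14_000.0, fs, 0.5)
        ts = TimeSeries(data, fs)
        rl = measure_rl_rms_fast(ts, 0.2)
        sel = ping_sel(ts, 0.2)
        assert sel == pytest.approx(rl + 10 * np.log10(0.5), abs=0.2)


class TestSnr:
    def test_constructed_snr(self):
        fs = 120_000.0
        rng = np.random.default_rng(0)
        data = rng.normal(0, 0.001, int(fs))
        data[int(0.3 * fs) : int(0.9 * fs)] += _tone(
            14_000.0, fs, 0.6, amp=0.001 * np.sqrt(2) * 10
        )
        snr = measure_snr(TimeSeries(data, fs), 0.3)
        assert snr == pytest.approx(20.0, abs=1.0)

    def test_ping_equal_to_noise_near_zero(self):
        fs = 120_000.0
        rng = np.random.default_rng(1)
        data = rng.normal(0, 0.001, int(fs))
        snr = measure_snr(TimeSeries(data, fs), 0.5)
        assert abs(snr) < 2.0

    def test_insufficient_preroll_raises(self):
        fs = 120_000.0
        with pytest.raises(ValueError):
            measure_snr(TimeSeries(np.zeros(int(fs)), fs), 0.05)


class TestPingSel:
    def test_tone_closed_form(self):
        """500-ms tone at 116.99 dB rms -> SEL 113.98 dB re 1 uPa^2 s."""
        fs = 120_000.0
        data = np.zeros(int(fs))
        data[: int(0.5 * fs)] = _tone(14_000.0, fs, 0.5)
        assert ping_sel(TimeSeries(data, fs), 0.0) == pytest.approx(113.98, abs=0.02)


class TestDetectPings:
    def _noise(self, fs, duration, seed=0, sigma=2e-3):
        return np.random.default_rng(seed).normal(0, sigma, int(duration * fs))

    def test_no_pings_empty(self):
        fs = 120_000.0
        ts = TimeSeries(self._noise(fs, 5.0), fs)
        assert detect_pings(ts) == []

    def test_minimum_interval_resolved(self):
        """Two pings 0.6 s apart (the minimum source interval) separate."""
        from ahdtag.synthetic import _ping_waveform
        from ahdtag.scenarios import ping_recovery_config

        cfg = ping_recovery_config(0)
        fs = cfg.fs_audio
        data = self._noise(fs, 5.0)
        wave = _ping_waveform(cfg, 110.0, fs)
        for t0 in (2.0, 2.6):
            i = int(t0 * fs)
            data[i : i + len(wave)] += wave
        onsets = detect_pings(TimeSeries(data, fs))
        assert len(onsets) == 2
        assert onsets[0] == pytest.approx(2.0, abs=0.01)
        assert onsets[1] == pytest.approx(2.6, abs=0.01)


class TestRecovery:
    def test_all_pings_recovered_within_1db(self, ping_recovery):
        """Detected count matches truth; RL within 1 dB for SNR > 10 dB."""
        _, truth, pings = ping_recovery
        assert len(pings) == len(truth.ping_times)
        det_t = np.array([p.time for p in pings])
        for t_true, rl_true in zip(truth.ping_times, truth.ping_rls):
            j = int(np.argmin(np.abs(det_t - t_true)))
            assert abs(det_t[j] - t_true) < 0.005
            if pings[j].snr > 10.0:
                assert abs(pings[j].rl_rms_fast - rl_true) <= 1.0

    def test_accepted_iff_snr_above_10(self, ping_recovery):
        _, _, pings = ping_recovery
        for p in pings:
            assert p.accepted == (p.snr > 10.0)


def _ping(time, sel, accepted=True):
    return PingDetection(time, sel + 3.01, sel, 30.0, accepted)


class TestCumulativeSel:
    def test_ten_identical_pings_add_10db(self):
        pings = [_ping(float(i), 113.98) for i in range(10)]
        dose = cumulate_sel(pings)
        assert dose.selcum_series[-1] == pytest.approx(123.98, abs=0.01)

    def test_single_ping_at_threshold_flags_risk(self):
        dose = cumulate_sel([_ping(0.0, 142.0)], margin=0.0)
        assert dose.tts_exceeded and dose.tts_risk

    def test_within_margin_flags_risk_but_not_exceedance(self):
        dose = cumulate_sel([_ping(0.0, 140.0)], margin=3.0)
        assert dose.tts_risk and not dose.tts_exceeded

    def test_unordered_pings_rejected(self):
        with pytest.raises(ValidationError):
            cumulate_sel([_ping(2.0, 120.0), _ping(1.0, 120.0)])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=90.0, max_value=150.0), min_size=1, max_size=30)
    )
    def test_series_non_decreasing_and_permutation_invariant(self, sels):
        pings = [_ping(float(i), s) for i, s in enumerate(sels)]
        dose = cumulate_sel(pings)
        assert np.all(np.diff(dose.selcum_series) >= 0)
        perm = [_ping(float(i), s) for i, s in enumerate(sorted(sels, reverse=True))]
        dose_perm = cumulate_sel(perm)
        assert dose.selcum_series[-1] == pytest.approx(
            dose_perm.selcum_series[-1], abs=1e-9
        )
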