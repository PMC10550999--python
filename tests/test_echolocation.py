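"""Click detection, apparent levels, buzz classification, feeding resumption."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahdtag.echolocation import (
    BuzzEvent,
    ClickDetection,
    SamplingRateError,
    click_apparent_level,
    click_rate,
    detect_buzzes,
    detect_clicks,
    feeding_resumption,
    highpass_clicks,
    level_percentile,
)
from ahdtag.synthetic import ClickConfig, _click_waveform
from ahdtag.tag_io import TimeSeries

FS = 300_000.0


def _tone(freq, duration, amp=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestHighpass:
    def test_click_pip_preserved(self):
        pip = _click_waveform(ClickConfig(), 150.0, FS)
        data = np.zeros(int(0.1 * FS))
        data[2000 : 2000 + len(pip)] = pip
        out = highpass_clicks(TimeSeries(data, FS))
        assert np.max(np.abs(out.data)) == pytest.approx(np.max(np.abs(pip)), rel=0.12)

    def test_ahd_tone_rejected(self):
        ts = TimeSeries(_tone(14_000.0, 0.2), FS)
        out = highpass_clicks(ts)
        atten = 20 * np.log10(
            np.sqrt(np.mean(out.data**2)) / np.sqrt(np.mean(ts.data**2))
        )
        assert atten < -40.0

    def test_mid_frequency_tag_raises_with_buzz_hint(self):
        with pytest.raises(SamplingRateError, match="buzz"):
            highpass_clicks(TimeSeries(np.zeros(1000), 240_000.0))


class TestDetectClicks:
    def _audio_with_clicks(self, times, level=150.0, seed=0):
        rng = np.random.default_rng(seed)
        dur = max(times) + 0.05
        data = rng.normal(0, 0.02, int(dur * FS))
        pip = _click_waveform(ClickConfig(), level, FS)
        for t in times:
            i = int(t * FS)
            data[i : i + len(pip)] += pip
        return highpass_clicks(TimeSeries(data, FS))

    def test_click_train_fully_recovered(self):
        times = 0.05 + np.arange(100) * 0.021
        clicks = detect_clicks(self._audio_with_clicks(times))
        assert len(clicks) == 100

    def test_silence_empty(self):
        rng = np.random.default_rng(1)
        hp = highpass_clicks(TimeSeries(rng.normal(0, 0.02, int(0.5 * FS)), FS))
        assert detect_clicks(hp) == []

    def test_buzz_clicks_resolved_individually(self):
        times = 0.05 + np.arange(20) * 0.010  # 10-ms ICI buzz
        clicks = detect_clicks(self._audio_with_clicks(times))
        assert len(clicks) == 20

    def test_programmed_level_recovered(self):
        clicks = detect_clicks(self._audio_with_clicks([0.05], level=150.0))
        assert len(clicks) == 1
        assert clicks[0].apparent_level_pp == pytest.approx(150.0, abs=0.5)


class TestApparentLevel:
    def test_symmetric_extremes(self):
        """+1/-1 Pa extremes: 20 log10(2e6) = 126.02 dB pp."""
        data = np.zeros(int(0.05 * FS))
        data[6000] = 1.0
        data[6010] = -1.0
        level = click_apparent_level(TimeSeries(data, FS), 6005 / FS)
        assert level == pytest.approx(126.02, abs=0.01)

    def test_positive_impulse_on_zero_baseline(self):
        data = np.zeros(int(0.05 * FS))
        data[6000] = 1.0
        level = click_apparent_level(TimeSeries(data, FS), 6000 / FS)
        assert level == pytest.approx(120.0, abs=0.01)

    def test_segment_outside_recording_raises(self):
        with pytest.raises(ValueError):
            click_apparent_level(TimeSeries(np.zeros(100), FS), 0.0)


class TestRatesAndPercentiles:
    def test_click_rate_examples(self):
        clicks = [ClickDetection(t, 150.0) for t in np.linspace(0, 899, 300)]
        assert click_rate(clicks, (0.0, 900.0)) == pytest.approx(20.0)
        assert click_rate([], (0.0, 900.0)) == 0.0

    def test_constant_levels(self):
        clicks = [ClickDetection(float(i), 150.0) for i in range(10)]
        assert level_percentile(clicks, (0.0, 10.0)) == 150.0

    def test_uniform_levels_interpolated(self):
        clicks = [ClickDetection(float(i), 100.0 + i) for i in range(100)]
        assert level_percentile(clicks, (0.0, 100.0), 95.0) == pytest.approx(194.05)

    def test_empty_window_undefined(self):
        clicks = [ClickDetection(1.0, 150.0)]
        assert level_percentile(clicks, (5.0, 10.0)) is None

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=100.0, max_value=190.0), min_size=2, max_size=50),
        st.floats(min_value=5.0, max_value=50.0),
    )
    def test_percentile_monotone_in_q(self, levels, dq):
        clicks = [ClickDetection(float(i), lv) for i, lv in enumerate(levels)]
        w = (0.0, float(len(levels)))
        assert level_percentile(clicks, w, 45.0 + dq) >= level_percentile(clicks, w, 45.0 - 1e-9)


def _jerk_with_transient(t_spike=None, duration=10.0, fs=25.0):
    rng = np.random.default_rng(0)
    data = np.abs(rng.normal(2.0, 0.3, int(duration * fs)))
    if t_spike is not None:
        data[int(t_spike * fs)] = 50.0
    return TimeSeries(data, fs)


class TestBuzzes:
    def _clicks(self, ici, n=20, t0=4.0):
        return [ClickDetection(t0 + i * ici, 140.0) for i in range(n)]

    def test_fast_run_with_jerk_is_one_buzz(self):
        buzzes = detect_buzzes(self._clicks(0.010), _jerk_with_transient(4.1))
        assert len(buzzes) == 1
        assert buzzes[0].n_clicks == 20

    def test_fast_run_without_jerk_rejected_as_social(self):
        buzzes = detect_buzzes(self._clicks(0.010), _jerk_with_transient(None))
        assert buzzes == []

    def test_slow_run_not_a_buzz(self):
        buzzes = detect_buzzes(self._clicks(0.020), _jerk_with_transient(4.1))
        assert buzzes == []

    def test_buzz_icis_all_below_bound(self):
        clicks = self._clicks(0.010) + [ClickDetection(4.5, 140.0)]
        buzzes = detect_buzzes(sorted(clicks, key=lambda c: c.time),
                               _jerk_with_transient(4.1))
        for b in buzzes:
            members = [c.time for c in clicks if b.start <= c.time <= b.end]
            assert np.all(np.diff(members) < 0.015)


class TestFeedingResumption:
    def _buzzes(self, starts):
        return [BuzzEvent(s, s + 0.5, 10, 30.0) for s in starts]

    def test_fifth_buzz_marks_resumption(self):
        t0 = 100.0
        buzzes = self._buzzes([t0 + 60 * k for k in (1, 2, 3, 4, 5, 6)])
        assert feeding_resumption(buzzes, t0) == t0 + 300.0

    def test_fewer_than_five_is_none(self):
        assert feeding_resumption(self._buzzes([1, 2, 3, 4]), 0.0) is None

    def test_buzz_exactly_at_t0_excluded(self):
        buzzes = self._buzzes([0.0, 1, 2, 3, 4])
        assert feeding_resumption(buzzes, 0.0) is None
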