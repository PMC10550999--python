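"""Deployment I/O, calibration and decimation."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.io import wavfile

from ahdtag import tag_io
from ahdtag.synthetic import generate_deployment
from ahdtag.tag_io import (
    FormatError,
    TimeSeries,
    ValidationError,
    db_to_pa,
    decimate_series,
    pa_to_db,
    read_deployment,
    read_events,
    write_deployment,
    write_events,
)


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=60.0, max_value=175.0))
def test_pa_db_conversion_self_inverse(level):
    assert pa_to_db(db_to_pa(level)) == pytest.approx(level, abs=1e-9)


def test_full_scale_wav_maps_to_clip_level_pressure(tmp_path):
    """A full-scale sample must decode to the clip-level pressure (175 dB
    re 1 uPa -> 10**(175/20) uPa = 562.34 Pa)."""
    fs = 4000
    wav = tmp_path / "square.wav"
    wavfile.write(wav, fs, np.tile(np.array([1.0, -1.0], dtype=np.float32), fs))
    (tmp_path / "calib.json").write_text(
        json.dumps({"clip_level_db": 175.0, "rates": {"accel": 50, "depth": 50}})
    )
    t = np.arange(0, 2.0, 1 / 50)
    pd.DataFrame(
        {"time": t, "ax": 0.0, "ay": 0.0, "az": 9.81, "depth": 1.0}
    ).to_csv(tmp_path / "sensors.csv", index=False)
    dep = read_deployment(
        str(wav), str(tmp_path / "sensors.csv"), str(tmp_path / "calib.json")
    )
    assert np.max(np.abs(dep.audio.data)) == pytest.approx(562.34, rel=1e-3)
    assert dep.duration == pytest.approx(2.0)
    assert dep.gps == []


def test_missing_sensor_column_names_the_column(tmp_path):
    (tmp_path / "calib.json").write_text(
        json.dumps({"clip_level_db": 175.0, "rates": {"accel": 50, "depth": 50}})
    )
    wavfile.write(tmp_path / "a.wav", 1000, np.zeros(1000, dtype=np.float32))
    pd.DataFrame({"time": [0.0], "ax": [0.0], "ay": [0.0], "az": [9.8]}).to_csv(
        tmp_path / "sensors.csv", index=False
    )
    with pytest.raises(FormatError, match="depth"):
        read_deployment(
            str(tmp_path / "a.wav"),
            str(tmp_path / "sensors.csv"),
            str(tmp_path / "calib.json"),
        )


def test_nonpositive_rate_rejected(tmp_path):
    (tmp_path / "calib.json").write_text(
        json.dumps({"clip_level_db": 175.0, "rates": {"accel": 0, "depth": 50}})
    )
    wavfile.write(tmp_path / "a.wav", 1000, np.zeros(100, dtype=np.float32))
    pd.DataFrame(
        {"time": [0.0], "ax": [0.0], "ay": [0.0], "az": [9.8], "depth": [0.1]}
    ).to_csv(tmp_path / "sensors.csv", index=False)
    with pytest.raises(ValidationError):
        read_deployment(
            str(tmp_path / "a.wav"),
            str(tmp_path / "sensors.csv"),
            str(tmp_path / "calib.json"),
        )


def test_synthetic_deployment_round_trip(tmp_path, small_scenario_config):
    """Write-then-read of a generated deployment preserves every stream."""
    dep, _ = generate_deployment(small_scenario_config)
    paths = write_deployment(dep, str(tmp_path / "dep"))
    back = read_deployment(
        paths["audio"], paths["sensors"], paths["calib"], paths.get("gps")
    )
    np.testing.assert_allclose(back.audio.data, dep.audio.data, rtol=1e-6)
    np.testing.assert_array_equal(back.accel.data, dep.accel.data)
    np.testing.assert_array_equal(back.depth.data, dep.depth.data)
    np.testing.assert_array_equal(back.ecg.data, dep.ecg.data)
    assert len(back.gps) == len(dep.gps)
    for a, b in zip(back.gps, dep.gps):
        assert (a.time, a.lat, a.lon) == (b.time, b.lat, b.lon)
    assert back.exposure.exposure_start == dep.exposure.exposure_start


class TestDecimation:
    def test_constant_series_preserved(self):
        ts = TimeSeries(np.full(2000, 3.7), 200.0)
        out = decimate_series(ts, 25.0)
        assert out.fs == 25.0
        np.testing.assert_allclose(out.data, 3.7, rtol=1e-6)

    def test_in_band_sinusoid_amplitude_within_1pct(self):
        t = np.arange(0, 30, 1 / 200)
        ts = TimeSeries(np.sin(2 * np.pi * 1.0 * t), 200.0)
        out = decimate_series(ts, 25.0)
        mid = out.data[len(out.data) // 4 : -len(out.data) // 4]
        assert np.sqrt(np.mean(mid**2)) == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_aliasing_suppressed(self):
        t = np.arange(0, 30, 1 / 200)
        ts = TimeSeries(np.sin(2 * np.pi * 90.0 * t), 200.0)
        out = decimate_series(ts, 25.0)
        assert np.sqrt(np.mean(out.data**2)) < 0.05 * np.sqrt(0.5)

    def test_band_limited_rms_preserved(self):
        rng = np.random.default_rng(0)
        # noise band-limited well below 0.4 x target rate
        from scipy.signal import sosfiltfilt, butter

        x = sosfiltfilt(butter(6, 8.0, fs=200.0, output="sos"), rng.normal(size=8000))
        ts = TimeSeries(x, 200.0)
        out = decimate_series(ts, 25.0)
        assert np.sqrt(np.mean(out.data**2)) == pytest.approx(
            np.sqrt(np.mean(x**2)), rel=0.01
        )

    def test_target_rate_above_native_rejected(self):
        with pytest.raises(ValueError):
            decimate_series(TimeSeries(np.zeros(100), 25.0), 200.0)


class TestEvents:
    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "events.csv"
        write_events([], str(path))
        assert read_events(str(path)).empty

    def test_round_trip(self, tmp_path):
        path = tmp_path / "pings.csv"
        events = [{"time": 1.0, "rl": 120.0}, {"time": 2.5, "rl": 119.0},
                  {"time": 4.0, "rl": 118.5}]
        write_events(events, str(path))
        back = read_events(str(path))
        assert list(back.columns) == ["time", "rl"]
        np.testing.assert_array_equal(back["time"], [1.0, 2.5, 4.0])

    def test_large_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0, 3600, 10_000))
        levels = rng.uniform(100, 160, 10_000)
        path = tmp_path / "clicks.csv"
        write_events(pd.DataFrame({"time": times, "level": levels}), str(path))
        back = read_events(str(path))
        np.testing.assert_array_equal(back["time"].to_numpy(), times)
        np.testing.assert_array_equal(back["level"].to_numpy(), levels)

    def test_unordered_times_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_events([{"time": 2.0}, {"time": 1.0}], str(tmp_path / "x.csv"))
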