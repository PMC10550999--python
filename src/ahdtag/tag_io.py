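"""Reading, writing and calibration of multi-sensor tag deployments.

A deployment bundles the synchronized streams recorded by a suction-cup
sound-and-movement tag on a harbour porpoise: calibrated audio (Pa),
triaxial acceleration (m/s^2), pressure-derived depth (m, positive down),
optionally ECG voltage and GPS fixes, plus metadata about the acoustic
exposure (source position, source level, start/stop).

Conventions used throughout the package:

* All stream time bases share one epoch: seconds from deployment start
  (float).  UTC only appears in the calibration sidecar.
* Audio is held internally in pascal.  A single pair of helpers,
  :func:`pa_to_db` / :func:`db_to_pa`, does every conversion to and from
  dB re 1 uPa so the reference pressure lives in exactly one place.
* A full-scale audio sample corresponds to the tag's clip level
  (dB re 1 uPa, peak), e.g. 175 dB re 1 uPa for the tags emulated here.

On-disk layout of a deployment directory::

    audio.wav      float32 or PCM16 WAV, full scale == clip level
    sensors.csv    time,ax,ay,az,depth[,ecg]  (per-stream rates in sidecar)
    calib.json     {clip_level_db, rates: {audio,accel,depth[,ecg]},
                    epoch_utc, exposure: {...}}
    gps.csv        time,lat,lon  (optional)
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

P_REF_PA = 1e-6  # 1 uPa in Pa; reference pressure for all dB conversions


def pa_to_db(p: np.ndarray | float) -> np.ndarray | float:
    """Convert a pressure (Pa) to dB re 1 uPa: ``20*log10(p / 1 uPa)``."""
    return 20.0 * np.log10(np.asarray(p, dtype=float) / P_REF_PA)


def db_to_pa(level_db: np.ndarray | float) -> np.ndarray | float:
    """Convert dB re 1 uPa back to pascal (inverse of :func:`pa_to_db`)."""
    return P_REF_PA * 10.0 ** (np.asarray(level_db, dtype=float) / 20.0)


class FormatError(ValueError):
    """A file is readable but does not match the expected layout."""


class ValidationError(ValueError):
    """Stream contents violate a deployment invariant."""


@dataclass
class TimeSeries:
    """A uniformly sampled series: ``data`` (n,) or (n, k), rate ``fs`` Hz.

    ``t0`` is the time of the first sample on the shared deployment clock.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def index(self, t: float) -> int:
        """Nearest sample index for time ``t``, clipped to the record."""
        return int(np.clip(round((t - self.t0) * self.fs), 0, self.n - 1))

    def segment(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples in ``[t_start, t_end)`` (a view, not a copy)."""
        i0 = int(np.clip(np.ceil((t_start - self.t0) * self.fs - 1e-9), 0, self.n))
        i1 = int(np.clip(np.ceil((t_end - self.t0) * self.fs - 1e-9), 0, self.n))
        return self.data[i0:i1]


@dataclass
class GpsFix:
    time: float
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (abs(self.lat) <= 90.0 and abs(self.lon) <= 180.0):
            raise ValidationError(f"bad coordinates ({self.lat}, {self.lon})")


@dataclass
class ExposureMeta:
    """When and from where the deterrence source transmitted."""

    exposure_start: float
    exposure_end: float
    ahd_lat: float
    ahd_lon: float
    source_level: float = 189.0  # dB re 1 uPa rms @ 1 m
    ping_duration: float = 0.5  # s

    def __post_init__(self) -> None:
        if self.exposure_end <= self.exposure_start:
            raise ValidationError("exposure_end must exceed exposure_start")
        if self.ping_duration <= 0:
            raise ValidationError("ping_duration must be > 0")


@dataclass
class SensorDeployment:
    """Synchronized, calibrated streams from one tag deployment."""

    deployment_id: str
    audio: TimeSeries  # pressure, Pa
    clip_level_db: float  # dB re 1 uPa, peak, == full-scale audio sample
    accel: TimeSeries  # (n, 3) m/s^2
    depth: TimeSeries  # m, positive down
    exposure: ExposureMeta
    ecg: Optional[TimeSeries] = None  # arbitrary voltage units
    gps: list[GpsFix] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.accel.data.ndim != 2 or self.accel.data.shape[1] != 3:
            raise ValidationError("accel must have shape (n, 3)")
        if np.nanmin(self.depth.data) < -0.5:
            raise ValidationError("depth below -0.5 m: bad pressure calibration?")
        peak = float(np.max(np.abs(self.audio.data))) if self.audio.n else 0.0
        if peak > db_to_pa(self.clip_level_db) * (1 + 1e-6):
            raise ValidationError("audio exceeds clip level")
        times = [f.time for f in self.gps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("GPS fixes must be strictly time-ordered")

    @property
    def duration(self) -> float:
        return self.audio.duration


# ---------------------------------------------------------------------------
# reading / writing


def _audio_from_wav(path: str, clip_level_db: float) -> TimeSeries:
    fs, raw = wavfile.read(path)
    if raw.ndim == 2:  # stereo tags: level analysis defaults to channel 0
        raw = raw[:, 0]
    if raw.dtype == np.int16:
        scaled = raw.astype(np.float32) / 32768.0
    elif raw.dtype in (np.float32, np.float64):
        scaled = raw.astype(np.float32)
    else:
        raise FormatError(f"unsupported WAV sample format {raw.dtype}")
    full_scale_pa = db_to_pa(clip_level_db)
    return TimeSeries(scaled * np.float32(full_scale_pa), float(fs))


def read_deployment(
    audio_path: str,
    sensors_path: str,
    calib_path: str,
    gps_path: Optional[str] = None,
    deployment_id: Optional[str] = None,
) -> SensorDeployment:
    """Assemble a validated :class:`SensorDeployment` from on-disk files.

    The calibration sidecar (JSON) must provide ``clip_level_db`` and a
    ``rates`` mapping with entries for every sensor column present; audio
    samples are converted to Pa such that a full-scale sample equals the
    clip-level pressure.
    """
    with open(calib_path) as fh:
        calib = json.load(fh)
    for key in ("clip_level_db", "rates"):
        if key not in calib:
            raise FormatError(f"calibration sidecar missing '{key}'")
    rates = calib["rates"]
    for name, rate in rates.items():
        if rate <= 0:
            raise ValidationError(f"rate for '{name}' must be > 0, got {rate}")

    audio = _audio_from_wav(audio_path, calib["clip_level_db"])

    sensors = pd.read_csv(sensors_path, float_precision="round_trip")
    for col in ("time", "ax", "ay", "az", "depth"):
        if col not in sensors.columns:
            raise FormatError(f"sensors CSV missing column '{col}'")

    def column_series(cols: Sequence[str], rate_key: str) -> TimeSeries:
        if rate_key not in rates:
            raise FormatError(f"calibration rates missing '{rate_key}'")
        sub = sensors[["time", *cols]].dropna()
        data = sub[list(cols)].to_numpy(dtype=float)
        if len(cols) == 1:
            data = data[:, 0]
        t0 = float(sub["time"].iloc[0]) if len(sub) else 0.0
        return TimeSeries(data, float(rates[rate_key]), t0)

    accel = column_series(("ax", "ay", "az"), "accel")
    depth = column_series(("depth",), "depth")
    ecg = None
    if "ecg" in sensors.columns and sensors["ecg"].notna().any():
        ecg = column_series(("ecg",), "ecg")

    gps: list[GpsFix] = []
    if gps_path is not None and os.path.exists(gps_path):
        gdf = pd.read_csv(gps_path, float_precision="round_trip")
        for col in ("time", "lat", "lon"):
            if col not in gdf.columns:
                raise FormatError(f"GPS CSV missing column '{col}'")
        gps = [GpsFix(float(r.time), float(r.lat), float(r.lon)) for r in gdf.itertuples()]

    exp = calib.get("exposure")
    if exp is None:
        # deployment without a recorded exposure: degenerate 1-s window
        exposure = ExposureMeta(0.0, max(audio.duration, 1.0), 0.0, 0.0)
    else:
        exposure = ExposureMeta(**exp)

    if deployment_id is None:
        deployment_id = os.path.splitext(os.path.basename(audio_path))[0]
    return SensorDeployment(
        deployment_id=deployment_id,
        audio=audio,
        clip_level_db=float(calib["clip_level_db"]),
        accel=accel,
        depth=depth,
        ecg=ecg,
        gps=gps,
        exposure=exposure,
    )


def write_deployment(dep: SensorDeployment, out_dir: str) -> dict[str, str]:
    """Write a deployment to ``out_dir`` in the standard on-disk layout.

    Audio is stored as float32 WAV (full scale == clip level) so that
    synthetic deployments round-trip bit-exactly.  Returns the paths
    written, keyed by role.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "audio": os.path.join(out_dir, "audio.wav"),
        "sensors": os.path.join(out_dir, "sensors.csv"),
        "calib": os.path.join(out_dir, "calib.json"),
    }
    full_scale_pa = db_to_pa(dep.clip_level_db)
    wavfile.write(
        paths["audio"],
        int(round(dep.audio.fs)),
        (dep.audio.data / np.float32(full_scale_pa)).astype(np.float32),
    )

    frames = [
        pd.DataFrame(
            {
                "time": dep.accel.times(),
                "ax": dep.accel.data[:, 0],
                "ay": dep.accel.data[:, 1],
                "az": dep.accel.data[:, 2],
            }
        ),
        pd.DataFrame({"time": dep.depth.times(), "depth": dep.depth.data}),
    ]
    rates = {"audio": dep.audio.fs, "accel": dep.accel.fs, "depth": dep.depth.fs}
    if dep.ecg is not None:
        frames.append(pd.DataFrame({"time": dep.ecg.times(), "ecg": dep.ecg.data}))
        rates["ecg"] = dep.ecg.fs
    merged = frames[0]
    for frame in frames[1:]:
        merged = merged.merge(frame, on="time", how="outer")
    merged = merged.sort_values("time", kind="mergesort")
    merged.to_csv(paths["sensors"], index=False, float_format="%.17g")

    calib = {
        "clip_level_db": dep.clip_level_db,
        "rates": rates,
        "epoch_utc": None,
        "exposure": {
            "exposure_start": dep.exposure.exposure_start,
            "exposure_end": dep.exposure.exposure_end,
            "ahd_lat": dep.exposure.ahd_lat,
            "ahd_lon": dep.exposure.ahd_lon,
            "source_level": dep.exposure.source_level,
            "ping_duration": dep.exposure.ping_duration,
        },
    }
    with open(paths["calib"], "w") as fh:
        json.dump(calib, fh, indent=1)

    if dep.gps:
        paths["gps"] = os.path.join(out_dir, "gps.csv")
        pd.DataFrame(
            {
                "time": [f.time for f in dep.gps],
                "lat": [f.lat for f in dep.gps],
                "lon": [f.lon for f in dep.gps],
            }
        ).to_csv(paths["gps"], index=False, float_format="%.17g")
    return paths


# ---------------------------------------------------------------------------
# shared series utilities


def decimate_series(series: TimeSeries, target_rate: float) -> TimeSeries:
    """Anti-alias low-pass then downsample to ``target_rate``.

    Zero-phase 8-pole Butterworth low-pass with cutoff at 0.4 x the target
    rate, followed by stride sampling with an integer factor
    ``round(fs / target_rate)``; the output rate is exact when the ratio is
    an integer and within one-sample rounding otherwise.
    """
    if target_rate >= series.fs:
        raise ValueError(
            f"target rate {target_rate} Hz must be below native rate {series.fs} Hz"
        )
    q = max(int(round(series.fs / target_rate)), 2)
    sos = signal.butter(8, 0.4 * target_rate, btype="low", fs=series.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=0)
    return TimeSeries(filtered[::q], series.fs / q, series.t0)


def write_events(events: pd.DataFrame | Sequence[dict], path: str) -> None:
    """Write timestamped detector output as CSV, time column first.

    An empty input produces a header-only file (the ``time`` column alone
    when no other fields are known).  Times must be non-decreasing.
    """
    df = pd.DataFrame(events)
    if "time" not in df.columns:
        if len(df):
            raise ValidationError("events must have a 'time' column")
        df = pd.DataFrame({"time": []})
    if len(df) and (np.diff(df["time"].to_numpy(dtype=float)) < 0).any():
        raise ValidationError("event times must be non-decreasing")
    cols = ["time"] + [c for c in df.columns if c != "time"]
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_events(path: str) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
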