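"""Synthetic tag deployments with known ground truth.

Every downstream stage of the pipeline is exercised against deployments
generated here: calibrated audio containing deterrence pings, NBHF
echolocation clicks and buzzes, surface blows and flow noise; triaxial
acceleration with fluking, startle flinches and prey-capture transients;
a dive profile over a flat seafloor; optionally ECG following a
programmed instantaneous-heart-rate schedule and GPS fixes subsampled
from the true track.  The generator logs every event it places
(:class:`GroundTruth`), which is what recovery tests compare against.

Default signal parameters are the study conditions the pipeline is
built around: 500-ms 14-kHz pings with harmonics at 28 and 42 kHz at
randomized 0.6-90 s intervals from a 189 dB re 1 uPa rms @ 1 m source;
~130 kHz Gaussian-enveloped click pips (a standard NBHF surrogate);
175 dB re 1 uPa tag clip level.  Received ping levels follow the
configured propagation model applied to the instantaneous animal-source
range, so dosimetry recovery is checked against a closed-form truth.

The generator is deterministic: the same seed reproduces every waveform
and the event log bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .tag_io import (
    ExposureMeta,
    GpsFix,
    SensorDeployment,
    TimeSeries,
    db_to_pa,
)
from .tracking import PropagationModel, enu_offset_to_latlon, received_level

SOUND_SPEED = 1500.0  # m/s

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AhdConfig:
    enabled: bool = True
    source_level: float = 189.0  # dB re 1 uPa rms @ 1 m
    ping_duration: float = 0.5  # s
    base_freq: float = 14_000.0  # Hz
    harmonic_levels: tuple[float, ...] = (-20.0, -30.0)  # dB rel. fundamental (28, 42 kHz)
    interval_range: tuple[float, float] = (0.6, 90.0)  # s between pings
    ramp: float = 0.005  # s cosine on/off ramp: the fast rise time drives startle


@dataclass(frozen=True)
class TrackLeg:
    t_start: float
    speed: float  # m/s
    heading_deg: Optional[float] = None  # None = directly away from the source


@dataclass(frozen=True)
class TrackConfig:
    start_range_m: float = 1000.0
    start_bearing_deg: float = 0.0  # bearing from the source to the animal
    legs: tuple[TrackLeg, ...] = (TrackLeg(0.0, 1.4),)


@dataclass(frozen=True)
class DivePhase:
    t_start: float
    max_depth: float = 15.0  # m
    period: float = 60.0  # s per dive cycle
    surface_fraction: float = 0.3
    bottom_fraction: float = 0.5  # of submerged time spent at max depth (U vs V)


@dataclass(frozen=True)
class DiveConfig:
    phases: tuple[DivePhase, ...] = (DivePhase(0.0),)
    seafloor_depth: float = 30.0  # m, flat
    surface_depth: float = 0.2  # m while "at the surface"


@dataclass(frozen=True)
class ClickConfig:
    rate_schedule: tuple[tuple[float, float], ...] = ((0.0, 30.0),)  # (t, clicks/min)
    level_schedule: tuple[tuple[float, float], ...] = ((0.0, 150.0),)  # (t, dB pp)
    buzz_rate_schedule: tuple[tuple[float, float], ...] = ((0.0, 1.0),)  # (t, buzzes/min)
    buzz_ici: float = 0.010  # s
    buzz_n_clicks: tuple[int, int] = (15, 25)
    buzz_level_offset: float = -10.0  # dB rel. search clicks
    center_freq: float = 130_000.0  # Hz
    duration: float = 50e-6  # s
    min_gap: float = 0.02  # s between search clicks (keeps pp segments clean)


@dataclass(frozen=True)
class StartleConfig:
    enabled: bool = True
    latency: float = 0.1  # s from ping arrival to flinch
    amplitude: float = 15.0  # m/s^2 peak on each axis
    duration: float = 0.08  # s
    n_pings: int = 3  # flinches follow the first n ping arrivals


@dataclass(frozen=True)
class EcgConfig:
    enabled: bool = False
    fs: float = 5000.0
    fh_schedule: tuple[tuple[float, float], ...] = ((0.0, 80.0),)  # (t, bpm), linear
    r_amplitude: float = 1.0
    noise: float = 0.03


@dataclass(frozen=True)
class RespirationConfig:
    rate_schedule: tuple[tuple[float, float], ...] = ((0.0, 3.5),)  # (t, breaths/min)
    level_db: float = 110.0  # blow transient band level, dB re 1 uPa


@dataclass(frozen=True)
class NoiseConfig:
    band_level_db: float = 85.0  # flow-noise rms in the 10-46 kHz band, dB re 1 uPa


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int
    duration: float  # s
    exposure_start: float
    exposure_end: float
    fs_audio: float = 300_000.0
    fs_accel: float = 200.0
    fs_depth: float = 50.0
    clip_level_db: float = 175.0
    ahd_lat: float = 55.0
    ahd_lon: float = 10.0
    ahd: AhdConfig = AhdConfig()
    propagation: PropagationModel = PropagationModel()
    track: TrackConfig = TrackConfig()
    dive: DiveConfig = DiveConfig()
    clicks: Optional[ClickConfig] = ClickConfig()
    startle: StartleConfig = StartleConfig()
    ecg: Optional[EcgConfig] = None
    respiration: RespirationConfig = RespirationConfig()
    noise: NoiseConfig = NoiseConfig()
    gps_interval: Optional[tuple[float, float]] = (180.0, 300.0)  # s; None = no GPS
    gps_noise_m: float = 5.0
    fluke_freq: float = 1.4  # Hz
    fluke_coeff: float = 0.5  # accel amplitude per m/s of speed
    multipath_tail: Optional[float] = None  # s; exponential reverberation decay

    def validate(self) -> None:
        a, b = self.ahd.interval_range
        if not (0 < a <= b):
            raise ValueError("ping interval range must satisfy 0 < min <= max")
        if self.exposure_end <= self.exposure_start:
            raise ValueError("exposure_end must exceed exposure_start")
        if self.duration < self.exposure_start + a:
            raise ValueError("duration too short for a single ping interval")
        if self.ahd.enabled and self.fs_audio < 2.2 * self.ahd.base_freq:
            raise ValueError("audio rate too low for the ping fundamental")
        if self.clicks is not None and self.fs_audio < 2.05 * self.clicks.center_freq:
            raise ValueError(
                "audio rate too low for NBHF clicks; set clicks=None for this tag"
            )


@dataclass
class GroundTruth:
    """The generator's event log: what a perfect analysis would recover."""

    ping_emit_times: np.ndarray
    ping_times: np.ndarray  # arrival at the tag
    ping_rls: np.ndarray  # dB re 1 uPa rms at the tag
    click_times: np.ndarray  # all clicks, buzz clicks included
    buzz_events: list[tuple[float, float, int]]  # (start, end, n_clicks)
    startle_times: np.ndarray
    respiration_times: np.ndarray
    r_peak_times: np.ndarray
    track_times: np.ndarray  # 1-Hz true track
    east_m: np.ndarray
    north_m: np.ndarray
    range_m: np.ndarray
    speed: np.ndarray
    seafloor_depth: float
    crypsis_mask: np.ndarray  # at the depth rate, from the true seafloor

    def range_at(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.track_times, self.range_m)


# ---------------------------------------------------------------------------
# schedule helpers


def _step_value(schedule: Sequence[tuple[float, float]], t: float) -> float:
    v = schedule[0][1]
    for ts, val in schedule:
        if t >= ts:
            v = val
        else:
            break
    return v


def _linear_value(schedule: Sequence[tuple[float, float]], t: float) -> float:
    ts = np.array([s[0] for s in schedule])
    vs = np.array([s[1] for s in schedule])
    return float(np.interp(t, ts, vs))


# ---------------------------------------------------------------------------
# component synthesis


def _simulate_track(cfg: ScenarioConfig) -> tuple[np.ndarray, ...]:
    """True 1-Hz track in local ENU metres with the source at the origin."""
    t = np.arange(0.0, cfg.duration + 1.0)
    brg = math.radians(cfg.track.start_bearing_deg)
    x = np.empty_like(t)
    y = np.empty_like(t)
    x[0] = cfg.track.start_range_m * math.sin(brg)
    y[0] = cfg.track.start_range_m * math.cos(brg)
    speed = np.empty_like(t)
    legs = sorted(cfg.track.legs, key=lambda l: l.t_start)
    for k in range(len(t)):
        leg = legs[0]
        for cand in legs:
            if t[k] >= cand.t_start:
                leg = cand
        speed[k] = leg.speed
        if k + 1 < len(t):
            if leg.heading_deg is None:  # radially away from the source
                r = math.hypot(x[k], y[k])
                ux, uy = (x[k] / r, y[k] / r) if r > 0 else (0.0, 1.0)
            else:
                h = math.radians(leg.heading_deg)
                ux, uy = math.sin(h), math.cos(h)
            x[k + 1] = x[k] + leg.speed * ux
            y[k + 1] = y[k] + leg.speed * uy
    rng_m = np.hypot(x, y)
    return t, x, y, rng_m, speed


def _simulate_depth(cfg: ScenarioConfig) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Depth at fs_depth plus the list of surface intervals (for breaths)."""
    n = int(round(cfg.duration * cfg.fs_depth))
    depth = np.full(n, cfg.dive.surface_depth)
    surface_spans: list[tuple[float, float]] = []
    t = 0.0
    phases = sorted(cfg.dive.phases, key=lambda p: p.t_start)
    while t < cfg.duration:
        ph = phases[0]
        for cand in phases:
            if t >= cand.t_start:
                ph = cand
        t_surf = ph.period * ph.surface_fraction
        submerged = ph.period - t_surf
        t_bottom = submerged * ph.bottom_fraction
        t_leg = (submerged - t_bottom) / 2.0
        surface_spans.append((t, min(t + t_surf, cfg.duration)))
        marks = [t, t + t_surf, t + t_surf + t_leg, t + t_surf + t_leg + t_bottom, t + ph.period]
        depths = [cfg.dive.surface_depth, cfg.dive.surface_depth, ph.max_depth, ph.max_depth,
                  cfg.dive.surface_depth]
        i0 = int(round(t * cfg.fs_depth))
        i1 = min(int(round((t + ph.period) * cfg.fs_depth)), n)
        tt = np.arange(i0, i1) / cfg.fs_depth
        depth[i0:i1] = np.interp(tt, marks, depths)
        t += ph.period
    return depth, surface_spans


def _schedule_pings(cfg: ScenarioConfig, rng: np.random.Generator,
                    track_t: np.ndarray, track_r: np.ndarray):
    emit, arrive, rls = [], [], []
    lo, hi = cfg.ahd.interval_range
    t = cfg.exposure_start
    while t <= cfg.exposure_end:
        r = float(np.interp(t, track_t, track_r))
        t_arr = t + r / SOUND_SPEED
        if t_arr + cfg.ahd.ping_duration + 0.1 < cfg.duration:
            emit.append(t)
            arrive.append(t_arr)
            rls.append(received_level(cfg.ahd.source_level, r, cfg.propagation))
        t += rng.uniform(lo, hi)
    return np.array(emit), np.array(arrive), np.array(rls)


def _schedule_breaths(cfg: ScenarioConfig, surface_spans) -> np.ndarray:
    times = []
    for a, b in surface_spans:
        t = a + 1.0
        while t < b - 0.3:
            times.append(t)
            rate = _step_value(cfg.respiration.rate_schedule, t)
            if rate <= 0:
                break
            t += 60.0 / rate
    return np.array(times)


def _schedule_clicks(cfg: ScenarioConfig, rng: np.random.Generator,
                     ping_arrivals: np.ndarray):
    """Search clicks (rate schedule) + buzzes; buzzes avoid the 2 s after a
    ping arrival, since a porpoise interrupts prey capture at a startling
    stimulus — and it keeps buzz jerk transients out of startle windows."""
    cc = cfg.clicks
    click_times: list[float] = []
    buzz_events: list[tuple[float, float, int]] = []
    if cc is None:
        return np.array([]), buzz_events

    max_rate = max(v for _, v in cc.rate_schedule) / 60.0
    t = 0.5
    last = -np.inf
    while t < cfg.duration - 0.1 and max_rate > 0:
        t += rng.exponential(1.0 / max_rate)
        rate = _step_value(cc.rate_schedule, t) / 60.0
        if rate <= 0 or rng.uniform() > rate / max_rate:
            continue
        if t - last < cc.min_gap or t >= cfg.duration - 0.1:
            continue
        click_times.append(t)
        last = t

    max_bz = max(v for _, v in cc.buzz_rate_schedule) / 60.0
    t = 2.0
    while t < cfg.duration - 2.0 and max_bz > 0:
        t += rng.exponential(1.0 / max_bz)
        bz_rate = _step_value(cc.buzz_rate_schedule, t) / 60.0
        if bz_rate <= 0 or rng.uniform() > bz_rate / max_bz:
            continue
        if len(ping_arrivals) and np.any((ping_arrivals <= t) & (t - ping_arrivals < 2.0)):
            continue
        n = int(rng.integers(cc.buzz_n_clicks[0], cc.buzz_n_clicks[1] + 1))
        buzz = t + np.arange(n) * cc.buzz_ici
        if buzz[-1] >= cfg.duration - 0.1:
            continue
        click_times.extend(buzz.tolist())
        buzz_events.append((float(buzz[0]), float(buzz[-1]), n))
        t = buzz[-1] + 1.0
    return np.array(sorted(click_times)), buzz_events


def _schedule_beats(cfg: ScenarioConfig) -> np.ndarray:
    if cfg.ecg is None or not cfg.ecg.enabled:
        return np.array([])
    beats = [0.3]
    while True:
        fh = _linear_value(cfg.ecg.fh_schedule, beats[-1])
        nxt = beats[-1] + 60.0 / fh
        if nxt >= cfg.duration - 0.1:
            break
        beats.append(nxt)
    return np.array(beats)


# --- waveform primitives ----------------------------------------------------


def _ping_waveform(cfg: ScenarioConfig, rl_db: float, fs: float) -> np.ndarray:
    """Multi-harmonic tone burst with cosine ramps, scaled to rl_db rms."""
    ac = cfg.ahd
    n = int(round(ac.ping_duration * fs))
    t = np.arange(n) / fs
    rel = np.concatenate(([0.0], np.asarray(ac.harmonic_levels)))
    amps = 10.0 ** (rel / 20.0)
    wave = np.zeros(n)
    kept = []
    for k, a in enumerate(amps, start=1):
        f = k * ac.base_freq
        if f < 0.47 * fs:
            wave += a * np.sin(2 * np.pi * f * t)
            kept.append(a)
    rms_unit = math.sqrt(0.5 * sum(a * a for a in kept))
    wave *= db_to_pa(rl_db) / rms_unit
    n_ramp = int(round(ac.ramp * fs))
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        wave[:n_ramp] *= ramp
        wave[-n_ramp:] *= ramp[::-1]
    if cfg.multipath_tail:
        tau = cfg.multipath_tail
        n_tail = int(3 * tau * fs)
        ir = np.zeros(n_tail)
        ir[0] = 1.0
        k = np.arange(1, n_tail)
        ir[1:] = 0.3 * np.exp(-k / (tau * fs)) * np.random.default_rng(0).standard_normal(
            n_tail - 1
        )
        wave = np.convolve(wave, ir)[: n + n_tail]
    return wave


def _click_waveform(cc: ClickConfig, level_pp_db: float, fs: float) -> np.ndarray:
    """Gaussian-enveloped tone pip (standard NBHF surrogate)."""
    sigma = cc.duration / 4.0
    half = int(round(3 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-0.5 * (t / sigma) ** 2)
    wave = env * np.cos(2 * np.pi * cc.center_freq * t)
    # calibrate on the realized waveform: envelope asymmetry makes the
    # trough slightly shallower than the crest
    pp_unit = float(wave.max() - wave.min())
    return wave * (db_to_pa(level_pp_db) / pp_unit)


def _blow_waveform(level_db: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """0.3-s broadband low-frequency burst emulating a surface blow."""
    from scipy.signal import sosfilt
    from ._dsp import butter_sos

    n = int(0.3 * fs)
    burst = rng.standard_normal(n)
    sos = butter_sos(4, (200.0, min(2000.0, 0.45 * fs)), fs, "bandpass")
    burst = sosfilt(sos, burst)
    burst *= np.sin(np.pi * np.arange(n) / n)  # half-sine envelope
    burst *= db_to_pa(level_db) / math.sqrt(np.mean(burst**2))
    return burst


def _add_at(buf: np.ndarray, wave: np.ndarray, t: float, fs: float) -> None:
    i0 = int(round(t * fs))
    i1 = min(i0 + len(wave), len(buf))
    if i0 < len(buf):
        buf[i0:i1] += wave[: i1 - i0].astype(buf.dtype)


# ---------------------------------------------------------------------------
# top-level generation


def generate_deployment(cfg: ScenarioConfig) -> tuple[SensorDeployment, GroundTruth]:
    """Generate one deployment plus its ground-truth event log."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    track_t, east, north, rng_m, speed = _simulate_track(cfg)
    depth_data, surface_spans = _simulate_depth(cfg)

    if cfg.ahd.enabled:
        emit, arrivals, rls = _schedule_pings(cfg, rng, track_t, rng_m)
    else:
        emit = arrivals = rls = np.array([])
    breath_times = _schedule_breaths(cfg, surface_spans)
    click_times, buzz_events = _schedule_clicks(cfg, rng, arrivals)
    r_times = _schedule_beats(cfg)
    startle_times = (
        arrivals[: cfg.startle.n_pings] + cfg.startle.latency
        if cfg.startle.enabled and len(arrivals)
        else np.array([])
    )

    # ---- audio ------------------------------------------------------------
    fs = cfg.fs_audio
    n_audio = int(round(cfg.duration * fs))
    band_rms_pa = db_to_pa(cfg.noise.band_level_db)
    sigma = band_rms_pa * math.sqrt((fs / 2.0) / 36_000.0)  # white -> 10-46 kHz band rms
    audio = rng.standard_normal(n_audio, dtype=np.float32)
    audio *= np.float32(sigma)

    for t_arr, rl in zip(arrivals, rls):
        _add_at(audio, _ping_waveform(cfg, rl, fs), t_arr, fs)
    if cfg.clicks is not None:
        buzz_starts = {b[0] for b in buzz_events}
        buzz_ranges = [(b[0], b[1]) for b in buzz_events]
        for t_c in click_times:
            level = _step_value(cfg.clicks.level_schedule, t_c)
            if any(a <= t_c <= b for a, b in buzz_ranges):
                level += cfg.clicks.buzz_level_offset
            _add_at(audio, _click_waveform(cfg.clicks, level, fs), t_c, fs)
    for t_b in breath_times:
        _add_at(audio, _blow_waveform(cfg.respiration.level_db, fs, rng), t_b, fs)
    np.clip(audio, -db_to_pa(cfg.clip_level_db), db_to_pa(cfg.clip_level_db), out=audio)

    # ---- acceleration -----------------------------------------------------
    n_acc = int(round(cfg.duration * cfg.fs_accel))
    t_acc = np.arange(n_acc) / cfg.fs_accel
    accel = rng.normal(0.0, 0.02, size=(n_acc, 3))
    accel[:, 2] += 9.81
    speed_acc = np.interp(t_acc, track_t, speed)
    fluke_amp = cfg.fluke_coeff * speed_acc
    phase = 2 * np.pi * cfg.fluke_freq * t_acc
    accel[:, 0] += fluke_amp * np.sin(phase)
    accel[:, 2] += 0.3 * fluke_amp * np.cos(phase)

    def add_accel_transient(t0: float, amp: float, dur: float, axes=(0, 1, 2)) -> None:
        i0 = int(round(t0 * cfg.fs_accel))
        n_tr = max(int(round(dur * cfg.fs_accel)), 2)
        if i0 + n_tr > n_acc:
            return
        pulse = amp * np.sin(np.pi * np.arange(n_tr) / n_tr)
        for ax_i, sign in zip(axes, (1.0, -1.0, 1.0)):
            accel[i0 : i0 + n_tr, ax_i] += sign * pulse

    for t_s in startle_times:
        add_accel_transient(t_s, cfg.startle.amplitude, cfg.startle.duration)
    for b_start, _, _ in buzz_events:
        add_accel_transient(b_start, 1.5, 0.12, axes=(0, 1))

    # ---- ECG --------------------------------------------------------------
    ecg_ts = None
    if cfg.ecg is not None and cfg.ecg.enabled:
        n_ecg = int(round(cfg.duration * cfg.ecg.fs))
        ecg = rng.normal(0.0, cfg.ecg.noise, size=n_ecg)
        qrs = _qrs_template(cfg.ecg.fs, cfg.ecg.r_amplitude)
        half = len(qrs) // 2
        for t_r in r_times:
            i = int(round(t_r * cfg.ecg.fs))
            i0, i1 = i - half, i - half + len(qrs)
            if 0 <= i0 and i1 <= n_ecg:
                ecg[i0:i1] += qrs
        ecg_ts = TimeSeries(ecg, cfg.ecg.fs)

    # ---- GPS --------------------------------------------------------------
    gps: list[GpsFix] = []
    if cfg.gps_interval is not None:
        t = 0.0
        while t < cfg.duration:
            e = float(np.interp(t, track_t, east)) + rng.normal(0.0, cfg.gps_noise_m)
            nn = float(np.interp(t, track_t, north)) + rng.normal(0.0, cfg.gps_noise_m)
            lat, lon = enu_offset_to_latlon(e, nn, cfg.ahd_lat, cfg.ahd_lon)
            gps.append(GpsFix(t, float(lat), float(lon)))
            t += rng.uniform(*cfg.gps_interval)

    exposure = ExposureMeta(
        cfg.exposure_start,
        cfg.exposure_end,
        cfg.ahd_lat,
        cfg.ahd_lon,
        cfg.ahd.source_level,
        cfg.ahd.ping_duration,
    )
    dep = SensorDeployment(
        deployment_id=f"synth_{cfg.seed:05d}",
        audio=TimeSeries(audio, fs),
        clip_level_db=cfg.clip_level_db,
        accel=TimeSeries(accel, cfg.fs_accel),
        depth=TimeSeries(depth_data, cfg.fs_depth),
        ecg=ecg_ts,
        gps=gps,
        exposure=exposure,
    )

    floor = cfg.dive.seafloor_depth
    crypsis = (depth_data <= 2.0) | (depth_data >= floor - 2.0)
    truth = GroundTruth(
        ping_emit_times=emit,
        ping_times=arrivals,
        ping_rls=rls,
        click_times=click_times,
        buzz_events=buzz_events,
        startle_times=startle_times,
        respiration_times=breath_times,
        r_peak_times=r_times,
        track_times=track_t,
        east_m=east,
        north_m=north,
        range_m=rng_m,
        speed=speed,
        seafloor_depth=floor,
        crypsis_mask=crypsis,
    )
    return dep, truth


def _qrs_template(fs: float, amplitude: float) -> np.ndarray:
    """Stylized QRS: a Mexican-hat R wave dominating small P/T bumps.

    Only R-peak *timing* matters downstream, so morphology is minimal.
    """
    width = 0.015  # s, R wave half-width scale
    t = np.arange(-0.1, 0.1, 1.0 / fs)
    x = t / width
    r_wave = amplitude * (1 - x**2) * np.exp(-0.5 * x**2)
    p_wave = 0.1 * amplitude * np.exp(-0.5 * ((t + 0.06) / 0.02) ** 2)
    t_wave = 0.15 * amplitude * np.exp(-0.5 * ((t - 0.07) / 0.025) ** 2)
    return r_wave + p_wave + t_wave


def generate_flight_scenario(
    cfg: ScenarioConfig, pre_speed: float, exp_speed: float
) -> tuple[SensorDeployment, GroundTruth]:
    """Deployment whose track speed switches at exposure start.

    The animal travels at ``pre_speed`` before the exposure and
    ``exp_speed`` (directly away from the source) from exposure start;
    fluking amplitude scales with speed, so swimming effort co-varies,
    and received ping levels decay as the range opens.
    """
    if pre_speed <= 0 or exp_speed <= 0:
        raise ValueError("speeds must be > 0")
    legs = (
        TrackLeg(0.0, pre_speed, heading_deg=None),
        TrackLeg(cfg.exposure_start, exp_speed, heading_deg=None),
    )
    return generate_deployment(replace(cfg, track=replace(cfg.track, legs=legs)))
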