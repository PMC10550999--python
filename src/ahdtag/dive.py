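"""Dive segmentation, apparent seafloor, visual crypsis and respirations.

Visual crypsis — time spent within 2 m of the surface or of the
apparent seafloor — is an anti-predator concealment proxy.  Without
bathymetry, the seafloor is inferred from U-shaped dives, whose flat
bottom phases track the bottom depth closely; a bathymetry grid plus
GPS, when available, takes precedence.

Respirations (blows) appear in tag audio as broadband low-frequency
transients while the animal is at the surface; the detector here is an
automated surrogate for manual spectrogram marking, and manually marked
times are accepted as first-class input everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.signal import find_peaks, resample_poly

from ._dsp import butter_sos, filter_series, smoothed_envelope
from .tag_io import GpsFix, TimeSeries

SURFACE_THRESHOLD = 0.5  # m: dive start/end gate
CRYPSIS_BAND = 2.0  # m from surface or seafloor
U_BOTTOM_DEPTH_FRAC = 0.85  # bottom phase = samples deeper than this x max depth
U_BOTTOM_TIME_FRAC = 0.50  # U if bottom phase occupies at least this fraction
V_BOTTOM_TIME_FRAC = 0.20  # V if at most this fraction


@dataclass
class DiveSegment:
    start: float
    end: float
    max_depth: float
    shape: str  # "U", "V" or "other"

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RespirationEvent:
    time: float
    iri_prev: float  # s since previous breath (nan for the first)


def segment_dives(
    depth: TimeSeries, surface_threshold: float = SURFACE_THRESHOLD
) -> list[DiveSegment]:
    """Maximal intervals with depth above the surface threshold.

    Shape: U when the bottom phase (samples deeper than 85% of max
    depth) occupies >= 50% of the dive, V when <= 20%, otherwise other.
    """
    if depth.fs < 1.0:
        raise ValueError("depth rate must be >= 1 Hz for dive segmentation")
    sub = depth.data > surface_threshold
    d = np.diff(sub.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if sub[0]:
        starts = np.concatenate(([0], starts))
    if sub[-1]:
        ends = np.concatenate((ends, [len(sub)]))

    dives = []
    for i0, i1 in zip(starts, ends):
        seg = depth.data[i0:i1]
        max_depth = float(seg.max())
        bottom_frac = float(np.mean(seg >= U_BOTTOM_DEPTH_FRAC * max_depth))
        if bottom_frac >= U_BOTTOM_TIME_FRAC:
            shape = "U"
        elif bottom_frac <= V_BOTTOM_TIME_FRAC:
            shape = "V"
        else:
            shape = "other"
        dives.append(
            DiveSegment(depth.t0 + i0 / depth.fs, depth.t0 + i1 / depth.fs, max_depth, shape)
        )
    return dives


@dataclass
class SeafloorEstimate:
    """Apparent seafloor depth as a function of time.

    ``available`` is False when neither U dives nor bathymetry constrain
    the bottom; crypsis then degrades to the surface band only.
    """

    available: bool
    times: np.ndarray | None = None
    depths: np.ndarray | None = None
    source: str = "none"

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        if not self.available:
            return np.full_like(np.asarray(t, dtype=float), np.inf)
        return np.interp(t, self.times, self.depths)


def estimate_seafloor(
    dives: list[DiveSegment],
    gps: Optional[list[GpsFix]] = None,
    bathymetry: Optional[Callable[[float, float], float]] = None,
) -> SeafloorEstimate:
    """Apparent seafloor from U-dive bottom depths, or bathymetry + GPS.

    A bathymetry lookup ``(lat, lon) -> depth`` combined with GPS fixes
    takes precedence; otherwise U-dive max depths are interpolated
    piecewise-linearly over time (held constant beyond the first/last U
    dive).
    """
    if bathymetry is not None and gps:
        t = np.array([f.time for f in gps])
        z = np.array([bathymetry(f.lat, f.lon) for f in gps])
        return SeafloorEstimate(True, t, z, source="bathymetry")
    u_dives = [d for d in dives if d.shape == "U"]
    if not u_dives:
        return SeafloorEstimate(False)
    t = np.array([0.5 * (d.start + d.end) for d in u_dives])
    z = np.array([d.max_depth for d in u_dives])
    return SeafloorEstimate(True, t, z, source="u-dives")


def crypsis_mask(
    depth: TimeSeries, seafloor: SeafloorEstimate, band: float = CRYPSIS_BAND
) -> np.ndarray:
    """Boolean series: within ``band`` metres of surface or apparent seafloor."""
    t = depth.times()
    floor = np.asarray(seafloor(t), dtype=float)
    return (depth.data <= band) | (depth.data >= floor - band)


def crypsis_fraction(
    depth: TimeSeries,
    seafloor: SeafloorEstimate,
    window: tuple[float, float],
    band: float = CRYPSIS_BAND,
) -> float:
    """Fraction of ``window`` spent in visual crypsis (0..1)."""
    mask = crypsis_mask(depth, seafloor, band)
    t = depth.times()
    sel = (t >= window[0]) & (t < window[1])
    if not sel.any():
        raise ValueError("window outside the depth record")
    return float(mask[sel].mean())


def detect_respirations(
    audio: TimeSeries,
    depth: TimeSeries,
    band: tuple[float, float] = (100.0, 5000.0),
    threshold_db: float = 12.0,
    min_gap: float = 2.0,
    max_depth: float = 1.0,
) -> list[RespirationEvent]:
    """Blow transients: low-frequency envelope peaks while near the surface.

    Audio is first decimated to ~6 x the upper band edge to keep the
    band-pass cheap on long high-rate recordings.  Peaks above the noise
    median by ``threshold_db`` and at least ``min_gap`` apart count, but
    only when the concurrent depth is at most ``max_depth`` (blow-like
    transients at depth are rejected).
    """
    target_fs = 6.0 * band[1]
    if audio.fs > 2 * target_fs:
        q = int(audio.fs // target_fs)
        data = resample_poly(audio.data.astype(np.float64), 1, q)
        low = TimeSeries(data, audio.fs / q, audio.t0)
    else:
        low = audio
    band = (band[0], min(band[1], 0.45 * low.fs))  # clamp for low-rate tags
    filt = filter_series(low, butter_sos(4, band, low.fs, "bandpass"))
    env = smoothed_envelope(filt.data, filt.fs, 0.05)
    height = np.median(env) * 10 ** (threshold_db / 20.0)
    idx, _ = find_peaks(env, height=height, distance=int(min_gap * filt.fs))

    events: list[RespirationEvent] = []
    prev: float | None = None
    for i in idx:
        t = filt.t0 + i / filt.fs
        if depth.data[depth.index(t)] > max_depth:
            continue
        iri = t - prev if prev is not None else np.nan
        events.append(RespirationEvent(float(t), float(iri)))
        prev = t
    return events


def respiration_rate(events: list[RespirationEvent], window: tuple[float, float]) -> float:
    """Breaths per minute within ``window``."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    n = sum(t0 <= e.time < t1 for e in events)
    return n / ((t1 - t0) / 60.0)


def iri_series(events: list[RespirationEvent]) -> np.ndarray:
    """Inter-respiration intervals (s), one per breath after the first."""
    times = np.array([e.time for e in events])
    return np.diff(times)
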