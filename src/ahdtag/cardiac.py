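"""ECG processing: R-peak extraction and instantaneous heart rate.

The ECG chain mirrors standard biologging practice: down-sample to
250 Hz, 1-10 Hz 4-pole band-pass (isolates the QRS complex, removes
baseline wander and electrode noise), adaptive-threshold R-peak picking
with a physiological refractory period, then instantaneous heart rate
fH = 60 / RR assigned at the end of each RR interval.  A review list of
added/removed beat times stands in for the visual-verification step of
a manual workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._dsp import butter_sos, filter_series
from .tag_io import TimeSeries, decimate_series

ECG_RATE = 250.0  # Hz after down-sampling
ECG_BAND = (1.0, 10.0)  # Hz, 4-pole band-pass
REFRACTORY = 0.25  # s; supports heart rates up to 240 bpm


def preprocess_ecg(ecg: TimeSeries) -> TimeSeries:
    """Down-sample to 250 Hz and band-pass 1-10 Hz (4-pole, zero-phase)."""
    if ecg.fs < ECG_RATE:
        raise ValueError(f"ECG rate {ecg.fs} Hz is below the {ECG_RATE} Hz working rate")
    work = decimate_series(ecg, ECG_RATE) if ecg.fs > ECG_RATE else ecg
    sos = butter_sos(4, ECG_BAND, work.fs, "bandpass")
    return filter_series(work, sos, zero_phase=True)


def detect_r_peaks(
    ecg_filtered: TimeSeries,
    threshold_frac: float = 0.5,
    envelope_window: float = 5.0,
    refractory: float = REFRACTORY,
    review_add: list[float] | None = None,
    review_remove: list[float] | None = None,
) -> list[float]:
    """R-peak times via an adaptive threshold with sub-sample refinement.

    The threshold tracks ``threshold_frac`` x the running 5-s maximum of
    the rectified signal, so slow amplitude drift (electrode movement,
    posture) does not drop beats.  Peak times are refined by parabolic
    interpolation around the sample maximum.  ``review_add`` /
    ``review_remove`` apply the visual-verification corrections (times
    in seconds; removals match the nearest detection within 50 ms).
    """
    x = np.abs(ecg_filtered.data.astype(np.float64))
    n_env = int(envelope_window * ecg_filtered.fs)
    # running max via strided blocks is enough for a slowly varying gate
    n_blocks = max(len(x) // n_env, 1)
    block_max = np.max(x[: n_blocks * n_env].reshape(n_blocks, n_env), axis=1)
    gate = np.repeat(block_max, n_env)[: len(x)]
    if len(gate) < len(x):
        gate = np.concatenate([gate, np.full(len(x) - len(gate), block_max[-1])])
    idx, _ = find_peaks(
        x, height=threshold_frac * gate, distance=int(refractory * ecg_filtered.fs)
    )

    times = []
    for i in idx:
        if 0 < i < len(x) - 1:
            denom = x[i - 1] - 2 * x[i] + x[i + 1]
            delta = 0.5 * (x[i - 1] - x[i + 1]) / denom if denom != 0 else 0.0
        else:
            delta = 0.0
        times.append(ecg_filtered.t0 + (i + float(np.clip(delta, -0.5, 0.5))) / ecg_filtered.fs)

    if review_remove:
        for t_rm in review_remove:
            if not times:
                break
            j = int(np.argmin(np.abs(np.array(times) - t_rm)))
            if abs(times[j] - t_rm) <= 0.05:
                del times[j]
    if review_add:
        times.extend(review_add)
    return sorted(times)


@dataclass
class HeartBeatSeries:
    """Instantaneous heart rate assigned at the end of each RR interval."""

    r_times: np.ndarray  # all R-peaks, s
    fh_times: np.ndarray  # interval-end times (r_times[1:])
    fh_inst: np.ndarray  # beats/min, exactly 60 / RR
    quality: np.ndarray = field(default=None)  # per-beat accept flag

    def __post_init__(self) -> None:
        if self.quality is None:
            self.quality = np.ones(len(self.fh_inst), dtype=bool)


def instantaneous_fh(r_times: list[float] | np.ndarray) -> HeartBeatSeries:
    """fH = 60 / RR from successive R-peaks; empty for fewer than 2 peaks."""
    r = np.asarray(r_times, dtype=float)
    if len(r) < 2:
        return HeartBeatSeries(r, np.array([]), np.array([]))
    if np.any(np.diff(r) <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    rr = np.diff(r)
    return HeartBeatSeries(r, r[1:], 60.0 / rr)


def running_median_fh(fh: HeartBeatSeries, width: float = 50.0) -> np.ndarray:
    """Running median of fH over a ``width``-second window centred per beat.

    The 50-s default smooths across one dive-surfacing cycle, giving the
    "diving heart rate" trend.
    """
    out = np.empty(len(fh.fh_inst))
    half = width / 2.0
    for k, t in enumerate(fh.fh_times):
        sel = (fh.fh_times >= t - half) & (fh.fh_times <= t + half)
        out[k] = np.median(fh.fh_inst[sel])
    return out


def fh_summary(
    fh: HeartBeatSeries, windows: dict[str, tuple[float, float]]
) -> dict[str, dict[str, float | None]]:
    """Per-window 10th/90th percentiles and median of instantaneous fH.

    Empty windows yield ``None`` entries rather than numbers.
    """
    out: dict[str, dict[str, float | None]] = {}
    for name, (t0, t1) in windows.items():
        sel = (fh.fh_times >= t0) & (fh.fh_times < t1) & fh.quality
        vals = fh.fh_inst[sel]
        if len(vals) == 0:
            out[name] = {"p10": None, "median": None, "p90": None, "n": 0}
        else:
            out[name] = {
                "p10": float(np.percentile(vals, 10)),
                "median": float(np.median(vals)),
                "p90": float(np.percentile(vals, 90)),
                "n": int(len(vals)),
            }
    return out
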