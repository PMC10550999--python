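"""Small shared signal-processing helpers (filters, envelopes, window rms)."""

from __future__ import annotations

import numpy as np
from scipy import signal

from .tag_io import TimeSeries


def butter_sos(
    order_poles: int,
    band: tuple[float, float] | float,
    fs: float,
    btype: str,
) -> np.ndarray:
    """Butterworth SOS with a total of ``order_poles`` poles.

    For band-pass filters scipy's ``N`` is the order per edge (poles are
    doubled), so a "6-pole band-pass" is ``N = 3``.
    """
    if btype == "bandpass":
        n = order_poles // 2
    else:
        n = order_poles
    return signal.butter(n, band, btype=btype, fs=fs, output="sos")


def filter_series(
    series: TimeSeries,
    sos: np.ndarray,
    zero_phase: bool = True,
) -> TimeSeries:
    """Apply an SOS filter to a series; zero-phase by default.

    Zero-phase filtering avoids level bias and onset smearing in
    measurement paths; causal filtering (``zero_phase=False``) preserves
    onset ordering for detection paths.
    """
    fn = signal.sosfiltfilt if zero_phase else signal.sosfilt
    out = fn(sos, series.data.astype(np.float64, copy=False), axis=0)
    return TimeSeries(out.astype(series.data.dtype, copy=False), series.fs, series.t0)


def moving_rms(x: np.ndarray, n: int) -> np.ndarray:
    """Causal moving rms over ``n`` samples (same length as input)."""
    c = np.cumsum(np.concatenate(([0.0], np.square(x, dtype=np.float64))))
    out = np.empty(len(x))
    out[n - 1 :] = (c[n:] - c[:-n]) / n
    # ramp-in: grow the window from 1 sample
    out[: n - 1] = c[1:n] / np.arange(1, n)
    return np.sqrt(out)


def window_rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x, dtype=np.float64))))


def max_sliding_rms(x: np.ndarray, n: int, step: int = 1) -> float:
    """Maximum rms over all length-``n`` windows starting every ``step`` samples."""
    if len(x) < n:
        return window_rms(x)
    c = np.cumsum(np.concatenate(([0.0], np.square(x, dtype=np.float64))))
    starts = np.arange(0, len(x) - n + 1, step)
    return float(np.sqrt(np.max((c[starts + n] - c[starts]) / n)))


def smoothed_envelope(x: np.ndarray, fs: float, smooth_s: float) -> np.ndarray:
    """Rectified, short-window-rms amplitude envelope.

    Cheaper than a Hilbert transform on tens of millions of samples and
    adequate for threshold detection of transients much longer than the
    smoothing window.
    """
    n = max(int(round(smooth_s * fs)), 1)
    return moving_rms(x, n)
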