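"""Body-movement metrics from triaxial acceleration: MSA, jerk, startle.

Minimum specific acceleration (MSA) is ``| ||a|| - g |`` on 25-Hz
decimated acceleration — a lower bound on the magnitude of specific
(non-gravitational) acceleration that requires no orientation estimate,
hence is invariant under any fixed rotation of the accelerometer frame.
The 95th percentile of MSA over 5-s bins proxies swimming effort.

Jerk is the norm of the first difference of the 25-Hz triaxial
acceleration times the rate (m/s^3); sharp transients mark prey-capture
strikes and whole-body startle flinches.

An acoustic startle response is scored per ping: a significant jerk
peak — above the 10-s pre-ping baseline mean + 3 sd — occurring within
0.2 s after the ping reaches the tag.  The 0.2-s window is referenced
to arrival at the tag (not emission), since acoustic travel time at
multi-km ranges is many times the startle latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tag_io import TimeSeries, decimate_series

G = 9.81  # m/s^2
STARTLE_WINDOW = 0.2  # s after ping arrival
STARTLE_BASELINE = 10.0  # s before ping
KINEMATIC_RATE = 25.0  # Hz


def _decimated_accel(accel: TimeSeries, rate: float) -> TimeSeries:
    if accel.fs < 50.0:
        raise ValueError(f"accelerometer rate {accel.fs} Hz too low (need >= 50 Hz)")
    if accel.fs == rate:
        return accel
    return decimate_series(accel, rate)


def compute_msa(accel: TimeSeries, rate: float = KINEMATIC_RATE) -> TimeSeries:
    """MSA = | ||a|| - g | on decimated triaxial acceleration, m/s^2."""
    dec = _decimated_accel(accel, rate)
    msa = np.abs(np.linalg.norm(dec.data, axis=1) - G)
    return TimeSeries(msa, dec.fs, dec.t0)


def swimming_effort(msa: TimeSeries, bin_s: float = 5.0, q: float = 95.0) -> TimeSeries:
    """Per-bin 95th percentile of MSA: the swimming-effort proxy.

    Output has one value per complete ``bin_s`` bin (partial trailing
    bins are dropped), at rate ``1 / bin_s``.
    """
    per_bin = int(round(bin_s * msa.fs))
    n_bins = msa.n // per_bin
    binned = msa.data[: n_bins * per_bin].reshape(n_bins, per_bin)
    effort = np.percentile(binned, q, axis=1)
    return TimeSeries(effort, 1.0 / bin_s, msa.t0)


def compute_jerk(accel: TimeSeries, rate: float = KINEMATIC_RATE) -> TimeSeries:
    """Norm of the differenced 25-Hz triaxial acceleration, scaled to m/s^3.

    ``jerk[i] = ||a[i] - a[i-1]|| * rate`` with ``jerk[0] = 0`` so the
    series stays aligned with the decimated acceleration.
    """
    dec = _decimated_accel(accel, rate)
    diff = np.diff(dec.data, axis=0)
    jerk = np.concatenate(([0.0], np.linalg.norm(diff, axis=1) * dec.fs))
    return TimeSeries(jerk, dec.fs, dec.t0)


@dataclass
class StartleCall:
    """Per-ping startle evaluation."""

    ping_time: float
    startled: bool
    peak_jerk: float  # m/s^3 inside the response window
    latency: float  # s from ping to the peak (nan when unevaluable)
    evaluable: bool = True


def detect_startle(
    jerk: TimeSeries,
    ping_times: list[float],
    window: float = STARTLE_WINDOW,
    baseline: float = STARTLE_BASELINE,
    n_sd: float = 3.0,
) -> list[StartleCall]:
    """Score each ping for a startle flinch.

    ``startled`` iff the max jerk in ``(ping, ping + window]`` exceeds
    baseline mean + ``n_sd`` * sd over the ``baseline`` seconds preceding
    the ping.  Pings without enough pre-roll or post-roll are flagged
    unevaluable rather than guessed.
    """
    calls: list[StartleCall] = []
    for t in ping_times:
        base = jerk.segment(t - baseline, t)
        resp = jerk.segment(t + 1.0 / jerk.fs, t + window + 1.0 / jerk.fs)
        if len(base) < int(0.9 * baseline * jerk.fs) or len(resp) == 0:
            calls.append(StartleCall(t, False, np.nan, np.nan, evaluable=False))
            continue
        gate = float(base.mean() + n_sd * base.std())
        peak = float(resp.max())
        latency = (int(np.argmax(resp)) + 1) / jerk.fs
        calls.append(StartleCall(t, peak > gate, peak, latency))
    return calls


def tag_slide_warning(
    accel: TimeSeries, window_s: float = 60.0, max_angle_deg: float = 20.0
) -> list[float]:
    """Times where the mean acceleration direction rotates beyond a gate.

    A coarse quality check for tag sliding: the windowed mean specific
    force direction should stay roughly fixed on a well-seated tag.
    Returns window-start times where the rotation relative to the
    previous window exceeds ``max_angle_deg``.
    """
    per = int(window_s * accel.fs)
    n = accel.n // per
    if n < 2:
        return []
    means = accel.data[: n * per].reshape(n, per, 3).mean(axis=1)
    means /= np.linalg.norm(means, axis=1, keepdims=True)
    cosang = np.clip(np.sum(means[:-1] * means[1:], axis=1), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    flagged = np.flatnonzero(angles > max_angle_deg) + 1
    return [accel.t0 + i * window_s for i in flagged]
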