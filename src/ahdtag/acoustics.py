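"""AHD ping detection and received-level / sound-exposure dosimetry.

The deterrence source transmits 500-ms, 14-kHz pulses ("pings") with
harmonics at 28 and 42 kHz.  Dosimetry on the tag audio proceeds as:

1. band-pass 10-46 kHz (6-pole Butterworth) to reject low-frequency flow
   noise and high-frequency echolocation while keeping the first two
   harmonics;
2. detect ping onsets from the envelope of a 12-16 kHz sub-band around
   the fundamental;
3. per ping, measure the rms-fast received level (RL): the maximum rms
   pressure over a 125-ms window slid across the ping, in dB re 1 uPa;
4. per ping, integrate the single-ping sound exposure level (SEL) over
   500 ms from onset, in dB re 1 uPa^2 s;
5. accumulate SEL non-leakily across pings (SELcum) and flag temporary
   threshold shift (TTS) risk against the single-pulse onset level of
   142 dB re 1 uPa^2 s.

Pings are screened on signal-to-noise ratio: only pings with SNR
strictly above 10 dB (ping rms vs. the rms of the 125 ms of band-limited
noise preceding the onset) are accepted for RL evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dsp import butter_sos, filter_series, max_sliding_rms, smoothed_envelope, window_rms
from .tag_io import ExposureMeta, TimeSeries, ValidationError, pa_to_db

AHD_BAND = (10_000.0, 46_000.0)
DETECT_SUBBAND = (12_000.0, 16_000.0)
RMS_FAST_WINDOW = 0.125  # s
SEL_INTEGRATION = 0.5  # s
SNR_MIN_DB = 10.0
TTS_THRESHOLD_DB = 142.0  # single-pulse TTS onset, dB re 1 uPa^2 s
SEL_REF = 1e-12  # (1 uPa)^2 * 1 s, in Pa^2 s


@dataclass
class PingDetection:
    """One received AHD ping: onset time plus its level measurements."""

    time: float  # onset at the tag, s
    rl_rms_fast: float  # dB re 1 uPa (max-hold 125-ms rms)
    sel_single: float  # dB re 1 uPa^2 s (500-ms integration)
    snr: float  # dB
    accepted: bool


@dataclass
class ExposureDose:
    """Running non-leaky SELcum over accepted pings with TTS-risk flags.

    ``tts_exceeded`` marks outright exceedance of the threshold;
    ``tts_risk`` additionally flags doses that come within ``margin`` dB
    of it ("close to the TTS limit").
    """

    pings: list[PingDetection]
    selcum_series: np.ndarray  # dB after each accepted ping
    tts_threshold: float = TTS_THRESHOLD_DB
    margin: float = 3.0
    tts_risk: bool = field(init=False)
    tts_exceeded: bool = field(init=False)

    def __post_init__(self) -> None:
        peak = float(self.selcum_series[-1]) if len(self.selcum_series) else -np.inf
        self.tts_exceeded = peak >= self.tts_threshold
        self.tts_risk = peak >= self.tts_threshold - self.margin


def bandpass_ahd(audio: TimeSeries, band=AHD_BAND, zero_phase: bool = True) -> TimeSeries:
    """10-46 kHz 6-pole band-pass; zero-phase for level measurement."""
    if audio.fs <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {audio.fs} Hz too low for a {band[1]/1000:.0f} kHz band edge"
        )
    sos = butter_sos(6, band, audio.fs, "bandpass")
    return filter_series(audio, sos, zero_phase=zero_phase)


def detect_pings(
    audio: TimeSeries,
    meta: ExposureMeta | None = None,
    subband=DETECT_SUBBAND,
    threshold_db: float = 10.0,
    min_gap: float = 0.5,
    min_duration: float = 0.05,
) -> list[float]:
    """Onset times of AHD pings from the fundamental-band envelope.

    Threshold = envelope noise median + ``threshold_db``; onset is the
    first threshold crossing, detections closer than ``min_gap`` are
    merged, and crossings shorter than ``min_duration`` are dropped as
    transients.  The search is restricted to the exposure window (with
    5 s slack) when ``meta`` is given.  The causal sub-band filter keeps
    onsets causally ordered.
    """
    sub = filter_series(audio, butter_sos(4, subband, audio.fs, "bandpass"), zero_phase=False)
    env = smoothed_envelope(sub.data, sub.fs, 0.005)
    threshold = np.median(env) * 10 ** (threshold_db / 20.0)

    above = env > threshold
    if meta is not None:
        t = np.arange(len(above)) / audio.fs + audio.t0
        above &= (t >= meta.exposure_start - 5.0) & (t <= meta.exposure_end + 5.0)

    edges = np.flatnonzero(np.diff(above.astype(np.int8)) == 1) + 1
    if above[0]:
        edges = np.concatenate(([0], edges))
    falls = np.flatnonzero(np.diff(above.astype(np.int8)) == -1) + 1
    if above[-1]:
        falls = np.concatenate((falls, [len(above)]))

    onsets: list[float] = []
    min_samples = int(min_duration * audio.fs)
    last = -np.inf
    for rise, fall in zip(edges, falls):
        if fall - rise < min_samples:
            continue
        t_on = audio.t0 + rise / audio.fs
        if t_on - last < min_gap:
            continue
        onsets.append(t_on)
        last = t_on
    return onsets


def measure_rl_rms_fast(
    audio: TimeSeries,
    ping_time: float,
    window: float = RMS_FAST_WINDOW,
    ping_span: float = SEL_INTEGRATION,
    mode: str = "max",
) -> float:
    """rms-fast RL of a ping, dB re 1 uPa.

    ``mode="max"`` (default) takes the maximum over 125-ms windows slid
    across [onset - 50 ms, onset + ping span + 50 ms]; ``mode="onset"``
    anchors a single window at the onset.  Expects band-passed audio.
    """
    if mode == "onset":
        seg = audio.segment(ping_time, ping_time + window)
        if len(seg) < int(window * audio.fs):
            raise ValueError("ping window exceeds the recording")
        return float(pa_to_db(window_rms(seg)))
    seg = audio.segment(ping_time - 0.05, ping_time + ping_span + 0.05)
    n = int(round(window * audio.fs))
    if len(seg) < n:
        raise ValueError("ping window exceeds the recording")
    step = max(int(round(0.005 * audio.fs)), 1)
    return float(pa_to_db(max_sliding_rms(seg, n, step)))


def measure_snr(
    audio: TimeSeries,
    ping_time: float,
    window: float = RMS_FAST_WINDOW,
    ping_span: float = SEL_INTEGRATION,
    guard: float = 0.01,
) -> float:
    """SNR (dB): ping rms-fast level vs. the 125 ms of noise before onset."""
    noise = audio.segment(ping_time - guard - window, ping_time - guard)
    if len(noise) < int(window * audio.fs):
        raise ValueError("insufficient pre-roll before ping for noise estimate")
    rl = measure_rl_rms_fast(audio, ping_time, window, ping_span)
    return rl - float(pa_to_db(window_rms(noise)))


def ping_sel(audio: TimeSeries, ping_time: float, integration: float = SEL_INTEGRATION) -> float:
    """Single-ping SEL: 10 log10( integral of p^2 dt / 1 uPa^2 s )."""
    seg = audio.segment(ping_time, ping_time + integration)
    if len(seg) < int(integration * audio.fs):
        raise ValueError("SEL integration window exceeds the recording")
    energy = float(np.sum(np.square(seg, dtype=np.float64))) / audio.fs
    return 10.0 * np.log10(energy / SEL_REF)


def analyze_pings(
    audio_raw: TimeSeries,
    meta: ExposureMeta | None = None,
    snr_min: float = SNR_MIN_DB,
    ping_times: list[float] | None = None,
) -> list[PingDetection]:
    """Full per-ping dosimetry: detect (or use manual marks), then measure.

    ``ping_times`` overrides the automatic detector with manually marked
    onsets, mirroring an annotation-first workflow.
    """
    band = bandpass_ahd(audio_raw)
    if ping_times is None:
        detect_src = filter_series(
            audio_raw, butter_sos(6, AHD_BAND, audio_raw.fs, "bandpass"), zero_phase=False
        )
        ping_times = detect_pings(detect_src, meta)
    out = []
    for t in ping_times:
        try:
            rl = measure_rl_rms_fast(band, t)
            snr = measure_snr(band, t)
            sel = ping_sel(band, t)
        except ValueError:
            continue  # ping truncated by the record edge
        out.append(PingDetection(t, rl, sel, snr, accepted=snr > snr_min))
    return out


def cumulate_sel(
    pings: list[PingDetection],
    tts_threshold: float = TTS_THRESHOLD_DB,
    margin: float = 3.0,
    accepted_only: bool = True,
) -> ExposureDose:
    """Non-leaky cumulative SEL over time-ordered pings.

    SELcum after ping k is ``10 log10(sum_{i<=k} 10**(SEL_i/10))``; the
    running series is non-decreasing by construction and its final value
    is permutation-invariant.
    """
    times = [p.time for p in pings]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValidationError("pings must be time-ordered")
    used = [p for p in pings if p.accepted or not accepted_only]
    energies = np.array([10.0 ** (p.sel_single / 10.0) for p in used])
    selcum = 10.0 * np.log10(np.cumsum(energies)) if len(energies) else np.array([])
    return ExposureDose(used, selcum, tts_threshold, margin)
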