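"""Per-animal exposure response table and group summaries.

The core comparison is acute: each metric is evaluated over the
exposure window and over a control window of equal length immediately
preceding it (15 min in the full design; both windows shrink together
when the exposure or the pre-exposure record is shorter).  Percent
metrics are percent-changed, dB metrics are differenced, and flags
(startle, flight, TTS risk) are carried as booleans.  Cells that cannot
be evaluated (no clicks detectable, no ECG, no GPS) stay ``None`` and
are rendered as "-"; they never enter counts or means.

The response index counts, per animal, all responses irrespective of
direction: a numeric cell counts when its magnitude reaches the index
threshold (8 % / 8 percentage points / 8 dB by default), a flag cell
counts when true.  The threshold rule is a reconstruction — the unique
simple magnitude gate consistent with the published per-animal indices —
and is exposed as a parameter rather than hard-wired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import theilslopes

from . import acoustics, cardiac, dive, echolocation, kinematics, tracking
from .acoustics import ExposureDose, PingDetection
from .tag_io import SensorDeployment
from .tracking import TrackEstimate

MAX_WINDOW = 900.0  # s; the full-design comparison window
INDEX_THRESHOLD = 8.0  # %, percentage points, or dB
RL_FLEE_SLOPE = -0.2  # dB/min; robust RL trend below this indicates fleeing
GPS_FLEE_SLOPE = 0.05  # m/s; range opening faster than this indicates fleeing


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting rule)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class WindowPair:
    """Pre-exposure control window and exposure window, equal length."""

    pre: tuple[float, float]
    exposure: tuple[float, float]

    @property
    def length(self) -> float:
        return self.exposure[1] - self.exposure[0]


def make_window_pair(
    exposure_start: float,
    exposure_end: float,
    record_duration: float,
    max_window: float = MAX_WINDOW,
) -> WindowPair:
    """Build the pre/exposure pair, shrinking both windows together.

    The window length is the smallest of: ``max_window``, the exposure
    duration, the record before the exposure, and the record covering
    the exposure.
    """
    if exposure_start <= 0 or exposure_start >= record_duration:
        raise ValueError("exposure window missing from the record")
    length = min(
        max_window,
        exposure_end - exposure_start,
        exposure_start,
        record_duration - exposure_start,
    )
    if length <= 0:
        raise ValueError("no usable comparison window")
    return WindowPair(
        pre=(exposure_start - length, exposure_start),
        exposure=(exposure_start, exposure_start + length),
    )


def percent_change(pre: float, post: float) -> Optional[int]:
    """100 * (post - pre) / pre, rounded to the nearest integer.

    ``None`` (undefined) when the baseline is zero.
    """
    if pre == 0:
        return None
    return round_half_away(100.0 * (post - pre) / pre)


def db_change(pre_db: Optional[float], post_db: Optional[float]) -> Optional[float]:
    """dB difference post - pre (never percent-changed), one decimal."""
    if pre_db is None or post_db is None:
        return None
    return round(post_db - pre_db, 1)


def flight_flag(
    pings: list[PingDetection],
    track: Optional[TrackEstimate] = None,
    source: Optional[tuple[float, float]] = None,
    window: Optional[tuple[float, float]] = None,
    rl_slope_gate: float = RL_FLEE_SLOPE,
    gps_slope_gate: float = GPS_FLEE_SLOPE,
) -> dict:
    """Did the animal increase distance to the source during exposure?

    Two independent indicators, both reported: a robust (Theil-Sen)
    declining trend of received level over time, and — when a track is
    available — a positive trend of GPS range to the source.  The
    combined ``fled`` is true when either defined indicator says so.
    """
    accepted = [p for p in pings if p.accepted]
    if window is not None:
        accepted = [p for p in accepted if window[0] <= p.time < window[1]]
    fled_rl: Optional[bool] = None
    rl_slope = None
    if len(accepted) >= 10:
        t_min = np.array([p.time for p in accepted]) / 60.0
        rl = np.array([p.rl_rms_fast for p in accepted])
        rl_slope = float(theilslopes(rl, t_min)[0])
        fled_rl = rl_slope < rl_slope_gate

    fled_gps: Optional[bool] = None
    gps_slope = None
    if track is not None and source is not None:
        fixes = track.kept_fixes()
        if window is not None:
            fixes = [f for f in fixes if window[0] <= f.time <= window[1]]
        if len(fixes) >= 3:
            t = np.array([f.time for f in fixes])
            r = np.array([tracking.range_to_source(f, *source) for f in fixes])
            gps_slope = float(theilslopes(r, t)[0])
            fled_gps = gps_slope > gps_slope_gate

    defined = [v for v in (fled_rl, fled_gps) if v is not None]
    fled = any(defined) if defined else None
    return {
        "fled": fled,
        "fled_rl": fled_rl,
        "rl_slope_db_per_min": rl_slope,
        "fled_gps": fled_gps,
        "gps_range_slope_m_per_s": gps_slope,
    }


@dataclass
class ResponseRow:
    """One animal's acute-exposure response cells (the table row)."""

    deployment_id: str
    startle: Optional[bool] = None
    crypsis_diff: Optional[int] = None  # percentage points
    click_rate_change: Optional[int] = None  # %
    click_level_change: Optional[float] = None  # dB, 95th percentiles
    msa_change: Optional[int] = None  # %, 5-s-bin effort basis
    fled: Optional[bool] = None
    resp_rate_change: Optional[int] = None  # %
    tts_risk: Optional[bool] = None
    speed_change: Optional[int] = None  # %, GPS leg speeds (not an index cell)
    provenance: dict = field(default_factory=dict)


_FLAG_CELLS = ("startle", "fled", "tts_risk")
_NUMERIC_CELLS = ("crypsis_diff", "click_rate_change", "click_level_change",
                  "msa_change", "resp_rate_change")


def response_index(row: ResponseRow, threshold: float = INDEX_THRESHOLD) -> int:
    """Count of responses irrespective of direction (undefined cells skipped)."""
    count = 0
    for name in _FLAG_CELLS:
        if getattr(row, name) is True:
            count += 1
    for name in _NUMERIC_CELLS:
        v = getattr(row, name)
        if v is not None and abs(v) >= threshold:
            count += 1
    return count


def index_from_cells(cells: dict, threshold: float = INDEX_THRESHOLD) -> int:
    """Response index straight from a dict of published-style cell values."""
    row = ResponseRow(deployment_id=cells.get("id", "?"))
    for name in _FLAG_CELLS + _NUMERIC_CELLS:
        if name in cells:
            setattr(row, name, cells[name])
    return response_index(row, threshold)


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass
class DeploymentAnalysis:
    """All stage outputs for one deployment, plus the assembled row."""

    windows: WindowPair
    pings: list[PingDetection]
    dose: ExposureDose
    startle_calls: list
    clicks: Optional[list]
    buzzes: list
    effort: object  # TimeSeries of 5-s-bin MSA 95th percentiles
    dives: list
    seafloor: object
    respirations: list
    fh: Optional[object]
    track: Optional[TrackEstimate]
    flight: dict
    row: ResponseRow


def _mean_in(ts, window: tuple[float, float]) -> float:
    t = ts.times()
    sel = (t >= window[0]) & (t < window[1])
    return float(ts.data[sel].mean()) if sel.any() else float("nan")


def analyze_deployment(
    dep: SensorDeployment,
    index_threshold: float = INDEX_THRESHOLD,
    ping_times: Optional[list[float]] = None,
) -> DeploymentAnalysis:
    """Run the full pipeline on one deployment and assemble its row.

    ``ping_times`` may supply manual ping marks, bypassing the detector.
    The analysis is deterministic: re-running on the same deployment
    reproduces the row bit-identically.
    """
    meta = dep.exposure
    windows = make_window_pair(meta.exposure_start, meta.exposure_end, dep.duration)
    prov = {"windows": windows}

    # dosimetry
    pings = acoustics.analyze_pings(dep.audio, meta, ping_times=ping_times)
    exp_pings = [p for p in pings if windows.exposure[0] <= p.time < windows.exposure[1]]
    dose = acoustics.cumulate_sel(exp_pings)
    prov["tts"] = f"SELcum over {len(dose.pings)} accepted pings in exposure window"

    # movement
    jerk = kinematics.compute_jerk(dep.accel)
    msa = kinematics.compute_msa(dep.accel)
    effort = kinematics.swimming_effort(msa)
    accepted_times = [p.time for p in exp_pings if p.accepted]
    startle_calls = kinematics.detect_startle(jerk, accepted_times[:5])
    startled = any(c.startled for c in startle_calls if c.evaluable) if startle_calls else None
    prov["startle"] = "any jerk peak > baseline+3sd within 0.2 s of first 5 accepted pings"

    msa_pre = _mean_in(effort, windows.pre)
    msa_exp = _mean_in(effort, windows.exposure)
    msa_change = percent_change(msa_pre, msa_exp) if np.isfinite(msa_pre) else None

    # echolocation (undefined on mid-frequency tags)
    clicks = None
    rate_change = None
    level_change = None
    try:
        hp = echolocation.highpass_clicks(dep.audio)
        clicks = echolocation.detect_clicks(hp)
    except echolocation.SamplingRateError:
        prov["clicks"] = "undefined: sampling rate too low for NBHF clicks"
    if clicks is not None:
        rate_pre = echolocation.click_rate(clicks, windows.pre)
        rate_exp = echolocation.click_rate(clicks, windows.exposure)
        rate_change = percent_change(rate_pre, rate_exp)
        level_change = db_change(
            echolocation.level_percentile(clicks, windows.pre),
            echolocation.level_percentile(clicks, windows.exposure),
        )
        prov["clicks"] = f"{len(clicks)} detections; rates {rate_pre:.1f}->{rate_exp:.1f} cpm"
    buzzes = echolocation.detect_buzzes(clicks, jerk) if clicks else []

    # dive / crypsis / respiration
    dives = dive.segment_dives(dep.depth)
    seafloor = dive.estimate_seafloor(dives)
    cr_pre = dive.crypsis_fraction(dep.depth, seafloor, windows.pre)
    cr_exp = dive.crypsis_fraction(dep.depth, seafloor, windows.exposure)
    crypsis_diff = round_half_away(100.0 * (cr_exp - cr_pre))
    prov["crypsis"] = f"seafloor source: {seafloor.source}"

    respirations = dive.detect_respirations(dep.audio, dep.depth)
    resp_pre = dive.respiration_rate(respirations, windows.pre)
    resp_exp = dive.respiration_rate(respirations, windows.exposure)
    resp_change = percent_change(resp_pre, resp_exp)

    # cardiac
    fh = None
    if dep.ecg is not None:
        filtered = cardiac.preprocess_ecg(dep.ecg)
        fh = cardiac.instantaneous_fh(cardiac.detect_r_peaks(filtered))

    # track + flight
    track = None
    speed_chg = None
    if len(dep.gps) >= 2:
        track = tracking.leg_speeds(dep.gps)
        pre_legs = [(t, s) for t, s in zip(track.leg_times, track.speeds)
                    if windows.pre[0] <= t < windows.pre[1]]
        exp_legs = [(t, s) for t, s in zip(track.leg_times, track.speeds)
                    if windows.exposure[0] <= t < windows.exposure[1]]
        if pre_legs and exp_legs:
            speed_chg = percent_change(
                float(np.mean([s for _, s in pre_legs])),
                float(np.mean([s for _, s in exp_legs])),
            )
    flight = flight_flag(
        pings, track, (meta.ahd_lat, meta.ahd_lon), window=windows.exposure
    )

    row = ResponseRow(
        deployment_id=dep.deployment_id,
        startle=startled,
        crypsis_diff=crypsis_diff,
        click_rate_change=rate_change,
        click_level_change=level_change,
        msa_change=msa_change,
        fled=flight["fled"],
        resp_rate_change=resp_change,
        tts_risk=dose.tts_risk,
        speed_change=speed_chg,
        provenance=prov,
    )
    return DeploymentAnalysis(
        windows=windows,
        pings=pings,
        dose=dose,
        startle_calls=startle_calls,
        clicks=clicks,
        buzzes=buzzes,
        effort=effort,
        dives=dives,
        seafloor=seafloor,
        respirations=respirations,
        fh=fh,
        track=track,
        flight=flight,
        row=row,
    )


def build_response_table(rows: list[ResponseRow], threshold: float = INDEX_THRESHOLD) -> pd.DataFrame:
    """Assemble rows into the per-animal response table (None -> "-")."""
    records = []
    for row in rows:
        rec = {
            "id": row.deployment_id,
            "response_index": response_index(row, threshold),
            "startle": row.startle,
            "crypsis_diff_points": row.crypsis_diff,
            "click_rate_change_pct": row.click_rate_change,
            "click_level_change_db": row.click_level_change,
            "msa_change_pct": row.msa_change,
            "fled": row.fled,
            "resp_rate_change_pct": row.resp_rate_change,
            "tts_risk": row.tts_risk,
        }
        records.append(rec)
    df = pd.DataFrame(records)
    return df.where(pd.notna(df), other="-")


@dataclass
class GroupSummary:
    """Arithmetic means over the defined animal subsets."""

    mean_msa_change_fleeing: Optional[int]  # % over fleeing animals
    mean_speed_change: Optional[int]  # % over GPS animals
    mean_click_rate_decrease: Optional[int]  # % over rate-decreasing animals
    mean_crypsis_diff: Optional[int]  # points over all defined


def summarize_group(
    rows: list[ResponseRow], speed_changes: Optional[list[float]] = None
) -> GroupSummary:
    """Group means mirroring the designated subsets.

    MSA over fleeing animals; click-rate decrease over animals whose rate
    decreased (reported as a positive decrease); speed over the GPS
    subset (``speed_changes`` overrides the rows); crypsis over all
    animals with a defined cell.
    """

    def mean_or_none(vals: list[float]) -> Optional[int]:
        return round_half_away(float(np.mean(vals))) if vals else None

    msa_vals = [r.msa_change for r in rows if r.fled and r.msa_change is not None]
    rate_vals = [
        -r.click_rate_change
        for r in rows
        if r.click_rate_change is not None and r.click_rate_change < 0
    ]
    crypsis_vals = [r.crypsis_diff for r in rows if r.crypsis_diff is not None]
    if speed_changes is None:
        speed_changes = [r.speed_change for r in rows if r.speed_change is not None]
    return GroupSummary(
        mean_msa_change_fleeing=mean_or_none(msa_vals),
        mean_speed_change=mean_or_none(list(speed_changes)),
        mean_click_rate_decrease=mean_or_none(rate_vals),
        mean_crypsis_diff=mean_or_none(crypsis_vals),
    )
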