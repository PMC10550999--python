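"""Pre-built synthetic scenarios: the response battery and recovery setups.

The six-scenario battery mirrors the direction pattern of the published
per-animal response table: which animals startled, fled, suppressed or
raised their click rates, changed crypsis or respiration, and which came
close to the TTS dose — each programmed decisively so that sign/flag
recovery is a meaningful end-to-end check rather than a coin flip.

Problem sizes are scaled down from the full study design (90-s
comparison windows instead of 15 min, 0.6-6 s ping intervals, 20-30 s
GPS fixes) so the battery runs in minutes; window logic is identical
because pre/exposure windows shrink together.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import analysis
from .synthetic import (
    AhdConfig,
    ClickConfig,
    DiveConfig,
    DivePhase,
    EcgConfig,
    NoiseConfig,
    RespirationConfig,
    ScenarioConfig,
    StartleConfig,
    TrackConfig,
    TrackLeg,
    generate_deployment,
)

BATTERY_DURATION = 200.0
BATTERY_EXPOSURE = (90.0, 180.0)
_PING_FAST = AhdConfig(interval_range=(0.6, 6.0))

# dive-phase building blocks
_SURFACE_HEAVY = DivePhase(0.0, max_depth=6.0, period=45.0, surface_fraction=0.7,
                           bottom_fraction=0.1)
_MIDWATER_V = DivePhase(0.0, max_depth=12.0, period=45.0, surface_fraction=0.3,
                        bottom_fraction=0.1)
_TRANSIT_SHALLOW = DivePhase(0.0, max_depth=10.0, period=45.0, surface_fraction=0.1,
                             bottom_fraction=0.15)
_SEAFLOOR_U = DivePhase(0.0, max_depth=29.0, period=90.0, surface_fraction=0.08,
                        bottom_fraction=0.7)


def _at(phase: DivePhase, t: float) -> DivePhase:
    return replace(phase, t_start=t)


def _clicks(rate_pre: float, rate_exp: float, level_pre: float = 150.0,
            level_exp: float = 150.0, buzz_pre: float = 1.5, buzz_exp: float = 0.5
            ) -> ClickConfig:
    t_on = BATTERY_EXPOSURE[0]
    return ClickConfig(
        rate_schedule=((0.0, rate_pre), (t_on, rate_exp)),
        level_schedule=((0.0, level_pre), (t_on, level_exp)),
        buzz_rate_schedule=((0.0, buzz_pre), (t_on, buzz_exp)),
    )


def _resp(pre: float, exp: float) -> RespirationConfig:
    return RespirationConfig(rate_schedule=((0.0, pre), (BATTERY_EXPOSURE[0], exp)))


def _flee(pre_speed: float, exp_speed: float, heading=None) -> TrackConfig:
    return TrackConfig(
        start_range_m=0.0,  # overridden per scenario
        legs=(
            TrackLeg(0.0, pre_speed, heading),
            TrackLeg(BATTERY_EXPOSURE[0], exp_speed, heading),
        ),
    )


def battery_configs(seed: int) -> list[tuple[str, ScenarioConfig, dict]]:
    """The six scenarios plus the programmed direction pattern of each.

    Expected cells: flags as bools; numeric cells as +1/-1 (programmed
    direction), 0 (programmed null — not asserted) or None (undefined by
    tag hardware).
    """
    base = dict(
        duration=BATTERY_DURATION,
        exposure_start=BATTERY_EXPOSURE[0],
        exposure_end=BATTERY_EXPOSURE[1],
        ahd=_PING_FAST,
        gps_interval=(20.0, 30.0),
    )
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)

    scenarios = []
    # fleeing + startling animal close to the source: click suppression with
    # level reduction, less crypsis (open-water transit), fewer breaths
    cfg1 = ScenarioConfig(
        seed=int(seeds[0]), **base,
        track=replace(_flee(1.3, 1.8), start_range_m=600.0),
        dive=DiveConfig(phases=(_at(_SURFACE_HEAVY, 0.0),
                                _at(_TRANSIT_SHALLOW, BATTERY_EXPOSURE[0]))),
        clicks=_clicks(40.0, 16.0, level_exp=142.0),
        respiration=_resp(5.0, 2.0),
        startle=StartleConfig(enabled=True),
    )
    scenarios.append(("S1", cfg1, dict(startle=True, fled=True, tts=True, crypsis=-1,
                                       click_rate=-1, click_level=-1, msa=+1, resp=-1)))

    # startling ECG animal: click rate up, crypsis up, respiration unchanged
    cfg2 = ScenarioConfig(
        seed=int(seeds[1]), **{**base, "gps_interval": None},
        track=replace(_flee(1.0, 1.5), start_range_m=600.0),
        dive=DiveConfig(phases=(_at(_MIDWATER_V, 0.0),
                                _at(_SURFACE_HEAVY, BATTERY_EXPOSURE[0]))),
        clicks=_clicks(15.0, 60.0),
        respiration=_resp(4.0, 4.0),
        startle=StartleConfig(enabled=True),
        ecg=EcgConfig(enabled=True, fh_schedule=((0.0, 85.0), (90.0, 85.0),
                                                 (100.0, 150.0), (112.0, 85.0),
                                                 (200.0, 85.0))),
    )
    scenarios.append(("S2", cfg2, dict(startle=True, fled=True, tts=True, crypsis=+1,
                                       click_rate=+1, click_level=0, msa=+1, resp=0)))

    # startling animal that stops clicking almost entirely, breathes more
    cfg3 = ScenarioConfig(
        seed=int(seeds[2]), **base,
        track=replace(_flee(1.4, 1.8), start_range_m=650.0),
        dive=DiveConfig(phases=(_at(_MIDWATER_V, 0.0),
                                _at(_SURFACE_HEAVY, BATTERY_EXPOSURE[0]))),
        clicks=_clicks(40.0, 0.5),
        respiration=_resp(2.5, 6.0),
        startle=StartleConfig(enabled=True),
    )
    scenarios.append(("S3", cfg3, dict(startle=True, fled=True, tts=True, crypsis=+1,
                                       click_rate=-1, click_level=0, msa=+1, resp=+1)))

    # non-fleeing, non-startling ECG animal at long range: quiet descent to
    # the seafloor (crypsis up, effort down), bradycardia, fewer breaths
    cfg4 = ScenarioConfig(
        seed=int(seeds[3]), **{**base, "gps_interval": None},
        track=replace(_flee(1.0, 0.6, heading=90.0), start_range_m=3000.0),
        dive=DiveConfig(phases=(_at(_MIDWATER_V, 0.0),
                                _at(_SEAFLOOR_U, BATTERY_EXPOSURE[0]))),
        clicks=_clicks(40.0, 16.0),
        respiration=_resp(6.0, 1.5),
        startle=StartleConfig(enabled=False),
        ecg=EcgConfig(enabled=True, fh_schedule=((0.0, 110.0), (90.0, 110.0),
                                                 (120.0, 60.0), (200.0, 60.0))),
    )
    scenarios.append(("S4", cfg4, dict(startle=False, fled=False, tts=False, crypsis=+1,
                                       click_rate=-1, click_level=0, msa=-1, resp=-1)))

    # distant animal that flees without startling; click suppression with
    # level reduction
    cfg5 = ScenarioConfig(
        seed=int(seeds[4]), **base,
        track=replace(_flee(1.3, 1.9), start_range_m=5000.0),
        dive=DiveConfig(phases=(_at(_MIDWATER_V, 0.0),
                                _at(_SURFACE_HEAVY, BATTERY_EXPOSURE[0]))),
        clicks=_clicks(40.0, 18.0, level_exp=142.0),
        respiration=_resp(3.0, 3.0),
        startle=StartleConfig(enabled=False),
    )
    scenarios.append(("S5", cfg5, dict(startle=False, fled=True, tts=False, crypsis=+1,
                                       click_rate=-1, click_level=-1, msa=+1, resp=0)))

    # mid-frequency tag: clicks unresolvable (undefined cells), startles and
    # flees near the surface
    cfg6 = ScenarioConfig(
        seed=int(seeds[5]), **{**base, "gps_interval": None},
        fs_audio=240_000.0,
        track=replace(_flee(1.0, 1.5), start_range_m=2000.0),
        dive=DiveConfig(phases=(_at(_MIDWATER_V, 0.0),
                                _at(_SEAFLOOR_U, BATTERY_EXPOSURE[0]))),
        clicks=None,
        respiration=_resp(6.0, 1.5),
        startle=StartleConfig(enabled=True),
    )
    scenarios.append(("S6", cfg6, dict(startle=True, fled=True, tts=False, crypsis=+1,
                                       click_rate=None, click_level=None, msa=+1, resp=-1)))
    return scenarios


def evaluate_battery(seed: int) -> tuple[list, "np.ndarray", list[dict]]:
    """Run the pipeline on the battery; compare against programmed directions.

    Returns ``(rows, agreement_flags, details)`` where ``agreement_flags``
    is one boolean per asserted cell across all scenarios and ``details``
    records per-scenario outcomes.
    """
    rows = []
    flags: list[bool] = []
    details: list[dict] = []
    for name, cfg, expected in battery_configs(seed):
        dep, truth = generate_deployment(cfg)
        result = analysis.analyze_deployment(dep)
        row = result.row
        row.deployment_id = name
        rows.append(row)

        checks: dict[str, bool] = {}

        def sign_ok(value, programmed) -> bool | None:
            if programmed is None:
                return value is None
            if programmed == 0:
                return None  # programmed null: not asserted
            return value is not None and np.sign(value) == programmed

        checks["startle"] = row.startle == expected["startle"]
        checks["fled"] = row.fled == expected["fled"]
        checks["tts"] = row.tts_risk == expected["tts"]
        for cell, attr in (("crypsis", "crypsis_diff"), ("click_rate", "click_rate_change"),
                           ("click_level", "click_level_change"), ("msa", "msa_change"),
                           ("resp", "resp_rate_change")):
            ok = sign_ok(getattr(row, attr), expected[cell])
            if ok is not None:
                checks[cell] = ok
        flags.extend(checks.values())
        details.append({"scenario": name, **checks})
    return rows, np.array(flags, dtype=bool), details


# ---------------------------------------------------------------------------
# single-purpose recovery scenarios


def ping_recovery_config(seed: int, start_range_m: float = 800.0,
                         exp_speed: float = 1.5) -> ScenarioConfig:
    """Receding animal, pings only, modest audio rate: dosimetry recovery."""
    return ScenarioConfig(
        seed=seed,
        duration=120.0,
        exposure_start=10.0,
        exposure_end=110.0,
        fs_audio=120_000.0,
        ahd=AhdConfig(interval_range=(0.6, 4.0)),
        track=TrackConfig(start_range_m=start_range_m,
                          legs=(TrackLeg(0.0, exp_speed),)),
        clicks=None,
        startle=StartleConfig(enabled=False),
        respiration=RespirationConfig(rate_schedule=((0.0, 0.0),)),
        gps_interval=None,
    )


def ecg_recovery_config(seed: int, fh_schedule, duration: float = 120.0) -> ScenarioConfig:
    """ECG-only scenario (acoustics disabled) for R-peak / fH recovery."""
    return ScenarioConfig(
        seed=seed,
        duration=duration,
        exposure_start=10.0,
        exposure_end=duration - 10.0,
        fs_audio=4000.0,
        ahd=AhdConfig(enabled=False),
        clicks=None,
        startle=StartleConfig(enabled=False),
        respiration=RespirationConfig(rate_schedule=((0.0, 0.0),)),
        ecg=EcgConfig(enabled=True, fh_schedule=tuple(fh_schedule)),
        gps_interval=None,
    )


def quiet_kinematics_config(seed: int, duration: float = 600.0,
                            speed: float = 1.4) -> ScenarioConfig:
    """Flinch-free swimming at constant speed: startle false-positive floor."""
    return ScenarioConfig(
        seed=seed,
        duration=duration,
        exposure_start=10.0,
        exposure_end=duration - 10.0,
        fs_audio=2000.0,
        ahd=AhdConfig(enabled=False),
        track=TrackConfig(start_range_m=1000.0, legs=(TrackLeg(0.0, speed),)),
        clicks=None,
        startle=StartleConfig(enabled=False),
        respiration=RespirationConfig(rate_schedule=((0.0, 0.0),)),
        gps_interval=None,
    )


def flight_recovery_config(seed: int) -> ScenarioConfig:
    """Long GPS-only scenario at full-design fix cadence for speed recovery."""
    return ScenarioConfig(
        seed=seed,
        duration=1800.0,
        exposure_start=900.0,
        exposure_end=1800.0,
        fs_audio=2000.0,
        ahd=AhdConfig(enabled=False),
        clicks=None,
        startle=StartleConfig(enabled=False),
        respiration=RespirationConfig(rate_schedule=((0.0, 0.0),)),
        gps_interval=(180.0, 300.0),
    )
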