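"""Shared fixtures: expensive synthetic deployments built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ahdtag import acoustics, cardiac
from ahdtag.scenarios import (
    ecg_recovery_config,
    evaluate_battery,
    ping_recovery_config,
)
from ahdtag.synthetic import ScenarioConfig, generate_deployment


@pytest.fixture(scope="session")
def ping_recovery():
    """Receding-animal, pings-only deployment plus its measured pings."""
    dep, truth = generate_deployment(ping_recovery_config(seed=11))
    pings = acoustics.analyze_pings(dep.audio, dep.exposure)
    return dep, truth, pings


@pytest.fixture(scope="session")
def ecg_ramp():
    """ECG deployment with a 50 -> 180 bpm programmed ramp."""
    cfg = ecg_recovery_config(seed=21, fh_schedule=[(0.0, 50.0), (120.0, 180.0)])
    dep, truth = generate_deployment(cfg)
    filtered = cardiac.preprocess_ecg(dep.ecg)
    r_times = np.array(cardiac.detect_r_peaks(filtered))
    return dep, truth, r_times


@pytest.fixture(scope="session")
def battery():
    """The six-scenario response battery, run once for the whole session."""
    return evaluate_battery(seed=1)


@pytest.fixture()
def small_scenario_config():
    """A cheap short scenario with every stream enabled (low audio rate)."""
    from ahdtag.synthetic import AhdConfig, EcgConfig, StartleConfig

    return ScenarioConfig(
        seed=5,
        duration=60.0,
        exposure_start=20.0,
        exposure_end=50.0,
        fs_audio=4000.0,
        ahd=AhdConfig(enabled=False),
        clicks=None,
        startle=StartleConfig(enabled=False),
        ecg=EcgConfig(enabled=True, fh_schedule=((0.0, 90.0),)),
        gps_interval=(10.0, 15.0),
    )
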