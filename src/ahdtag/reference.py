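"""Published per-animal results from the tagging study this pipeline models.

Six wild harbour porpoises (HP1-HP6) were tagged and exposed for 15 min
to a commercial 14-kHz acoustic harassment device.  The study's
response-table cells and a handful of printed scalar pairs are carried
here as *inputs*: the group summaries, physiology arithmetic and
impact-zone calculations recompute the derived numbers from these
cells.  Raw tag recordings were not deposited, so the cells are the
only bridge between the synthetic-deployment pipeline and the study's
per-animal results.

Cell conventions match :mod:`ahdtag.analysis`: percent / percentage
point / dB values, flags as booleans, ``None`` for cells the study
could not evaluate (e.g. click metrics on the mid-frequency tag of
HP6).
"""

from __future__ import annotations

# Per-animal acute response cells (15-min exposure vs 15 min before).
RESPONSE_CELLS: dict[str, dict] = {
    "HP1": {"startle": True, "crypsis_diff": -2, "click_rate_change": -39,
            "click_level_change": -8.0, "msa_change": 17, "fled": True,
            "resp_rate_change": -11, "tts_risk": True},
    "HP2": {"startle": True, "crypsis_diff": 33, "click_rate_change": 690,
            "click_level_change": -1.0, "msa_change": 25, "fled": True,
            "resp_rate_change": 5, "tts_risk": True},
    "HP3": {"startle": True, "crypsis_diff": 8, "click_rate_change": -98,
            "click_level_change": -1.0, "msa_change": 32, "fled": True,
            "resp_rate_change": 31, "tts_risk": True},
    "HP4": {"startle": False, "crypsis_diff": 10, "click_rate_change": -27,
            "click_level_change": -2.0, "msa_change": -31, "fled": False,
            "resp_rate_change": -15, "tts_risk": False},
    "HP5": {"startle": False, "crypsis_diff": 15, "click_rate_change": -53,
            "click_level_change": -8.0, "msa_change": 75, "fled": True,
            "resp_rate_change": 4, "tts_risk": False},
    "HP6": {"startle": True, "crypsis_diff": 26, "click_rate_change": None,
            "click_level_change": None, "msa_change": 141, "fled": True,
            "resp_rate_change": -13, "tts_risk": False},
}

# Published per-animal response indices (count of responses, any direction).
RESPONSE_INDICES = {"HP1": 7, "HP2": 6, "HP3": 7, "HP4": 4, "HP5": 5, "HP6": 5}

# GPS horizontal travel speed increases (%), the three GPS-tag animals.
SPEED_INCREASES_PCT = {"HP1": 5, "HP3": 30, "HP5": 43}

# Printed physiology pairs (pre, exposure) behind the percent arithmetic.
TACHYCARDIA_BPM = (83.0, 153.0)  # HP2 diving heart rate excursion
TACHYCARDIA_BPM_2 = (57.0, 174.0)  # HP2 second excursion
RESP_RATE_HP3 = (3.2, 4.2)  # breaths/min
RESP_RATE_HP4 = (3.9, 3.3)  # breaths/min
MIN_INSTANTANEOUS_FH = 39.0  # beats/min, HP4 floor (RR ~ 1.54 s)

# Impact-zone inputs: TTS-risk radii (km) at full source level for two
# exposure sites, and the deterrence source levels under comparison.
TTS_RADIUS_KM = {"HP1": 0.9, "HP3": 2.2}
AHD_SOURCE_LEVEL = 189.0  # dB re 1 uPa rms @ 1 m
FULL_SL = 190.0  # round figure used in the mitigation arithmetic
REDUCED_SL = 164.0  # dB; the proposed 26-dB reduction
RESPONSE_RL_THRESHOLD = 100.0  # dB re 1 uPa; consistent flight threshold
TTS_THRESHOLD_SEL = 142.0  # dB re 1 uPa^2 s, single pulse

# Behavioural-audiometry inputs for the predicted response threshold.
HEARING_THRESHOLD_14KHZ = 50.0  # dB re 1 uPa rms
SENSATION_LEVEL_RESPONSE = 45.0  # dB above hearing threshold
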