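# ahdtag

Analysis pipeline for multi-sensor biologging tags (DTAG-style) on harbour
porpoises exposed to an Acoustic Harassment Device (AHD, "seal scarer"): a
14-kHz source transmitting 500-ms pings at randomized 0.6–90 s intervals
with a source level of 189 dB re 1 µPa (rms) @ 1 m. The package quantifies,
per animal, the acute behavioural and physiological response to a 15-min
exposure relative to the 15 min immediately before it, and models how far
such responses — and the risk of temporary hearing threshold shift (TTS) —
extend from the source.

It is written for marine bioacousticians and biologging analysts. Because
raw tag recordings from AHD exposure studies are rarely deposited, the
package ships a first-class synthetic-deployment generator with complete
ground truth, so every detector and estimator is validated by recovery
tests rather than by eye.

## What it computes

**Acoustic dosimetry** (`ahdtag.acoustics`). Audio is band-passed 10–46 kHz
(6-pole Butterworth, retaining the 28/42 kHz harmonics), pings detected from
the 12–16 kHz envelope, and each ping measured as

- rms-fast received level: `RL = 20·log10(max_w rms_125ms(p) / 1 µPa)`,
  the maximum over 125-ms windows slid across the ping;
- single-ping sound exposure level: `SEL = 10·log10(∫₀^0.5s p² dt / 1 µPa²s)`;
- cumulative dose: `SELcum(k) = 10·log10(Σ_{i≤k} 10^{SEL_i/10})` (non-leaky),
  flagged against the single-pulse TTS onset of 142 dB re 1 µPa²s.

Pings are screened at SNR > 10 dB against the 125 ms of band noise before
onset.

**Echolocation** (`ahdtag.echolocation`). NBHF clicks (~130 kHz) are
detected on 80-kHz high-passed audio; apparent output level is peak-to-peak
pressure in a 20-ms segment (dB re 1 µPa pp, 95th percentiles compared
across windows); feeding buzzes are click runs with inter-click intervals
< 15 ms confirmed by a jerk transient; the 5th buzz after an event marks
resumption of feeding.

**Kinematics** (`ahdtag.kinematics`). MSA = |‖a‖ − g| on 25-Hz decimated
acceleration; swimming effort = 95th percentile of MSA per 5-s bin;
jerk = ‖Δa‖·25 Hz; an acoustic startle is a jerk peak above baseline
mean + 3 s.d. within 0.2 s of ping arrival.

**Dives and crypsis** (`ahdtag.dive`). Dive segmentation with U/V shape
classes, apparent seafloor from U-dive depths (or bathymetry + GPS), visual
crypsis = time within 2 m of the surface or seafloor, and respiration
detection gated to depth ≤ 1 m.

**Cardiac** (`ahdtag.cardiac`). ECG → 250 Hz, 1–10 Hz band-pass, adaptive
R-peak detection with sub-sample refinement; instantaneous heart rate
f_H = 60/RR.

**Tracking and propagation** (`ahdtag.tracking`). Geodesic leg speeds with
a 5 m/s outlier gate; transmission loss `TL(R) = k·log10(R) + α·R/1000`
(spherical k = 20 or cylindrical k = 10; α in dB/km), received level
`RL = SL − TL(R)`, effect-range inversion and impact-area ratios
`(r₁/r₂)²`.

**Response table** (`ahdtag.analysis`). Per-animal cells (startle, crypsis,
click rate and level, swimming effort, flight, respiration, TTS risk) and a
response index counting responses irrespective of direction (|change| ≥ 8 %
/ points / dB; flags when true).

## Worked example

```python
from ahdtag.tracking import (PropagationModel, transmission_loss,
                             received_level, solve_effect_range,
                             impact_area_ratio)

sph = PropagationModel("spherical", absorption_db_per_km=1.5)
print(round(transmission_loss(1000.0, sph)))          # 62  (dB at 1 km)
print(164.0 - round(transmission_loss(1000.0, sph)))  # 102.0 (dB re 1 µPa)
r190 = solve_effect_range(190.0, 100.0, sph)          # 7980 m
r164 = solve_effect_range(164.0, 100.0, sph)          # 1270 m
print(round(100 * impact_area_ratio(r164, r190), 1))  # 2.5 (% of area left)
```

A 164 dB source still delivers ~102 dB re 1 µPa at the 1-km mitigation
radius — above the ~95 dB predicted response threshold (50 dB hearing
threshold + 45 dB sensation level) — while shrinking the ensonified area to
a few percent of the 190-dB case.

End-to-end, on a synthetic deployment battery mirroring a six-animal
exposure design, `analysis/05_response_table.py` prints (seed 1):

```
id  response_index  startle  crypsis_diff_points click_rate_change_pct ...
S1               8     True                  -54                 -70.0
S2               7     True                   39                  53.0
...
programmed-direction agreement: 100% (43/43 cells)
```

i.e. every programmed flag and direction (startle, flight, click
suppression, crypsis, respiration, TTS proximity) is recovered by the
pipeline from raw synthetic waveforms.

The numbered scripts under `analysis/` walk the full workflow: simulate
deployments (01), dosimetry (02), behaviour metrics (03), cardiac response
(04), the response table (05) and impact-zone modelling (06). Each writes
its tables under `results/`.

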