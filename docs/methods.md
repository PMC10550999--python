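# Methods

This note documents the models, parameter choices and numerical
conventions behind the `ahdtag` pipeline, and what its synthetic-data
validation does and does not demonstrate.

## Analysis windows

The acute comparison is exposure vs. an equal-length control window
immediately before exposure start. The full design uses 15-min windows;
when the exposure or the pre-exposure record is shorter, both windows
shrink together to the largest common length, so pre and exposure are
always directly comparable. All times are seconds from deployment start;
GPS/UTC is converted on read.

## Acoustic dosimetry

Audio is held internally in pascal; a full-scale sample equals the tag
clip level (default 175 dB re 1 µPa, peak). All dB conversions go through
one helper pair against the 1 µPa reference.

* **Band-pass** 10–46 kHz, 6-pole Butterworth. Zero-phase
  (forward-backward) filtering is used for level measurement to avoid
  group-delay level bias; detection uses the causal filter so onsets stay
  causally ordered.
* **Detection** thresholds the rectified 12–16 kHz sub-band envelope
  (5-ms smoothing window) at the envelope noise median + 10 dB, with a
  0.5-s minimum gap (the minimum source interval is 0.6 s) and a 50-ms
  minimum crossing to reject transients. Manually marked ping times can
  replace the detector.
* **rms-fast RL** is the maximum over 125-ms windows slid (5-ms step)
  across [onset − 50 ms, onset + 550 ms]. Max-hold placement was chosen
  over onset anchoring because it is insensitive to small onset errors
  and to energy smeared by multipath; the onset-anchored variant remains
  available (`mode="onset"`).
* **SEL** integrates p² over 500 ms from onset (the emitted ping
  duration), even when reverberation stretches the received ping; the
  integration window is a parameter for sensitivity analyses. Note the
  source specification itself is slightly over-determined: a 189 dB rms,
  500-ms ping implies a single-ping source SEL of 186 dB re 1 µPa²s,
  whereas 184 is sometimes quoted; the generator synthesizes from the rms
  source level and leaves the 2-dB discrepancy unreconciled.
* **SNR screening**: ping rms vs. the rms of the 125 ms of band-limited
  noise ending 10 ms before onset; accepted strictly above 10 dB. The
  noise window directly precedes the ping rather than abutting it, to
  keep filter ringing out of the estimate.
* **SELcum** is a non-leaky energy sum over accepted pings; auditory
  recovery during the exposure is deliberately ignored, which can only
  overestimate dose. TTS risk is flagged both at outright exceedance of
  the 142 dB re 1 µPa²s single-pulse onset and within a 3-dB margin of it
  ("close to the limit"); both thresholds are parameters.

## Echolocation

Click analysis requires the ~130 kHz NBHF band below Nyquist; the
pipeline refuses audio sampled under 260 kHz (mid-frequency tags) and
suggests buzz-only analysis, mirroring the hardware limitation such tags
have in practice. The supervised click detector of a manual workflow is
replaced by an envelope-peak detector (0.1-ms smoothing, noise median
+ 15 dB, 1-ms dead time) plus an optional accept/reject review list.
Apparent levels are 20-ms peak-to-peak measurements on 80-kHz high-passed
audio and are never compared across deployments, since tag placement
scales them.

Buzzes are maximal runs of ≥ 5 clicks with all ICIs < 15 ms that coincide
(± 1 s) with a jerk exceeding twice the deployment median — the movement
gate separates prey-capture buzzes from social call series. Both the
minimum run and the jerk gate are parameters; 5 clicks and 2× median are
conservative defaults chosen so that isolated mis-detections cannot form
a buzz. Feeding resumption is the 5th buzz strictly after the event, so a
single mis-classified social call cannot move the estimate.

## Kinematics

Acceleration is decimated to 25 Hz (zero-phase 8-pole low-pass at 0.4×
the target rate, then stride sampling). MSA = |‖a‖ − g| with g = 9.81
m/s²; jerk is the norm of the first difference times the rate, which at
25 Hz is the standard discrete surrogate for da/dt. Both are invariant
under any fixed rotation of the tag frame, so tag orientation never needs
to be estimated.

A startle is scored per ping: max jerk in (arrival, arrival + 0.2 s]
above the mean + 3 s.d. of the 10 s preceding the ping. The window is
referenced to arrival at the tag, not emission — at 7 km the acoustic
travel time (~4.7 s) is more than twenty times the startle latency, so
referencing to emission would be meaningless. "Significant peak" is not
standardized; the 3-s.d. gate yields a measured false-positive rate of
0% (≤ 1% required) on flinch-free fluking and is a parameter. Per
exposure, the startle flag summarizes the first five accepted pings. A
coarse tag-slide warning flags > 20° rotations of the windowed mean
specific-force direction; full magnetometer QC is out of scope.

## Dives, crypsis, respiration

Dives are maximal intervals deeper than 0.5 m. Shape: U if the bottom
phase (≥ 85% of max depth) occupies ≥ 50% of the dive, V if ≤ 20%. The
apparent seafloor is the piecewise-linear interpolation of U-dive max
depths over time (held flat beyond the first/last U dive); a bathymetry
grid plus GPS takes precedence when supplied. Visual crypsis is depth
≤ 2 m or within 2 m of the apparent seafloor; the 2-m band is fixed for
the surface and a parameter for the seafloor side.

Respirations are envelope peaks of the 0.1–5 kHz band (audio first
decimated to ~30 kHz for speed), ≥ 2 s apart, accepted only at depth
≤ 1 m. The detector is an automated surrogate for manual spectrogram
marking, and manual marks are first-class input.

## Cardiac

ECG is down-sampled to 250 Hz and band-passed 1–10 Hz (4-pole), which
isolates QRS energy and removes baseline wander. R-peaks are picked above
0.5× the running 5-s envelope maximum with a 0.25-s refractory period
(supports up to 240 beats/min), then refined by parabolic interpolation
around the sample maximum — without the refinement, ±4 ms quantization at
250 Hz alone would approach the 2 bpm error budget at high rates.
f_H = 60/RR is assigned at each interval's end (causal, convenient for
event-locked analysis); a review list of added/removed beats reproduces
the visual-verification step, and removing a beat merges its two RR
intervals. Summaries report per-window 10th/90th percentiles and a 50-s
running median ("diving heart rate").

## Tracking and propagation

Geodesic distances use the flat-earth approximation on WGS84 local radii
of curvature at the mean latitude — at the < 12 km scales of these tracks
the error is sub-centimetre, far below the 5-m GPS noise — implemented
in-package so the pipeline has no geodesy dependency. Leg speeds above
5 m/s (well beyond sustained porpoise speeds) mark the later fix of the
leg erroneous; it is removed and legs re-linked, iterating until clean.
Speeds are reported raw and as running 5-sample means.

Transmission loss is idealized spreading plus linear absorption,
TL(R) = k·log10 R + αR/1000, with spherical (k = 20) or cylindrical
(k = 10) spreading and α defaulting to 1.5 dB/km (mid-frequency seawater
absorption near 14 kHz). Tag data of this kind are well described by the
spherical law at km scales. Effect ranges invert RL(R) = threshold by
bracketed root-finding (Brent, 0.5-m tolerance) on the strictly monotone
TL; the default bracket is 1 m – 100 km, covering all deterrence-relevant
scales (pure cylindrical spreading sheds 90 dB only at unphysical ranges
and needs an explicitly widened bracket). Impact areas compare as
(r₁/r₂)².

## Response table and index

Percent metrics are 100·(post − pre)/pre rounded half-away-from-zero to
integers; dB metrics are differenced (never percent-changed) and kept to
one decimal; crypsis differences are percentage points. Cells that cannot
be evaluated (no clicks resolvable, no ECG, no GPS, zero baseline) are
undefined, rendered "–", and never counted or averaged. The response
index counts flags that are true plus numeric cells with |change| ≥ 8
(% / points / dB). That threshold rule is a *reconstruction*: it is the
simplest magnitude gate consistent with the published per-animal indices
(7, 6, 7, 4, 5, 5, verified in the test suite), and it is exposed as a
parameter rather than presented as ground truth. Group summaries average
over the defined subsets only: swimming effort over fleeing animals,
click-rate decrease over animals whose rate decreased, speed over the
GPS-tagged subset, crypsis over all animals.

## Synthetic deployments

The generator emulates the statistical structure the analysis assumes:

* **Pings**: 14-kHz tone bursts, 500 ms, 5-ms cosine ramps (the fast rise
  time is what makes startle realistic), harmonics at 28/42 kHz at
  −20/−30 dB, intervals uniform in 0.6–90 s, source level 189 dB re 1 µPa
  rms @ 1 m. Received levels follow the configured propagation model at
  the instantaneous animal–source range (sound speed 1500 m/s for travel
  time), so dosimetry has a closed-form truth. An optional exponential
  reverberation tail emulates shallow-water multipath (off by default).
* **Clicks**: Gaussian-enveloped 130-kHz pips, 50 µs — the standard NBHF
  surrogate — calibrated on the realized waveform so the programmed pp
  level is exact. Buzzes are ICI-10 ms click runs with a small
  accompanying acceleration transient. Buzzes are not initiated within
  2 s after a ping arrival (a porpoise interrupts prey capture at a
  startling stimulus), which also keeps buzz transients out of startle
  windows.
* **Movement**: gravity plus a fluking sinusoid (1.4 Hz) whose amplitude
  scales with speed (0.5 m/s² per m/s), startle flinches as 80-ms
  half-sine pulses on all axes, accelerometer noise 0.02 m/s² (quiet,
  mg-level, as for tag-grade MEMS parts).
* **Depth/respiration**: trapezoidal dive cycles over a flat seafloor;
  breaths spaced by the scheduled rate during surface intervals, each
  placing a 0.3-s low-frequency broadband transient in the audio.
* **ECG**: beats integrated from a piecewise-linear instantaneous-rate
  schedule; a stylized QRS (Mexican-hat R wave dominating small P/T
  bumps) suffices because only R timing is used downstream.
* **GPS**: the true track (piecewise speed/heading, optionally "directly
  away from the source") subsampled at 180–300 s with isotropic 5-m
  Gaussian noise.
* **Noise**: white flow noise set by its rms in the 10–46 kHz band
  (default 85 dB re 1 µPa).

Audio defaults to 300 kHz sampling — inside the 240–576 kHz tag range and
above the NBHF Nyquist requirement — with 240 kHz used to emulate the
mid-frequency tag whose clicks are unresolvable. Same seed ⇒ bit-identical
waveforms and ground truth.

**What the generator does not emulate**: real flow-noise spectra and
surface noise, click directionality and body shading, multipath except as
an optional tail, tag slides, heart-rate variability beyond the schedule,
and any behavioural feedback of the animal on the stimulus. Passing
recovery tests therefore demonstrates that the estimators are correct and
unbiased under the assumed signal structure at realistic SNRs — not that
they are robust to every artefact of field recordings; the manual-override
inputs (ping marks, click review, beat review, respiration marks) are the
intended remedy there.

## Problem sizes

The validation battery uses six scenarios of 200 s each (90-s pre and
exposure windows, ping intervals 0.6–6 s, GPS fixes every 20–30 s),
chosen so the full six-animal pipeline runs in minutes while every
window, detector and comparison exercises the same code paths as the
full-scale design. Dosimetry recovery uses a 120-s receding-animal
scenario at 120 kHz; cardiac recovery a 120-s ramp spanning 50–180
beats/min plus a 39-bpm floor schedule; startle false positives 20 seeds
× 200 flinch-free pings; GPS speed recovery twenty 30-min tracks at the
full-design fix cadence.

## Known limitations

* The response-index threshold is inferred, not documented by any
  protocol; alternative rules consistent with the same six indices cannot
  be excluded.
* Apparent seafloor from U dives is only as good as the animal's habit of
  diving to the bottom; without U dives and bathymetry, crypsis degrades
  to the surface band.
* The RL-trend flight indicator assumes a roughly monotone range change
  within the exposure; circling animals need the GPS indicator.
* Stereo tags are analysed on channel 0 by default; channel combination
  is configurable but no cross-channel calibration is attempted.
* Frequency weighting of SEL and hearing-threshold/TTS-recovery modelling
  are intentionally out of scope.
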