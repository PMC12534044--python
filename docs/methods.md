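# Methods

## Pose-track preprocessing

Tracks arrive as per-frame (x, y) coordinates with tracker confidence for
the heel, center (metatarsophalangeal joint) and toe of one hind paw, plus
two chamber reference points. The processing chain is fixed as

**calibrate → interpolate → resize → filter → baseline**

* **Calibration.** Scale = known reference separation (mm) / median
  per-frame pixel separation of the reference pair. The median over frames
  is robust to occasional reference mistracking; the scale is invariant
  under translation and rotation of the camera frame.
* **Confidence gating.** Samples below the confidence cutoff (default
  0.45) or with missing coordinates are replaced by linear interpolation
  between the nearest flanking confident samples; leading/trailing runs
  are filled from the nearest valid sample rather than extrapolated, which
  keeps heights bounded. Samples at or above the cutoff are left
  bit-identical. A node with no confident samples at all is unrecoverable
  and raises.
* **Resizing.** All tracks are re-expressed on a common 2000 fps
  timeline. Below the reference rate, linear interpolation multiplies the
  sample count by `reference_fps / fps` (50 samples over 0.1 s at 500 fps
  become exactly 200); above it, the track is downsampled. Duration
  `n / fps` is preserved and the operation is the identity at the
  reference rate.
* **Rolling filter.** A centered 17-sample moving average on the
  reference timeline (8.5 ms); edges use shrinking windows so length is
  preserved and no phase shift is introduced. The filter runs *after*
  resizing so that its real-time span is the same for every camera rate —
  filtering a 500 fps track before expansion would smooth over 34 ms,
  attenuating 20 Hz shake oscillations by roughly 60% and visibly biasing
  peak height, and would break the observed equivalence of features across
  frame rates.
* **Baseline referencing.** The vertical coordinate is re-expressed as
  height above the resting paw. Rest is the modal pre-stimulus height
  (0.1 mm bins) — the mode is robust to tracking undershoot, unlike the
  minimum. With no usable pre-stimulus frames the global mode is used with
  a warning. A fixed 1 mm baseline band travels with the track for
  downstream detectors.

## Stimulus trajectories

Poke stimuli move through one sine period starting from the trough:
`h(t) = A (1 − cos 2πt/λ)`, clamped to zero outside `[0, λ]`. `A` is half
the peak-to-trough excursion, so the apex is `2A`. With the standard
pinprick parameters (A = 8 mm, λ = 0.8 s) and the mesh plane 14 mm above
the start position, the tip crosses the mesh at ≈ 0.3080 s and peaks 2 mm
above it. Reading "amplitude" as the full excursion instead would never
cross the mesh and is rejected as geometrically impossible. The mesh
crossing is found by bracketed root-finding on the rising half-period to
1 µs. Camera recording is scheduled a configurable lead (default 25 ms)
before the crossing, floored at zero.

The apex sweep generates profiles with requested apex `a` above the mesh
and a common above-mesh duration `T`: `A = (m + a)/2` puts the peak
exactly `a` above the mesh, and since a sine poke spends
`λ (π − θc)/π` above mesh with crossing phase `θc = arccos(1 − m/A)`,
the wavelength `λ = Tπ/(π − θc)` holds `T` fixed across the sweep. The
default `T` is the standard pinprick's above-mesh time, which makes the
2 mm-apex member reproduce the standard profile exactly.

von Frey presses are modeled either as a sine (A = 3.5 mm, λ = 2.2 s) or
as a linear rise (3 s) – hold – fast retraction. The vFH mesh offset is
configurable with no default asserted: the nominal 0.14 mm value is
inconsistent with a 7 mm press excursion and is not relied on anywhere.
The brush stimulus carries concurrent z- and radial-axis sines with all
four parameters explicit; no defaults are claimed.

## Closed-loop force stimulus

The controller is simulated against a *plant* — a function
`(t, commanded_g, indentation_mm) → sensed_g`. Ramp mode drives commanded
force linearly from 0.5 g to 8 g over 5 s; constant mode holds a set
force (0.25–12 g) by adjusting tip velocity proportionally to the force
error (gain 5 mm·g⁻¹·s⁻¹ by default; against a Hookean paw of stiffness
k this settles with time constant `1/(gain·k)` ≈ 0.1 s, comfortably
within ±10% over the second half of a multi-second hold). A sensed force
drop of ≥ 0.3 g within one control step registers paw withdrawal and
retracts the stimulus, reporting the withdrawal latency and maximum
applied force; a sensed force at or above a mesh-strike signature
(default 15 g, above the device's force range) aborts the trial. Control
step `dt` defaults to 1 ms; reported latency is accurate to one step.

Synthetic plants: *rigid* (sensed ≡ commanded), *compliant* (Hookean,
k = 2 g/mm default), *withdrawing* (compliant until a programmed time,
then zero within one step).

Session schedules interleave catch trials (stimulus to open air) at every
third position, appending the catch that completes the final block, so
six true trials produce catches at positions 3, 6 and 9. Habituation
schedules fill a fixed per-chamber duration with a seeded random sequence
of move / pause / air-stimulus actions (2–8 s each, last one truncated).

## Withdrawal features

All features are computed on the preprocessed (height-referenced,
2000 fps) track, default node "center".

* **t\*** — the first interior frame of the response rise that is a local
  height maximum (`h[i] ≥ h[i−1]` and `h[i] > h[i+1]`; plateaus resolve
  to their last frame). Only the rise above the 0.5 mm paw-lift threshold
  is considered; a monotone series returns the last frame flagged
  "no descent". t\* separates the reflexive phase from the affective
  phase.
* **Withdrawal latency** — while the stimulus is above the mesh, the
  first time the paw height exceeds the stimulus tip height above mesh
  (and the paw-lift threshold — at the crossing instant the trajectory is
  exactly at mesh level, where bare tracking noise would otherwise
  register zero latency), minus the mesh-crossing time. The crossing is
  located with sub-frame linear interpolation between the last
  sub-threshold and first supra-threshold frames. If the paw lifts only
  after the stimulus retracts, that lift time is used; a paw already above
  the trajectory at crossing is flagged pre-lifted with zero latency
  rather than discarded.
* **Reflexive metrics** — maximum height, maximum |vx| and |vy| (central
  differences, one-sided at edges) and 2D path length from response onset
  to t\*. Onset is the start of the monotone rise through the lift
  threshold (walking back from the first supra-threshold frame), so the
  path covers the full lift.
* **Shakes** — sign changes of the 5-sample-smoothed vertical velocity of
  the post-t\* segment, gated by height ≥ 0.35 mm at the inflection and
  peak speed ≥ 50 mm/s on both flanks ("rapid" is quantified by the speed
  knob; the height and speed axes are configurable). Velocity is
  differentiated within the affective segment so the pre-t\* rise cannot
  inject an inflection at the peak itself. Shakes closer than 50 ms merge
  into bouts; shaking duration is the total bout span.
* **Guarding** — maximal post-t\* intervals with height ≥ 0.5 mm (tied to
  the paw-lift threshold by default, independently settable) minus shake
  bouts; guarding duration is the remaining length.
* **Windowed distance** — path length in the 1.5 s after mesh crossing.
* 2D path length is the default for all distances; a vertical-only switch
  is provided since the convention is ambiguous in the field.

## Synthetic withdrawal generator

The waveform family is chosen for analytic invertibility, not
biomechanics: rest until mesh-crossing + latency; half-cosine rise to the
programmed peak over 30 ms; half-cosine descent to the top of the shake
band; a cosine bout at 20 Hz whose duration `(n + ½)/2f` contains exactly
`n` velocity sign changes; a guarding plateau; half-cosine return to rest.
Gaussian tracking noise (default 0.02 mm) and seeded dropout frames
(NaN coordinates with confidence drawn uniform below the cutoff) exercise
the interpolation gate. Tracks are emitted in pixel space with reference
nodes placed so calibration recovers the exact scale. The programmed peak
must be at least the shake-band top, otherwise it would not be the first
height maximum and the parameters are rejected.

Ground truth is computed on the noiseless waveform passed through a
continuous-time moving average matching the default filter span, on a
0.05 ms grid, independently of the extractor code: the features are
*defined* on the filtered track, so raw programmed parameters are not the
correct expected values (the filter biases a sharp peak by a few
hundredths of a millimeter, comparable to the noise band). Shake count
and times are exact by construction. Ground truth is scored against the
default detector thresholds.

What the generator does *not* emulate: multi-node articulation (heel and
toe copy the center waveform), horizontal paw motion, correlated tracking
error, occlusion-structured dropout, or biomechanical variability. Passing
recovery tests therefore demonstrates the extractor's correctness on
well-posed inputs, not robustness to every real-video pathology.

## Peri-event calcium analysis

Traces (cell × time ΔF/F, 20–25 Hz) are aligned to events; segments
extending past a recording edge are dropped with a warning.

* **Population classification** — per cell, mean activity in the pre
  (−2–0 s) and post (0–2 s) windows per event; Wilcoxon signed-rank
  across events on the paired differences (paired is an assumption — the
  upstream platform does not state it); label up/down at p < α = 0.05 by
  the sign of the median difference. Fewer than 5 events cannot reach
  significance and yields all-ns with a warning; zero-variance cells are
  ns. No multiple-testing correction by default (matching the platform
  workflow); Benjamini–Hochberg is available behind a flag.
* **Background events** — seeded uniform draws from the recording
  interior, at least an exclusion distance (default 6 s) from every true
  event and one full window apart from each other; classification on
  background events calibrates the false-positive level, and a
  two-proportion z-test compares regulated fractions.
* **Cross-day categories** — given an externally supplied registration
  map, a cell is *pain* if regulated in any pinprick/max-pinprick session
  and no cotton-swab session, *touch* for the converse, *both* if both;
  unmapped cells are excluded and counted. The output is a partition and
  ignores session order.
* **Single-event regulation** — each population-identified pain cell is
  z-scored by its −4 to −2 s baseline mean/SD; baseline samples vs 0–2 s
  samples are compared with the Wilcoxon rank-sum test. A cell *matches*
  when its single-event direction is significant and agrees with its
  population label. Cells with zero baseline SD are skipped for the test
  but kept in the denominator, keeping fractions comparable across
  events. The total fraction combines both directions over all pain
  cells.
* **Behavior correlation** — Pearson r, r² and two-sided p for every
  (regulation fraction, behavioral feature) pair, with pairwise NaN
  dropping; fewer than 3 complete pairs or zero variance is reported as
  undefined.

The calcium generator adds exponentially decaying transients (amplitude =
effect size × noise SD, decay 1 s) after each event to up cells and the
negative mirror to down cells, over Gaussian (optionally AR(1)) baseline
noise, at 20 Hz with events every 2 min by default — the recording
conditions the analysis is designed for. Tests and batch runs pass
shorter inter-event spacings (12–30 s) to keep array sizes proportionate
to the questions being asked; the statistical windows never overlap
between events in either regime. Slow indicator drift, spike-to-
fluorescence nonlinearity and pre-stimulus anticipation are not modeled,
and no hardware-latency correction is applied.

## Numerical conventions

* Mesh-crossing root-finding: `brentq` to 1 µs; apex-sweep above-mesh
  durations agree to < 1 ms by construction.
* Velocity: `np.gradient` (central interior, one-sided edges).
* Zero velocities in shake detection inherit the previous sign, so
  plateaus do not create inflections.
* Feature CSVs round-trip at full precision (shortest-round-trip float
  formatting on write, `float_precision="round_trip"` on read).
* All generators and schedulers take explicit seeds and are bitwise
  deterministic; the batch CLI reproduces byte-identical outputs for a
  fixed seed and config.

## Known limitations

* The confidence-gate retuning that practitioners apply when a video
  fails at default settings is exposed as knobs but not automated.
* Shake counting is by vertical-velocity inflection by default; whether
  the upstream convention uses x, y or speed inflections is unknown, so
  the axis is a flagged compatibility caveat.
* The constant-force control law is proportional velocity control; the
  physical device documents only that velocity is "adjusted up and down".
* Cross-day registration maps are consumed, never computed; image-based
  registration is out of scope.
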