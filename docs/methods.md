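# Methods

This note documents the models, conventions, and numerical choices behind
`finloop`, and what its synthetic tests do and do not establish about real
rigs.

## Arena and coordinates

The tank is modelled as a 60 × 30 × 36 cm rectangular prism with water at
15 cm and an opaque divider running 25 cm from the screen wall down the
middle of the tank, creating a Y-maze whose two arms face the stimulus
screen. All task geometry lives in a single **tank-floor frame**: origin at
the corner where the screen meets the left wall, *x* along the screen
(0–30 cm), *y* away from it (0–60 cm). The camera is modelled as a
top-down view with a single isotropic scale factor (`cm_per_px`) and a crop
rectangle bounding the tank interior; there is no lens-distortion model,
which matches the flat-floor, overhead-camera geometry the pipeline is
designed for. The default camera is 1280 × 720 at ~33 fps with a
300 × 600 px crop (0.1 cm/px).

Regions of interest are closed axis-aligned rectangles in the tank-floor
frame:

| ROI | default | purpose |
| --- | --- | --- |
| `start` | 10 × 10 cm, centred on the long axis at the far end | trial self-initiation |
| `choice_left` / `choice_right` | 15 × 15 cm, abutting the screen wall on either side of the divider | choice registration |
| `screen_probe` | 3 × 1 cm strip at the top-centre of the screen edge | epoch luminance readout |

The start zone's exact placement is stated in the protocol only as opposite
the screen and equidistant from both choice arms; the centred far-end square
is this package's fixed interpretation. Pre-training uses larger start-zone
variants (back half: *y* > 30 cm; back quarter; then the final square), all
expressible as ordinary ROIs.

Stimuli are 3.5 cm circles (red, green, blue, white) on a mid-grey
background, centres 5 cm above the tank bottom and 7 cm from each side
wall; pre-training uses a 13.5 × 12 cm Gaussian white-noise rectangle
(mean 0, variance 10). The epoch-indicator strip at the top of the screen
takes grey level 0 during the ITI, 128 while a trial is available *and*
while stimuli are on (stimuli sit on the same grey background, so only
three luminance classes are distinguishable), and 255 after a choice.

## Tracking pipeline

Each frame is cropped, converted to HSV (hue 0–179 half-degrees, S/V
0–255), thresholded against a per-subject HSV range, median-filtered, and
reduced to the arithmetic-mean centroid of the remaining pixels.

Numerical choices:

- **HSV conversion** is the standard hexcone formula, vectorised in
  float32. The general-purpose converters in image libraries cost more per
  frame than the rest of the pipeline combined, which matters in a loop that
  runs at video rate; the unit tests pin this implementation to scikit-image's
  converter to within one quantisation step.
- **Hue wraparound** is supported (`h_min > h_max` is read modularly)
  because orange fish body hues sit near the red wrap point.
- **Smoothing** is a median filter (the platform's smoothing step is not
  otherwise specified), default radius 3: it removes threshold speckle
  without biasing centroids of blobs much larger than the window.
- **Occupancy** is a strict comparison — the binarized pixel sum inside the
  ROI must *exceed* the threshold — applied to the smoothed mask (one
  binarized representation feeds the whole pipeline).
- `min_blob_px` (default 25) suppresses phantom centroids from residual
  noise; `calibrate_entry_threshold` mirrors per-subject rig calibration by
  taking a fixed fraction (default 0.25) of the median in-ROI blob size.
- **Probe luminance** is the unweighted RGB mean: the probe only needs to
  separate three widely spaced grey levels, so no luma weighting is needed.

## Trial state machine

One step consumes one tracking sample and returns the successor state plus
commands (screen updates, pellet dispenses, log events). Epochs: ITI →
TRIAL_AVAILABLE → STIMULUS_ON → OUTCOME_DELAY → (ITI | ENDED). Defaults
follow the main protocol: ITI ~ U[20, 40] s, 5 s outcome delay, 24 trials
per session; choice-zone pre-training uses ITI ~ U[5, 10] s, 12 trials, and
a 30 min session limit; start-position training a 1 h limit.

Design choices the protocol leaves open, fixed here:

- **Start triggering is presence-based**: start-zone occupancy on any frame
  after ITI offset triggers stimuli (no outside→inside transition needed).
- **Choice latching**: the first choice-zone entry after stimulus onset is
  final; later entries within the trial are ignored.
- **No within-trial timeout**: only session-level limits apply. The main
  experiments state no session limit; the pre-training 1 h limit is reused
  as a default.
- **Simultaneous double entry** (nearly impossible with the divider) is
  broken by the larger in-ROI pixel sum, then left.
- During pre-training, entry into the unsignalled choice zone is ignored
  (the trial neither ends nor resets); signalled sides are split exactly
  evenly across the session in random order.
- The event vocabulary (ITI_START, TRIAL_AVAILABLE, START_ENTRY, STIM_ON,
  CHOICE_LEFT/RIGHT, REWARD, OMISSION, SESSION_END, SESSION_TRUNCATED) is
  fixed by this implementation; the platform's format only prescribes the
  three-column shape. The code column is the trial index, except for choice
  events where it flags whether the chosen side carried S+. Timestamps are
  session-relative seconds at three decimals, headerless CSV.

## Virtual tank and fish agent

The generator renders what the rig's camera sees: a uniform light floor
(grey ≈ 235), a dark surround outside the crop, the fish as a filled
ellipse (default body length 8 cm, within the 7–10 cm range of the modelled
subjects; width 0.35 × length) in an orange hue near the red wrap point,
and the epoch-indicator strip along the screen edge, drawn last because the
screen cannot be occluded by anything in the tank.

The agent:

- **Learning**: Rescorla–Wagner, `V ← V + α(λ − V)` on the chosen cue only,
  cue basis either side or colour. Defaults α = 0.3, β = 5 — fast but not
  degenerate learning, chosen so a naive agent shows visible acquisition
  within one or two 24-trial sessions.
- **Choice**: softmax over the two offered cues with inverse temperature β.
- **Locomotion**: heading relaxes toward the goal bearing at rate 6 s⁻¹
  with Gaussian angular noise (0.4 rad/√s); speed 8 cm/s; positions reflect
  off walls (with a half-body-length margin so the rendered blob stays
  interior) and off the divider segment, which the agent can never cross.
  Straight paths that would cross the divider are routed around its tip via
  a waypoint. These values are invented; they make a trial complete in a
  few seconds of simulated time.
- **Perception is symbolic**: the agent reads the `ScreenSpec`, not pixels.
  Only the tracker consumes rendered frames. Closed-loop tests therefore
  validate the platform (tracking, contingencies, logging), not fish vision
  or psychophysics.

What the simulator does **not** emulate: hydrodynamics, realistic
initiation/response-time distributions (movement times are essentially
travel times plus noise), body flexion, lighting gradients, water-surface
glare, or multiple animals. Passing closed-loop tests shows the software
chain is correct and self-consistent, not that tracking will be robust to
the optical nuisances of a physical tank.

`simulate_choice_sequence` runs the same contingency/softmax/update loop at
one iteration per trial with no rendering, tracking, or movement; it exists
for asymptotic learning-rule properties (hundreds of trials) where the
video loop adds only cost.

## Statistics

- Choice proportions are arcsine-square-root transformed (asin √p) before
  t tests and ANOVAs; the transformed repeated-measures ANOVA is reported
  alongside its untransformed counterpart for comparison.
- Performance-versus-chance uses one-sided (greater) one-sample t tests
  against 50 %; movement-time comparisons use two-sided paired t tests;
  α = 0.05 throughout. t tests are delegated to scipy.
- The one-way repeated-measures ANOVA partitions total SS into condition,
  subject, and error; `F = MS_cond / MS_err` with df `(k−1, (k−1)(n−1))`.
  It is written directly from this closed form and is cross-checked in the
  tests against both an explicit cell-by-cell sums-of-squares oracle
  (agreement to 1e-10) and pingouin's implementation. Matrices with
  identical columns return F = 0; other zero-error-variance inputs raise.
- Session terciles are contiguous thirds in trial order, remainder to the
  earliest bins (24 → 8/8/8, 25 → 9/8/8).
- Movement-time summaries use within-session medians and across-subject
  means, matching how the group curves are built from per-subject panels.
- The published tercile ANOVAs are printed with df (2, 9), which no
  5-subject repeated-measures layout produces (that gives (2, 8)); the
  report therefore computes the tercile analysis under both the
  repeated-measures and the plain one-way layout (df (2, 12)) and asserts
  neither against the printed values.

## Problem sizes and runtime

Full-scale defaults (1280 × 720 at 33 fps, ITI 20–40 s) are faithful but
produce ~30 000 frames per 24-trial session. The test suite and the
acceptance script run the closed loop at a coarser scale chosen as this
package's standard simulation size: a 150 × 300 px crop (0.2 cm/px) at
11 fps with ITIs of 1–2 s and a 1 s outcome delay. None of these enter the
asserted quantities (choice proportions, reward counts, centroid errors in
px, determinism), which are invariant to ITI length and frame rate; they
only set how much video is rendered per trial. The acceptance script runs
one greedy 24-trial session, one 200-trial indifferent session, and a
2-session acquisition + 3-session reversal sequence, all through the full
render→track→step loop.

## Known limitations

- Single animal, single camera, no identity maintenance or pose estimation.
- The feeder is an abstract dispense command; pellet physics, consumption,
  and satiation are not modelled.
- The published group statistics can only be recomputed from the original
  per-subject supplementary panels; synthetic cohorts generated here have
  the same layout but are clearly labelled synthetic and are used only to
  test the pipeline's arithmetic.
- Timer transitions are frame-quantised, so logged epoch durations carry up
  to one frame interval of jitter relative to nominal durations.
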