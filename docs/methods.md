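# Methods

## Scope and model

flockmotion estimates real-world locomotion speed from pixel trajectories of
animals moving on a flat floor observed by a single fixed, possibly oblique,
camera, and scores tracker output with the standard multi-object tracking
and segmentation metrics. The upstream tracker is out of scope: the toolkit
consumes its output (MOTChallenge CSV, optional instance masks) and is
agnostic to how it was produced.

Two assumptions carry everything: (i) motion is **planar** — animals stay on
the calibrated floor plane, so a single homography relates camera pixels to
a metric top-down view; (ii) the camera is **distortion-free** — lens
distortion, multi-camera fusion and 3-D pose are non-goals.

## Calibration

Four pixel corners of a floor rectangle of known physical size (listed
cyclically from the world-origin corner: +x, +x+y, +y) determine the
rectifying homography. We solve the minimal 4-point problem with a
normalized direct linear transform: both point sets are translated to their
centroid and isotropically scaled to RMS radius √2 before forming the 8×9
homogeneous system, whose null vector (via SVD) gives H; the similarity
transforms are then undone and H scaled so H₃₃ = 1. Normalization keeps the
system well conditioned when pixel coordinates are O(10³); recovery of
random generating matrices is verified to 1e−8 and point round trips to
1e−9. Configurations with three collinear points on either side are rejected
as degenerate.

The top-down scale *W* (m/px) is the ratio of the rectangle's physical
extent to its rectified extent. If no rectified raster size is configured,
the destination plane is metric and *W* = 1; if one is given, its horizontal
and vertical scales must agree (anisotropic rasters are rejected rather than
silently averaged).

Conventions, fixed once: pixel indices are 0-based, origin top-left,
v increases downward; the world frame originates at the rectangle's first
corner. On disk, MOTChallenge frame numbers are 1-based; in memory frames
are 0-based.

## Speed

For a track rectified to the top-down plane, each frame window [N, M]
yields V = ΔY·W/((M−N)·Δt) with Δt = 1/fps. Choices that matter:

- **Displacement mode.** The default uses the vertical component only
  (|v_M − v_N|): the rectification is constructed so vertical pixel shift is
  proportional to distance travelled, and this is the faithful reading of
  the estimator the toolkit packages. It is a lower bound — oblique motion
  is underestimated (the worked example in the README shows a cohort mean
  of 0.033 m/s for birds whose true mean is 0.05 m/s). The `euclidean`
  mode uses the planar displacement magnitude and is the right choice
  whenever headings are uncontrolled; it is what the acceptance script uses
  for cohort speed statistics.
- **Window.** Default 18 frames = 1 s at the default 18 FPS. Shorter
  windows amplify localization noise (the jitter-to-displacement ratio
  scales as 1/window); longer windows underestimate speed on curved paths,
  since the chord between endpoints is shorter than the path.
- **Displacement sign.** ΔY is absolute, so reported speeds are
  nonnegative; direction is not a deliverable.
- **Gaps.** A window containing any missed frame is skipped, not
  interpolated — interpolation would fabricate displacement and bias RMSE
  optimistically. Skips are logged.
- **Degenerate input.** Trajectories shorter than window+1 detections yield
  an empty series with a warning rather than an error, because false-positive
  tracklets of length 1 are routine in real tracker output.

## Tracking metrics

The CLEAR-MOT accumulator matches ground truth to predictions per frame by
minimum-cost bipartite assignment (Hungarian algorithm) on centroid
Euclidean distance, gated at a threshold of 0.1 × frame height by default
(108 px at 1080p), or on 1 − IoU gated at 0.5 when boxes are used. Two
protocol details are easy to get wrong and are covered by dedicated tests:

- **Persistence**: an existing ground-truth↔prediction pairing is kept as
  long as it stays within the gate, even if another prediction drifts
  closer; only unmatched entities enter the assignment step.
- **Switch counting**: an identity switch is charged at the frame where a
  ground-truth object's matched predicted identity differs from its last
  match, *ignoring gaps* (a miss between two consistent matches costs
  misses, not a switch).

MOTA = 1 − (FP + Miss + IDS)/GT may be negative and equals 1 only for
perfect tracking. The identity metrics use the trajectory-level optimal
mapping: per-pair agreement counts frames where both are present within the
gate; the mapping maximizing total agreement gives IDTP, hence
IDP = IDTP/(IDTP+IDFP), IDR = IDTP/(IDTP+IDFN) and IDF1 as their harmonic
mean (equivalently 2·IDTP/(2·IDTP+IDFP+IDFN)). IoU of two empty masks is
defined as 0 with a warning; classes empty on both sides are excluded from
the mIoU mean. Throughput FPS is reported but hardware-dependent, so no test
asserts a value for it.

The whole protocol is cross-checked for exact (not approximate) agreement
against an independent brute-force reference implementation — exhaustive
per-frame assignment search and a bitmask dynamic program for the identity
mapping — on 100 simulated scenarios.

## Simulator

The generator's defaults *are* the study conditions the package is
validated under: 18 FPS, 1440×1080 frames, mean speed 0.05 m/s, speeds
confined to [0, 0.21] m/s. Remaining values are chosen once as realistic
for a small observation pen and documented here:

- **Arena** 4 m × 3 m (matches the 4:3 frame aspect so an axis-aligned
  camera is a pure scale), default camera an oblique trapezoid inside the
  frame, about 25° off-nadir in effect.
- **Kinematics**: correlated random walk. Heading
  θ_{t+1} = θ_t + (1−κ)·η, η ~ N(0, 0.6² rad), κ = 0.9; speed is a
  mean-reverting walk s_{t+1} = s + 0.1·(0.05 − s) + N(0, 0.005²) m/s,
  clipped to the envelope. The stationary speed spread (≈0.012 m/s) keeps
  the clip boundaries ≈4σ away, so the time-averaged speed matches the
  configured mean (checked by Monte Carlo to within 3 standard errors).
  Walls reflect: the overshoot is mirrored and the heading component
  flipped, preserving path length.
- **Noise presets**: "dyed" σ = 1 px jitter, 2% misses, 0.01 false
  positives/frame, 0.1% swap chance/frame; "undyed" σ = 2 px, 5%, 0.05,
  0.5%. The magnitudes are invented; they are chosen to reproduce the
  *qualitative ordering* (marked birds track better) and nothing else.
  Identity swaps transpose the labels of the two nearest birds
  **persistently** — from the event frame onward — because that is the
  failure a real tracker commits during an occlusion and what IDS counting
  presupposes; occlusion itself is abstracted as misses + swaps, not
  modelled geometrically.
- **Reproducibility**: each bird draws from its own seeded substream
  (`default_rng([seed, bird])`), so adding a bird leaves existing
  trajectories bit-identical; degradation uses a separate stream.
- **Masks**: each bird renders as a filled ellipse (default semi-axes
  26×16 px) oriented along its pixel-space heading, clipped at the frame
  edge; rendered area matches πab within 2%.

What the simulator does *not* emulate — appearance, lighting, feather
texture, geometric occlusion, lens distortion, tracker-specific error
correlations — bounds what passing tests show: they validate the
measurement layer (calibration → rectification → speed equation → metrics)
exactly, and the noise response only under independent, stationary error
models. Real tracker errors are correlated in time and space; absolute
MOTA/RMSE values from the simulator do not transfer to field video, though
orderings between noise regimes are expected to.

## Numerical choices

- Homography fits use SVD; matrices are rejected as singular below
  |det| = 1e−12 after normalization; points whose homogeneous third
  coordinate vanishes raise rather than return infinities.
- Assignment ties in matching are theoretically possible but measure-zero
  under the simulator's continuous coordinates; the Hungarian solver's
  tie-break is accepted as-is.
- Gating uses ≤, so a prediction exactly at the threshold matches.
- MOT CSV floats are written with `repr` (shortest round-tripping form);
  integral values print without a decimal point. Read→write→read is
  field-for-field lossless, which the byte-identity CLI tests rely on.
- Problem sizes in the validation suite — up to 10 birds, 100-frame
  scenarios for protocol equivalence, 2000-frame runs for the noise-ordering
  benchmark — are chosen so event counts (switches, misses) are large enough
  for strict orderings while the whole suite stays interactive (seconds, one
  CPU).

## Known limitations

- Vertical-only mode systematically underestimates speeds of oblique motion;
  it is retained as the faithful default, with `euclidean` as the corrective.
- Bounding boxes are dropped when a track set is rectified (a homography
  does not map axis-aligned boxes to boxes); downstream evaluation in
  top-down coordinates is centroid-based.
- mIoU treats each class mask as the union of its instances across the
  supplied frames; per-frame averaging is not offered.
- The false-positive model scatters detections uniformly; real spurious
  detections cluster near true objects, so simulated FPs are easier to
  discount than real ones.
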