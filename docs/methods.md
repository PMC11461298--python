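# Methods

## Motion-onset detection

A clip is a stack of 8-bit frames at a nominal 60 frames/s. Frame 1 is
treated as a static reference and is never updated (no running-average
background model): the footage this detector targets has a stationary
camera and a static naturalistic background, so the initial frame is the
best available estimate of "no motion".

For each frame t ≥ 2:

1. convert frame t and the reference to grayscale (BT.601 luma weights
   0.299/0.587/0.114, rounded half-up — the usual broadcast convention; any
   fixed weighting would do, but it must be fixed for thresholds to mean
   anything);
2. mark pixels with |I_t − I_ref| ≥ `threshold_fraction` × 255. At the
   default 10 % the cutoff is 25.5 gray levels, so an integer difference of
   26 is the smallest registering change ("at least 10 %": ties count as
   changed). The mask is boolean with truth = changed; any black/white
   display polarity is presentation only;
3. label 8-connected changed regions and take each region's bounding box.
   Box area means w × h of the bounding box, not the filled region — the
   filter is deliberately generous so that a loose cloud of changed pixels
   from one limb movement still counts;
4. keep boxes with area ≥ `min_box_area` (default 400 px) whose row extent
   intersects the actor band `roi_y` (default: full frame, so the tool
   works without actor annotations). The area floor rejects sensor noise,
   flicker and small shadows; the Y-band restriction rejects changes away
   from where the actor sits. Both defaults are tuned for 720×1280 footage
   and scale with resolution; on the 200×200 synthetic rasters used in
   tests a 30×30 patch (900 px) comfortably clears the 400 px floor.

The onset is the first frame with a surviving box; a clip with none gets
`None` rather than a guess. The per-frame box log is kept for all frames so
oversensitivity (the practical failure mode: shadows, clothing wrinkles,
eye movements) can be audited frame by frame. Human judgments, supplied as
a CSV of per-video onsets, always override the detector; the resolution
report lists every disagreement.

Trimming cuts a clip to frames [onset−1, end]: frame 1 of the result is the
still frame preceding motion, frame 2 the first moving frame. Output length
is n − onset + 2, and re-detection on the trimmed clip must (and in tests
does) yield onset 2 whenever motion persists at its onset frame.

Monotonicity properties used as tests: raising the threshold or the area
floor can only delay (never advance) the detected onset.

## Between-subject staircase

One staircase iteration = one naive participant classifying every clip once
(pseudo-random order, seeded). The first participant sees each clip up to
its 50th-percentile frame (round-half-up). After iteration n−1's response,
the pause frame moves by the step evaluated at the destination iteration:

    N(n) = Nframe/2 × 2^(−(n−2)/2.5)

down after a correct classification, up after an error, rounded half-up to
whole frames (only whole frames can be played) and clamped to [1, Nframe].
N itself stays real-valued for the stopping test: the run ends at the first
iteration n\* with N(n\*) < 1, when reversals can no longer move the pause
point; the frame played at n\* is the recognition frame. Consequences worth
stating plainly:

- The step into iteration 2 has magnitude Nframe/2 (the exponent is zero at
  n = 2), so the second iteration always sits at a clamped extreme (frame 1
  or Nframe). This follows from the formula taken at face value and is not
  hidden.
- The schedule is response-independent: n\* depends only on Nframe
  (n\* = 21 for 300–360-frame clips, 18 for 128, 3 for the degenerate
  2-frame clip). Because step sizes quarter every 5 iterations, the total
  correction available after iteration n is ≈ 4.1 × N(n+1).
- `run_staircase(..., n_iterations=...)` overrides the stopping rule for
  schedules that stop earlier (e.g. a fixed 17-participant session).

Simulated observers implement a step psychometric function: correct with
probability 1 − lapse at or beyond their true recognition frame r, with
probability `guess_rate` (1/3 for a three-category task) before it. Each
observer draws from an independent seeded stream, so whole sessions replay
exactly.

**Recovery accuracy.** With a deterministic threshold responder the
staircase recovers r to within 1 frame for every r ∈ [1, 300] (established
by exhaustive simulation and frozen as a regression bound). With guessing
observers a *single* run is much noisier — median absolute error ≈ 9–10
frames, occasionally far worse — because one lucky guess early in the run
displaces the track by tens of frames that the shrinking schedule cannot
fully undo. This is an inherent property of a single-track between-subject
staircase with three-alternative guessing, not an implementation artifact;
studies wanting tighter per-clip estimates need repeated tracks or more
response alternatives.

## Psychometric evaluation

Ratings are items × raters labels from a fixed set (default Normal / How /
What). Validity is per-rater recognition accuracy (count and percent
against the intended category); reliability is Fleiss' κ in its standard
formulation (per-item agreement P_i, marginal proportions p_j,
κ = (P̄ − P̄ₑ)/(1 − P̄ₑ)), requiring an equal number of ratings per item.
The degenerate case P̄ₑ = 1 (all mass in one category) yields a flagged
undefined result instead of an exception so simulated batches survive it.
Accuracy is compared to the chance level n_items/k with a one-sample
t-test; Cohen's d = (x̄ − μ₀)/s and a t-based 95 % CI accompany it. A
summary-statistics entry point (mean, SD, n) mirrors the raw-values path to
10 significant digits so published summaries can be checked without raw
data. Category-by-angle ANOVAs and post-hoc machinery are deliberately out
of scope; `RatingMatrix.to_long()` exports tidy CSV for any stats package.

## Synthetic data

The clip generator emulates the statistical skeleton of the target footage
at desk scale: a constant (optionally Gaussian-noise) background, one
rectangular patch stepping `patch_intensity_step` gray levels that appears
at a true onset in [2, 18] (the empirically observed onset range) and
optionally drifts linearly inside a vertical actor band, plus distractor
rectangles that flicker on alternating runs of `period` frames — cartoons
of the shadow/flicker false-positive sources. Defaults: 200×200, 60
frames, 60 fps, background level 30, noise SD 0 (real backgrounds are
static), 30×30 patch, step 120. What it does *not* emulate: articulated
human kinematics, gradual motion ramps, lighting drift, compression
artifacts — so passing tests demonstrate correct mechanics of detection and
trimming, not field performance on arbitrary footage (where the human
override path exists for a reason).

The rating generator draws balanced truths (categories as even as possible,
matching a 45/45/45 design over 135 items; a uniform-draw mode exists) and
responses from a per-truth confusion kernel; the default diagonal of 0.886
reproduces a high-validity stimulus set (mean accuracy ≈ 89 %, κ ≈ 0.67–0.70
with 51 raters). Observer pools spawn independent child seeds per video, so
generators are pure functions of (spec, seed) and all outputs are
bit-reproducible.

## Numerical choices and degenerate inputs

- 1-based frame indexing in every public interface; 0-based storage is
  converted at the boundary.
- Round-half-up everywhere a real quantity becomes a frame count (grayscale
  luma, percentile frame, staircase steps). Ties in N are rounded up; the
  convention is stated because the alternative is equally defensible.
- 8-bit intensities only; the threshold scales with (levels − 1) = 255.
- Empty difference masks yield empty box lists, not errors; single-frame
  clips, onset = 1 trims, single-category κ, and zero-variance t-tests are
  rejected or flagged explicitly.

## Problem sizes in the test and acceptance suites

Synthetic suites use 200×200 (pipeline tests 120×120) rasters, 40–60-frame
clips, 51-clip onset-recovery sweeps, 200 random ≤ 64×64 masks against a
brute-force flood-fill oracle, 500 staircase replicates, and 200-replicate
null-κ batches — sizes chosen so the full characterization logic is
exercised end-to-end while the whole suite runs in well under a minute.
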