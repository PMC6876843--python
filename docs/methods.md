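# Methods

## Scope and model of the problem

`arenatrack` tracks the centroids of dark animals (flies, larvae, worms,
fish) moving on a bright back-lit field that is partitioned into many
spatially segregated arenas.  Identity is carried by the arena (ROI), not
by appearance: as long as each arena holds a known number of animals and
walls prevent mixing, a per-ROI assignment of blob centroids to traces is
sufficient, and the per-frame cost stays linear in the number of arenas.
The package deliberately does not resolve identities through collisions
within an arena — a real-time tracker cannot use future frames to
disambiguate merges, so multi-animal ROIs expose unordered,
displacement-consistent individual slots only.

## Per-frame loop

1. **Difference image.** For each ROI, `clamp(reference − frame, 0)` over
   the ROI crop, masked to the ROI shape (a config flag flips the
   polarity for light-on-dark organisms).  Per-ROI crops rather than a
   whole-frame reference let each arena's background evolve independently.
2. **Noise decision.** The total above-threshold pixel count is compared
   against a clean-imaging baseline (below).  Noisy frames contribute no
   positions (NaN) and count toward forced background reacquisition.
3. **Segmentation and matching.** 8-connected components of the
   thresholded difference, filtered to `[min_area, max_area]`; centroids
   are binary-mask pixel means (sub-pixel by averaging, which suffices
   for the sub-pixel error regime; intensity weighting was not needed).
   Candidates are matched to the ROI's traces by minimizing total
   frame-to-frame displacement, solved exactly with the Hungarian
   algorithm (`scipy.optimize.linear_sum_assignment`); a greedy fallback
   exists for more than 32 objects in one ROI.  Cost ties break to the
   lower candidate index so runs are reproducible.

## Background model

Each ROI keeps a rolling stack of up to `K = 10` sample crops combined
pixel-wise by median (mean optional).  A sample is admitted only when
every tracked animal in the ROI lies at least `d_min` from its position
in *all* stored samples; `d_min` defaults to one body length, estimated
as `2·sqrt(median blob area)`.  With three or more gated samples each
pixel is animal-free in a majority of the stack and the median reference
contains no animal.  Neither the stack depth nor the gate distance is
prescribed by the underlying method description (initialization is
"activity dependent"); `K = 10` keeps the reference responsive while
bounding memory, and the one-body-length gate is the smallest distance
that guarantees non-overlapping animal footprints between samples.

Forced reacquisition resets the stack to the single current frame.  The
animals are in that frame, so the new reference has *dead spots*: a
stationary animal at its reacquisition position is invisible until it
moves and gated updates rebuild the stack.  Note the polarity: with the
clamped difference a dark spot baked into the reference produces *no*
spurious blob, only missing detections, which is why recovery costs
coverage rather than accuracy.

## Noise monitor

Before tracking, the distribution of the above-threshold pixel count is
sampled over ≥ 30 clean frames (default 60).  During tracking a frame is
noisy when the rolling mean of the last `W = 10` counts exceeds
`baseline_mean + k·max(baseline_std, 1)` with `k = 5`; `m = 10`
consecutive noisy frames force background reacquisition.  The rule is
one-sided: abnormally low counts mean animals absorbed into the
background, which the gated updates — not the monitor — repair.  All
three constants are config-exposed; they are the simplest monotone
realization of "flag when the rolling sample substantially deviates".

Two details matter in practice and were found by simulation:

* **Baseline timing.**  Counts rise during warm-up while partially built
  stacks still hide animals, so the baseline is collected only after the
  frames consumed by the initializer have been replayed.
* **Rebaseline ratchet.**  After a reacquisition the monitor resamples
  the baseline once 60 clean frames have passed (using the last 30, past
  the unveiling ramp), but the update only ever moves the mean and
  spread *up*.  Adopting a post-reacquisition lull as the new baseline
  makes the animals' reappearance look like noise and locks the tracker
  into a reacquisition loop.

## Behavioral metrics

* **Speed**: `‖Δposition‖·fps·px2mm`; missing positions poison both
  adjacent intervals.
* **Movement threshold**: Gaussian KDE (Silverman bandwidth) of
  log-speed (zeros excluded); the threshold is the density minimum
  between the two largest modes — the low mode is frame-to-frame
  centroid jitter, the high mode locomotion.  Local maxima below 5 % of
  the peak density are ignored and the valley must fall below 90 % of
  the smaller mode, otherwise the distribution is declared unimodal.
* **Bouts**: maximal runs of consecutive frames at or above threshold;
  NaN breaks a run.
* **Y-maze scoring**: a choice is the first frame in a new arm after a
  center passage; re-entries do not count.  Arms are three 120° sectors
  (plus a central disc) labeled counterclockwise *as seen on screen*
  starting from 12 o'clock.  A turn into the counterclockwise neighbor is
  a left turn — the convention is arbitrary but fixed and documented.
  Turn bias is the fraction of right turns, phototactic bias the fraction
  of choices into the lit arm; conditional variants split trials by
  whether the lit arm was the left or right neighbor of the origin arm.
* **Optomotor index**: magnitude-weighted — per trial, the shortest-arc
  heading changes during the stimulus are split by sign into *with* and
  *against* the rotation and the index is `(with − against)/(with +
  against)`.  Weighting by angular magnitude (rather than frame counts)
  follows from defining the index as the fraction of body-angle *change*
  in the stimulus direction.
* Headings come from displacement vectors at frame speeds above a
  threshold (carried forward below it), because displacement has an
  unambiguous sign, unlike ellipse orientation.

## Closed-loop controllers

All controllers are frame-synchronous and hardware-agnostic: per frame
they consume tracked state and emit command records (LED on/off,
pinwheel parameters, light on/off) into an append-only log; sinks (a
null sink, a 3-byte serial-line sink) deliver them.  Commands at frame
`t` depend only on positions ≤ `t`, each arena draws from its own RNG
stream spawned from one seed, and identical inputs reproduce the log
bit-exactly.

* **LED Y-maze**: on entry into a new arm all LEDs go off, the trial is
  scored toward/away from the lit arm, and an LED lights in one of the
  two now-unoccupied arms chosen uniformly (the split is not specified by
  the source assay description; uniform is the natural null).
* **Optomotor**: a trial starts only when the animal is moving (speed
  threshold), the minimum inter-trial interval (2 s) has elapsed, and the
  animal is at least `0.25 × arena radius` from the wall (the source
  states the purpose of the edge gate, not its value; a quarter radius
  keeps the pinwheel well inside the animal's field of view).  Stimulus
  direction (and optionally contrast, spatial frequency, angular speed)
  randomize per trial; the pinwheel center follows the tracked position
  through the camera→projector registration and holds the last known
  position during dropouts; the stimulus ends after 2 s.
* **Speed-contingent optogenetics**: 8 alternating baseline/
  reinforcement periods of 8 min; light on when speed is above
  (lit-when-fast) or at-or-below (lit-when-slow) 6.8 mm/s; missing speed
  fails safe to light off.

Registration is a normalized DLT projective fit (similarity-normalized
coordinates, SVD null vector, ≥ 4 correspondences, rank check).  The
pinwheel raster (angular square wave) exists for tests only; no display
code lives in the core.

## Synthetic data generator

The generator is the package's test bed and defines its study
conditions.  Defaults describe one fixed imaging regime:

* **Scene**: a 4×3 grid of bright circular arenas (radius 50 px, pitch
  110 px, ~200 vs ~40 intensity levels) on a 440×330 px frame, with a
  ±5-level linear illumination tilt and Gaussian pixel noise σ = 2.
  Tracked ROIs extend 4 px beyond the bright disc so the high-contrast
  arena wall lies inside the ROI, as drawn in practice — this is what
  makes reference misalignment visible to the noise monitor.
* **Animals**: dark ellipses with 6×4 px half-axes (~75 px², a ~4 mm
  animal at ~3 px/mm) and a 90-level dip, rendered with a ~1 px
  anti-aliased edge so the rendered intensity centroid matches the
  requested position to < 0.25 px.
* **Walkers**: two-state Markov (mean move bout 2 s, mean pause 4 s),
  lognormal bout speed (median 30 px/s ≈ 10 mm/s, log-sd 0.4), heading
  diffusion 0.25 rad/frame, steered back near the wall; paused animals
  jitter by 0.12 px to emulate apparent centroid noise, giving the
  characteristic bimodal log-speed distribution.

What the generator does *not* emulate: body shape change, shadows,
reflections, condensation and other slow structured background drift,
occlusions, and multi-animal contact.  Passing tests therefore
demonstrate the algorithmic properties of the pipeline (segmentation
accuracy, assignment optimality, monitor behavior, controller logic)
under a faithful but idealized imaging model, not performance on any
particular laboratory's imagery.

## Robustness procedures and problem sizes

Three stressors mirror the published failure modes; all statistics are
measured, never assumed.  The default problem sizes keep a full
reproduction on one CPU in a few minutes: noise and compression sweeps
use a 2-minute, 30 fps, 12-arena video; the reference-shift session runs
5 minutes with a 2 px displacement of the stored background (stack and
reference, edges wrapping) in a uniformly random direction every 2 s.
Binary noise sets each thresholded pixel to foreground with probability
`p`, injected downstream of the monitor and upstream of segmentation.
Error statistics pool all tracked (non-missing) frame×arena samples;
the shift session additionally reports the Pearson correlation between
tracked and true coordinates and the reacquisition count.

## The delta video codec

No general-purpose video codec is part of the toolchain here, and the
dominant redundancy in arena video is temporal, so the compression
procedure uses a purpose-built lossy inter-frame codec: a JPEG keyframe
followed, per frame, by the sparse set of pixels whose value differs
from the running reconstruction by at least half the quantization step
(zlib-compressed).  Quantizing against the reconstruction bounds the
error and lets slow drifts flush once they accumulate; quantization
steps of 8–64 levels suppress sensor noise (the main size cost) while
preserving the 90-level animals; optional 2× or 4× block-average
downsampling trades spatial resolution for further reduction.  The
achieved raw-to-encoded ratio (`H·W·frames / file bytes`) is recorded
per setting.

## Trace container

Little-endian binary: self-describing header (magic, version, layout,
fps, pixel scale, field names, start time), fixed-size float32 records
(frame-major; NaN = missing), footer with frame count and CRC32.  A
reader needs ~20 lines: parse header, seek `header + frame·record_size`,
read float32 — the format, not the implementation, is the contract.
Truncated files (crash mid-record) recover all complete frames with a
warning.  CSV export is lossless up to the printed precision (3
decimals, i.e. milli-pixels).

## Numerical and degenerate-input choices

* Coordinates are 0-based, x = column, y = row, origin top-left;
  centroids continuous.
* Missing is IEEE NaN everywhere; no zero sentinels.
* Overlapping ROIs are allowed with a nearest-center tie-break and a
  construction-time warning.
* ROI auto-detection thresholds at a configurable intensity quantile
  (default 0.9), applies a binary opening (removes 1-px noise bridges
  between arenas), 8-connected components, an area filter, then fits a
  max-inscribed-radius circle to roughly round components and a bounding
  box otherwise.  The right quantile depends on the fraction of bright
  pixels; for scenes where arenas dominate the frame a low quantile is
  needed.
* Background-shift perturbations roll arrays with wrapping edges; the
  wrap artifact is part of the injected corruption.
* Empty candidate sets, empty choice sequences, unimodal speed
  distributions, and rank-deficient registrations raise or return
  documented empty/NaN results rather than guessing.
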