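# Methods

This note documents the models, conventions and numerical choices behind
`damscore`, and what its synthetic validation does and does not show.

## Input model

A recording session consists of (a) a dam pose table: for each frame, 32
keypoints with `(x, y, p)` where `p ∈ [0, 1]` is the pose model's
detection likelihood; (b) raw pup detections: per frame and per bodypart
(9 pup keypoints, nose to tail base) a variable-length list of
`(x, y, confidence)` with **no pup identity** — identity maintenance
across frames is deliberately not attempted, because litters huddle and
occlude each other so heavily that tracklet stitching discards most
detections, and the pipeline only needs the litter as a unit (its
centroid and extent); (c) interval annotations `(behavior, start s,
stop s)` for seven behaviors: nest attendance, active nursing, passive
nursing, licking/grooming, self-grooming, eating, drinking.

Conventions fixed here:

* **Pup slots.** Detections are assigned per frame and per bodypart to
  slots 1..max_pups (default 12, covering typical Long-Evans litters) in
  descending confidence, ties broken by ascending x then y, surplus
  dropped, empty slots `(0, 0, p=0)`. The assignment is deterministic and
  order-independent; a slot does not denote the same pup across frames.
  Every feature computed from pup data is symmetric in the slots, and a
  test asserts the full feature matrix is invariant under per-frame slot
  permutation.
* **Annotation rasterization.** Half-open `[start, stop)` at the video
  frame rate: frame *f* is positive iff `start ≤ f/fps < stop`, so
  adjacent bouts never double-count a boundary frame.
* **Length mismatch.** Dam and pup streams of unequal length are
  truncated to the shorter (padding would fabricate detections).
* **Likelihoods out of range** are clipped to [0, 1] with a warning
  (upstream float noise), never rejected.
* **Calibration.** Distances are converted to millimetres with a single
  px/mm scalar measured on a landmark of known size — conventionally the
  wire cage-top width at its lowest point. With a side-view camera the
  true scale varies with cage depth; the single scalar is a deliberate
  first-order correction for camera distance and resolution differences
  between recordings, not a full geometric calibration.
* Recording hours are printed truncated to one decimal (e.g. a
  3,366,254-frame corpus at 30 fps prints 31.1 h).

## Feature engineering

No outlier-correction pass is applied; occlusion robustness comes
entirely from the likelihoods, in two regimes: *probability-weighted*
(centroids weight coordinates by `p`; movement scales by
`min(p_t, p_{t-1})`) and *threshold-excluded* (hulls, the back-arch
circle fit and detected-point counts use only points with `p ≥ p_min`,
default 0.5, matching the pose models' likelihood cutoff).

The 218-feature roster (manifest version 1, shipped as YAML) satisfies
the fixed constraints — eight categories, 172 dam / 19 pup / 27 joint
features, rolling mean/sum/std windows at 0.1 / 1 / 2 s, and 30/60-min
pup-centroid variants inside the dam–pup distance family — with this
composition:

| category | n | content |
|---|---|---|
| dam_location | 16 | px coordinates of centroid/nose/head/tail anchors, smoothed and dispersion summaries of the centroid track |
| dam_areas | 40 | convex hulls (all points, head+ears, trunk) and nose–tailbase body length, each windowed |
| dam_angles | 22 | back-arch angle and head–body angle (each windowed), head and body bearings |
| dam_probabilities | 15 | mean/sum likelihood, low-likelihood count, per-group means, windowed |
| dam_movement | 79 | per-keypoint displacement (32), centroid/nose/ear movement windowed, mean back movement windowed |
| pup_area | 10 | litter convex hull, windowed |
| pup_probabilities | 9 | litter mean/sum likelihood and detected-point count, windowed |
| dam_pup_distances | 27 | centroid/nose/head vs instantaneous and 30/60-min pup centroids, two of them windowed |

Numerical conventions:

* **Rolling windows are trailing (causal)**, `w = max(1, round(span·fps))`
  frames ending at the current frame, shrinking at the start of the
  series; std is the population std (a single-frame window has std 0).
  Alignment is not dictated by any external convention; causal windows
  keep single-pass streaming possible.
* **Back-arch angle**: an algebraic least-squares (Kåsa) circle through
  the admissible back points, returning the unsigned angle subtended at
  the fitted centre between the first and last admissible points, in
  [0, 180]° (a dam's spine cannot arch past a half-turn). Collinear
  configurations (normal-equation determinant below 1e-12 of its scale)
  and frames with fewer than 3 admissible points return 0 with a
  low-confidence flag. On noise-free points from a known circle the fit
  recovers the analytic angle to 1e-6°.
* **Degenerate geometry never emits NaN** (tree models cannot ingest it):
  areas → 0, angles → 0, undefined centroids hold the last valid value
  (leading undefined frames take the first valid value; a video with no
  valid frame falls back to the cage centre).
* Long-window pup centroids pool all slot points of the trailing 30/60
  minutes, likelihood-weighted, with the same hold rule; they exist to
  bridge stretches when the litter is fully hidden by bedding or the dam.
* Location features stay in pixel coordinates of the frame (raw, not
  cage-normalized); distances/areas/movement are mm-based. Tests assert
  translation equivariance (mm/deg features invariant, px locations
  shifting exactly) and px/mm rescaling covariance (mm halves, mm²
  quarters when the calibration doubles).

## Classification

One independent binary random forest per behavior; no mutual exclusivity
(co-occurrence is real: nursing implies nest attendance). Configuration
is constrained to 100–1500 trees, minimum leaf 1 or 2, Gini impurity,
√d candidate features per split, a 20 % test split, and no class
rebalancing; defaults are 500 trees, leaf 1 (mid-range; every bundle
records its exact configuration and seed). Training halves the frames by
taking every other frame per video first — adjacent frames are
near-duplicates — and uses a stratified split at a fixed seed so rare
behaviors (passive nursing can sit near 2.5 % prevalence) appear in both
splits. The discrimination threshold is read off the precision–recall
curve on the test split: the smallest threshold attaining maximal F1.
A manual override (the programmatic equivalent of choosing a threshold
after visually inspecting predictions) is recorded with provenance
`"manual"`. Probability exactly at the threshold classifies positive
(≥). Bundles stamp the feature-manifest version and refuse to score a
matrix built under a different one.

## Bouts and summaries

A bout is a maximal run of positive frames; spans are inclusive on both
ends and `duration = (end − start + 1)/fps`, so a single frame is a
1-frame bout. Minimum-bout smoothing drops bouts shorter than a cutoff
and never merges across gaps; gap merging exists but is off by default,
and the default minimum is 0 (headline summaries are computed
unsmoothed). Per-video summaries report total duration, percent of
recording time, bout count and mean bout duration per behavior; a
behavior's own percentage never exceeds 100 but percentages across
behaviors may jointly exceed it. The long-format cohort export (video ×
behavior rows with litter id and postnatal day) feeds external
mixed-model analysis, which is out of scope here.

## Explainability

Permutation importance (scikit-learn backend, F1 scoring, seeded) ranks
features 1..218, ties broken by manifest order; category summaries are
arithmetic means of ranks within each of the eight categories.
Attributions use an exact additive path decomposition through every tree
of the forest: at each split on a sample's decision path, the change in
node-probability is credited to the split feature, and contributions are
averaged over trees. By construction `base + Σ contributions` equals the
forest's predicted probability to machine precision; the base value is
the mean of the trees' root-node class fractions (the training positive
rate as resampled by bagging — it can differ from the raw training
positive fraction by the bootstrap). Sampling follows the 150
behavior-present + 150 behavior-absent convention (all available frames,
with a warning, when a class is smaller); category sums are means over
each frame set, summed across a category's features with sign preserved.

## Synthetic sessions

The generator is a test oracle, not a biomechanical model: parametric
posture templates are deliberately simple and chosen so that the feature
families the classifiers rely on in practice (dam–pup distances, convex
hulls, ear/nose movement, back-arch angle) are what separates the
classes. Defaults mirror typical recordings: 30 fps, 1280×780 px,
2 px/mm, an 8-pup litter; tests use 60 s sessions. The nest zone is
placed at a seed-dependent location because real nests are built
anywhere; food and water zones are fixed cage hardware; unlabeled idle
segments target seeded random off-nest locations (a fixed idle spot
would let raw location features shortcut nest attendance). Templates:
nest behaviors put the dam at the nest near the pup centroid; active
nursing arches the back to 130°, passive nursing flattens it to 8° with
a stretched, limbs-out posture; licking/grooming adds 6 Hz nose/ear
oscillation at the nest and self-grooming the same oscillation at a
floor corner away from the litter (floor corners only, so the spot
cannot coincide with the wall-mounted water spout); drinking pitches the
head up at the water zone. Dam keypoints drop out i.i.d. (likelihood 0)
at rate 0.08; pup occlusion is episodic — litter-wide hidden episodes of
mean 8 s covering `dropout²` of the session, plus per-point dropout at
0.4 × the nominal rate while visible — reflecting that litters vanish
for long stretches under bedding or the dam, which is the premise of the
30/60-min centroid windows. Coordinates carry 2 px Gaussian jitter. All
randomness flows from one scenario seed through independent spawned
substreams (layout / schedule / dam / pups), so sessions are
bit-reproducible, and the generator emits every on-disk format the IO
layer reads (the fixture set round-trips losslessly).

What passing the synthetic suite shows: the pipeline's plumbing,
geometry, training, thresholding and bout logic are correct, and the
intended feature families do carry the class signal (held-out F1 ≥ 0.95
for nest attendance and ≥ 0.85 for every behavior when training on 20
sessions and scoring 4 held-out ones; nest-attendance F1 degrades
monotonically as pup occlusion rises). What it does not show: performance
on real video, where pose errors are structured (left/right confusions,
identity swaps), postures are continuous rather than templated, and
annotation boundaries are uncertain. Real-data scores must be
established per laboratory with annotated held-out videos.

## Problem sizes and determinism

Test and acceptance runs use 60 s sessions (1800 frames at 30 fps) —
20 training + 4 held-out sessions for the recovery check, 6 + 2 per
occlusion level for the degradation check, 12 + 3 in the acceptance
script — and 100-tree forests; these sizes give stable scores while
keeping the suites quick, and all of them are the package's own
defaults for its validation harness, configurable by the caller. Every
stochastic step (simulation, splits, forests, permutation importance,
attribution sampling) is seeded; identical inputs and seeds reproduce
identical bundles and predictions.

## Known limitations

* The feature roster is a documented, versioned choice satisfying the
  published constraints; other rosters satisfying the same constraints
  exist, and trained bundles are only valid for the manifest version
  they were trained on.
* The single px/mm scalar under-corrects perspective; distances for a
  dam at the back of the cage are overestimated relative to the front.
* Episodic occlusion uses a two-state process with fixed mean episode
  length; real occlusion durations are heavier-tailed.
* The threshold-selection default (max-F1) is a convention; deployments
  that prize precision over recall should override it per behavior.
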