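# Methods

## Problem setting and model

`wildtrack` implements tracking-by-detection for wildlife video under a weak
(few-shot) detector. The inputs are per-frame detections — boxes with
confidences, optionally with unit-norm appearance (re-ID) embeddings — and
the output is a set of per-identity trajectories. The tracker is an online
one: frame T is processed knowing nothing of frame T+1.

### Motion model

Each track holds a constant-velocity Kalman filter on the state
(cx, cy, a, h, ċx, ċy, ȧ, ḣ), where a = w/h. The measurement selects the
first four components. Process and measurement noise standard deviations are
proportional to the box height — weights 1/20 for position-like terms and
1/160 for velocity-like terms — and the time step is one frame. These are
the de-facto standard constants for appearance-based tracking-by-detection;
nothing in the method depends delicately on them, and all are configurable.
The association gate on motion is the squared Mahalanobis distance of the
measurement under the predicted state, thresholded at the χ² 0.95 quantile
with 4 degrees of freedom (9.4877).

### Three-stage association

1. **Cascade matching** (appearance): confirmed tracks, grouped by
   `time_since_update` and processed most-recent-first, are matched to
   detections by the minimum cosine distance between the detection embedding
   and the track's gallery (bounded at 100 entries, oldest evicted), gated
   at cosine distance 0.2 and by the Mahalanobis gate. Recency priority
   means a stale track can never steal a detection from a fresh track, even
   at equal cost.
2. **Central-point matching** (geometry): tentative tracks plus confirmed
   tracks that went unmatched in the cascade and were seen one frame ago are
   matched to the remaining detections by Euclidean center distance divided
   by the image diagonal, gated at 0.05. This stage exists because IoU
   between a detection and two heavily overlapping candidate tracks is
   nearly tied while the center distances are not; normalizing by the
   diagonal makes the gate resolution-independent. The stage is purely
   geometric (no appearance term): it runs precisely when appearance
   matching has already failed or is unavailable.
3. **IoU matching**: the stage-2 leftovers are matched on cost 1 − IoU,
   gated at 0.7 (i.e. IoU ≥ 0.3).

Each stage is a gated linear assignment problem: forbidden pairs carry a
sentinel cost (1e5, far above any feasible total) and are discarded from the
solution; `scipy.optimize.linear_sum_assignment` solves the rest. Ties break
toward the lowest (track index, detection index), making runs deterministic.
Geometric stages use the Kalman-predicted box of the track, so a track that
just missed a frame is compared at its extrapolated position.

"Two-stage" mode — the ablation comparator — disables the IoU stage,
leaving cascade + central-point matching. A separate toggle can instead
disable the central-point stage; both toggles live in `RunConfig`.

### Track lifecycle

New tracks start *tentative*; a tentative track is deleted the first frame
it goes unmatched and is promoted to *confirmed* at 3 cumulative hits
(`n_init`). Confirmed tracks are deleted after 30 consecutive unmatched
frames (`max_age`). Only confirmed tracks emit output. The emitted box for a
matched frame is the matched detection's box rather than the Kalman
posterior: the filter's posterior carries a small steady-state lag on moving
targets, and the detection is the better localization whenever one exists
(the Kalman state is still updated normally and drives gating/prediction).

### Trajectory reconstruction

If a confirmed track finds no detection in frame T, and the center of its
last box lies in the closed central region [mW, (1−m)W] × [mH, (1−m)H] with
margin m = 0.1, the tracker re-emits the last box as the frame T record
(flagged `reconstructed`) — for at most 5 consecutive frames
(`reconstruction_cap`). The cap reflects the observation that a lower cap
leaves trajectories broken while a higher one fabricates them; any real
match resets the consecutive counter ("continuous" reconstruction is a
streak, not a lifetime budget). Reconstruction also resets
`time_since_update`, so a reconstructed track re-enters the cascade at depth
1 the next frame. The re-emitted box is a verbatim copy of the last box;
constant-velocity extrapolation of the box is available behind
`reconstruct_with_prediction` but off by default, since copying is the
conservative choice when the detector — not the motion model — is what
failed. Tracks whose last center lies in the margin do not reconstruct: an
animal at the frame border plausibly left the scene.

The reconstruction interacts with evaluation in one deliberate way:
reconstructed records are ordinary output records, so each one that still
overlaps the ground truth at IoU ≥ 0.5 removes a false negative. That is the
mechanism by which reconstruction raises MOTA.

## Metrics

CLEAR-MOT with correspondence persistence: pairs matched in frame T−1 are
kept in frame T whenever their IoU still clears the threshold (0.5 default),
and only the remainder enters a fresh minimum-(1 − IoU) assignment.
Persistence is what makes identity switches well-defined; a switch is
counted when a ground-truth object's matched identity differs from the
identity it was *most recently* matched with, so switches across occlusion
gaps are counted too. MOTA = 1 − (FN+FP+IDSW)/GT may be negative; MOTP is
reported as mean (1 − IoU) over matched pairs (lower is better, ~0 for
pixel-perfect boxes). Identity metrics use one global bipartite matching
between ground-truth and predicted identities maximizing the number of
frame-level IoU hits (IDTP); IDF1/IDP/IDR follow from IDTP, IDFP, IDFN.
Aggregation over classes sums count columns and recomputes every ratio from
the pooled counts — overall MOTA is GT-weighted, not a mean of per-class
percentages.

The test suite cross-checks FP/FN/IDSW/MOTA/IDTP/IDF1 against an
independent enumeration-based implementation (`tests/reference_mot.py`) that
shares no code with the package: exhaustive permutation search in place of
the Hungarian algorithm, its own IoU, its own bookkeeping. The reference
deliberately mirrors the Hungarian *objective* (minimum total cost with
unit cost for infeasible cells) because maximum-cardinality matching is a
genuinely different criterion that can disagree on legitimate inputs.

## Curation and augmentation

**Perceptual hash.** Resize to 32×32 (bilinear, on the luma image using
0.299/0.587/0.114 weights), 2-D type-II DCT as F = A f Aᵀ with the
orthonormal basis A(i,j) = c(i)·cos[(j+0.5)πi/N], c(0)=√(1/N),
c(i>0)=√(2/N) (so A Aᵀ = I, verified to 1e-9 in tests), keep the top-left
8×8 block, and set bit = 1 iff the coefficient exceeds the block mean
computed without the DC term. The DC bit is forced to 0 — it encodes only
overall brightness — which also makes the hash invariant to uniform
brightness scaling and gives the constant image the all-zero signature. The
comparison uses a scale-relative epsilon (1e-8 of the largest coefficient)
so float residue in degenerate images cannot flip "equal to the mean" bits.

**Similarity filtering.** All-pairs Hamming distances; any pair at distance
≤ 5 (configurable) loses its later member; survivors are ranked by their
nearest-neighbor distance, most dissimilar first, and the top
ceil(keep_fraction · n_survivors) are kept, with keep_fraction defaulting to
0.6. The 60% cut is applied *after* duplicate removal (the two steps are
otherwise order-sensitive; applying the fraction to the already-deduplicated
pool is the reading that keeps the two rules independent). Compositing is
`mask·fg + (1−mask)·bg` with user-supplied masks; the spatial-constraint
check refuses to pair a foreground twice with backgrounds that are
near-duplicates of each other, which is how implausible repeated pastes are
suppressed without any semantic scene model (foreground/background
segmentation and inpainting are the user's problem, by design).

**Elastic distortion.** Per-pixel displacement fields dx, dy sampled
uniformly in [−1, 1] from a seeded generator, Gaussian-smoothed with
σ = δ·min(W,H) pixels, scaled by α, applied by bilinear resampling with
edge clamping. Defaults δ = 0.07 and α = 5 px. δ is interpreted as a
fraction of the short image side because a smoothing scale of 0.07 *pixels*
would be a no-op; a raw-pixels mode (`delta_in_pixels=True`) is provided for
users who want the other unit. Since smoothing is a convex average of values
in [−1, 1], displacements are bounded by α — α = 0 is the exact identity
(asserted in tests) — and in practice heavy smoothing shrinks the typical
displacement well below the bound.

## Synthetic study conditions

The generator emulates a small camera-trap tracking dataset: 1–5 animals in
a fixed W×H frame (default 640×480), velocity-damped reflected random walks
(v ← 0.9 v + N(0, 0.5²) per axis, speed capped at 2 px/frame) with fixed
per-identity box sizes (40–80 px); Bernoulli missed detections (default
p = 0.1), Poisson false positives (0.1/frame, uniform boxes, fresh random
embeddings), Gaussian box jitter (2 px), and embeddings built as a
per-identity unit anchor plus isotropic noise (σ = 0.1 at D = 32),
renormalized. Anchors are reject-sampled to pairwise |cos| < 0.5 so that
appearance is informative at small D, mimicking a trained re-ID space.
Every stream is reproducible from one seed.

Three named conditions (`wildtrack.scenarios`) fix the study settings:

* `perfect_scenario` — all corruption off; a correct tracker must reproduce
  ground truth exactly after the n_init−1 warm-up frames (evaluation starts
  at frame n_init, using the generator's `confirmed_from` map).
* `central_gap_scenario` — clean detector except constructed 4-frame
  blackouts (two per animal), placed only where the animal's center stays in
  the central region for the whole gap and the preceding frame, separated by
  ≥ 5 detected frames so the reconstruction streak counter resets. Gap
  length 4 < cap 5, box sizes ≥ 40 px and speed ≤ 2 px/frame keep the
  re-emitted box above IoU 0.5 against the moving ground truth, so
  reconstruction removes every gap FN.
* `overlap_scenario` — 3 animals with 100–140 px boxes in a 320×240 frame,
  speed up to 8 px/frame, 15% misses, 6 px jitter, embedding noise σ = 0.25.
  Here the appearance gate fails often and the jitter regularly exceeds the
  central-point gate (0.05·diag = 20 px), so the IoU stage carries much of
  the association — the regime in which three-stage matching beats
  two-stage on both FP and FN.

What the synthetic data does *not* model: appearance drift over time,
lighting changes, camera motion, inter-animal occlusion correlated with
proximity, detector confidence structure, or box-size errors correlated with
pose. Passing tests therefore demonstrate the correctness of the tracking,
reconstruction, association and metric machinery under controlled
statistics — not field-accuracy claims for any particular species or camera
setup.

## Numerical and design choices

* IoU returns exactly 1.0 for identical boxes (fast path) and clamps at 1.0:
  `(l+w)−l` can round either side of `w`, which property-based testing
  surfaced as self-IoU ≠ 1.
* The assignment sentinel is 1e5, orders of magnitude above any feasible
  gated total (≤ 5 for 5 pairs of cost ≤ 1), so minimizing total cost first
  maximizes the number of feasible matches.
* Tracks matched at the center or IoU stage receive Kalman updates and
  gallery appends exactly as cascade matches do; uniform treatment is the
  simplest contract and is what the lifecycle tests pin down.
* Result files render coordinates with `repr` (shortest exact decimal), so
  write → read round-trips are bit-exact; integers print without a decimal
  point, matching the common MOT16 result style.
* Metric evaluation windows by `start_frame` to exclude the tracker's
  confirmation warm-up, which is a property of the tracker configuration,
  not of the scenario.
* Problem sizes in tests and the acceptance script (200–300-frame scenarios,
  3 animals, 40-frame cross-check scenarios, 500 assignment matrices up to
  5×5) are chosen so the whole suite runs in seconds while every code path —
  cascade depth > 1, reconstruction caps, gap re-acquisition, duplicate
  suppression — is exercised.

## Known limitations

* The tracker is strictly online and single-camera; no re-identification
  across long absences beyond `max_age`, no camera-motion compensation.
* Reconstruction re-emits a stationary box; a fast animal can outrun it
  within the 5-frame cap (IoU with ground truth decays with speed × gap
  length). The `reconstruct_with_prediction` switch trades this against
  fabricating motion the detector never saw.
* Appearance quality is entirely inherited from the supplied embeddings; the
  package neither trains nor fine-tunes an extractor, so the elastic
  distortion utility improves tracking only through whatever external
  training pipeline consumes its output.
* Per-class evaluation requires the caller to split files by class; the
  aggregator then pools the reports.
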