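# wildtrack

Multi-object tracking-by-detection for wildlife video, built for the
camera-trap regime where the detector is weak: it was trained on a handful
of images per species, so it misses animals for runs of frames and produces
occasional false boxes. `wildtrack` links such detections into stable
per-animal trajectories and provides the data-curation and augmentation
utilities used to prepare few-shot training imagery, plus the standard
evaluation metrics for the result.

It is aimed at ecologists and computer-vision practitioners who already have
per-frame detections (MOT16/MOTChallenge text format, optionally with re-ID
embedding vectors in a sidecar file) and need tracking, evaluation, or
ablation tooling — not at training detectors, which is out of scope.

## The method

**Tracker.** Each track carries a constant-velocity Kalman filter over the
box state (cx, cy, w/h, h) and a gallery of appearance embeddings. Each
frame is associated in three stages:

1. *Cascade matching* — confirmed tracks, most recently seen first, are
   matched to detections by the smallest cosine distance between the
   detection embedding and the track's gallery, gated by the cosine
   threshold and by the squared Mahalanobis distance
   (χ²₀.₉₅, 4 dof = 9.4877) of the box under the Kalman prediction.
2. *Central-point matching* — leftovers are matched by Euclidean distance
   between box centers, normalized by the image diagonal. When animals
   overlap heavily, IoU costs between candidate pairs tie while center
   distances do not, so this stage resolves exactly the ambiguity that IoU
   matching cannot.
3. *IoU matching* — the final geometric fallback on cost 1 − IoU.

Every stage is a gated linear assignment problem solved by the Hungarian
algorithm; gated pairs can never match.

**Trajectory reconstruction.** When a confirmed track finds no detection in
frame T but its last center lies in the central region of the image (margin
0.1 of each side), the tracker re-emits the frame T−1 box as the frame T
position, for at most 5 consecutive frames. The rationale: an animal in the
frame interior that vanished from the detections was almost certainly missed
by the weak detector (an animal at the border plausibly left the scene), and
over a few frames it has barely moved, so the previous box still localizes
it. This directly removes the false negatives a few-shot detector is prone
to.

**Evaluation.** CLEAR-MOT with persistent frame-to-frame correspondence at
IoU ≥ 0.5:

    MOTA = 1 − (FN + FP + IDSW) / GT,   MOTP = mean(1 − IoU) over matches

and identity metrics from one global bipartite matching of ground-truth to
predicted identities:

    IDF1 = 2·IDTP / (2·IDTP + IDFP + IDFN)

with per-class reports pooled by summing count columns (never by averaging
percentages).

**Data curation and augmentation.** A 64-bit perceptual hash (32×32
grayscale → orthonormal 2-D DCT `F = A f Aᵀ` → top-left 8×8 block
thresholded at its mean) compared by Hamming distance
`d(x,y) = Σ x[i] ⊕ y[i]` drives near-duplicate removal and keeps composite
training samples from reusing effectively identical backgrounds. Elastic
distortion warps images by a Gaussian-smoothed random displacement field
(smoothness δ = 0.07 of the short side, strength α = 5 px) to enrich animal
poses without destroying the image.

## Worked example

```bash
python examples/track_synthetic_sequence.py
```

generates a 3-animal 200-frame sequence with a mildly unreliable detector
(10% missed boxes, 0.1 false positives/frame, 2 px jitter, noisy 32-d
embeddings), tracks it, and prints:

```
    Class  IDF1   IDP   IDR  FP  FN  IDs  MOTA  MOTP
synthetic 99.32 100.0 98.65   0   8    0 98.65 0.098
```

Read: of ~590 ground-truth boxes after the confirmation warm-up, 8 were
missed (FN), none were hallucinated (FP), and no animal changed identity
(IDs = 0), giving MOTA 98.65%; IDF1 99.32% says essentially every frame of
every animal was attributed to a single stable identity; MOTP 0.098 is the
mean localization distance (1 − IoU) of matched boxes, reflecting the 2 px
detector jitter.

The other examples show each capability in isolation:
`reconstruction_ablation.py` (FN 24 → 0 when reconstruction fills central
detector gaps), `matching_stage_ablation.py` (FP 84 → 7, FN 79 → 8 when the
IoU stage is added to cascade+center matching on overlap-heavy video),
`curate_images_with_phash.py`, and `elastic_distortion_demo.py`.

The same operations are available from a shell:

```bash
wildtrack simulate --out-dir scen --seed 5 --n-objects 2 --n-frames 100
wildtrack track --det scen/det.txt --embeddings scen/embeddings.txt \
    --embedding-dim 32 --out result.txt
wildtrack evaluate --gt scen/gt.txt --result result.txt --start-frame 3
wildtrack ablate --toggle reconstruction --scenario central_gaps
```

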