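"""Synthetic tracking scenarios and test imagery.

Emulates the statistical structure of a small camera-trap tracking dataset:
a handful of animals per sequence moving smoothly inside a fixed frame, a
detector that misses boxes (Bernoulli, or constructed central gaps), emits
false positives (Poisson per frame), and jitters box coordinates (Gaussian),
and a re-identification embedder that returns a noisy copy of a per-identity
anchor direction on the unit sphere.  Everything is reproducible from the
scenario seed.

The generator also reports, per identity, the frame from which a tracker
with an ``n_init``-frame confirmation delay can be expected to output it
(`confirmed_from`), so evaluations can window away warm-up frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import BoundingBox, Detection, GroundTruthEntry

__all__ = ["ScenarioConfig", "Scenario", "generate_scenario", "generate_test_images"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic sequence.

    Defaults describe a modest wildlife clip: a few animals in a 640x480
    frame, gentle smooth motion, mid-sized boxes, a detector with a 10% miss
    rate and 0.1 false positives per frame, 2 px of box jitter, and 32-d
    embeddings with enough anchor separation that appearance is informative.
    """

    n_objects: int = 3
    n_frames: int = 200
    width: int = 640
    height: int = 480
    velocity_sd: float = 0.5        # px/frame random acceleration
    max_speed: float = 2.0          # px/frame speed cap (smooth motion)
    box_size_range: tuple[int, int] = (40, 80)
    p_miss: float = 0.1
    gap_mode: str = "random"        # "random" | "central_gaps"
    gap_length: int = 4             # central_gaps: frames per constructed gap
    n_gaps_per_object: int = 2
    fp_rate: float = 0.1            # expected false positives per frame
    box_jitter_sd: float = 2.0
    embedding_dim: int = 32
    embedding_noise_sd: float = 0.1
    central_margin: float = 0.1
    n_init: int = 3                 # confirmation delay assumed for warm-up windowing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 1 or self.n_frames < 1:
            raise ValueError("need at least one object and one frame")
        if not (0.0 <= self.p_miss <= 1.0):
            raise ValueError("p_miss must be a probability")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")
        if self.box_size_range[1] >= min(self.width, self.height):
            raise ValueError("box sizes must fit inside the image")
        if self.gap_mode not in ("random", "central_gaps"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")


@dataclass
class Scenario:
    config: ScenarioConfig
    ground_truth: list[GroundTruthEntry]
    detections: list[Detection]
    confirmed_from: dict[int, int] = field(default_factory=dict)

    def detections_by_frame(self) -> list[list[Detection]]:
        buckets: list[list[Detection]] = [[] for _ in range(self.config.n_frames)]
        for d in self.detections:
            buckets[d.frame - 1].append(d)
        return buckets


def _anchors(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    """Per-identity unit anchors, reject-sampled until pairwise |cos| < 0.5 so
    appearance matching is informative even at small dimension."""
    anchors: list[np.ndarray] = []
    while len(anchors) < n:
        v = rng.normal(size=dim)
        v /= np.linalg.norm(v)
        if all(abs(float(v @ a)) < 0.5 for a in anchors):
            anchors.append(v)
    return np.array(anchors)


def _smooth_tracks(cfg: ScenarioConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Reflected, velocity-damped random walks for object centers; fixed
    per-identity box sizes.  Returns (centers[n_obj, n_frames, 2], sizes[n_obj, 2])."""
    sizes = rng.integers(cfg.box_size_range[0], cfg.box_size_range[1] + 1, size=(cfg.n_objects, 2)).astype(float)
    centers = np.zeros((cfg.n_objects, cfg.n_frames, 2))
    for k in range(cfg.n_objects):
        w, h = sizes[k]
        lo = np.array([w / 2 + 1, h / 2 + 1])
        hi = np.array([cfg.width - w / 2 - 1, cfg.height - h / 2 - 1])
        pos = rng.uniform(lo, hi)
        vel = rng.uniform(-cfg.max_speed, cfg.max_speed, size=2)
        for t in range(cfg.n_frames):
            centers[k, t] = pos
            vel = 0.9 * vel + rng.normal(scale=cfg.velocity_sd, size=2)
            speed = float(np.hypot(*vel))
            if speed > cfg.max_speed:
                vel *= cfg.max_speed / speed
            pos = pos + vel
            for ax in range(2):  # reflect at the walls, keeping the box inside
                if pos[ax] < lo[ax]:
                    pos[ax] = 2 * lo[ax] - pos[ax]
                    vel[ax] = -vel[ax]
                elif pos[ax] > hi[ax]:
                    pos[ax] = 2 * hi[ax] - pos[ax]
                    vel[ax] = -vel[ax]
    return centers, sizes


def _central_gap_frames(
    cfg: ScenarioConfig, centers: np.ndarray, rng: np.random.Generator
) -> list[set[int]]:
    """Choose per-object gap frames entirely inside the central region.

    A gap of length L starting at frame s requires the object center to lie
    in the central region on frames s-1 .. s+L-1 (the tracker reconstructs
    from the last pre-gap box, which must itself be central).  Gaps are
    separated by at least 5 detected frames so the consecutive-
    reconstruction counter resets between them.
    """
    m = cfg.central_margin
    lo = np.array([m * cfg.width, m * cfg.height])
    hi = np.array([(1 - m) * cfg.width, (1 - m) * cfg.height])
    gaps: list[set[int]] = []
    for k in range(cfg.n_objects):
        central = np.all((centers[k] >= lo) & (centers[k] <= hi), axis=1)
        chosen: set[int] = set()
        # frames are 1-based; keep early frames intact for track confirmation
        candidates = [
            s
            for s in range(10, cfg.n_frames - cfg.gap_length)
            if central[s - 2 : s + cfg.gap_length - 1].all()
        ]
        rng.shuffle(candidates)
        for s in candidates:
            if len(chosen) >= cfg.n_gaps_per_object * cfg.gap_length:
                break
            frames = set(range(s, s + cfg.gap_length))
            near = set(range(s - 6, s + cfg.gap_length + 6))
            if chosen & near:
                continue
            chosen |= frames
        gaps.append(chosen)
    return gaps


def generate_scenario(config: Optional[ScenarioConfig] = None, **overrides) -> Scenario:
    """Generate ground truth and corrupted detections for one sequence."""
    cfg = replace(config or ScenarioConfig(), **overrides) if overrides else (config or ScenarioConfig())
    rng = np.random.default_rng(cfg.seed)

    centers, sizes = _smooth_tracks(cfg, rng)
    anchors = _anchors(rng, cfg.n_objects, cfg.embedding_dim)

    if cfg.gap_mode == "central_gaps":
        gap_frames = _central_gap_frames(cfg, centers, rng)
    else:
        gap_frames = [set() for _ in range(cfg.n_objects)]

    ground_truth: list[GroundTruthEntry] = []
    detections: list[Detection] = []
    for t in range(1, cfg.n_frames + 1):
        for k in range(cfg.n_objects):
            cx, cy = centers[k, t - 1]
            w, h = sizes[k]
            gt_box = BoundingBox(cx - w / 2, cy - h / 2, w, h)
            ground_truth.append(GroundTruthEntry(frame=t, identity=k + 1, box=gt_box))

            if t in gap_frames[k]:
                continue
            if cfg.gap_mode == "random" and cfg.p_miss > 0 and rng.uniform() < cfg.p_miss:
                continue
            jitter = rng.normal(scale=cfg.box_jitter_sd, size=2) if cfg.box_jitter_sd > 0 else np.zeros(2)
            det_box = BoundingBox(gt_box.left + jitter[0], gt_box.top + jitter[1], w, h)
            emb = anchors[k] + rng.normal(scale=cfg.embedding_noise_sd, size=cfg.embedding_dim)
            emb = emb / np.linalg.norm(emb)
            detections.append(Detection(frame=t, box=det_box, confidence=1.0, embedding=emb))

        for _ in range(rng.poisson(cfg.fp_rate)):
            fw = float(rng.uniform(*cfg.box_size_range))
            fh = float(rng.uniform(*cfg.box_size_range))
            fl = float(rng.uniform(1, cfg.width - fw))
            ft = float(rng.uniform(1, cfg.height - fh))
            femb = rng.normal(size=cfg.embedding_dim)
            femb = femb / np.linalg.norm(femb)
            detections.append(
                Detection(frame=t, box=BoundingBox(fl, ft, fw, fh), confidence=0.5, embedding=femb)
            )

    # with detections present from frame 1, a tracker with an n_init
    # confirmation delay first outputs each identity at frame n_init
    confirmed_from = {k + 1: cfg.n_init for k in range(cfg.n_objects)}
    return Scenario(
        config=cfg,
        ground_truth=ground_truth,
        detections=detections,
        confirmed_from=confirmed_from,
    )


def generate_test_images(
    n: int, size: int = 64, seed: int = 0, n_duplicates: int = 0
) -> list[np.ndarray]:
    """Deterministic textured grayscale test images (smooth random blobs on a
    gradient).  The last ``n_duplicates`` images are near-copies of the first
    ones with faint pixel noise, giving controllable near-duplicate pairs for
    similarity-filter tests."""
    if n < 1:
        raise ValueError("need at least one image")
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    n_base = n - n_duplicates
    if n_base < 1:
        raise ValueError("n_duplicates must leave at least one base image")
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    for k in range(n_base):
        gx, gy = rng.uniform(-1, 1, size=2)
        img = 128 + 40 * (gx * xx + gy * yy) / size
        img = img + gaussian_filter(rng.normal(scale=120, size=(size, size)), sigma=size / 10)
        images.append(np.clip(img, 0, 255))
    for k in range(n_duplicates):
        base = images[k % n_base]
        images.append(np.clip(base + rng.normal(scale=1.0, size=base.shape), 0, 255))
    return images
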