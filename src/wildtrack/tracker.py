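"""Per-frame tracking orchestration with trajectory reconstruction.

Each frame: predict all live tracks, run the three-stage matching, update
matched tracks, *reconstruct* unmatched confirmed tracks whose last center
lies in the central region of the image (re-emitting their last box for up
to a capped number of consecutive frames — this compensates for a weak
detector's missed detections), initiate tentative tracks from unmatched
detections, and apply the tentative/confirmed/deleted lifecycle.

Reconstruction is limited to the central region because an object whose last
position touched the frame margin has plausibly left the field of view,
whereas one in the interior was most likely missed by the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .association import three_stage_match
from .io import BoundingBox, Detection, ResultRecord, RunConfig
from .motion import KalmanFilter, KalmanState

__all__ = [
    "Track",
    "CentralRegion",
    "TrajectorySet",
    "Tracker",
    "in_central_region",
    "run",
]

TENTATIVE, CONFIRMED, DELETED = "tentative", "confirmed", "deleted"


@dataclass(frozen=True)
class CentralRegion:
    """Interior of the frame at a fixed margin fraction on each side."""

    margin: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (0.0 < self.margin < 0.5):
            raise ValueError("margin must lie in (0, 0.5)")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")


def in_central_region(point: tuple[float, float], region: CentralRegion) -> bool:
    """True iff the point lies in the closed central rectangle
    [m*W, (1-m)*W] x [m*H, (1-m)*H]."""
    x, y = point
    m = region.margin
    return (
        m * region.width <= x <= (1 - m) * region.width
        and m * region.height <= y <= (1 - m) * region.height
    )


@dataclass
class Track:
    """A persistent identity: Kalman state, appearance gallery, lifecycle
    counters, and the consecutive-reconstruction counter."""

    identity: int
    kalman: KalmanState
    state: str = TENTATIVE
    hits: int = 1
    time_since_update: int = 0
    consecutive_reconstructions: int = 0
    last_box: BoundingBox = None
    gallery: list[np.ndarray] = field(default_factory=list)
    gallery_budget: int = 100

    @property
    def is_confirmed(self) -> bool:
        return self.state == CONFIRMED

    @property
    def is_deleted(self) -> bool:
        return self.state == DELETED

    @property
    def last_center(self) -> tuple[float, float]:
        return self.last_box.center

    @property
    def predicted_box(self) -> BoundingBox:
        """Box at the Kalman-predicted mean (constant-velocity extrapolation)."""
        return BoundingBox.from_cxcyah(self.kalman.mean[:4])

    def append_embedding(self, embedding: Optional[np.ndarray]) -> None:
        if embedding is None:
            return
        self.gallery.append(embedding)
        if len(self.gallery) > self.gallery_budget:
            del self.gallery[: len(self.gallery) - self.gallery_budget]


@dataclass
class TrajectorySet:
    """Final tracker output: at most one record per (frame, identity)."""

    records: list[ResultRecord] = field(default_factory=list)

    def by_frame(self) -> dict[int, list[ResultRecord]]:
        out: dict[int, list[ResultRecord]] = {}
        for r in self.records:
            out.setdefault(r.frame, []).append(r)
        return out


def reconstruct(track: Track, region: CentralRegion, cap: int) -> Optional[BoundingBox]:
    """Attempt trajectory reconstruction for a confirmed, unmatched track.

    If the track's last center lies in the central region and fewer than
    ``cap`` consecutive reconstructions have been used, the last box is
    re-emitted as this frame's position: the object moves little over a few
    frames, so the previous box still localizes it.  Returns the box, having
    updated the track's counters; returns None (track ages normally) when
    the region predicate or the cap forbids it.
    """
    if not track.is_confirmed:
        return None
    if track.consecutive_reconstructions >= cap:
        return None
    if not in_central_region(track.last_center, region):
        return None
    track.consecutive_reconstructions += 1
    track.time_since_update = 0
    return track.last_box


class Tracker:
    """Online multi-object tracker over externally produced detections."""

    def __init__(self, config: Optional[RunConfig] = None, reconstruction: bool = True):
        self.config = config or RunConfig()
        self.reconstruction = reconstruction
        self.kf = KalmanFilter()
        self.tracks: list[Track] = []
        self._next_identity = 1
        self.region = CentralRegion(
            self.config.central_margin, self.config.image_width, self.config.image_height
        )
        # per-frame stage tallies for ablation logging
        self.stage_counts: dict[str, int] = {"cascade": 0, "center": 0, "iou": 0}
        self.reconstructions_used = 0
        self.frame = 0

    def step(self, detections: Sequence[Detection]) -> list[ResultRecord]:
        """Advance one frame; returns the output records for that frame.

        An empty detection list advances to the next consecutive frame (the
        detector saw nothing), which is when reconstruction matters most.
        """
        if detections:
            frames = {d.frame for d in detections}
            if len(frames) > 1:
                raise ValueError(f"detections span multiple frames: {sorted(frames)}")
            frame = detections[0].frame
            if frame <= self.frame:
                raise ValueError(f"frames out of order: {frame} after {self.frame}")
        else:
            frame = self.frame + 1
        self.frame = frame

        # 1. predict
        for t in self.tracks:
            t.kalman = self.kf.predict(t.kalman)
            t.time_since_update += 1

        # 2. associate
        assignment = three_stage_match(self.tracks, detections, self.config)

        records: list[ResultRecord] = []

        # 3. update matched tracks
        for track_idx, det_idx, stage in assignment.matches:
            track, det = self.tracks[track_idx], detections[det_idx]
            self.stage_counts[stage] += 1
            track.kalman = self.kf.update(track.kalman, det.box.to_cxcyah())
            track.append_embedding(det.embedding)
            track.hits += 1
            track.time_since_update = 0
            track.consecutive_reconstructions = 0
            track.last_box = det.box
            if track.state == TENTATIVE and track.hits >= self.config.n_init:
                track.state = CONFIRMED
            if track.is_confirmed:
                records.append(ResultRecord(det.frame, track.identity, det.box, "detected"))

        # 4. reconstruction / ageing of unmatched tracks
        for track_idx in assignment.unmatched_tracks:
            track = self.tracks[track_idx]
            box = None
            if self.reconstruction:
                box = reconstruct(track, self.region, self.config.reconstruction_cap)
            if box is not None:
                if self.config.reconstruct_with_prediction:
                    box = track.predicted_box
                self.reconstructions_used += 1
                records.append(ResultRecord(frame, track.identity, box, "reconstructed"))
            elif track.state == TENTATIVE:
                track.state = DELETED
            elif track.time_since_update > self.config.max_age:
                track.state = DELETED

        # 5. initiate tentative tracks from unmatched detections
        for det_idx in assignment.unmatched_detections:
            det = detections[det_idx]
            track = Track(
                identity=self._next_identity,
                kalman=self.kf.initiate(det.box.to_cxcyah()),
                last_box=det.box,
                gallery_budget=self.config.gallery_budget,
            )
            track.append_embedding(det.embedding)
            self._next_identity += 1
            self.tracks.append(track)

        # 6. drop deleted tracks
        self.tracks = [t for t in self.tracks if not t.is_deleted]
        return records


def run(
    detection_stream: Iterable[Sequence[Detection]],
    config: Optional[RunConfig] = None,
    reconstruction: bool = True,
) -> TrajectorySet:
    """Track a whole sequence.

    ``detection_stream`` yields one list of detections per frame, in
    increasing frame order (empty lists for frames without detections).
    Deterministic given inputs and config; identities are assigned in order
    of track initiation.
    """
    tracker = Tracker(config, reconstruction=reconstruction)
    out = TrajectorySet()
    last_frame = 0
    for frame_dets in detection_stream:
        if frame_dets:
            f = frame_dets[0].frame
            if f <= last_frame:
                raise ValueError(f"frames out of order: {f} after {last_frame}")
            last_frame = f
        out.records.extend(tracker.step(list(frame_dets)))
    return out


def group_by_frame(
    detections: Sequence[Detection], n_frames: Optional[int] = None
) -> list[list[Detection]]:
    """Bucket a flat detection list into consecutive per-frame lists
    1..n_frames (missing frames become empty lists)."""
    if n_frames is None:
        n_frames = max((d.frame for d in detections), default=0)
    buckets: list[list[Detection]] = [[] for _ in range(n_frames)]
    for d in detections:
        buckets[d.frame - 1].append(d)
    return buckets
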