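"""Cost matrices and the three-stage track--detection association.

Stage 1 (*cascade matching*) associates confirmed tracks against detections
by appearance — smallest cosine distance to the track's embedding gallery,
gated by both the cosine threshold and the squared-Mahalanobis motion gate —
iterating track age from most recently seen to oldest so that fresher tracks
get priority.  Stage 2 (*central-point matching*) associates the leftovers by
Euclidean distance between box centers, normalized by the image diagonal; it
resolves the heavily-overlapping-box case where IoU costs tie but centers do
not.  Stage 3 (*IoU matching*) catches what remains with a 1 - IoU cost.

All stages are gated linear assignment problems: forbidden pairs carry a
sentinel cost and are never matched; the solver minimizes total cost with
scipy's Hungarian implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import BoundingBox, Detection, RunConfig

if TYPE_CHECKING:  # pragma: no cover
    from .tracker import Track

__all__ = [
    "GATE_SENTINEL",
    "FrameAssignment",
    "iou",
    "iou_cost_matrix",
    "center_cost_matrix",
    "appearance_cost_matrix",
    "solve_assignment",
    "cascade_match",
    "three_stage_match",
]

# strictly larger than any feasible gated cost (costs are <= 64 in practice)
GATE_SENTINEL = 1e5


@dataclass
class FrameAssignment:
    """Outcome of one frame's matching: matches tagged by the stage that made
    them, plus the unmatched track and detection index sets."""

    matches: list[tuple[int, int, str]] = field(default_factory=list)
    unmatched_tracks: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)


def iou(box_a: BoundingBox, box_b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 1 iff identical, 0 iff disjoint."""
    if box_a == box_b:
        return 1.0
    lx = max(box_a.left, box_b.left)
    ty = max(box_a.top, box_b.top)
    rx = min(box_a.left + box_a.width, box_b.left + box_b.width)
    by = min(box_a.top + box_a.height, box_b.top + box_b.height)
    iw, ih = max(0.0, rx - lx), max(0.0, by - ty)
    inter = iw * ih
    union = box_a.area + box_b.area - inter
    if union <= 0:
        return 0.0
    # clamp: (l + w) - l can round above w, pushing self-IoU past 1
    return min(1.0, inter / union)


def iou_cost_matrix(
    track_boxes: Sequence[BoundingBox],
    det_boxes: Sequence[BoundingBox],
    gate: float = 0.7,
) -> np.ndarray:
    """(1 - IoU) cost, entries above ``gate`` replaced by the sentinel."""
    cost = np.full((len(track_boxes), len(det_boxes)), GATE_SENTINEL)
    for j, tb in enumerate(track_boxes):
        for i, db in enumerate(det_boxes):
            c = 1.0 - iou(tb, db)
            if c <= gate:
                cost[j, i] = c
    return cost


def center_cost_matrix(
    track_boxes: Sequence[BoundingBox],
    det_boxes: Sequence[BoundingBox],
    image_diag: float,
    gate: float = 0.05,
) -> np.ndarray:
    """Center-to-center Euclidean distance over the image diagonal, gated."""
    if image_diag <= 0:
        raise ValueError("image diagonal must be positive")
    cost = np.full((len(track_boxes), len(det_boxes)), GATE_SENTINEL)
    for j, tb in enumerate(track_boxes):
        tcx, tcy = tb.center
        for i, db in enumerate(det_boxes):
            dcx, dcy = db.center
            c = float(np.hypot(tcx - dcx, tcy - dcy)) / image_diag
            if c <= gate:
                cost[j, i] = c
    return cost


def appearance_cost_matrix(
    galleries: Sequence[Sequence[np.ndarray]],
    embeddings: Sequence[np.ndarray],
    gate: float = 0.2,
) -> np.ndarray:
    """Smallest cosine distance from each detection embedding to each track's
    gallery of past embeddings, gated by the cosine threshold.

    All vectors must be unit-norm and share one dimension.  An empty gallery
    or a missing embedding yields the sentinel (pair cannot be appearance-
    matched).
    """
    n_t, n_d = len(galleries), len(embeddings)
    cost = np.full((n_t, n_d), GATE_SENTINEL)
    for j, gallery in enumerate(galleries):
        if not len(gallery):
            continue
        g = np.asarray(gallery)
        for i, e in enumerate(embeddings):
            if e is None:
                continue
            if g.shape[1] != e.shape[0]:
                raise ValueError(
                    f"embedding dimension mismatch: gallery {g.shape[1]} vs detection {e.shape[0]}"
                )
            c = float(np.min(1.0 - g @ e))
            if c <= gate:
                cost[j, i] = c
    return cost


def solve_assignment(cost: np.ndarray) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost one-to-one assignment on a gated cost matrix.

    Sentinel pairs are never matched.  Ties are broken toward the lowest
    (row, column) pair because scipy's solver scans rows in order; the result
    is deterministic for a fixed matrix.
    """
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    n_rows, n_cols = cost.shape
    if n_rows == 0 or n_cols == 0:
        return [], list(range(n_rows)), list(range(n_cols))
    rows, cols = linear_sum_assignment(cost)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < GATE_SENTINEL]
    matched_rows = {r for r, _ in matches}
    matched_cols = {c for _, c in matches}
    unmatched_rows = [r for r in range(n_rows) if r not in matched_rows]
    unmatched_cols = [c for c in range(n_cols) if c not in matched_cols]
    return matches, unmatched_rows, unmatched_cols


def _gated_appearance_cost(
    tracks: Sequence["Track"],
    detections: Sequence[Detection],
    config: RunConfig,
) -> np.ndarray:
    """Appearance cost with the Mahalanobis motion gate applied on top."""
    from .motion import KalmanFilter

    cost = appearance_cost_matrix(
        [t.gallery for t in tracks],
        [d.embedding for d in detections],
        gate=config.appearance_gate,
    )
    if not len(tracks) or not len(detections):
        return cost
    kf = KalmanFilter()
    measurements = np.array([d.box.to_cxcyah() for d in detections])
    for j, track in enumerate(tracks):
        gating = kf.gating_distance(track.kalman, measurements)
        cost[j, gating > config.mahalanobis_gate] = GATE_SENTINEL
    return cost


def cascade_match(
    tracks: Sequence["Track"],
    detections: Sequence[Detection],
    config: RunConfig,
    track_indices: Optional[Sequence[int]] = None,
    det_indices: Optional[Sequence[int]] = None,
) -> FrameAssignment:
    """Age-prioritized appearance matching of confirmed tracks.

    Tracks are grouped by ``time_since_update`` and matched depth by depth
    (1 .. max_age): a track missed for fewer frames competes for detections
    before an older one, so a stale track can never steal a detection from a
    fresh one even at equal cost.
    """
    track_indices = list(range(len(tracks))) if track_indices is None else list(track_indices)
    det_indices = list(range(len(detections))) if det_indices is None else list(det_indices)

    assignment = FrameAssignment()
    remaining_dets = list(det_indices)
    for depth in range(1, config.max_age + 1):
        if not remaining_dets:
            break
        level = [k for k in track_indices if tracks[k].time_since_update == depth]
        if not level:
            continue
        cost = _gated_appearance_cost(
            [tracks[k] for k in level], [detections[i] for i in remaining_dets], config
        )
        matches, _, _ = solve_assignment(cost)
        matched_dets = set()
        for r, c in matches:
            assignment.matches.append((level[r], remaining_dets[c], "cascade"))
            matched_dets.add(remaining_dets[c])
        remaining_dets = [i for i in remaining_dets if i not in matched_dets]

    matched_tracks = {t for t, _, _ in assignment.matches}
    assignment.unmatched_tracks = [k for k in track_indices if k not in matched_tracks]
    assignment.unmatched_detections = remaining_dets
    return assignment


def three_stage_match(
    tracks: Sequence["Track"],
    detections: Sequence[Detection],
    config: RunConfig,
) -> FrameAssignment:
    """Run the full cascade -> central-point -> IoU matching for one frame.

    Confirmed tracks enter the cascade; tentative tracks and confirmed tracks
    that just missed (``time_since_update == 1``) fall through to the
    geometric stages.  The center and IoU stages can each be disabled via the
    config toggles for ablation runs.
    """
    confirmed = [k for k, t in enumerate(tracks) if t.is_confirmed]
    tentative = [k for k, t in enumerate(tracks) if not t.is_confirmed]

    cascade = cascade_match(tracks, detections, config, confirmed)

    # geometric pool: tentative tracks plus confirmed tracks that went
    # unmatched in the cascade and were seen only one frame ago
    pool = tentative + [
        k for k in cascade.unmatched_tracks if tracks[k].time_since_update == 1
    ]
    pool.sort()
    stale = [k for k in cascade.unmatched_tracks if tracks[k].time_since_update != 1]
    remaining_dets = list(cascade.unmatched_detections)

    result = FrameAssignment(matches=list(cascade.matches))

    if config.use_center_stage and pool and remaining_dets:
        cost = center_cost_matrix(
            [tracks[k].predicted_box for k in pool],
            [detections[i].box for i in remaining_dets],
            config.image_diagonal,
            gate=config.center_gate,
        )
        matches, um_t, um_d = solve_assignment(cost)
        for r, c in matches:
            result.matches.append((pool[r], remaining_dets[c], "center"))
        pool = [pool[r] for r in um_t]
        remaining_dets = [remaining_dets[c] for c in um_d]

    if config.use_iou_stage and pool and remaining_dets:
        cost = iou_cost_matrix(
            [tracks[k].predicted_box for k in pool],
            [detections[i].box for i in remaining_dets],
            gate=config.iou_gate,
        )
        matches, um_t, um_d = solve_assignment(cost)
        for r, c in matches:
            result.matches.append((pool[r], remaining_dets[c], "iou"))
        pool = [pool[r] for r in um_t]
        remaining_dets = [remaining_dets[c] for c in um_d]

    result.unmatched_tracks = sorted(pool + stale)
    result.unmatched_detections = remaining_dets
    return result
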