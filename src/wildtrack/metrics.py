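"""CLEAR-MOT and identity metrics for tracker evaluation.

Per frame, ground-truth boxes are put in correspondence with hypothesis
boxes: pairs that corresponded in the previous frame persist whenever their
IoU still clears the threshold, and the remainder is matched by minimum
(1 - IoU) assignment.  Unmatched ground truth counts as a false negative,
unmatched hypotheses as false positives, and a ground-truth object whose
matched identity differs from the identity it last corresponded with counts
as an identity switch.  From the accumulated counts:

    MOTA = 1 - (FN + FP + IDSW) / GT          (can be negative, at most 1)
    MOTP = mean (1 - IoU) over matched pairs  (lower is better)

Identity metrics come from a single *global* bipartite matching between
ground-truth identities and hypothesis identities that maximizes the number
of frame-level overlaps attributable to matched identity pairs:

    IDF1 = 2*IDTP / (2*IDTP + IDFP + IDFN),  IDP = IDTP/(IDTP+IDFP),
    IDR = IDTP/(IDTP+IDFN)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .association import iou
from .io import BoundingBox, GroundTruthEntry, ResultRecord

__all__ = ["MetricsReport", "match_frame", "evaluate", "aggregate", "report_table"]


@dataclass
class MetricsReport:
    """Counts and derived scores for one sequence or class."""

    FP: int = 0
    FN: int = 0
    IDSW: int = 0
    GT: int = 0
    IDTP: int = 0
    IDFP: int = 0
    IDFN: int = 0
    motp_sum: float = 0.0   # sum of (1 - IoU) over matched pairs
    n_matches: int = 0
    name: str = ""

    @property
    def MOTA(self) -> float:
        if self.GT == 0:
            return 1.0 if (self.FP + self.FN + self.IDSW) == 0 else float("-inf")
        return 1.0 - (self.FN + self.FP + self.IDSW) / self.GT

    @property
    def MOTP(self) -> float:
        return self.motp_sum / self.n_matches if self.n_matches else 0.0

    @property
    def IDF1(self) -> float:
        denom = 2 * self.IDTP + self.IDFP + self.IDFN
        return 2 * self.IDTP / denom if denom else 1.0

    @property
    def IDP(self) -> float:
        denom = self.IDTP + self.IDFP
        return self.IDTP / denom if denom else 1.0

    @property
    def IDR(self) -> float:
        denom = self.IDTP + self.IDFN
        return self.IDTP / denom if denom else 1.0


def match_frame(
    gt_boxes: dict[int, BoundingBox],
    hyp_boxes: dict[int, BoundingBox],
    prev_correspondence: dict[int, int],
    last_matched: dict[int, int],
    iou_threshold: float = 0.5,
) -> tuple[dict[int, int], int, int, int, float]:
    """One frame of the CLEAR correspondence protocol.

    Parameters
    ----------
    gt_boxes, hyp_boxes
        identity -> box for this frame.
    prev_correspondence
        gt identity -> hyp identity pairs holding in the previous frame.
    last_matched
        gt identity -> hyp identity it was most recently matched with, over
        the whole sequence (used to detect switches across gaps); updated
        in place.

    Returns ``(correspondence, fp, fn, idsw, motp_increment)``.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must lie in (0, 1)")
    correspondence: dict[int, int] = {}
    motp_inc = 0.0

    # keep persisting pairs first: this is what makes IDSW well-defined
    for g, h in prev_correspondence.items():
        if g in gt_boxes and h in hyp_boxes:
            ov = iou(gt_boxes[g], hyp_boxes[h])
            if ov >= iou_threshold:
                correspondence[g] = h
                motp_inc += 1.0 - ov

    free_gt = sorted(g for g in gt_boxes if g not in correspondence)
    used_hyps = set(correspondence.values())
    free_hyp = sorted(h for h in hyp_boxes if h not in used_hyps)

    idsw = 0
    if free_gt and free_hyp:
        cost = np.ones((len(free_gt), len(free_hyp)))
        for r, g in enumerate(free_gt):
            for c, h in enumerate(free_hyp):
                ov = iou(gt_boxes[g], hyp_boxes[h])
                if ov >= iou_threshold:
                    cost[r, c] = 1.0 - ov
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] < 1.0:  # 1.0 marks pairs below the IoU threshold
                g, h = free_gt[r], free_hyp[c]
                correspondence[g] = h
                motp_inc += cost[r, c]

    for g, h in correspondence.items():
        if g in last_matched and last_matched[g] != h:
            idsw += 1
        last_matched[g] = h

    fn = len(gt_boxes) - len(correspondence)
    fp = len(hyp_boxes) - len(correspondence)
    return correspondence, fp, fn, idsw, motp_inc


def _id_counts(
    gt_frames: dict[int, dict[int, BoundingBox]],
    hyp_frames: dict[int, dict[int, BoundingBox]],
    iou_threshold: float,
) -> tuple[int, int, int]:
    """Global identity matching: maximize frame-overlap hits over a one-to-one
    pairing of ground-truth identities with hypothesis identities."""
    gt_ids = sorted({g for frame in gt_frames.values() for g in frame})
    hyp_ids = sorted({h for frame in hyp_frames.values() for h in frame})
    total_gt = sum(len(f) for f in gt_frames.values())
    total_hyp = sum(len(f) for f in hyp_frames.values())
    if not gt_ids or not hyp_ids:
        return 0, total_hyp, total_gt

    # hits[j, i] = number of frames where gt_ids[j] and hyp_ids[i] overlap
    hits = np.zeros((len(gt_ids), len(hyp_ids)))
    g_index = {g: j for j, g in enumerate(gt_ids)}
    h_index = {h: i for i, h in enumerate(hyp_ids)}
    for frame in gt_frames:
        gts = gt_frames.get(frame, {})
        hyps = hyp_frames.get(frame, {})
        for g, gb in gts.items():
            for h, hb in hyps.items():
                if iou(gb, hb) >= iou_threshold:
                    hits[g_index[g], h_index[h]] += 1
    rows, cols = linear_sum_assignment(-hits)
    idtp = int(hits[rows, cols].sum())
    return idtp, total_hyp - idtp, total_gt - idtp


def evaluate(
    gt: Sequence[GroundTruthEntry],
    hyp: Sequence[ResultRecord | GroundTruthEntry],
    iou_threshold: float = 0.5,
    start_frame: int = 1,
    end_frame: Optional[int] = None,
    name: str = "",
) -> MetricsReport:
    """Evaluate a hypothesis track set against ground truth.

    ``start_frame``/``end_frame`` window the evaluation (inclusive); frames
    outside the window contribute nothing, which is how warm-up frames of a
    tracker with a confirmation delay are excluded.
    """
    gt_frames: dict[int, dict[int, BoundingBox]] = {}
    for e in gt:
        if e.frame < start_frame or (end_frame is not None and e.frame > end_frame):
            continue
        gt_frames.setdefault(e.frame, {})[e.identity] = e.box
    hyp_frames: dict[int, dict[int, BoundingBox]] = {}
    for r in hyp:
        if r.frame < start_frame or (end_frame is not None and r.frame > end_frame):
            continue
        hyp_frames.setdefault(r.frame, {})[r.identity] = r.box

    report = MetricsReport(name=name)
    report.GT = sum(len(f) for f in gt_frames.values())

    frames = sorted(set(gt_frames) | set(hyp_frames))
    correspondence: dict[int, int] = {}
    last_matched: dict[int, int] = {}
    for f in frames:
        correspondence, fp, fn, idsw, motp_inc = match_frame(
            gt_frames.get(f, {}),
            hyp_frames.get(f, {}),
            correspondence,
            last_matched,
            iou_threshold,
        )
        report.FP += fp
        report.FN += fn
        report.IDSW += idsw
        report.motp_sum += motp_inc
        report.n_matches += len(correspondence)

    report.IDTP, report.IDFP, report.IDFN = _id_counts(gt_frames, hyp_frames, iou_threshold)
    return report


def aggregate(reports: Sequence[MetricsReport], name: str = "OVERALL") -> MetricsReport:
    """Pool per-class reports: count fields are summed and every ratio is
    recomputed from the pooled counts (never averaged across classes)."""
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    out = MetricsReport(name=name)
    for r in reports:
        out.FP += r.FP
        out.FN += r.FN
        out.IDSW += r.IDSW
        out.GT += r.GT
        out.IDTP += r.IDTP
        out.IDFP += r.IDFP
        out.IDFN += r.IDFN
        out.motp_sum += r.motp_sum
        out.n_matches += r.n_matches
    return out


def report_table(reports: Sequence[MetricsReport], overall: bool = True) -> pd.DataFrame:
    """Render reports as the conventional per-class table with an OVERALL row
    of pooled counts."""
    rows = list(reports)
    if overall and len(rows) > 1:
        rows.append(aggregate(rows))
    return pd.DataFrame(
        {
            "Class": [r.name for r in rows],
            "IDF1": [round(100 * r.IDF1, 2) for r in rows],
            "IDP": [round(100 * r.IDP, 2) for r in rows],
            "IDR": [round(100 * r.IDR, 2) for r in rows],
            "FP": [r.FP for r in rows],
            "FN": [r.FN for r in rows],
            "IDs": [r.IDSW for r in rows],
            "MOTA": [round(100 * r.MOTA, 2) for r in rows],
            "MOTP": [round(r.MOTP, 3) for r in rows],
        }
    )
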