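"""Independent brute-force reference for CLEAR-MOT and identity metrics.

Deliberately shares no code with the package: its own IoU, exhaustive
permutation search instead of the Hungarian algorithm, and plain-dict
bookkeeping.  Only usable at small problem sizes; exists as a test oracle.
"""

from __future__ import annotations

import itertools


def ref_iou(a, b) -> float:
    # boxes as (left, top, width, height) tuples
    ax2, ay2 = a[0] + a[2], a[1] + a[3]
    bx2, by2 = b[0] + b[2], b[1] + b[3]
    iw = min(ax2, bx2) - max(a[0], b[0])
    ih = min(ay2, by2) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a[2] * a[3] + b[2] * b[3] - inter)


def _best_assignment(gt_items, hyp_items, threshold):
    """Exhaustive minimum-cost matching, mirroring the Hungarian objective:
    every assigned pair costs 1 - IoU when the IoU clears the threshold and
    1.0 otherwise, exactly min(n_gt, n_hyp) cells are assigned, and pairs
    below the threshold are discarded afterwards.  Returns gt_id -> hyp_id.
    """
    gt_ids = list(gt_items)
    hyp_ids = list(hyp_items)
    if not gt_ids or not hyp_ids:
        return {}

    def cost(g, h):
        ov = ref_iou(gt_items[g], hyp_items[h])
        return 1.0 - ov if ov >= threshold else 1.0

    best, best_total = {}, float("inf")
    if len(gt_ids) <= len(hyp_ids):
        for perm in itertools.permutations(hyp_ids, len(gt_ids)):
            total = sum(cost(g, h) for g, h in zip(gt_ids, perm))
            if total < best_total - 1e-12:
                best_total = total
                best = {g: h for g, h in zip(gt_ids, perm) if cost(g, h) < 1.0}
    else:
        for perm in itertools.permutations(gt_ids, len(hyp_ids)):
            total = sum(cost(g, h) for g, h in zip(perm, hyp_ids))
            if total < best_total - 1e-12:
                best_total = total
                best = {g: h for g, h in zip(perm, hyp_ids) if cost(g, h) < 1.0}
    return best


def reference_clear(gt_frames, hyp_frames, threshold=0.5):
    """gt_frames/hyp_frames: frame -> {identity: (l, t, w, h)}.

    Returns dict with FP, FN, IDSW, GT, MOTA, motp_sum, n_matches.
    """
    frames = sorted(set(gt_frames) | set(hyp_frames))
    corr = {}
    last = {}
    fp = fn = idsw = 0
    motp_sum = 0.0
    n_matches = 0
    total_gt = sum(len(gt_frames.get(f, {})) for f in frames)
    for f in frames:
        gts = gt_frames.get(f, {})
        hyps = hyp_frames.get(f, {})
        new_corr = {}
        for g, h in corr.items():
            if g in gts and h in hyps and ref_iou(gts[g], hyps[h]) >= threshold:
                new_corr[g] = h
                motp_sum += 1.0 - ref_iou(gts[g], hyps[h])
        free_gt = {g: gts[g] for g in gts if g not in new_corr}
        used = set(new_corr.values())
        free_hyp = {h: hyps[h] for h in hyps if h not in used}
        extra = _best_assignment(free_gt, free_hyp, threshold)
        for g, h in extra.items():
            new_corr[g] = h
            motp_sum += 1.0 - ref_iou(gts[g], hyps[h])
        for g, h in new_corr.items():
            if g in last and last[g] != h:
                idsw += 1
            last[g] = h
        fn += len(gts) - len(new_corr)
        fp += len(hyps) - len(new_corr)
        n_matches += len(new_corr)
        corr = new_corr
    mota = 1.0 - (fn + fp + idsw) / total_gt if total_gt else 1.0
    return {
        "FP": fp,
        "FN": fn,
        "IDSW": idsw,
        "GT": total_gt,
        "MOTA": mota,
        "motp_sum": motp_sum,
        "n_matches": n_matches,
    }


def reference_id_metrics(gt_frames, hyp_frames, threshold=0.5):
    """Identity metrics by exhaustive search over gt-id -> hyp-id pairings."""
    gt_ids = sorted({g for f in gt_frames.values() for g in f})
    hyp_ids = sorted({h for f in hyp_frames.values() for h in f})
    total_gt = sum(len(f) for f in gt_frames.values())
    total_hyp = sum(len(f) for f in hyp_frames.values())

    hits = {}
    for f in set(gt_frames) | set(hyp_frames):
        for g, gb in gt_frames.get(f, {}).items():
            for h, hb in hyp_frames.get(f, {}).items():
                if ref_iou(gb, hb) >= threshold:
                    hits[(g, h)] = hits.get((g, h), 0) + 1

    best_idtp = 0
    padded = hyp_ids + [None] * len(gt_ids)
    for perm in set(itertools.permutations(padded, len(gt_ids))):
        idtp = sum(hits.get((g, h), 0) for g, h in zip(gt_ids, perm) if h is not None)
        best_idtp = max(best_idtp, idtp)
    idfp = total_hyp - best_idtp
    idfn = total_gt - best_idtp
    denom = 2 * best_idtp + idfp + idfn
    idf1 = 2 * best_idtp / denom if denom else 1.0
    return {"IDTP": best_idtp, "IDFP": idfp, "IDFN": idfn, "IDF1": idf1}
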