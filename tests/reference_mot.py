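"""Independent reference implementation of the CLEAR-MOT and identity metrics.

Deliberately naive and structurally unrelated to the package code path: the
per-frame assignment is found by exhaustive recursive search (maximum match
count, then minimum total distance) instead of the Hungarian algorithm, and
the global identity mapping by a bitmask dynamic program maximizing total
per-frame agreement instead of a padded minimum-cost assignment.  Used only
as a test oracle.
"""

from __future__ import annotations

import math
from functools import lru_cache


def trackset_to_frames(ts):
    """Flatten a TrackSet into {frame: [(track_id, (u, v)), ...]}."""
    out = {}
    for frame, dets in ts.by_frame().items():
        out[frame] = [(d.track_id, d.centroid) for d in dets]
    return out


def _gated_dist(g, p, threshold):
    d = math.hypot(g[0] - p[0], g[1] - p[1])
    return d if d <= threshold else None


def _best_assignment(free_g, free_p, dist):
    """Exhaustive search: maximize matches, break ties by minimal total cost.

    free_g / free_p are index lists; dist maps (gi, pj) -> gated cost.
    Returns a list of (gi, pj) pairs.
    """

    @lru_cache(maxsize=None)
    def solve(k, used):
        if k == len(free_g):
            return (0, 0.0, ())
        gi = free_g[k]
        best = solve(k + 1, used)  # leave gi unmatched
        for idx, pj in enumerate(free_p):
            if used >> idx & 1:
                continue
            c = dist.get((gi, pj))
            if c is None:
                continue
            n, cost, pairs = solve(k + 1, used | (1 << idx))
            cand = (n + 1, cost + c, ((gi, pj),) + pairs)
            if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
        return best

    result = solve(0, 0)[2]
    solve.cache_clear()
    return list(result)


def ref_clearmot(gt_frames, pred_frames, threshold):
    """Frame-by-frame CLEAR-MOT tallies with match persistence.

    Returns a dict with tp, fp, miss, ids, total_gt.
    """
    tp = fp = miss = ids = total_gt = 0
    last = {}  # gt id -> last matched pred id (across gaps)
    for f in sorted(set(gt_frames) | set(pred_frames)):
        gts = gt_frames.get(f, [])
        preds = pred_frames.get(f, [])
        total_gt += len(gts)
        dist = {}
        for i, (_, gp) in enumerate(gts):
            for j, (_, pp) in enumerate(preds):
                d = _gated_dist(gp, pp, threshold)
                if d is not None:
                    dist[(i, j)] = d

        pairs = []
        used_p = set()
        free_g = []
        pred_pos = {pid: j for j, (pid, _) in enumerate(preds)}
        for i, (gid, _) in enumerate(gts):
            h = last.get(gid)
            j = pred_pos.get(h) if h is not None else None
            if j is not None and (i, j) in dist:
                pairs.append((i, j))
                used_p.add(j)
            else:
                free_g.append(i)
        free_p = [j for j in range(len(preds)) if j not in used_p]
        pairs += _best_assignment(free_g, free_p, dist)

        for i, j in pairs:
            gid, pid = gts[i][0], preds[j][0]
            tp += 1
            if gid in last and last[gid] != pid:
                ids += 1
            last[gid] = pid
        miss += len(gts) - len(pairs)
        fp += len(preds) - len(pairs)
    return {"tp": tp, "fp": fp, "miss": miss, "ids": ids, "total_gt": total_gt}


def ref_id_metrics(gt_frames, pred_frames, threshold):
    """IDP/IDR/IDF1 by maximizing total trajectory agreement with a bitmask DP."""
    gt_ids = sorted({gid for dets in gt_frames.values() for gid, _ in dets})
    pred_ids = sorted({pid for dets in pred_frames.values() for pid, _ in dets})
    n_gt_det = sum(len(v) for v in gt_frames.values())
    n_pred_det = sum(len(v) for v in pred_frames.values())
    if n_gt_det == 0 and n_pred_det == 0:
        return 1.0, 1.0, 1.0

    gi = {g: i for i, g in enumerate(gt_ids)}
    pi = {p: j for j, p in enumerate(pred_ids)}
    overlap = [[0] * len(pred_ids) for _ in gt_ids]
    for f in set(gt_frames) & set(pred_frames):
        for gid, gp in gt_frames[f]:
            for pid, pp in pred_frames[f]:
                if _gated_dist(gp, pp, threshold) is not None:
                    overlap[gi[gid]][pi[pid]] += 1

    # DP over predicted trajectories; state = bitmask of consumed gt trajectories.
    dp = {0: 0}
    for j in range(len(pred_ids)):
        ndp = dict(dp)
        for state, val in dp.items():
            for i in range(len(gt_ids)):
                if state >> i & 1 or overlap[i][j] == 0:
                    continue
                ns, nv = state | (1 << i), val + overlap[i][j]
                if ndp.get(ns, -1) < nv:
                    ndp[ns] = nv
        dp = ndp
    idtp = max(dp.values()) if dp else 0

    idp = idtp / n_pred_det if n_pred_det else 0.0
    idr = idtp / n_gt_det if n_gt_det else 0.0
    idf1 = 2 * idp * idr / (idp + idr) if (idp + idr) > 0 else 0.0
    return idp, idr, idf1
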