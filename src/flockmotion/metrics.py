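"""Multi-object tracking and segmentation evaluation metrics.

Implements the CLEAR-MOT protocol (per-frame gated minimum-cost assignment
with match persistence, tallying false positives, misses and identity
switches into MOTA), the identity metrics IDP/IDR/IDF1 under an optimal
global trajectory mapping, throughput FPS, instance/class IoU and mIoU for
segmentation masks, and the speed RMSE.

Matching rule: within a frame, ground-truth objects and predictions are
paired by minimum-cost bipartite assignment, with cost either the centroid
Euclidean distance (gated at ``threshold``, default one tenth of the frame
height) or ``1 − IoU`` of the boxes gated at 0.5.  An existing pairing from
the previous frame is kept while it stays within the gate, as CLEAR-MOT
prescribes; an identity switch is charged at the frame where a ground-truth
object's matched predicted identity changes, ignoring gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .tracks_io import Detection, MaskRLE, TrackSet, decode_rle

__all__ = [
    "MetricError",
    "MotCounts",
    "MetricsReport",
    "match_tracks",
    "mota",
    "identification_metrics",
    "fps_throughput",
    "iou",
    "iou_bbox",
    "miou",
    "rmse",
    "evaluate",
]


class MetricError(ValueError):
    """Undefined metric or invalid metric input."""


@dataclass
class MotCounts:
    """Frame-level CLEAR-MOT event tallies."""

    true_positives: int = 0
    false_positives: int = 0
    misses: int = 0
    identity_switches: int = 0
    total_ground_truth_objects: int = 0

    def validate(self) -> None:
        if min(self.true_positives, self.false_positives, self.misses,
               self.identity_switches, self.total_ground_truth_objects) < 0:
            raise MetricError("negative count")
        if self.true_positives + self.misses != self.total_ground_truth_objects:
            raise MetricError("TP + misses must equal total ground-truth objects")
        if self.identity_switches > self.true_positives:
            raise MetricError("more identity switches than matches")


@dataclass
class MetricsReport:
    """All evaluation metrics of one ground-truth/prediction comparison."""

    mota: float
    idp: float
    idr: float
    idf1: float
    ids: int
    counts: MotCounts
    fps_throughput: float | None = None
    miou: float | None = None
    rmse: float | None = None

    def to_dict(self) -> dict:
        d = {
            "mota": self.mota,
            "idp": self.idp,
            "idr": self.idr,
            "idf1": self.idf1,
            "ids": self.ids,
            "true_positives": self.counts.true_positives,
            "false_positives": self.counts.false_positives,
            "misses": self.counts.misses,
            "total_gt_objects": self.counts.total_ground_truth_objects,
        }
        for k in ("fps_throughput", "miou", "rmse"):
            if getattr(self, k) is not None:
                d[k] = getattr(self, k)
        return d

    def summary(self) -> str:
        lines = [
            f"{'MOTA':<8}{self.mota:10.4f}",
            f"{'IDF1':<8}{self.idf1:10.4f}",
            f"{'IDP':<8}{self.idp:10.4f}",
            f"{'IDR':<8}{self.idr:10.4f}",
            f"{'IDS':<8}{self.ids:10d}",
            f"{'FP':<8}{self.counts.false_positives:10d}",
            f"{'Miss':<8}{self.counts.misses:10d}",
        ]
        if self.miou is not None:
            lines.append(f"{'mIoU':<8}{self.miou:10.4f}")
        if self.rmse is not None:
            lines.append(f"{'RMSE':<8}{self.rmse:10.4f} m/s")
        return "\n".join(lines)


def _pairwise_cost(gts: Sequence[Detection], preds: Sequence[Detection],
                   distance: str, threshold: float) -> np.ndarray:
    """Gated cost matrix; entries above the gate are +inf."""
    cost = np.full((len(gts), len(preds)), np.inf)
    for i, g in enumerate(gts):
        for j, p in enumerate(preds):
            if distance == "iou":
                c = 1.0 - iou_bbox(g.bbox, p.bbox)
            else:
                c = float(np.hypot(g.centroid[0] - p.centroid[0],
                                   g.centroid[1] - p.centroid[1]))
            if c <= threshold:
                cost[i, j] = c
    return cost


def default_threshold(ts: TrackSet) -> float:
    """Default centroid gate: one tenth of the frame height."""
    if ts.frame_size is None:
        raise MetricError("no frame size on the TrackSet: pass an explicit threshold")
    return 0.1 * ts.frame_size[1]


def match_tracks(
    gt: TrackSet,
    pred: TrackSet,
    threshold: float | None = None,
    distance: Literal["centroid", "iou"] = "centroid",
) -> tuple[dict[int, list[tuple[int, int]]], MotCounts]:
    """Run the CLEAR-MOT per-frame matching over two TrackSets.

    Returns the per-frame list of matched ``(gt_id, pred_id)`` pairs and the
    accumulated :class:`MotCounts`.  ``distance="iou"`` requires boxes on
    both sides and gates at ``threshold`` on ``1 − IoU`` (default 0.5).
    """
    if gt.fps != pred.fps:
        raise MetricError(f"fps mismatch: gt {gt.fps} vs pred {pred.fps}")
    if threshold is None:
        threshold = 0.5 if distance == "iou" else default_threshold(gt)

    gt_frames = gt.by_frame()
    pred_frames = pred.by_frame()
    frames = sorted(set(gt_frames) | set(pred_frames))

    counts = MotCounts()
    assignment: dict[int, list[tuple[int, int]]] = {}
    last_match: dict[int, int] = {}  # gt id -> last matched pred id (persists over gaps)

    for f in frames:
        gts = gt_frames.get(f, [])
        preds = pred_frames.get(f, [])
        counts.total_ground_truth_objects += len(gts)
        cost = _pairwise_cost(gts, preds, distance, threshold)

        matched_g: set[int] = set()
        matched_p: set[int] = set()
        pairs: list[tuple[int, int]] = []

        # CLEAR-MOT persistence: keep last frame's pairing while within the gate.
        pred_idx = {p.track_id: j for j, p in enumerate(preds)}
        for i, g in enumerate(gts):
            h = last_match.get(g.track_id)
            if h is None or h not in pred_idx:
                continue
            j = pred_idx[h]
            if np.isfinite(cost[i, j]):
                matched_g.add(i)
                matched_p.add(j)
                pairs.append((g.track_id, h))

        # Hungarian assignment on the remainder.
        free_g = [i for i in range(len(gts)) if i not in matched_g]
        free_p = [j for j in range(len(preds)) if j not in matched_p]
        if free_g and free_p:
            sub = cost[np.ix_(free_g, free_p)]
            finite = np.isfinite(sub)
            if finite.any():
                big = sub[finite].max() * (len(free_g) + len(free_p) + 1) + 1.0
                rows, cols = linear_sum_assignment(np.where(finite, sub, big))
                for r, c in zip(rows, cols):
                    if finite[r, c]:
                        i, j = free_g[r], free_p[c]
                        g, p = gts[i], preds[j]
                        matched_g.add(i)
                        matched_p.add(j)
                        pairs.append((g.track_id, p.track_id))

        for gid, pid in pairs:
            counts.true_positives += 1
            if gid in last_match and last_match[gid] != pid:
                counts.identity_switches += 1
            last_match[gid] = pid

        counts.misses += len(gts) - len(matched_g)
        counts.false_positives += len(preds) - len(matched_p)
        assignment[f] = sorted(pairs)

    counts.validate()
    return assignment, counts


def mota(c: MotCounts) -> float:
    """Multiple-object tracking accuracy:
    1 − (FP + misses + identity switches) / total ground-truth objects.

    At most 1; negative when errors outnumber ground-truth objects.
    """
    if c.total_ground_truth_objects <= 0:
        raise MetricError("MOTA undefined: no ground-truth objects")
    return 1.0 - (c.false_positives + c.misses + c.identity_switches) / c.total_ground_truth_objects


def identification_metrics(
    gt: TrackSet,
    pred: TrackSet,
    threshold: float | None = None,
    distance: Literal["centroid", "iou"] = "centroid",
) -> tuple[float, float, float]:
    """IDP, IDR and IDF1 under the optimal global identity mapping.

    Every ground-truth trajectory is assigned to at most one predicted
    trajectory (and vice versa) by a minimum-cost bipartite assignment whose
    cost counts the frames on which the pair disagrees; IDTP is the total
    per-frame agreement of the chosen mapping, and

        IDP = IDTP / (IDTP + IDFP),  IDR = IDTP / (IDTP + IDFN),
        IDF1 = 2·IDP·IDR / (IDP + IDR).
    """
    if threshold is None:
        threshold = 0.5 if distance == "iou" else default_threshold(gt)

    gt_ids = sorted(gt.trajectories)
    pred_ids = sorted(pred.trajectories)
    n_gt_det = gt.n_detections
    n_pred_det = pred.n_detections
    if n_gt_det == 0 and n_pred_det == 0:
        warnings.warn("empty ground truth and prediction: identity metrics defined as 1",
                      stacklevel=2)
        return 1.0, 1.0, 1.0

    # Per-pair frame agreement: frames where both are present within the gate.
    gt_frames = gt.by_frame()
    pred_frames = pred.by_frame()
    overlap = np.zeros((len(gt_ids), len(pred_ids)))
    gi = {t: i for i, t in enumerate(gt_ids)}
    pi = {t: j for j, t in enumerate(pred_ids)}
    for f in sorted(set(gt_frames) & set(pred_frames)):
        cost = _pairwise_cost(gt_frames[f], pred_frames[f], distance, threshold)
        for a, g in enumerate(gt_frames[f]):
            for b, p in enumerate(pred_frames[f]):
                if np.isfinite(cost[a, b]):
                    overlap[gi[g.track_id], pi[p.track_id]] += 1

    ng, np_ = len(gt_ids), len(pred_ids)
    len_g = np.array([len(gt.trajectories[t]) for t in gt_ids])
    len_p = np.array([len(pred.trajectories[t]) for t in pred_ids])
    # Padded square cost: matching a trajectory to "nothing" costs all its frames.
    full = np.zeros((ng + np_, ng + np_))
    full[:ng, :np_] = len_g[:, None] + len_p[None, :] - 2.0 * overlap
    full[:ng, np_:] = np.inf
    full[ng:, :np_] = np.inf
    for i in range(ng):
        full[i, np_ + i] = len_g[i]
    for j in range(np_):
        full[ng + j, j] = len_p[j]
    rows, cols = linear_sum_assignment(np.where(np.isinf(full), len_g.sum() + len_p.sum() + 1.0, full))
    idtp = sum(
        overlap[r, c] for r, c in zip(rows, cols) if r < ng and c < np_
    )
    idfp = n_pred_det - idtp
    idfn = n_gt_det - idtp
    idp = idtp / (idtp + idfp) if (idtp + idfp) > 0 else 0.0
    idr = idtp / (idtp + idfn) if (idtp + idfn) > 0 else 0.0
    idf1 = 2 * idp * idr / (idp + idr) if (idp + idr) > 0 else 0.0
    return float(idp), float(idr), float(idf1)


def fps_throughput(total_frames: int, total_time_s: float) -> float:
    """Processing throughput in frames per second (hardware-dependent)."""
    if not total_time_s > 0:
        raise MetricError(f"total time must be > 0 s, got {total_time_s}")
    if total_frames < 0:
        raise MetricError(f"negative frame count {total_frames}")
    return total_frames / total_time_s


def iou_bbox(a: tuple[float, float, float, float] | None,
             b: tuple[float, float, float, float] | None) -> float:
    """Intersection over union of two (left, top, w, h) boxes; 0 if either is missing."""
    if a is None or b is None:
        return 0.0
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix = max(0.0, min(ax0 + aw, bx0 + bw) - max(ax0, bx0))
    iy = max(0.0, min(ay0 + ah, by0 + bh) - max(ay0, by0))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def iou(a: MaskRLE, b: MaskRLE) -> float:
    """Pixel IoU of two masks sharing a frame size; 0 (with warning) if both empty."""
    if a.frame_size != b.frame_size:
        raise MetricError(f"frame size mismatch: {a.frame_size} vs {b.frame_size}")
    ra, rb = decode_rle(a).astype(bool), decode_rle(b).astype(bool)
    union = np.logical_or(ra, rb).sum()
    if union == 0:
        warnings.warn("IoU of two empty masks defined as 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(ra, rb).sum() / union)


def miou(pred_by_class: dict[int, list[MaskRLE]],
         gt_by_class: dict[int, list[MaskRLE]]) -> float:
    """Mean IoU over classes; each class mask is the union of its instances.

    Classes present in neither prediction nor ground truth are excluded from
    the mean with a warning.
    """
    classes = sorted(set(pred_by_class) | set(gt_by_class))
    if not classes:
        raise MetricError("no classes to evaluate")
    ious = []
    for c in classes:
        pm = _union_raster(pred_by_class.get(c, []))
        gm = _union_raster(gt_by_class.get(c, []))
        if pm is None and gm is None:
            warnings.warn(f"class {c} empty on both sides; excluded from mIoU", stacklevel=2)
            continue
        if pm is None or gm is None:
            ious.append(0.0)
            continue
        if pm.shape != gm.shape:
            raise MetricError(f"class {c}: frame size mismatch")
        union = np.logical_or(pm, gm).sum()
        ious.append(float(np.logical_and(pm, gm).sum() / union) if union else 0.0)
    if not ious:
        raise MetricError("all classes empty on both sides: mIoU undefined")
    return float(np.mean(ious))


def _union_raster(masks: list[MaskRLE]) -> np.ndarray | None:
    union = None
    for m in masks:
        r = decode_rle(m).astype(bool)
        union = r if union is None else (union | r)
    if union is not None and not union.any():
        return None
    return union


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error between paired actual and predicted speeds (m/s)."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise MetricError(f"paired 1-D vectors required, got shapes {y.shape} and {yhat.shape}")
    if y.size == 0:
        raise MetricError("RMSE undefined on empty input")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def speed_rmse(actual_series, predicted_series) -> float:
    """RMSE between two speed-series collections, paired by (track, window).

    ``actual_series`` and ``predicted_series`` map track id ->
    :class:`~flockmotion.speed.SpeedSeries`.  Only windows present on both
    sides are compared (a predicted track may be missing windows where
    detections were dropped); raises if no window pairs exist.
    """
    actual = {(tid, s.window): s.velocity_v
              for tid, series in actual_series.items() for s in series.samples}
    pred = {(tid, s.window): s.velocity_v
            for tid, series in predicted_series.items() for s in series.samples}
    keys = sorted(set(actual) & set(pred))
    if not keys:
        raise MetricError("no (track, window) pairs shared between actual and predicted speeds")
    return rmse([actual[k] for k in keys], [pred[k] for k in keys])


def evaluate(
    gt: TrackSet,
    pred: TrackSet,
    threshold: float | None = None,
    distance: Literal["centroid", "iou"] = "centroid",
    gt_masks_by_class: dict[int, list[MaskRLE]] | None = None,
    pred_masks_by_class: dict[int, list[MaskRLE]] | None = None,
    actual_speeds: Sequence[float] | None = None,
    predicted_speeds: Sequence[float] | None = None,
    elapsed_s: float | None = None,
) -> MetricsReport:
    """Full evaluation of a predicted TrackSet against ground truth."""
    _, counts = match_tracks(gt, pred, threshold=threshold, distance=distance)
    idp, idr, idf1 = identification_metrics(gt, pred, threshold=threshold, distance=distance)
    report = MetricsReport(
        mota=mota(counts),
        idp=idp,
        idr=idr,
        idf1=idf1,
        ids=counts.identity_switches,
        counts=counts,
    )
    if gt_masks_by_class is not None and pred_masks_by_class is not None:
        report.miou = miou(pred_masks_by_class, gt_masks_by_class)
    if actual_speeds is not None and predicted_speeds is not None:
        report.rmse = rmse(actual_speeds, predicted_speeds)
    if elapsed_s is not None:
        n_frames = 0
        fr = gt.frame_range
        if fr is not None:
            n_frames = fr[1] - fr[0] + 1
        report.fps_throughput = fps_throughput(n_frames, elapsed_s)
    return report
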