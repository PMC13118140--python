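"""Detection and keypoint evaluation metrics.

Boxes are compared with intersection-over-union (IoU); keypoint sets with
object keypoint similarity (OKS),

    OKS = Σ_i exp(−d_i² / (2 s² k_i²)) δ(v_i > 0) / Σ_i δ(v_i > 0)

where d_i is the pixel distance between predicted and ground-truth keypoint
i, s² the object scale (bounding-box pixel area by default), k_i the
per-keypoint falloff constant from the schema and δ(v_i>0) selects
annotated ground-truth keypoints.  Either similarity drives a greedy
one-to-one matcher (predictions in descending score order), from which
precision/recall/F1, per-threshold average precision (101-point COCO
interpolation), mAP@50 and mAP@[0.5:0.95] follow.

A keypoint-level confusion matrix attributes each annotated ground-truth
keypoint of a matched pose pair to the nearest predicted keypoint within a
radius, exposing systematic identity errors such as left/right symmetry
swaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .annotation import BoundingBox, Pose, N_KEYPOINTS
from .schema import SkeletonSchema

__all__ = [
    "OKSParams",
    "MatchResult",
    "EvalReport",
    "iou",
    "box_loss",
    "pose_error",
    "oks",
    "match",
    "average_precision",
    "summarize",
    "keypoint_confusion",
    "COCO_THRESHOLDS",
]

#: mAP@[0.5:0.95] threshold grid: 10 values, 0.50 to 0.95 step 0.05.
COCO_THRESHOLDS = tuple(round(0.5 + 0.05 * t, 2) for t in range(10))


@dataclass(frozen=True)
class OKSParams:
    """OKS configuration: 25 falloff constants and the object-scale rule.

    ``scale_mode="bbox_area"`` uses s² = box width × height in pixels
    (the COCO convention); ``"bbox_area_squared"`` squares the area, for
    readings of the scale term where s itself is the area.
    """

    k: tuple[float, ...]
    scale_mode: Literal["bbox_area", "bbox_area_squared"] = "bbox_area"

    def __post_init__(self) -> None:
        if len(self.k) != N_KEYPOINTS:
            raise ValueError(f"need {N_KEYPOINTS} constants, got {len(self.k)}")
        if any(not ki > 0 for ki in self.k):
            raise ValueError("all OKS constants must be > 0")

    @classmethod
    def from_schema(cls, schema: SkeletonSchema, **kwargs) -> "OKSParams":
        return cls(k=tuple(schema.oks_constants()), **kwargs)

    @classmethod
    def uniform(cls, k: float = 0.1, **kwargs) -> "OKSParams":
        return cls(k=(k,) * N_KEYPOINTS, **kwargs)


@dataclass
class MatchResult:
    """Greedy one-to-one matching outcome for one image."""

    pairs: list[tuple[int, int, float]]    # (pred id, gt id, similarity)
    tp: int
    fp: int
    fn: int


@dataclass
class EvalReport:
    """Aggregate evaluation: counts at threshold 0.5, AP per threshold, mAP."""

    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    ap_per_threshold: dict[float, float]
    map50: float
    map5095: float
    pr_curve: list[tuple[float, float]] = field(default_factory=list)
    confusion: np.ndarray | None = None


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 1 iff identical, 0 iff disjoint."""
    ax0, ay0, ax1, ay1 = a.xyxy
    bx0, by0, bx1, by1 = b.xyxy
    # areas from the same corner arithmetic as the intersection, so that
    # identical boxes yield exactly 1.0
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("zero-area box")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def box_loss(a: BoundingBox, b: BoundingBox) -> float:
    """1 − IoU: zero iff the boxes coincide."""
    return 1.0 - iou(a, b)


def pose_error(pred: Pose, gt: Pose, visible_only: bool = False) -> float:
    """Mean squared keypoint distance (1/K) Σ ‖p_i − g_i‖².

    The default averages over all 25 keypoints regardless of visibility.
    ``visible_only=True`` restricts the mean to ground-truth keypoints with
    v>0, which is the meaningful variant when unlabeled keypoints sit at
    the origin placeholder.
    """
    total, n = 0.0, 0
    for pk, gk in zip(pred.keypoints, gt.keypoints):
        if visible_only and not gk.visible:
            continue
        total += (pk.x - gk.x) ** 2 + (pk.y - gk.y) ** 2
        n += 1
    if n == 0:
        raise ValueError("no keypoints to average over")
    return total / n


def oks(pred: Pose, gt: Pose, params: OKSParams) -> float:
    """Object keypoint similarity between a prediction and a ground truth.

    Both poses must be in pixel coordinates.  Raises if the ground truth
    has no annotated (v>0) keypoint, which leaves the similarity undefined.
    """
    area = gt.box.area
    if area <= 0:
        raise ValueError("ground-truth box has zero area")
    s2 = area if params.scale_mode == "bbox_area" else area * area
    num, den = 0.0, 0
    for ki, pk, gk in zip(params.k, pred.keypoints, gt.keypoints):
        if not gk.visible:
            continue
        d2 = (pk.x - gk.x) ** 2 + (pk.y - gk.y) ** 2
        num += math.exp(-d2 / (2.0 * s2 * ki * ki))
        den += 1
    if den == 0:
        raise ValueError("OKS undefined: ground truth has no visible keypoints")
    return num / den


def _similarity_fn(similarity: str, params: OKSParams | None):
    if similarity == "iou":
        return lambda p, g: iou(p.box, g.box)
    if similarity == "oks":
        if params is None:
            raise ValueError("OKS matching requires OKSParams")
        return lambda p, g: oks(p, g, params)
    raise ValueError(f"unknown similarity {similarity!r}")


def match(
    preds: Sequence[Pose],
    gts: Sequence[Pose],
    similarity: Literal["iou", "oks"] = "oks",
    threshold: float = 0.5,
    params: OKSParams | None = None,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truths.

    Predictions are visited in descending score order (ties by input
    order); each claims the unmatched ground truth with the highest
    similarity ≥ threshold, similarity ties broken by the lower
    ground-truth id.  Deterministic by construction.
    """
    sim = _similarity_fn(similarity, params)
    order = sorted(range(len(preds)), key=lambda i: (-(preds[i].score or 0.0), i))
    taken: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for pi in order:
        best_gi, best_s = -1, -1.0
        for gi, gt in enumerate(gts):          # ascending gi: ties go to the lower gt id
            if gi in taken:
                continue
            s = sim(preds[pi], gt)
            if s >= threshold and s > best_s:
                best_gi, best_s = gi, s
        if best_gi >= 0:
            taken.add(best_gi)
            pairs.append((pi, best_gi, best_s))
    tp = len(pairs)
    return MatchResult(pairs=pairs, tp=tp, fp=len(preds) - tp, fn=len(gts) - tp)


def _pr_points(scored: Sequence[tuple[float, bool]], n_gt: int) -> tuple[np.ndarray, np.ndarray]:
    """Precision/recall staircase from (score, is_tp) detections."""
    order = sorted(range(len(scored)), key=lambda i: (-scored[i][0], i))
    tps = np.cumsum([1 if scored[i][1] else 0 for i in order]) if order else np.array([])
    fps = np.cumsum([0 if scored[i][1] else 1 for i in order]) if order else np.array([])
    if len(order) == 0:
        return np.array([]), np.array([])
    precision = tps / (tps + fps)
    recall = tps / n_gt
    return precision, recall


def average_precision(
    scored: Sequence[tuple[float, bool]],
    n_gt: int,
    n_points: int = 101,
) -> float:
    """Average precision from scored detections via 101-point interpolation.

    ``scored`` holds one (confidence, matched?) entry per prediction across
    the whole image set at a fixed similarity threshold; ``n_gt`` is the
    total number of ground-truth instances.
    """
    if n_gt <= 0:
        raise ValueError("AP undefined with no ground truths")
    precision, recall = _pr_points(scored, n_gt)
    if len(precision) == 0:
        return 0.0
    # precision envelope: best precision at recall >= r
    p_envelope = np.maximum.accumulate(precision[::-1])[::-1]
    grid = np.linspace(0.0, 1.0, n_points)
    idx = np.searchsorted(recall, grid, side="left")
    ap = np.where(idx < len(p_envelope), p_envelope[np.minimum(idx, len(p_envelope) - 1)], 0.0)
    return float(ap.mean())


def summarize(
    image_pairs: Iterable[tuple[Sequence[Pose], Sequence[Pose]]],
    similarity: Literal["iou", "oks"] = "oks",
    params: OKSParams | None = None,
    thresholds: Sequence[float] = COCO_THRESHOLDS,
    schema: SkeletonSchema | None = None,
    confusion_radius_frac: float = 0.1,
) -> EvalReport:
    """Evaluate (predictions, ground truths) pairs over a whole image set.

    Precision/recall/F1 come from aggregate match counts at threshold 0.5;
    AP is computed per threshold and averaged into mAP@[0.5:0.95].  When a
    schema is supplied the keypoint confusion matrix is accumulated over
    the threshold-0.5 matched pairs.
    """
    image_pairs = list(image_pairs)
    n_gt = sum(len(gts) for _, gts in image_pairs)
    if n_gt == 0:
        raise ValueError("no ground-truth instances to evaluate")

    scored_at: dict[float, list[tuple[float, bool]]] = {t: [] for t in thresholds}
    tp = fp = fn = 0
    confusion = np.zeros((N_KEYPOINTS, N_KEYPOINTS + 1), dtype=int) if schema is not None else None
    pr_scored: list[tuple[float, bool]] = []

    for preds, gts in image_pairs:
        for t in thresholds:
            res = match(preds, gts, similarity=similarity, threshold=t, params=params)
            matched_preds = {pi for pi, _, _ in res.pairs}
            for pi, p in enumerate(preds):
                scored_at[t].append((p.score or 0.0, pi in matched_preds))
        res50 = match(preds, gts, similarity=similarity, threshold=0.5, params=params)
        tp += res50.tp
        fp += res50.fp
        fn += res50.fn
        matched_preds = {pi for pi, _, _ in res50.pairs}
        pr_scored.extend((p.score or 0.0, pi in matched_preds) for pi, p in enumerate(preds))
        if confusion is not None:
            for pi, gi, _ in res50.pairs:
                confusion += keypoint_confusion_single(
                    preds[pi], gts[gi], radius_frac=confusion_radius_frac
                )

    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn)
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    ap_per_threshold = {t: average_precision(scored_at[t], n_gt) for t in thresholds}
    map5095 = float(np.mean(list(ap_per_threshold.values())))
    p_pts, r_pts = _pr_points(pr_scored, n_gt)
    return EvalReport(
        precision=precision,
        recall=recall,
        f1=f1,
        tp=tp,
        fp=fp,
        fn=fn,
        ap_per_threshold=ap_per_threshold,
        map50=ap_per_threshold.get(0.5, math.nan),
        map5095=map5095,
        pr_curve=list(zip(map(float, p_pts), map(float, r_pts))),
        confusion=confusion,
    )


def keypoint_confusion_single(pred: Pose, gt: Pose, radius_frac: float = 0.1) -> np.ndarray:
    """Confusion increments for one matched (prediction, ground-truth) pair.

    For each annotated ground-truth keypoint, the nearest predicted
    keypoint of *any* index within ``radius_frac × max(box w, box h)``
    claims the cell [gt index][pred index]; no prediction in radius
    increments the trailing "missed" column.
    """
    mat = np.zeros((N_KEYPOINTS, N_KEYPOINTS + 1), dtype=int)
    radius = radius_frac * max(gt.box.w, gt.box.h)
    px = np.array([(kp.x, kp.y) for kp in pred.keypoints])
    for gi, gk in enumerate(gt.keypoints):
        if not gk.visible:
            continue
        d = np.hypot(px[:, 0] - gk.x, px[:, 1] - gk.y)
        best = int(np.argmin(d))
        if d[best] <= radius:
            mat[gi, best] += 1
        else:
            mat[gi, N_KEYPOINTS] += 1
    return mat


def keypoint_confusion(
    matched_pairs: Iterable[tuple[Pose, Pose]],
    schema: SkeletonSchema,
    radius_frac: float = 0.1,
) -> np.ndarray:
    """25×26 confusion matrix over matched pose pairs (last column = missed)."""
    mat = np.zeros((N_KEYPOINTS, N_KEYPOINTS + 1), dtype=int)
    for pred, gt in matched_pairs:
        mat += keypoint_confusion_single(pred, gt, radius_frac=radius_frac)
    return mat


def symmetry_swap_rate(confusion: np.ndarray, schema: SkeletonSchema) -> float:
    """Fraction of assigned ground-truth keypoints landing on their mirror index."""
    assigned = confusion[:, :N_KEYPOINTS].sum()
    if assigned == 0:
        return 0.0
    swapped = sum(
        confusion[i, schema.mirror_index(i)]
        for i in range(N_KEYPOINTS)
        if schema.mirror_index(i) != i
    )
    return float(swapped) / float(assigned)
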