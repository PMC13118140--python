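"""Occlusion-ablation harness.

A pose detector's reliance on image regions is probed by masking either the
image periphery (a border band, hiding distal extremities) or the anatomical
core (the torso–pelvis rectangle spanned by the shoulders and hips) and
comparing the keypoints predicted on the occluded image with those predicted
on the original.  Per-keypoint displacement is the plain Euclidean distance

    d = sqrt((x_base − x_occ)² + (y_base − y_occ)²)

and the Mean Relative Error (MRE) report averages d normalized by an object
scale — the baseline bounding-box diagonal by default — per keypoint over
the image set.

The harness is detector-agnostic: anything callable as image → Pose can
serve as the prediction provider, including the jittered-oracle test double
from :mod:`posekin.synth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .annotation import Pose, N_KEYPOINTS

__all__ = [
    "OcclusionSpec",
    "KeypointError",
    "MREReport",
    "make_mask",
    "displacement",
    "mre_report",
    "box_diagonal_normalizer",
]

Normalizer = Literal["box_diagonal", "image_diagonal", "box_max_side"]


@dataclass(frozen=True)
class OcclusionSpec:
    """Which region to occlude and how.

    ``peripheral`` fills a border band of ``border_frac`` of each dimension;
    ``central`` fills the axis-aligned rectangle spanning the shoulders
    (4, 9) and hips (15, 16), padded outward by ``core_pad_frac`` of its
    size.  ``fill`` is the RGB fill color.
    """

    mode: Literal["peripheral", "central"]
    border_frac: float = 0.2
    core_pad_frac: float = 0.1
    fill: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.mode not in ("peripheral", "central"):
            raise ValueError(f"unknown occlusion mode {self.mode!r}")
        for name in ("border_frac", "core_pad_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.5):
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")


@dataclass(frozen=True)
class KeypointError:
    """Displacement of one keypoint between two prediction sets."""

    index: int
    d: float          # pixels
    rel: float        # d / normalizer


@dataclass
class MREReport:
    """Per-keypoint mean relative error over an image set."""

    per_keypoint_mre: list[float]
    overall_mre: float
    n_images: int


CORE_INDICES = (4, 9, 15, 16)     # shoulders and hips


def make_mask(image: np.ndarray, spec: OcclusionSpec, gt_pose: Pose | None = None) -> np.ndarray:
    """Return a copy of ``image`` with the occlusion region filled.

    Central mode needs a pose in *pixel* coordinates to locate the core and
    requires all four shoulder/hip keypoints to be annotated.  Pixels
    outside the declared region are bit-identical to the input.
    """
    h, w = image.shape[:2]
    out = image.copy()
    fill = np.array(spec.fill[: image.shape[2]], dtype=image.dtype)
    if spec.mode == "peripheral":
        bw = int(round(spec.border_frac * w))
        bh = int(round(spec.border_frac * h))
        if bw == 0 and bh == 0:
            return out
        out[:bh, :] = fill
        out[h - bh :, :] = fill
        out[:, :bw] = fill
        out[:, w - bw :] = fill
        return out
    # central
    if gt_pose is None:
        raise ValueError("central ablation requires a ground-truth pose to locate the core")
    pts = [gt_pose.keypoints[i] for i in CORE_INDICES]
    if any(not kp.visible for kp in pts):
        raise ValueError("cannot locate core: a shoulder or hip keypoint is unannotated")
    xs = [kp.x for kp in pts]
    ys = [kp.y for kp in pts]
    x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
    px, py = spec.core_pad_frac * (x1 - x0), spec.core_pad_frac * (y1 - y0)
    c0, c1 = max(0, int(math.floor(x0 - px))), min(w, int(math.ceil(x1 + px)))
    r0, r1 = max(0, int(math.floor(y0 - py))), min(h, int(math.ceil(y1 + py)))
    out[r0:r1, c0:c1] = fill
    return out


def box_diagonal_normalizer(pose: Pose) -> float:
    return pose.box.diagonal


def displacement(
    baseline: Pose,
    occluded: Pose,
    normalizer: float | None = None,
) -> list[KeypointError]:
    """Per-keypoint Euclidean displacement between two predictions.

    Both poses must be in pixel coordinates from the same image.
    ``normalizer`` defaults to the baseline bounding-box diagonal; pass the
    image diagonal or box max-side for the alternative MRE conventions.
    """
    if normalizer is None:
        normalizer = baseline.box.diagonal
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    errors = []
    for i, (b, o) in enumerate(zip(baseline.keypoints, occluded.keypoints)):
        d = math.hypot(b.x - o.x, b.y - o.y)
        errors.append(KeypointError(index=i, d=d, rel=d / normalizer))
    return errors


def mre_report(
    errors_per_image: Iterable[Sequence[KeypointError]],
    bins: int = 20,
) -> tuple[MREReport, dict]:
    """Aggregate per-image keypoint errors into the MRE report.

    Returns the report plus histogram data (per-keypoint mean relative
    error plus binned distribution of all relative errors) ready for
    plotting.  Order of images is immaterial.
    """
    per_kp: list[list[float]] = [[] for _ in range(N_KEYPOINTS)]
    all_rel: list[float] = []
    n_images = 0
    for errors in errors_per_image:
        n_images += 1
        for e in errors:
            per_kp[e.index].append(e.rel)
            all_rel.append(e.rel)
    if n_images == 0:
        raise ValueError("mre_report needs at least one image")
    per_keypoint_mre = [float(np.mean(v)) if v else math.nan for v in per_kp]
    evaluated = [m for m in per_keypoint_mre if not math.isnan(m)]
    overall = float(np.mean(evaluated)) if evaluated else math.nan
    counts, edges = np.histogram(all_rel, bins=bins) if all_rel else (np.array([]), np.array([]))
    hist = {
        "per_keypoint": per_keypoint_mre,
        "bin_counts": counts.tolist(),
        "bin_edges": edges.tolist(),
    }
    return MREReport(per_keypoint_mre=per_keypoint_mre, overall_mre=overall, n_images=n_images), hist
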