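"""Synthetic articulated-pose generator.

A stick figure is built by forward kinematics from the spine root: each
limb segment's direction is obtained by rotating the direction back to its
parent joint by the requested interior joint angle, so every controllable
angle (neck, shoulder, elbow, hip, knee) is realized *exactly* by
construction and the geometry module must recover it.  Segment lengths
default to textbook body-segment proportions scaled to a ~190 px figure.

The generator is the test substrate for the whole package: it renders the
figure as a stick image, emits the annotation record in the standard text
format, and can jitter copies of the ground truth into surrogate
"predictions" with known displacement statistics (isotropic Gaussian jitter
of per-axis σ has Rayleigh-distributed displacement with mean σ√(π/2)).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .annotation import (
    AnnotationSet,
    BoundingBox,
    Keypoint,
    N_KEYPOINTS,
    Pose,
    to_normalized,
    write_annotation,
)
from .schema import SkeletonSchema, default_schema

__all__ = [
    "PoseSpec",
    "generate",
    "generate_dataset",
    "random_spec",
    "jitter_pose",
    "noisy_oracle",
    "DEFAULT_ANGLES",
    "DEFAULT_SEGMENTS",
    "ANGLE_RANGES",
]

Vec = tuple[float, float]

#: Controllable joint angles (degrees) and their neutral defaults.
DEFAULT_ANGLES: dict[str, float] = {
    "neck angle": 180.0,
    "right shoulder abduction": 150.0,
    "left shoulder abduction": 150.0,
    "right elbow flexion": 170.0,
    "left elbow flexion": 170.0,
    "right hip flexion": 170.0,
    "left hip flexion": 170.0,
    "right knee flexion": 175.0,
    "left knee flexion": 175.0,
}

#: Sampling ranges for random specs: wide but anatomically plausible, and
#: clear of the collinear limits where arccos loses precision.
ANGLE_RANGES: dict[str, tuple[float, float]] = {
    "neck angle": (140.0, 178.0),
    "right shoulder abduction": (30.0, 175.0),
    "left shoulder abduction": (30.0, 175.0),
    "right elbow flexion": (40.0, 178.0),
    "left elbow flexion": (40.0, 178.0),
    "right hip flexion": (70.0, 178.0),
    "left hip flexion": (70.0, 178.0),
    "right knee flexion": (60.0, 178.0),
    "left knee flexion": (60.0, 178.0),
}

#: Segment lengths in pixels (≈190 px standing figure).
DEFAULT_SEGMENTS: dict[str, float] = {
    "torso": 50.0,        # spine -> neck
    "head": 20.0,         # neck -> nose
    "eye": 6.0,           # nose -> eye (lateral)
    "clavicle": 18.0,     # neck -> shoulder
    "upper_arm": 35.0,
    "forearm": 30.0,
    "hand": 10.0,         # wrist -> thumb/pinky
    "hip_drop": 25.0,     # spine -> hip (vertical)
    "hip_width": 14.0,    # spine -> hip (lateral)
    "thigh": 45.0,
    "shank": 40.0,
    "foot": 12.0,         # ankle -> toe/heel
}

GROUP_COLORS = {
    "head": (220, 60, 60),
    "torso": (60, 120, 220),
    "arm": (60, 180, 90),
    "hand": (60, 180, 90),
    "leg": (230, 160, 40),
    "foot": (230, 160, 40),
}


@dataclass(frozen=True)
class PoseSpec:
    """Full specification of one synthetic figure."""

    joint_angles: Mapping[str, float] = field(default_factory=dict)
    segment_lengths: Mapping[str, float] = field(default_factory=dict)
    root: Vec | None = None                    # spine position, px; default frame center
    global_rotation: float = 0.0               # trunk lean, degrees clockwise from upright
    image_size: tuple[int, int] = (256, 256)   # (W, H)
    seed: int = 0

    def resolved_angles(self) -> dict[str, float]:
        angles = dict(DEFAULT_ANGLES)
        for name, deg in self.joint_angles.items():
            if name not in angles:
                raise ValueError(f"no controllable joint angle named {name!r}")
            if not (0.0 <= deg <= 180.0):
                raise ValueError(f"{name}: angle {deg} outside [0, 180]")
            angles[name] = float(deg)
        return angles

    def resolved_segments(self) -> dict[str, float]:
        segs = dict(DEFAULT_SEGMENTS)
        for name, length in self.segment_lengths.items():
            if name not in segs:
                raise ValueError(f"no segment named {name!r}")
            if not length > 0:
                raise ValueError(f"{name}: segment length must be > 0")
            segs[name] = float(length)
        return segs


def _rot(v: Vec, deg: float) -> Vec:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return (c * v[0] - s * v[1], s * v[0] + c * v[1])


def _add(p: Vec, v: Vec, scale: float) -> Vec:
    return (p[0] + scale * v[0], p[1] + scale * v[1])


def _unit(a: Vec, b: Vec) -> Vec:
    dx, dy = b[0] - a[0], b[1] - a[1]
    n = math.hypot(dx, dy)
    return (dx / n, dy / n)


def keypoint_positions(spec: PoseSpec) -> list[Vec]:
    """Forward kinematics: 25 (x, y) pixel positions for the spec.

    Interior joint angles are realized exactly: each child direction is the
    rotation of the direction back to the parent by the requested angle,
    with the rotation sense mirrored between left and right so the figure
    is laterally symmetric at equal angles.
    """
    angles = spec.resolved_angles()
    seg = spec.resolved_segments()
    w, h = spec.image_size
    root = spec.root if spec.root is not None else (w / 2.0, h * 0.55)

    up = _rot((0.0, -1.0), spec.global_rotation)
    pos: dict[int, Vec] = {}
    spine = root
    neck = _add(spine, up, seg["torso"])
    pos[14], pos[3] = spine, neck

    # head: nose direction realizes the neck angle (nose-neck-spine)
    to_spine = _unit(neck, spine)
    head_dir = _rot(to_spine, angles["neck angle"])
    nose = _add(neck, head_dir, seg["head"])
    pos[1] = nose
    eye_perp_r = _rot(head_dir, -90.0)
    pos[0] = _add(nose, eye_perp_r, seg["eye"])      # right eye
    pos[2] = _add(nose, eye_perp_r, -seg["eye"])     # left eye

    for side, sign, i_sh, i_el, i_wr, i_th, i_pk in (
        ("right", -1.0, 4, 5, 6, 7, 8),
        ("left", +1.0, 9, 10, 11, 13, 12),
    ):
        shoulder = _add(neck, _rot(up, sign * 90.0), seg["clavicle"])
        pos[i_sh] = shoulder
        to_neck = _unit(shoulder, neck)
        uarm_dir = _rot(to_neck, sign * angles[f"{side} shoulder abduction"])
        elbow = _add(shoulder, uarm_dir, seg["upper_arm"])
        pos[i_el] = elbow
        to_shoulder = _unit(elbow, shoulder)
        farm_dir = _rot(to_shoulder, sign * angles[f"{side} elbow flexion"])
        wrist = _add(elbow, farm_dir, seg["forearm"])
        pos[i_wr] = wrist
        # hand landmarks at fixed offsets off the forearm axis
        pos[i_th] = _add(wrist, _rot(farm_dir, sign * 35.0), seg["hand"])
        pos[i_pk] = _add(wrist, _rot(farm_dir, -sign * 35.0), seg["hand"])

    for side, sign, i_hip, i_kn, i_an, i_toe, i_heel, i_sh in (
        ("right", -1.0, 15, 17, 18, 19, 20, 4),
        ("left", +1.0, 16, 21, 22, 24, 23, 9),
    ):
        hip = _add(_add(spine, up, -seg["hip_drop"]), _rot(up, sign * 90.0), seg["hip_width"])
        pos[i_hip] = hip
        to_shoulder = _unit(hip, pos[i_sh])
        thigh_dir = _rot(to_shoulder, sign * angles[f"{side} hip flexion"])
        knee = _add(hip, thigh_dir, seg["thigh"])
        pos[i_kn] = knee
        to_hip = _unit(knee, hip)
        shank_dir = _rot(to_hip, sign * angles[f"{side} knee flexion"])
        ankle = _add(knee, shank_dir, seg["shank"])
        pos[i_an] = ankle
        foot_dir = _rot(shank_dir, -sign * 90.0)     # toes point outward/forward
        pos[i_toe] = _add(ankle, foot_dir, seg["foot"])
        pos[i_heel] = _add(ankle, foot_dir, -0.6 * seg["foot"])

    return [pos[i] for i in range(N_KEYPOINTS)]


def _tight_box(points: Sequence[Vec], visible: Sequence[bool], frame: tuple[int, int]) -> BoundingBox:
    """Tight pixel box around visible keypoints, padded 5 %, clipped to frame."""
    xs = [p[0] for p, v in zip(points, visible) if v]
    ys = [p[1] for p, v in zip(points, visible) if v]
    if not xs:
        raise ValueError("no visible keypoints to box")
    x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
    pad_x = 0.05 * max(x1 - x0, 1.0)
    pad_y = 0.05 * max(y1 - y0, 1.0)
    w, h = frame
    return BoundingBox.from_xyxy(
        max(0.0, x0 - pad_x), max(0.0, y0 - pad_y),
        min(float(w), x1 + pad_x), min(float(h), y1 + pad_y),
    )


def _render(points: Sequence[Vec], visible: Sequence[bool], schema: SkeletonSchema,
            size: tuple[int, int]) -> np.ndarray:
    img = Image.new("RGB", size, (235, 235, 235))
    draw = ImageDraw.Draw(img)
    for a, b in schema.edges:
        if visible[a] and visible[b]:
            color = GROUP_COLORS[schema.keypoints[b].group]
            draw.line([points[a], points[b]], fill=color, width=3)
    for i, (p, v) in enumerate(zip(points, visible)):
        if v:
            color = GROUP_COLORS[schema.keypoints[i].group]
            draw.ellipse([p[0] - 3, p[1] - 3, p[0] + 3, p[1] + 3], fill=color)
    return np.asarray(img)


def generate(
    spec: PoseSpec,
    schema: SkeletonSchema | None = None,
) -> tuple[np.ndarray, AnnotationSet, dict[str, float]]:
    """Render one figure: (image, annotation, realized joint angles).

    Keypoints landing outside the frame keep their coordinates but are
    flagged v=0.  The returned angle table holds the requested angles,
    which the construction realizes exactly.
    """
    schema = schema or default_schema()
    w, h = spec.image_size
    points = keypoint_positions(spec)
    visible = [0.0 <= x <= w and 0.0 <= y <= h for x, y in points]
    if not any(visible):
        raise ValueError("figure lies entirely outside the frame")
    image = _render(points, visible, schema, (w, h))
    box_px = _tight_box(points, visible, (w, h))
    kps_px = tuple(
        Keypoint(x, y, 2 if v else 0) for (x, y), v in zip(points, visible)
    )
    pose_px = Pose(class_id=0, box=box_px, keypoints=kps_px)
    ann = AnnotationSet(
        image_path="", image_width=w, image_height=h,
        poses=[to_normalized(pose_px, w, h)],
    )
    return image, ann, spec.resolved_angles()


def random_spec(rng: np.random.Generator,
                angle_ranges: Mapping[str, tuple[float, float]] | None = None,
                image_size: tuple[int, int] = (256, 256)) -> PoseSpec:
    """Sample a random articulated spec with angles uniform in their ranges."""
    ranges = dict(ANGLE_RANGES)
    if angle_ranges:
        ranges.update(angle_ranges)
    angles = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    rotation = float(rng.uniform(-25.0, 25.0))
    return PoseSpec(joint_angles=angles, global_rotation=rotation, image_size=image_size)


def jitter_pose(pose_norm: Pose, sigma_px: float, size: tuple[int, int],
                rng: np.random.Generator, score: float = 1.0) -> Pose:
    """Surrogate prediction: i.i.d. Gaussian jitter of σ px per coordinate.

    The box is recomputed tight around the jittered visible keypoints, so
    σ=0 returns a record identical to the ground truth (plus a score).
    """
    w, h = size
    pts, vis = [], []
    for kp in pose_norm.keypoints:
        dx, dy = (rng.normal(0.0, sigma_px), rng.normal(0.0, sigma_px)) if sigma_px > 0 else (0.0, 0.0)
        # clamp to the frame so the record stays a valid annotation
        pts.append((min(max(kp.x * w + dx, 0.0), w), min(max(kp.y * h + dy, 0.0), h)))
        vis.append(kp.visible)
    if sigma_px > 0:
        box_px = _tight_box(pts, vis, (w, h))
    else:
        box_px = BoundingBox(pose_norm.box.cx * w, pose_norm.box.cy * h,
                             pose_norm.box.w * w, pose_norm.box.h * h)
    kps = tuple(Keypoint(x / w, y / h, kp.v) for (x, y), kp in zip(pts, pose_norm.keypoints))
    return Pose(class_id=pose_norm.class_id, box=to_normalized_box(box_px, w, h),
                keypoints=kps, score=score)


def to_normalized_box(box_px: BoundingBox, w: int, h: int) -> BoundingBox:
    return BoundingBox(box_px.cx / w, box_px.cy / h, box_px.w / w, box_px.h / h)


def noisy_oracle(gt_by_name: Mapping[str, Pose], sigma_px: float,
                 size: tuple[int, int], seed: int = 0) -> Callable[[str], Pose]:
    """Detector test double: name → jittered copy of the ground-truth pose.

    Stands in for a trained detector in the ablation harness; the jitter
    statistics are known, so harness outputs are checkable in closed form.
    """
    rng = np.random.default_rng(seed)
    def predict(name: str) -> Pose:
        return jitter_pose(gt_by_name[name], sigma_px, size, rng)
    return predict


def _split_of(i: int, n: int, order: np.ndarray) -> str:
    rank = int(np.nonzero(order == i)[0][0])
    n_train = int(round(0.8 * n))
    n_valid = int(round(0.1 * n))
    if rank < n_train:
        return "train"
    if rank < n_train + n_valid:
        return "valid"
    return "test"


def generate_dataset(
    n: int,
    out_dir: str | Path,
    angle_ranges: Mapping[str, tuple[float, float]] | None = None,
    jitter_sigma: float = 0.0,
    occlusion_prob: float = 0.0,
    seed: int = 0,
    image_size: tuple[int, int] = (256, 256),
    write_images: bool = True,
) -> list[dict]:
    """Write a full synthetic dataset tree with surrogate predictions.

    Layout: ``out/{train,valid,test}/{images,labels,predictions}`` with an
    80/10/10 split.  Predictions are jittered copies of the ground truth
    (σ = ``jitter_sigma`` px per coordinate, confidence 1.0).  With
    ``occlusion_prob`` > 0, each visible ground-truth keypoint is degraded
    to v=1 (annotated but occluded) with that probability.  Returns the
    truth table: one row per image with split, requested angles and jitter
    parameters; also written as ``truth.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    schema = default_schema()
    master = np.random.default_rng(seed)
    order = master.permutation(n)
    for split in ("train", "valid", "test"):
        for sub in ("images", "labels", "predictions"):
            (out / split / sub).mkdir(parents=True, exist_ok=True)

    truth: list[dict] = []
    for i in range(n):
        rng = np.random.default_rng((seed + 1) * 100_003 + i)   # per-image stream
        spec = random_spec(rng, angle_ranges, image_size)
        image, ann, angles = generate(spec, schema)
        gt = ann.poses[0]
        if occlusion_prob > 0:
            kps = tuple(
                Keypoint(kp.x, kp.y, 1 if kp.v == 2 and rng.random() < occlusion_prob else kp.v)
                for kp in gt.keypoints
            )
            gt = gt.with_keypoints(kps)
        pred = jitter_pose(gt, jitter_sigma, image_size, rng, score=1.0)
        split = _split_of(i, n, order)
        stem = f"pose_{i:05d}"
        if write_images:
            Image.fromarray(image).save(out / split / "images" / f"{stem}.png")
        write_annotation([gt], out / split / "labels" / f"{stem}.txt")
        write_annotation([pred], out / split / "predictions" / f"{stem}.txt")
        row = {"stem": stem, "split": split, "jitter_sigma": jitter_sigma,
               "image_width": image_size[0], "image_height": image_size[1]}
        row.update({name.replace(" ", "_"): deg for name, deg in angles.items()})
        truth.append(row)

    with open(out / "truth.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(truth[0].keys()))
        writer.writeheader()
        writer.writerows(truth)
    return truth
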