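"""Pose annotation text format and dataset layout.

One plain-text annotation file per image, one line per person:

    class cx cy w h  x1 y1 v1  x2 y2 v2 ... x25 y25 v25  [score]

All coordinates are normalized to [0, 1] with the origin at the top-left
corner, x rightward and y downward; boxes use the center-size convention.
Ground-truth lines carry 80 fields, prediction lines append a confidence
score for 81.  Visibility follows the COCO convention: 0 = not labeled,
1 = labeled but not visible, 2 = visible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

__all__ = [
    "Keypoint",
    "BoundingBox",
    "Pose",
    "AnnotationSet",
    "AnnotationFormatError",
    "read_annotation",
    "write_annotation",
    "to_pixels",
    "to_normalized",
    "scan_dataset",
    "DatasetIndex",
    "N_KEYPOINTS",
    "FIELDS_GT",
    "FIELDS_PRED",
]

N_KEYPOINTS = 25
FIELDS_GT = 1 + 4 + 3 * N_KEYPOINTS          # 80
FIELDS_PRED = FIELDS_GT + 1                  # 81
SPLITS = ("train", "valid", "test")


class AnnotationFormatError(ValueError):
    """Malformed annotation file: wrong field count or out-of-range value."""


@dataclass(frozen=True)
class Keypoint:
    """A 2D landmark with a visibility flag (0 unlabeled, 1 occluded, 2 visible)."""

    x: float
    y: float
    v: int = 0

    @property
    def visible(self) -> bool:
        return self.v > 0


@dataclass(frozen=True)
class BoundingBox:
    """Center-size box. Normalized unless the owning pose is in pixel space."""

    cx: float
    cy: float
    w: float
    h: float

    @property
    def xyxy(self) -> tuple[float, float, float, float]:
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def diagonal(self) -> float:
        return math.hypot(self.w, self.h)

    @staticmethod
    def from_xyxy(x0: float, y0: float, x1: float, y1: float) -> "BoundingBox":
        return BoundingBox((x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0)


@dataclass(frozen=True)
class Pose:
    """One person instance: class id, box, 25 keypoints, optional confidence."""

    class_id: int
    box: BoundingBox
    keypoints: tuple[Keypoint, ...]
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.keypoints) != N_KEYPOINTS:
            raise ValueError(f"pose must carry exactly {N_KEYPOINTS} keypoints, got {len(self.keypoints)}")

    @property
    def is_prediction(self) -> bool:
        return self.score is not None

    def with_keypoints(self, keypoints: Sequence[Keypoint]) -> "Pose":
        return replace(self, keypoints=tuple(keypoints))


@dataclass
class AnnotationSet:
    """An image's annotation: path, pixel dimensions and pose records."""

    image_path: str
    image_width: int
    image_height: int
    poses: list[Pose] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")


def _parse_line(fields: list[str], lineno: int, path, clip: bool) -> Pose:
    if len(fields) not in (FIELDS_GT, FIELDS_PRED):
        raise AnnotationFormatError(
            f"{path}:{lineno}: expected {FIELDS_GT} (ground truth) or "
            f"{FIELDS_PRED} (prediction) fields, got {len(fields)}"
        )
    try:
        values = [float(f) for f in fields]
    except ValueError as exc:
        raise AnnotationFormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
    class_id = int(values[0])
    box = BoundingBox(*values[1:5])
    if not (0 < box.w <= 1 and 0 < box.h <= 1):
        raise AnnotationFormatError(
            f"{path}:{lineno}: box size ({box.w}, {box.h}) outside (0, 1]"
        )
    score = values[FIELDS_GT] if len(values) == FIELDS_PRED else None
    kps = []
    for i in range(N_KEYPOINTS):
        x, y, v = values[5 + 3 * i : 8 + 3 * i]
        v = int(round(v))            # accepts real-valued visibility on read
        if v not in (0, 1, 2):
            raise AnnotationFormatError(f"{path}:{lineno}: visibility {v} not in {{0, 1, 2}}")
        if v > 0 and not (0 <= x <= 1 and 0 <= y <= 1):
            if clip:
                warnings.warn(
                    f"{path}:{lineno}: keypoint {i} at ({x:.4f}, {y:.4f}) clipped to unit square",
                    stacklevel=3,
                )
                x, y = min(max(x, 0.0), 1.0), min(max(y, 0.0), 1.0)
            else:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: keypoint {i} at ({x}, {y}) outside [0, 1] with v={v}"
                )
        kps.append(Keypoint(x, y, v))
    return Pose(class_id=class_id, box=box, keypoints=tuple(kps), score=score)


def read_annotation(path: str | Path, clip: bool = False) -> list[Pose]:
    """Read one annotation file into a list of poses.

    Parameters
    ----------
    path : path
        Annotation text file; empty file yields an empty list.
    clip : bool
        When true, out-of-range visible keypoints are clipped to the unit
        square with a warning instead of raising.
    """
    poses: list[Pose] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            poses.append(_parse_line(fields, lineno, path, clip))
    return poses


def write_annotation(poses: Sequence[Pose], path: str | Path) -> None:
    """Write poses in input order, space-separated, 6-decimal fixed formatting."""
    lines = []
    for pose in poses:
        fields = [str(pose.class_id)]
        fields += [f"{v:.6f}" for v in (pose.box.cx, pose.box.cy, pose.box.w, pose.box.h)]
        for kp in pose.keypoints:
            fields += [f"{kp.x:.6f}", f"{kp.y:.6f}", str(kp.v)]
        if pose.score is not None:
            fields.append(f"{pose.score:.6f}")
        lines.append(" ".join(fields))
    Path(path).write_text("".join(line + "\n" for line in lines))


def to_pixels(pose: Pose, width: int, height: int) -> Pose:
    """Scale a normalized pose to pixel coordinates (x·W, y·H)."""
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    box = BoundingBox(pose.box.cx * width, pose.box.cy * height,
                      pose.box.w * width, pose.box.h * height)
    kps = tuple(Keypoint(kp.x * width, kp.y * height, kp.v) for kp in pose.keypoints)
    return replace(pose, box=box, keypoints=kps)


def to_normalized(pose: Pose, width: int, height: int) -> Pose:
    """Inverse of :func:`to_pixels`."""
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    box = BoundingBox(pose.box.cx / width, pose.box.cy / height,
                      pose.box.w / width, pose.box.h / height)
    kps = tuple(Keypoint(kp.x / width, kp.y / height, kp.v) for kp in pose.keypoints)
    return replace(pose, box=box, keypoints=kps)


IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass
class DatasetIndex:
    """Per-split (image, annotation) pairs plus files that failed to pair up."""

    pairs: dict[str, list[tuple[Path, Path]]]
    unpaired: dict[str, list[Path]]

    def counts(self) -> dict[str, int]:
        return {split: len(v) for split, v in self.pairs.items()}


def scan_dataset(root: str | Path) -> DatasetIndex:
    """Index a ``root/{split}/images, root/{split}/labels`` dataset tree.

    Missing split directories produce a warning and an empty split; images
    without a matching label file (and orphan label files) are reported
    under ``unpaired``.
    """
    root = Path(root)
    pairs: dict[str, list[tuple[Path, Path]]] = {s: [] for s in SPLITS}
    unpaired: dict[str, list[Path]] = {s: [] for s in SPLITS}
    for split in SPLITS:
        images_dir = root / split / "images"
        labels_dir = root / split / "labels"
        if not images_dir.is_dir():
            warnings.warn(f"missing split directory: {images_dir}", stacklevel=2)
            continue
        labels = {p.stem: p for p in sorted(labels_dir.glob("*.txt"))} if labels_dir.is_dir() else {}
        matched: set[str] = set()
        for img in sorted(images_dir.iterdir()):
            if img.suffix.lower() not in IMAGE_SUFFIXES:
                continue
            label = labels.get(img.stem)
            if label is None:
                unpaired[split].append(img)
            else:
                pairs[split].append((img, label))
                matched.add(img.stem)
        unpaired[split].extend(p for stem, p in sorted(labels.items()) if stem not in matched)
    return DatasetIndex(pairs=pairs, unpaired=unpaired)
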