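"""25-keypoint skeleton schema.

The skeleton extends the familiar 17-keypoint COCO layout with a neck, a
spine (mid-torso) point, two extra hand landmarks per wrist (thumb, pinky)
and heel/toe points per ankle, so that hand orientation, foot propulsion and
trunk flexion become measurable from 2D keypoints alone.  The index→name
mapping is fixed; every other module (annotation IO, angle catalog,
evaluation, the synthetic generator) consumes this schema.

Per-keypoint OKS falloff constants default to the published COCO sigmas for
the 17 analogous joints; the 8 extra keypoints inherit the constant of their
nearest anatomical analog (neck→shoulder, spine→hip, thumb/pinky→wrist,
heel/toe→ankle).  All constants are overridable through the schema YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "KeypointDef",
    "SkeletonSchema",
    "SchemaError",
    "default_schema",
    "load_schema",
    "save_schema",
    "mirror_index",
    "N_KEYPOINTS",
]

N_KEYPOINTS = 25

SIDES = ("left", "right", "center")
GROUPS = ("head", "arm", "hand", "torso", "leg", "foot")


class SchemaError(ValueError):
    """Raised when a schema file or object violates the skeleton invariants."""


@dataclass(frozen=True)
class KeypointDef:
    """One anatomical landmark definition.

    Parameters
    ----------
    index : int
        Slot 0–24 in the annotation record.
    name : str
        Anatomical name, e.g. ``"right elbow"``.
    side : str
        ``"left"``, ``"right"`` or ``"center"``.
    group : str
        Body region: head, arm, hand, torso, leg or foot.
    oks_k : float
        Per-keypoint falloff constant k_i of the object keypoint
        similarity; larger values forgive larger localization error.
    """

    index: int
    name: str
    side: str
    group: str
    oks_k: float

    def __post_init__(self) -> None:
        if not (0 <= self.index < N_KEYPOINTS):
            raise SchemaError(f"keypoint index {self.index} outside 0..{N_KEYPOINTS - 1}")
        if self.side not in SIDES:
            raise SchemaError(f"keypoint {self.name!r}: side must be one of {SIDES}, got {self.side!r}")
        if self.group not in GROUPS:
            raise SchemaError(f"keypoint {self.name!r}: group must be one of {GROUPS}, got {self.group!r}")
        if not self.oks_k > 0:
            raise SchemaError(f"keypoint {self.name!r}: oks_k must be > 0, got {self.oks_k}")


@dataclass(frozen=True)
class SkeletonSchema:
    """A validated 25-keypoint skeleton: definitions, limbs, symmetry.

    Attributes
    ----------
    keypoints : tuple of KeypointDef
        Ordered by index, exactly 25 entries.
    edges : tuple of (int, int)
        Limb connectivity (shoulder–elbow, hip–knee, ...), used for
        rendering and for the synthetic kinematic tree.
    symmetry_pairs : tuple of (int, int)
        (left index, right index) for every sided landmark.
    """

    keypoints: tuple[KeypointDef, ...]
    edges: tuple[tuple[int, int], ...]
    symmetry_pairs: tuple[tuple[int, int], ...]
    _mirror: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        validate(self.keypoints, self.edges, self.symmetry_pairs)
        mirror = {i: i for i in range(N_KEYPOINTS)}
        for left, right in self.symmetry_pairs:
            mirror[left] = right
            mirror[right] = left
        object.__setattr__(self, "_mirror", mirror)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(kp.name for kp in self.keypoints)

    def index_of(self, name: str) -> int:
        for kp in self.keypoints:
            if kp.name == name:
                return kp.index
        raise KeyError(name)

    def oks_constants(self) -> list[float]:
        """Per-keypoint OKS falloff constants, index order."""
        return [kp.oks_k for kp in self.keypoints]

    def mirror_index(self, index: int) -> int:
        """Left↔right partner of ``index``; center keypoints map to themselves."""
        if not (0 <= index < N_KEYPOINTS):
            raise SchemaError(f"index {index} outside 0..{N_KEYPOINTS - 1}")
        return self._mirror[index]


def validate(
    keypoints: Iterable[KeypointDef],
    edges: Iterable[tuple[int, int]],
    symmetry_pairs: Iterable[tuple[int, int]],
) -> None:
    """Check the skeleton invariants, raising :class:`SchemaError` on the first violation."""
    kps = list(keypoints)
    if len(kps) != N_KEYPOINTS:
        raise SchemaError(f"schema must define exactly {N_KEYPOINTS} keypoints, got {len(kps)}")
    indices = [kp.index for kp in kps]
    if sorted(indices) != list(range(N_KEYPOINTS)):
        raise SchemaError("keypoint indices must be a permutation of 0..24")
    if indices != list(range(N_KEYPOINTS)):
        raise SchemaError("keypoints must be listed in index order")
    names = [kp.name for kp in kps]
    if len(set(names)) != len(names):
        raise SchemaError("keypoint names must be unique")

    by_index = {kp.index: kp for kp in kps}
    pairs = [tuple(p) for p in symmetry_pairs]
    paired: set[int] = set()
    for left, right in pairs:
        if left not in by_index or right not in by_index:
            raise SchemaError(f"symmetry pair ({left}, {right}) references an unknown index")
        lkp, rkp = by_index[left], by_index[right]
        if lkp.side != "left" or rkp.side != "right":
            raise SchemaError(
                f"symmetry pair ({left}, {right}) must be (left, right); got "
                f"({lkp.side}, {rkp.side})"
            )
        if lkp.name.replace("left", "right") != rkp.name:
            raise SchemaError(f"pair names {lkp.name!r}/{rkp.name!r} are not mirror images")
        if left in paired or right in paired:
            raise SchemaError(f"index appears in more than one symmetry pair: ({left}, {right})")
        paired.update((left, right))
    for kp in kps:
        if kp.side in ("left", "right") and kp.index not in paired:
            raise SchemaError(f"sided keypoint {kp.name!r} has no symmetry partner")
        if kp.side == "center" and kp.index in paired:
            raise SchemaError(f"center keypoint {kp.name!r} appears in a symmetry pair")

    mirror = {i: i for i in range(N_KEYPOINTS)}
    for left, right in pairs:
        mirror[left], mirror[right] = right, left
    edge_set = {tuple(sorted(e)) for e in edges}
    for a, b in edges:
        if a not in by_index or b not in by_index:
            raise SchemaError(f"edge ({a}, {b}) references an unknown index")
        if a == b:
            raise SchemaError(f"self-loop edge ({a}, {b})")
        mirrored = tuple(sorted((mirror[a], mirror[b])))
        if mirrored not in edge_set:
            raise SchemaError(f"edge ({a}, {b}) lacks its mirrored counterpart {mirrored}")


_DEFAULT_RESOURCE = "skeleton25.yaml"


def default_schema() -> SkeletonSchema:
    """The canonical 25-keypoint skeleton shipped with the package."""
    with resources.files("posekin.data").joinpath(_DEFAULT_RESOURCE).open("r") as fh:
        return _from_mapping(yaml.safe_load(fh))


def _from_mapping(doc: dict) -> SkeletonSchema:
    if not isinstance(doc, dict):
        raise SchemaError("schema file must be a YAML mapping")
    for key in ("keypoints", "edges", "symmetry_pairs"):
        if key not in doc:
            raise SchemaError(f"schema file missing required key {key!r}")
    kps = []
    for entry in doc["keypoints"]:
        try:
            kps.append(
                KeypointDef(
                    index=int(entry["index"]),
                    name=str(entry["name"]),
                    side=str(entry["side"]),
                    group=str(entry["group"]),
                    oks_k=float(entry["oks_k"]),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"keypoint entry {entry!r} missing field {exc}") from exc
    kps.sort(key=lambda kp: kp.index)
    edges = tuple((int(a), int(b)) for a, b in doc["edges"])
    pairs = tuple((int(a), int(b)) for a, b in doc["symmetry_pairs"])
    return SkeletonSchema(keypoints=tuple(kps), edges=edges, symmetry_pairs=pairs)


def load_schema(path: str | Path) -> SkeletonSchema:
    """Load and validate a skeleton schema from a YAML file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaError(f"cannot parse schema file {path}: {exc}") from exc
    return _from_mapping(doc)


def save_schema(schema: SkeletonSchema, path: str | Path) -> None:
    """Write a schema as YAML such that ``load_schema`` restores it exactly."""
    doc = {
        "keypoints": [
            {"index": kp.index, "name": kp.name, "side": kp.side, "group": kp.group, "oks_k": kp.oks_k}
            for kp in schema.keypoints
        ],
        "edges": [list(e) for e in schema.edges],
        "symmetry_pairs": [list(p) for p in schema.symmetry_pairs],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def mirror_index(schema: SkeletonSchema, index: int) -> int:
    """Module-level convenience for :meth:`SkeletonSchema.mirror_index`."""
    return schema.mirror_index(index)
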