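"""Joint-angle kinematics for posture assessment.

The core primitive is the interior angle at a joint vertex p2 formed by the
two segments p2→p1 and p2→p3:

    θ = arccos( (ba · bc) / (‖ba‖ ‖bc‖) ) · 180/π,   ba = p1 − p2, bc = p3 − p2

with the cosine clamped to [−1, 1] to guard floating-point overshoot on
near-collinear points.  θ lives in [0°, 180°] and is invariant under
swapping p1↔p3, uniform scaling about p2, and rigid motion.

Angles must be computed in pixel (aspect-true) coordinates: normalized
coordinates shear angles on non-square images, so :func:`measure` expects a
pose already converted with :func:`posekin.annotation.to_pixels`.

The clinical catalog covers the flexion angles a physiotherapist reads off
a sagittal photograph: neck (nose–neck–spine), elbow (shoulder–elbow–wrist),
knee (hip–knee–ankle), hip (shoulder–hip–knee), and the trunk inclination at
the spine between the neck and the midpoint of the two hips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

from .annotation import Pose
from .schema import SkeletonSchema

__all__ = [
    "AngleDefinition",
    "AngleMeasurement",
    "DegenerateGeometryError",
    "HIP_MIDPOINT",
    "angle_at",
    "measure",
    "measure_all",
    "clinical_catalog",
    "assess",
]

Point = tuple[float, float]

#: Sentinel endpoint: the virtual midpoint of the two hip keypoints (15, 16).
HIP_MIDPOINT = "hip_mid"

Endpoint = Union[int, str]


class DegenerateGeometryError(ValueError):
    """A zero-length segment makes the angle undefined."""


@dataclass(frozen=True)
class AngleDefinition:
    """A named joint angle: (p1, vertex p2, p3) keypoint indices.

    Endpoints are keypoint indices 0–24; an endpoint may also be the
    :data:`HIP_MIDPOINT` sentinel for measurements anchored on the pelvis
    midline (trunk inclination).  ``provisional`` marks catalog entries
    whose triple is a documented best guess rather than a settled
    convention.
    """

    name: str
    triple: tuple[Endpoint, Endpoint, Endpoint]
    provisional: bool = False

    def __post_init__(self) -> None:
        if len(self.triple) != 3:
            raise ValueError(f"{self.name}: triple must have 3 endpoints")
        if len(set(self.triple)) != 3:
            raise ValueError(f"{self.name}: endpoints must be distinct, got {self.triple}")
        for e in self.triple:
            if isinstance(e, int):
                if not (0 <= e <= 24):
                    raise ValueError(f"{self.name}: index {e} outside 0..24")
            elif e != HIP_MIDPOINT:
                raise ValueError(f"{self.name}: unknown endpoint {e!r}")


@dataclass(frozen=True)
class AngleMeasurement:
    """A computed joint angle; ``valid`` is false when a keypoint was
    invisible or the geometry degenerate (never an exception)."""

    definition: AngleDefinition
    theta_deg: float
    valid: bool


def angle_at(p1: Point, p2: Point, p3: Point) -> float:
    """Interior angle in degrees at vertex ``p2``; raises on zero-length segments."""
    bax, bay = p1[0] - p2[0], p1[1] - p2[1]
    bcx, bcy = p3[0] - p2[0], p3[1] - p2[1]
    na = math.hypot(bax, bay)
    nc = math.hypot(bcx, bcy)
    if na == 0.0 or nc == 0.0:
        raise DegenerateGeometryError(f"zero-length segment at vertex {p2}")
    cos_theta = (bax * bcx + bay * bcy) / (na * nc)
    cos_theta = max(-1.0, min(1.0, cos_theta))
    return math.degrees(math.acos(cos_theta))


def _resolve(pose: Pose, endpoint: Endpoint) -> tuple[Point, bool]:
    """Endpoint → (pixel point, visible)."""
    if endpoint == HIP_MIDPOINT:
        r, l = pose.keypoints[15], pose.keypoints[16]
        return ((r.x + l.x) / 2, (r.y + l.y) / 2), r.visible and l.visible
    kp = pose.keypoints[endpoint]
    return (kp.x, kp.y), kp.visible


def measure(pose_pixels: Pose, definition: AngleDefinition) -> AngleMeasurement:
    """Measure one named angle on a pose in pixel coordinates.

    An invisible keypoint (v=0) or coincident coordinates yield
    ``valid=False`` with ``theta_deg`` as NaN rather than an error, so
    batch measurement over partially occluded detections never aborts.
    """
    points, vis = zip(*(_resolve(pose_pixels, e) for e in definition.triple))
    if not all(vis):
        return AngleMeasurement(definition, math.nan, valid=False)
    try:
        theta = angle_at(*points)
    except DegenerateGeometryError:
        return AngleMeasurement(definition, math.nan, valid=False)
    return AngleMeasurement(definition, theta, valid=True)


def measure_all(pose_pixels: Pose, definitions: Sequence[AngleDefinition]) -> list[AngleMeasurement]:
    return [measure(pose_pixels, d) for d in definitions]


def clinical_catalog(schema: SkeletonSchema | None = None) -> list[AngleDefinition]:
    """The default set of clinically meaningful joint angles.

    Triples are stated on the canonical 25-keypoint schema.  Trunk
    inclination and pelvic tilt use the virtual hip midpoint and are
    flagged provisional: the measurements are standard, the exact landmark
    triple is a package convention.
    """
    return [
        AngleDefinition("neck angle", (1, 3, 14)),
        AngleDefinition("right elbow flexion", (4, 5, 6)),
        AngleDefinition("left elbow flexion", (9, 10, 11)),
        AngleDefinition("right knee flexion", (15, 17, 18)),
        AngleDefinition("left knee flexion", (16, 21, 22)),
        AngleDefinition("right hip flexion", (4, 15, 17)),
        AngleDefinition("left hip flexion", (9, 16, 21)),
        AngleDefinition("trunk inclination", (3, 14, HIP_MIDPOINT), provisional=True),
        AngleDefinition("pelvic tilt", (14, HIP_MIDPOINT, 17), provisional=True),
    ]


def assess(
    measurements: Sequence[AngleMeasurement],
    reference_ranges: Mapping[str, tuple[float, float]],
) -> dict[str, str]:
    """Compare measured angles against user-supplied reference ranges.

    Returns angle name → one of ``within``, ``below``, ``above``,
    ``indeterminate`` (invalid measurement or no range configured).  The
    package ships no default ranges: acceptable joint angles are
    exercise- and patient-specific and must come from the clinician.
    """
    flags: dict[str, str] = {}
    for m in measurements:
        name = m.definition.name
        rng = reference_ranges.get(name)
        if rng is None or not m.valid:
            flags[name] = "indeterminate"
            continue
        lo, hi = rng
        if lo > hi:
            raise ValueError(f"range for {name!r} has lo > hi: ({lo}, {hi})")
        if m.theta_deg < lo:
            flags[name] = "below"
        elif m.theta_deg > hi:
            flags[name] = "above"
        else:
            flags[name] = "within"
    return flags
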