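import numpy as np
import pytest

from posekin.annotation import BoundingBox, Keypoint, Pose
from posekin.schema import default_schema
from posekin.synth import PoseSpec, generate


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def neutral_figure():
    """One rendered default figure: (image, annotation set, requested angles)."""
    return generate(PoseSpec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_pose(points_px, size=(100.0, 100.0), visibility=None, score=None, box=None):
    """Pixel-space pose from a list of 25 (x, y) points."""
    assert len(points_px) == 25
    if visibility is None:
        visibility = [2] * 25
    kps = tuple(Keypoint(x, y, v) for (x, y), v in zip(points_px, visibility))
    if box is None:
        xs = [p[0] for p in points_px]
        ys = [p[1] for p in points_px]
        box = BoundingBox.from_xyxy(min(xs), min(ys), max(max(xs), min(xs) + 1.0),
                                    max(max(ys), min(ys) + 1.0))
    return Pose(class_id=0, box=box, keypoints=kps, score=score)


def grid_points(origin=(10.0, 10.0), step=3.0):
    """25 distinct points on a 5×5 grid."""
    ox, oy = origin
    return [(ox + step * (i % 5), oy + step * (i // 5)) for i in range(25)]
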