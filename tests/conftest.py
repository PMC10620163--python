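import numpy as np
import pytest

from vrgaze import reference
from vrgaze.scene_model import (
    ColliderMesh,
    DistanceClass,
    FocalObject,
    SceneRole,
    SceneSpec,
    SceneType,
    make_box_collider,
)


@pytest.fixture(scope="session")
def default_scenes():
    return reference.default_scene_set()


@pytest.fixture(scope="session")
def test_scenes(default_scenes):
    return [s for s in default_scenes if s.role is SceneRole.TEST]


@pytest.fixture
def axis_scene():
    """Two boxes on the +z axis: FO1 spans z in [4, 5], FO2 in [2, 3]."""
    fo1 = FocalObject(
        "fo1", make_box_collider([0, 0, 4.5], 1.0, "fo1"), DistanceClass.EQUAL
    )
    fo2 = FocalObject(
        "fo2", make_box_collider([0, 0, 2.5], 1.0, "fo2"), DistanceClass.EQUAL
    )
    return SceneSpec("axis", SceneType.EQUAL, (fo1, fo2))


@pytest.fixture
def side_scene():
    """Two boxes well separated left/right of the forward axis."""
    fo1 = FocalObject(
        "fo1", make_box_collider([-1.0, 0, 3.0], 0.8, "fo1"), DistanceClass.EQUAL
    )
    fo2 = FocalObject(
        "fo2", make_box_collider([1.0, 0, 3.0], 0.8, "fo2"), DistanceClass.EQUAL
    )
    return SceneSpec("side", SceneType.EQUAL, (fo1, fo2))


def random_convex_mesh(rng: np.random.Generator, center, spread=0.6) -> ColliderMesh:
    """Random convex polyhedron: hull of 12 random points around center."""
    from scipy.spatial import ConvexHull

    pts = np.asarray(center) + rng.normal(0, spread, size=(12, 3))
    hull = ConvexHull(pts)
    return ColliderMesh(pts[hull.vertices], ConvexHull(pts[hull.vertices]).simplices)
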