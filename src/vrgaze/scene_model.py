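"""3D scene representation and collider-based gaze classification.

A trial scene contains two salient focal objects, each wrapped in an
invisible convex collider mesh — the 3D analogue of a 2D region of
interest — inflated to 110% of the object's size so that gaze samples
landing just off the object's contour (eye-tracker inaccuracy) still
count as object hits.  A gaze ray is classified against the scene as a
hit on focal object 1, focal object 2, or the background; invalid
samples are labelled missing.

Coordinate convention: right-handed, meters, viewer head at the origin,
+z pointing forward into the scene.  Gaze is a single combined
(cyclopean) ray.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "ColliderMesh",
    "DistanceClass",
    "FocalObject",
    "GeometryError",
    "HitLabel",
    "SceneRole",
    "SceneSpec",
    "SceneType",
    "classify_gaze",
    "classify_rays",
    "load_obj_collider",
    "load_scenes",
    "make_box_collider",
    "ray_collider_hit",
    "save_scenes",
    "scale_collider",
]

#: exact distance ties between the two colliders resolve to focal object 1
TIE_EPS = 1e-9


class GeometryError(ValueError):
    """Raised for degenerate or non-convex collider meshes."""


class HitLabel(IntEnum):
    """Per-sample gaze classification; exhaustive and mutually exclusive."""

    FO1 = 0
    FO2 = 1
    BACKGROUND = 2
    MISSING = 3


class DistanceClass(str, Enum):
    EQUAL = "EQUAL"
    CLOSER = "CLOSER"
    FURTHER = "FURTHER"


class SceneType(str, Enum):
    EQUAL = "EQUAL"
    VARIED = "VARIED"


class SceneRole(str, Enum):
    TRAINING = "TRAINING"
    TEST = "TEST"


@dataclass
class ColliderMesh:
    """A convex, watertight triangle mesh acting as a gaze collider.

    Parameters
    ----------
    vertices
        ``(V, 3)`` float array of vertex positions in meters.
    faces
        ``(F, 3)`` integer array of triangle vertex indices.
    object_id
        Identifier of the object the collider wraps.
    """

    vertices: np.ndarray
    faces: np.ndarray
    object_id: str = ""
    # half-space representation n·x <= b, cached at construction
    _normals: np.ndarray = field(init=False, repr=False)
    _offsets: np.ndarray = field(init=False, repr=False)
    _volume: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (V, 3) array")
        try:
            hull = ConvexHull(self.vertices)
        except Exception as exc:  # qhull rejects flat/degenerate input
            raise GeometryError(f"degenerate collider mesh: {exc}") from exc
        if hull.volume <= 0:
            raise GeometryError("collider mesh has zero volume")
        # convexity: every vertex on or inside the hull of all vertices
        eqs = hull.equations  # rows [n, -b] with n·x + (-b) <= 0 inside
        dist = self.vertices @ eqs[:, :3].T + eqs[:, 3]
        if np.any(dist > 1e-8 * max(1.0, np.abs(self.vertices).max())):
            raise GeometryError("collider mesh is not convex")
        # coplanar hull facets are triangulated by qhull; collapse them
        eqs = np.unique(np.round(eqs, 12), axis=0)
        self._normals = eqs[:, :3].copy()
        self._offsets = -eqs[:, 3].copy()
        self._volume = float(hull.volume)

    @property
    def volume(self) -> float:
        """Convex-hull volume in cubic meters."""
        return self._volume

    @property
    def centroid(self) -> np.ndarray:
        """Mean of the hull vertices (the scaling center)."""
        return self.vertices.mean(axis=0)

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Half-space membership test for one point or an ``(N, 3)`` array."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inside = np.all(pts @ self._normals.T <= self._offsets + atol, axis=1)
        return inside if np.asarray(points).ndim > 1 else bool(inside[0])


@dataclass
class FocalObject:
    """A focal object with its (already inflated) collider."""

    object_id: str
    collider: ColliderMesh
    distance_class: DistanceClass = DistanceClass.EQUAL
    distance_from_viewer: float = 0.0

    def __post_init__(self) -> None:
        self.distance_class = DistanceClass(self.distance_class)
        if self.distance_from_viewer <= 0.0:
            self.distance_from_viewer = float(
                np.linalg.norm(self.collider.centroid)
            )
        if self.distance_from_viewer <= 0:
            raise ValueError("distance_from_viewer must be positive")


@dataclass
class SceneSpec:
    """One trial environment: exactly two focal objects plus background."""

    scene_id: str
    scene_type: SceneType
    objects: tuple[FocalObject, FocalObject]
    trial_duration_ms: float = 4000.0
    role: SceneRole = SceneRole.TEST

    def __post_init__(self) -> None:
        self.scene_type = SceneType(self.scene_type)
        self.role = SceneRole(self.role)
        self.objects = tuple(self.objects)
        if len(self.objects) != 2:
            raise ValueError("a scene has exactly two focal objects")
        if self.trial_duration_ms <= 0:
            raise ValueError("trial_duration_ms must be positive")
        classes = {o.distance_class for o in self.objects}
        if self.scene_type is SceneType.EQUAL:
            if classes != {DistanceClass.EQUAL}:
                raise ValueError("EQUAL scene requires both objects EQUAL")
        else:
            if classes != {DistanceClass.CLOSER, DistanceClass.FURTHER}:
                raise ValueError(
                    "VARIED scene requires one CLOSER and one FURTHER object"
                )

    @property
    def closer_index(self) -> int | None:
        """Index (0/1) of the CLOSER object, or None for EQUAL scenes."""
        for i, obj in enumerate(self.objects):
            if obj.distance_class is DistanceClass.CLOSER:
                return i
        return None


def scale_collider(mesh: ColliderMesh, factor: float) -> ColliderMesh:
    """Inflate a collider about its centroid by ``factor``.

    Every vertex maps to ``centroid + factor * (vertex - centroid)``;
    convexity is preserved and the volume scales by ``factor**3``.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    c = mesh.centroid
    return ColliderMesh(
        vertices=c + factor * (mesh.vertices - c),
        faces=mesh.faces.copy(),
        object_id=mesh.object_id,
    )


def ray_collider_hit(
    origin: np.ndarray, direction: np.ndarray, mesh: ColliderMesh
) -> float | None:
    """Distance along a ray to a convex collider, or None for a miss.

    Returns the smallest nonnegative ``t`` with ``origin + t*direction``
    on the mesh surface; an origin inside the mesh returns ``t = 0``.
    Clips the parameter interval against the half-space representation
    (the standard slab test generalised to arbitrary convex polytopes).
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("gaze direction must be a nonzero vector")
    if abs(norm - 1.0) > 1e-9:
        warnings.warn("gaze direction not unit-norm; normalizing", stacklevel=2)
        direction = direction / norm

    den = mesh._normals @ direction
    num = mesh._offsets - mesh._normals @ origin
    t_enter, t_exit = -np.inf, np.inf
    for d, n in zip(den, num):
        if d > 0:
            t_exit = min(t_exit, n / d)
        elif d < 0:
            t_enter = max(t_enter, n / d)
        elif n < 0:  # parallel and outside this half-space
            return None
    if t_enter > t_exit or t_exit < 0:
        return None
    return max(t_enter, 0.0)


def classify_rays(
    directions: np.ndarray,
    valid: np.ndarray,
    scene: SceneSpec,
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised gaze classification for a whole trial.

    Parameters
    ----------
    directions
        ``(N, 3)`` unit gaze directions.
    valid
        ``(N,)`` boolean validity flags; invalid rows become MISSING.
    scene
        Scene whose two colliders are tested.
    origin
        Shared ray origin, default the viewer head at ``(0, 0, 0)``.

    Returns
    -------
    ``(N,)`` int array of :class:`HitLabel` values.  When a ray pierces
    both colliders the nearer intersection wins (occlusion order); exact
    ties resolve to FO1.
    """
    directions = np.asarray(directions, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    o = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    n = directions.shape[0]
    dists = np.full((2, n), np.inf)
    # cache transposed plane matrices per scene (hot path in simulation)
    cache = scene.__dict__.get("_plane_cache")
    if cache is None:
        cache = [
            (obj.collider._normals.T.copy(), obj.collider._offsets.copy())
            for obj in scene.objects
        ]
        scene.__dict__["_plane_cache"] = cache
    for k, (normals_t, offsets) in enumerate(cache):
        den = directions @ normals_t                 # (N, P)
        num = offsets - o @ normals_t                # (P,)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = num[None, :] / den
        t_enter = np.where(den < 0, ratio, -np.inf).max(axis=1)
        t_exit = np.where(den > 0, ratio, np.inf).min(axis=1)
        infeasible = np.any((den == 0) & (num[None, :] < 0), axis=1)
        hit = (~infeasible) & (t_enter <= t_exit) & (t_exit >= 0)
        dists[k, hit] = np.maximum(t_enter[hit], 0.0)

    labels = np.full(n, int(HitLabel.BACKGROUND), dtype=np.int8)
    any_hit = np.isfinite(dists).any(axis=0)
    # nearest collider wins; ties (< TIE_EPS) go to FO1 via stable argmin
    nearer = np.where(dists[1] < dists[0] - TIE_EPS, HitLabel.FO2, HitLabel.FO1)
    labels[any_hit] = nearer[any_hit].astype(np.int8)
    labels[~valid] = int(HitLabel.MISSING)
    return labels


def classify_gaze(sample, scene: SceneSpec) -> HitLabel:
    """Classify a single gaze sample (see :class:`HitLabel`)."""
    if not sample.valid:
        return HitLabel.MISSING
    label = classify_rays(
        np.asarray(sample.direction, dtype=float)[None, :],
        np.array([True]),
        scene,
        origin=np.asarray(sample.origin, dtype=float),
    )[0]
    return HitLabel(int(label))


# ---------------------------------------------------------------------------
# construction helpers and I/O

def make_box_collider(
    center, size, object_id: str = "", scale: float = 1.0
) -> ColliderMesh:
    """Axis-aligned box collider, optionally pre-inflated by ``scale``."""
    center = np.asarray(center, dtype=float)
    half = 0.5 * np.asarray(size, dtype=float) * np.ones(3)
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )
    mesh = ColliderMesh(
        vertices=center + corners * half,
        faces=ConvexHull(center + corners * half).simplices,
        object_id=object_id,
    )
    return scale_collider(mesh, scale) if scale != 1.0 else mesh


def load_obj_collider(path, object_id: str | None = None) -> ColliderMesh:
    """Load a collider mesh from a Wavefront OBJ file (vertices/faces)."""
    import trimesh

    tm = trimesh.load(str(path), file_type="obj", force="mesh", process=False)
    return ColliderMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=int),
        object_id=object_id or Path(path).stem,
    )


def _scene_to_dict(scene: SceneSpec) -> dict:
    return {
        "scene_id": scene.scene_id,
        "scene_type": scene.scene_type.value,
        "trial_duration_ms": scene.trial_duration_ms,
        "role": scene.role.value,
        "objects": [
            {
                "object_id": o.object_id,
                "distance_class": o.distance_class.value,
                "distance_from_viewer": o.distance_from_viewer,
                "vertices": o.collider.vertices.tolist(),
                "faces": o.collider.faces.tolist(),
            }
            for o in scene.objects
        ],
    }


def _scene_from_dict(d: dict) -> SceneSpec:
    objects = tuple(
        FocalObject(
            object_id=o["object_id"],
            collider=ColliderMesh(
                vertices=np.asarray(o["vertices"], dtype=float),
                faces=np.asarray(o["faces"], dtype=int),
                object_id=o["object_id"],
            ),
            distance_class=DistanceClass(o["distance_class"]),
            distance_from_viewer=float(o.get("distance_from_viewer", 0.0)),
        )
        for o in d["objects"]
    )
    return SceneSpec(
        scene_id=d["scene_id"],
        scene_type=SceneType(d["scene_type"]),
        objects=objects,
        trial_duration_ms=float(d.get("trial_duration_ms", 4000.0)),
        role=SceneRole(d.get("role", "TEST")),
    )


def save_scenes(scenes, path) -> None:
    """Write a scene set to a JSON file."""
    payload = [_scene_to_dict(s) for s in scenes]
    Path(path).write_text(json.dumps(payload))


def load_scenes(path) -> list[SceneSpec]:
    """Read a scene set from a JSON file."""
    payload = json.loads(Path(path).read_text())
    return [_scene_from_dict(d) for d in payload]
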