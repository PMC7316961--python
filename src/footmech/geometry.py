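"""Shared geometric primitives.

Rigid transforms (intrinsic Z-Y-X Euler angles + translation, millimetres),
point clouds, triangle meshes, nearest-neighbour queries and surface
distance metrics used throughout the registration / morphing workflow.

All coordinates are world-space millimetres.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "PointCloud",
    "SpatialIndex",
    "TriangleIndex",
    "apply_rigid",
    "compose",
    "invert",
    "closest_distances",
    "surface_distances",
    "hrmsd",
    "center_of_mass",
    "make_mesh",
]


class InvalidTransformError(ValueError):
    """Raised for non-finite rotation angles or translations."""


@dataclass(frozen=True)
class RigidTransform:
    """Rigid body motion: rotation by intrinsic Z-Y-X Euler angles, then translation.

    The rotation matrix is ``R = Rz(a) @ Ry(b) @ Rx(c)`` for
    ``euler_zyx = (a, b, c)`` in radians; translation is in mm.
    """

    euler_zyx: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        ang = np.asarray(self.euler_zyx, dtype=float)
        tra = np.asarray(self.translation, dtype=float)
        if ang.shape != (3,) or tra.shape != (3,):
            raise InvalidTransformError("euler_zyx and translation must be 3-vectors")
        if not (np.all(np.isfinite(ang)) and np.all(np.isfinite(tra))):
            raise InvalidTransformError("non-finite transform parameters")
        object.__setattr__(self, "euler_zyx", tuple(ang))
        object.__setattr__(self, "translation", tuple(tra))

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYX", self.euler_zyx).as_matrix()

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix
        m[:3, 3] = self.translation
        return m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        ang = Rotation.from_matrix(rotation).as_euler("ZYX")
        return cls(tuple(ang), tuple(np.asarray(translation, dtype=float)))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation_matrix.T + np.asarray(self.translation)
        return out if np.asarray(points).ndim == 2 else out[0]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "euler_zyx_rad": list(self.euler_zyx),
            "translation_mm": list(self.translation),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["euler_zyx_rad"]), tuple(d["translation_mm"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        return cls.from_dict(json.loads(s))


@dataclass
class PointCloud:
    """A set of N >= 1 finite points in mm, with an optional label."""

    points: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError("points must be an (N, 3) array with N >= 1")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def apply_rigid(t: RigidTransform, pts: PointCloud) -> PointCloud:
    """Apply ``p -> R p + T`` to every point of the cloud."""
    return PointCloud(t.apply(pts.points), label=pts.label)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform acting as ``a`` after ``b``: x -> a(b(x))."""
    ra, rb = a.rotation_matrix, b.rotation_matrix
    ta = np.asarray(a.translation)
    tb = np.asarray(b.translation)
    return RigidTransform.from_matrix(ra @ rb, ra @ tb + ta)


def invert(t: RigidTransform) -> RigidTransform:
    r = t.rotation_matrix
    return RigidTransform.from_matrix(r.T, -r.T @ np.asarray(t.translation))


class SpatialIndex:
    """Nearest-point index over a fixed point set (KD-tree)."""

    def __init__(self, points: np.ndarray | PointCloud):
        pts = points.points if isinstance(points, PointCloud) else np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError("index requires an (N, 3) array with N >= 1")
        self.points = pts
        self._tree = cKDTree(pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def query(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distances and indices of the nearest indexed point for each query point."""
        d, i = self._tree.query(np.asarray(pts, dtype=float))
        return np.atleast_1d(d), np.atleast_1d(i)


def closest_distances(query: PointCloud, ref: SpatialIndex) -> np.ndarray:
    """Euclidean distance from each query point to its nearest reference point."""
    if len(query) < 1:
        raise ValueError("empty query cloud")
    d, _ = ref.query(query.points)
    return d


# ---------------------------------------------------------------------------
# Triangle queries
# ---------------------------------------------------------------------------


def _closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on triangle ``tri[i]`` to ``points[i]`` (paired, vectorized).

    Standard region-classification algorithm (Ericson, Real-Time Collision
    Detection, 5.1.5) evaluated branch-free over all regions.
    """
    p = points
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # face interior
    m = ~done
    denom = va + vb + vc
    safe = np.where(denom == 0, 1.0, denom)
    v = vb / safe
    w = vc / safe
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    d = np.linalg.norm(p - out, axis=1)
    return out, d


class TriangleIndex:
    """Nearest point-on-surface queries over a fixed triangle set.

    Candidate triangles are pre-selected with a KD-tree over triangle
    centroids, then refined with exact point-to-triangle distances.  A
    radius re-query guarantees the exact nearest triangle is examined.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        faces = np.asarray(mesh.faces)
        areas = np.asarray(mesh.area_faces)
        keep = areas > 1e-14
        if not np.all(keep):
            warnings.warn(f"skipping {int((~keep).sum())} degenerate faces in triangle index")
            faces = faces[keep]
        if len(faces) == 0:
            raise ValueError("mesh has no non-degenerate faces")
        self.triangles = np.asarray(mesh.vertices, dtype=float)[faces]
        self._centroids = self.triangles.mean(axis=1)
        # circumradius bound: max vertex distance from centroid, per triangle
        self._radius = np.linalg.norm(
            self.triangles - self._centroids[:, None, :], axis=2
        ).max(axis=1)
        self._rmax = float(self._radius.max())
        self._tree = cKDTree(self._centroids)
        self._k = min(32, len(faces))

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest surface points, distances) for each query point."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        best_pt = np.empty((n, 3))
        best_d = np.full(n, np.inf)

        dcent, idx = self._tree.query(pts, k=self._k)
        idx = np.atleast_2d(idx)
        dcent = np.atleast_2d(dcent)
        for j in range(idx.shape[1]):
            cp, d = _closest_point_on_triangles(pts, self.triangles[idx[:, j]])
            upd = d < best_d
            best_d[upd] = d[upd]
            best_pt[upd] = cp[upd]

        # exactness guarantee: an unexamined triangle can only win if its
        # centroid lies within best_d + rmax, i.e. closer than the farthest
        # candidate centroid already scanned
        unsure = np.flatnonzero(best_d + self._rmax >= dcent[:, -1])
        if self._k == len(self.triangles):
            unsure = np.empty(0, dtype=int)
        for i in unsure:
            cand = np.asarray(self._tree.query_ball_point(pts[i], best_d[i] + self._rmax))
            if len(cand) <= self._k:
                continue
            cp, d = _closest_point_on_triangles(
                np.repeat(pts[i][None, :], len(cand), axis=0), self.triangles[cand]
            )
            jmin = int(np.argmin(d))
            if d[jmin] < best_d[i]:
                best_d[i] = d[jmin]
                best_pt[i] = cp[jmin]
        return best_pt, best_d


def surface_distances(points: np.ndarray, mesh: trimesh.Trimesh | TriangleIndex) -> np.ndarray:
    """Unsigned distance from each point to the mesh surface."""
    index = mesh if isinstance(mesh, TriangleIndex) else TriangleIndex(mesh)
    _, d = index.closest(points)
    return d


def hrmsd(a: trimesh.Trimesh, b: trimesh.Trimesh) -> float:
    """Symmetric Hausdorff root-mean-square distance between two surfaces.

    RMS of vertex-to-opposite-surface distances pooled over both
    directions; zero iff each mesh's vertices lie on the other surface.
    """
    da = surface_distances(np.asarray(a.vertices), b)
    db = surface_distances(np.asarray(b.vertices), a)
    pooled = np.concatenate([da, db])
    return float(np.sqrt(np.mean(pooled**2)))


def center_of_mass(m: trimesh.Trimesh) -> np.ndarray:
    """Volume-weighted centroid (divergence theorem); surface centroid fallback.

    Open meshes have no well-defined enclosed volume, so the area-weighted
    surface centroid is returned with a warning.
    """
    if m.is_watertight:
        return np.asarray(m.center_mass, dtype=float)
    warnings.warn("mesh is not closed; falling back to area-weighted surface centroid")
    return np.asarray(m.centroid, dtype=float)


def make_mesh(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    """Build a Trimesh without any automatic processing/merging."""
    return trimesh.Trimesh(vertices=np.asarray(vertices, dtype=float),
                           faces=np.asarray(faces), process=False)
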