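"""Hierarchical rigid registration of bones onto a thresholded skeleton cloud.

Each loaded CT configuration yields one *skeleton* point cloud (all bone
voxels, bones not separated).  Every bone, manually segmented once in the
reference scan, is placed in that configuration by minimizing the mean
squared distance from its transformed points to their nearest skeleton
points — an ICP-style cost solved directly with SLSQP over 6 rigid
parameters.  To escape the local minima created by interconnected joints,
segments of bones are registered coarse-to-fine (whole foot first, then
anatomical sub-groups, finally bone by bone from proximal to distal),
each level initializing the next.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    PointCloud,
    RigidTransform,
    SpatialIndex,
    apply_rigid,
    compose,
)

__all__ = [
    "BoneModel",
    "SegmentHierarchy",
    "RegistrationResult",
    "default_hierarchy",
    "BONE_IDS",
    "PROXIMAL_TO_DISTAL",
    "registration_cost",
    "register_rigid",
    "hierarchical_register",
    "subtract_registered",
]

log = logging.getLogger(__name__)

# one voxel diagonal at 0.66 x 0.66 x 1.0 mm
DEFAULT_SUBTRACT_RADIUS = float(np.sqrt(0.66**2 + 0.66**2 + 1.0**2))
DEFAULT_SUBSAMPLE = 1500

# ---------------------------------------------------------------------------
# Bone inventory and segment hierarchy
# ---------------------------------------------------------------------------

BONE_IDS: tuple[str, ...] = (
    "tibia",
    "fibula",
    "calcaneus",
    "talus",
    "navicular",
    "cuboid",
    "cuneiform_medial",
    "cuneiform_intermediate",
    "cuneiform_lateral",
    "metatarsal_1",
    "metatarsal_2",
    "metatarsal_3",
    "metatarsal_4",
    "metatarsal_5",
    "sesamoid_medial",
    "sesamoid_lateral",
    "prox_phalanx_1",
    "prox_phalanx_2",
    "prox_phalanx_3",
    "prox_phalanx_4",
    "prox_phalanx_5",
    "mid_phalanx_2",
    "mid_phalanx_3",
    "mid_phalanx_4",
    "mid_phalanx_5",
    "dist_phalanx_1",
    "dist_phalanx_2",
    "dist_phalanx_3",
    "dist_phalanx_4",
    "dist_phalanx_5",
)

#: bone-by-bone pass order: lower leg, ankle, midfoot, metatarsus, then
#: proximal, middle and distal phalanges
PROXIMAL_TO_DISTAL: tuple[str, ...] = (
    "tibia",
    "fibula",
    "calcaneus",
    "talus",
    "navicular",
    "cuboid",
    "cuneiform_medial",
    "cuneiform_intermediate",
    "cuneiform_lateral",
    "metatarsal_1",
    "metatarsal_2",
    "metatarsal_3",
    "metatarsal_4",
    "metatarsal_5",
    "sesamoid_medial",
    "sesamoid_lateral",
    "prox_phalanx_1",
    "prox_phalanx_2",
    "prox_phalanx_3",
    "prox_phalanx_4",
    "prox_phalanx_5",
    "mid_phalanx_2",
    "mid_phalanx_3",
    "mid_phalanx_4",
    "mid_phalanx_5",
    "dist_phalanx_1",
    "dist_phalanx_2",
    "dist_phalanx_3",
    "dist_phalanx_4",
    "dist_phalanx_5",
)


@dataclass
class BoneModel:
    """One bone in its reference pose: id, surface point cloud, surface mesh."""

    bone_id: str
    points: PointCloud
    mesh: object = None  # trimesh.Trimesh, optional for registration-only use


@dataclass
class SegmentHierarchy:
    """Ordered coarse-to-fine bone groups; the last level is bone-by-bone."""

    levels: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("hierarchy has no levels")

    @property
    def all_bones(self) -> set[str]:
        return {b for _, members in self.levels for b in members}

    def validate(self, bone_ids: set[str]) -> None:
        missing = self.all_bones - bone_ids
        if missing:
            raise ValueError(f"hierarchy references unknown bones: {sorted(missing)}")
        # final level must cover every bone exactly once
        final = self.levels[-1][1]
        if sorted(final) != sorted(bone_ids):
            raise ValueError("final hierarchy level must cover every bone exactly once")


def default_hierarchy() -> SegmentHierarchy:
    """The standard 15-level foot segment hierarchy.

    Level 1 groups all bones except tibia and fibula; intermediate levels
    follow anatomical groups (ankle, midfoot, rays, metatarsus, phalanx
    rows); the final level registers bone by bone, proximal to distal.
    """
    foot = [b for b in BONE_IDS if b not in ("tibia", "fibula")]
    lines = {
        1: ["metatarsal_1", "sesamoid_medial", "sesamoid_lateral",
            "prox_phalanx_1", "dist_phalanx_1"],
    }
    for k in (2, 3, 4, 5):
        lines[k] = [f"metatarsal_{k}", f"prox_phalanx_{k}",
                    f"mid_phalanx_{k}", f"dist_phalanx_{k}"]
    levels: list[tuple[str, list[str]]] = [
        ("foot", foot),
        ("upper_ankle", ["tibia", "fibula"]),
        ("ankle", ["calcaneus", "talus"]),
        ("midfoot", ["navicular", "cuboid", "cuneiform_medial",
                     "cuneiform_intermediate", "cuneiform_lateral"]),
        ("line_1", lines[1]),
        ("line_2", lines[2]),
        ("line_3", lines[3]),
        ("line_4", lines[4]),
        ("line_5", lines[5]),
        ("metatarse", [f"metatarsal_{k}" for k in range(1, 6)]
         + ["sesamoid_medial", "sesamoid_lateral"]),
        ("metatarse_1_plus", ["metatarsal_1", "sesamoid_medial", "sesamoid_lateral"]),
        ("proximal_phalanges", [f"prox_phalanx_{k}" for k in range(1, 6)]),
        ("middle_phalanges", [f"mid_phalanx_{k}" for k in range(2, 6)]),
        ("distal_phalanges", [f"dist_phalanx_{k}" for k in range(1, 6)]),
        ("bone_by_bone", list(PROXIMAL_TO_DISTAL)),
    ]
    return SegmentHierarchy(levels)


@dataclass
class RegistrationResult:
    """Per-bone recovered transforms with quality diagnostics."""

    transforms: dict[str, RigidTransform]
    residuals: dict[str, float]  # mean non-squared closest-point distance, mm
    rms_residuals: dict[str, float]  # sqrt of the optimized mean-squared cost, mm
    iterations: dict[str, int] = field(default_factory=dict)  # per segment
    converged: dict[str, bool] = field(default_factory=dict)

    @property
    def mean_residual(self) -> float:
        return float(np.mean(list(self.residuals.values())))


# ---------------------------------------------------------------------------
# Cost and single-body optimization
# ---------------------------------------------------------------------------


def _params_to_transform(params: np.ndarray, center: np.ndarray) -> RigidTransform:
    """Interpret a 6-vector as rotation about ``center`` plus translation."""
    t = RigidTransform(tuple(params[:3]), (0.0, 0.0, 0.0))
    r = t.rotation_matrix
    world_t = center + params[3:] - r @ center
    return RigidTransform.from_matrix(r, world_t)


def _transformed(params: np.ndarray, pts: np.ndarray, center: np.ndarray) -> np.ndarray:
    rot = RigidTransform(tuple(params[:3])).rotation_matrix
    return (pts - center) @ rot.T + center + params[3:]


def registration_cost(params: np.ndarray, bone_pts: PointCloud, skeleton: SpatialIndex) -> float:
    """Mean squared distance from transformed bone points to nearest skeleton points.

    Nearest neighbours are recomputed at every evaluation: the matched
    skeleton point depends on the candidate transform.  Rotation is about
    the bone cloud centroid, decoupling rotation and translation scales.
    """
    params = np.asarray(params, dtype=float)
    moved = _transformed(params, bone_pts.points, bone_pts.centroid)
    d, _ = skeleton.query(moved)
    return float(np.mean(d**2))


def register_rigid(
    bone_pts: PointCloud,
    skeleton: SpatialIndex,
    init: RigidTransform | None = None,
    max_iterations: int = 500,
    ftol: float = 1e-8,
    restarts: bool = False,
) -> tuple[RigidTransform, float, int, bool]:
    """SLSQP minimization of the closest-point cost for one rigid body.

    Returns ``(transform, residual, iterations, converged)`` where the
    transform maps reference-pose points into the loaded configuration and
    the residual is the mean *non-squared* closest-point distance at the
    optimum.  The search starts from ``init`` (identity by default) and the
    returned cost never exceeds the cost at ``init``.

    With ``restarts`` the minimization is repeated from small deterministic
    offsets along the cloud's principal axes (up to three improvement
    rounds), stepping out of the sub-voxel aliasing minima a discretized
    skeleton creates near the true pose.
    """
    if restarts:
        best_tf, best_res, nit, ok = register_rigid(
            bone_pts, skeleton, init, max_iterations, ftol)
        nudges = _nudge_candidates(bone_pts.points)
        for _round in range(3):
            improved = False
            for nudge in nudges:
                tf_n, res_n, nit_n, ok_n = register_rigid(
                    bone_pts, skeleton, compose(nudge, best_tf), 100, ftol)
                nit += nit_n
                if res_n < best_res - 1e-4:
                    best_tf, best_res, ok = tf_n, res_n, ok_n
                    improved = True
            if not improved:
                break
        return best_tf, best_res, nit, ok
    init = init or RigidTransform.identity()
    start = apply_rigid(init, bone_pts)
    center = start.centroid

    def cost(p: np.ndarray) -> float:
        moved = _transformed(p, start.points, center)
        d, _ = skeleton.query(moved)
        return float(np.mean(d**2))

    x0 = np.zeros(6)
    c0 = cost(x0)
    res = minimize(cost, x0, method="SLSQP",
                   options={"maxiter": max_iterations, "ftol": ftol})
    nit = int(res.nit)
    x, fx = res.x, res.fun
    # one polish restart: resets the quadratic model, which helps the
    # optimizer step over sub-voxel aliasing plateaus of the discrete cost
    res2 = minimize(cost, x, method="SLSQP",
                    options={"maxiter": max_iterations, "ftol": ftol * 1e-2})
    if res2.fun < fx:
        x, fx = res2.x, res2.fun
    nit += int(res2.nit)
    converged = bool(res.success or res2.success)
    if fx > c0:
        x, fx = x0, c0
    if not converged:
        log.warning("SLSQP did not converge after %d iterations (%s)",
                    nit, res2.message)
    delta = _params_to_transform(np.asarray(x, dtype=float), center)
    total = compose(delta, init)
    moved = total.apply(bone_pts.points)
    d, _ = skeleton.query(moved)
    return total, float(np.mean(d)), nit, converged


def subtract_registered(
    skeleton_pts: PointCloud, placed_bone_pts: PointCloud, radius: float
) -> PointCloud:
    """Remove skeleton points within ``radius`` mm of an already-placed bone.

    Subsequent bone-by-bone minimizations then see only the remaining
    points, which stabilizes the small middle/distal phalanges.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = SpatialIndex(placed_bone_pts)
    d, _ = tree.query(skeleton_pts.points)
    keep = d > radius
    if not keep.any():
        raise ValueError("skeleton exhausted: every point within subtraction radius")
    return PointCloud(skeleton_pts.points[keep], label=skeleton_pts.label)


# ---------------------------------------------------------------------------
# Hierarchical registration
# ---------------------------------------------------------------------------


def _nudge_candidates(points: np.ndarray, translations: tuple[float, ...] = (0.5, 1.0),
                      rotations_deg: tuple[float, ...] = (1.25, 2.5)) -> list[RigidTransform]:
    """Small rigid offsets along/about the cloud's principal axes."""
    from scipy.spatial.transform import Rotation as _R

    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    c = points.mean(axis=0)
    out: list[RigidTransform] = []
    for t in translations:
        for axis in vt:
            for sign in (1.0, -1.0):
                out.append(RigidTransform((0, 0, 0), tuple(sign * t * axis)))
    for a in rotations_deg:
        for sign in (1.0, -1.0):
            rot = _R.from_rotvec(np.radians(sign * a) * vt[0]).as_matrix()
            out.append(RigidTransform.from_matrix(rot, c - rot @ c))
    return out


def _subsample(pts: np.ndarray, cap: int) -> np.ndarray:
    """Deterministic even-stride subsample to at most ``cap`` points."""
    n = len(pts)
    if n <= cap:
        return pts
    idx = np.linspace(0, n - 1, cap).round().astype(int)
    return pts[idx]


def hierarchical_register(
    bones: list[BoneModel],
    hierarchy: SegmentHierarchy,
    skeleton_pts: PointCloud,
    subtract: bool = True,
    subtract_radius: float = DEFAULT_SUBTRACT_RADIUS,
    subsample: int = DEFAULT_SUBSAMPLE,
    max_iterations: int = 500,
    ftol: float = 1e-8,
    restarts: bool = True,
) -> RegistrationResult:
    """Register every bone through the coarse-to-fine segment hierarchy.

    At each level the member bones' clouds (carried by their current
    transforms) are pooled and registered as one rigid body; the found
    motion composes onto each member's transform and initializes the next
    level.  The final level runs bone by bone from proximal to distal,
    optionally subtracting each placed bone's neighbourhood from the
    skeleton cloud before the next bone is treated.
    """
    by_id = {b.bone_id: b for b in bones}
    if len(by_id) != len(bones):
        raise ValueError("duplicate bone_id in bone list")
    hierarchy.validate(set(by_id))

    current: dict[str, RigidTransform] = {b: RigidTransform.identity() for b in by_id}
    iterations: dict[str, int] = {}
    converged: dict[str, bool] = {}

    full_index = SpatialIndex(skeleton_pts)

    for level_no, (name, members) in enumerate(hierarchy.levels, start=1):
        is_final = level_no == len(hierarchy.levels)
        if not is_final:
            pooled = np.concatenate(
                [current[b].apply(by_id[b].points.points) for b in members]
            )
            cloud = PointCloud(_subsample(pooled, subsample), label=name)
            delta, _, nit, ok = register_rigid(
                cloud, full_index, max_iterations=max_iterations, ftol=ftol
            )
            for b in members:
                current[b] = compose(delta, current[b])
            iterations[name] = nit
            converged[name] = ok
            log.info("level %d (%s): %d iterations", level_no, name, nit)
        else:
            # Bone-by-bone pass.  With subtraction on, each bone's cost is
            # evaluated on the remaining points only: skeleton points lying
            # within the capture radius of any *other* bone (at its current
            # level-initialized placement) are removed, so neighbouring
            # bones' voxels cannot capture the minimization.
            dist_to_bone = None
            if subtract:
                dist_to_bone = np.empty((len(skeleton_pts), len(members)))
                for col, b in enumerate(members):
                    placed = SpatialIndex(current[b].apply(by_id[b].points.points))
                    dist_to_bone[:, col], _ = placed.query(skeleton_pts.points)
            for col, b in enumerate(members):
                if subtract:
                    placed = SpatialIndex(current[b].apply(by_id[b].points.points))
                    dist_to_bone[:, col], _ = placed.query(skeleton_pts.points)
                    others = np.delete(dist_to_bone, col, axis=1).min(axis=1)
                    # keep points whose nearest current placement is this
                    # bone, plus points not claimed by any bone at all
                    keep = (dist_to_bone[:, col] <= others) | (others > subtract_radius)
                    if keep.sum() < 10:
                        log.warning("subtraction left too few points for %s; using full skeleton", b)
                        index = full_index
                    else:
                        index = SpatialIndex(skeleton_pts.points[keep])
                else:
                    index = full_index
                cloud = PointCloud(_subsample(by_id[b].points.points, subsample), label=b)
                best_tf, best_res, nit, ok = register_rigid(
                    cloud, index, init=current[b],
                    max_iterations=max_iterations, ftol=ftol, restarts=restarts,
                )
                current[b] = best_tf
                iterations[b] = nit
                converged[b] = ok
                if subtract:
                    placed = SpatialIndex(current[b].apply(by_id[b].points.points))
                    dist_to_bone[:, col], _ = placed.query(skeleton_pts.points)

    residuals: dict[str, float] = {}
    rms: dict[str, float] = {}
    for b, model in by_id.items():
        moved = current[b].apply(model.points.points)
        d, _ = full_index.query(moved)
        residuals[b] = float(np.mean(d))
        rms[b] = float(np.sqrt(np.mean(d**2)))

    return RegistrationResult(current, residuals, rms, iterations, converged)


def registration_quality(
    result: RegistrationResult,
    bone_masks: dict[str, "VoxelVolume"],
    skeleton_mask: "VoxelVolume",
) -> dict[str, float]:
    """Mean surface distance (mm) between each registered bone and the skeleton.

    Both surfaces are extracted by marching cubes, which interpolates the
    interface to sub-voxel accuracy, so this is the registration quality
    metric: the mean distance from the registered bone surface to the
    skeleton surface.  The voxel-centre cloud residuals in
    ``RegistrationResult`` bound the optimizer's objective instead and
    carry an extra discretization offset of roughly half a voxel.
    """
    from .geometry import TriangleIndex, surface_distances
    from .image_io import mask_to_mesh

    skel_index = TriangleIndex(mask_to_mesh(skeleton_mask))
    out: dict[str, float] = {}
    for bone_id, tf in result.transforms.items():
        mesh = mask_to_mesh(bone_masks[bone_id])
        verts = tf.apply(np.asarray(mesh.vertices))
        out[bone_id] = float(np.mean(surface_distances(verts, skel_index)))
    return out
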