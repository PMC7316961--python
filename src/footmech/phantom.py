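"""Fully synthetic foot phantom with known ground truth.

No CT data ships with the package, so every other module is exercised on
synthetic feet: 30 bones (28 foot bones plus tibia and fibula) shaped as
smoothly perturbed superellipsoids, laid out in anatomical chains with
millimetre joint gaps, voxelized at CT resolution (0.66 x 0.66 x 1.0 mm by
default).  The phantom emits, alongside every dataset, the ground truth a
recovery test needs: per-bone rigid transforms, ligament attachment
points, and the analytic map linking the generic source model to the
patient bones.

Anatomical realism is deliberately limited to scale (10–80 mm bones,
calcaneus largest); algorithm validation needs correct geometry and known
truth, not bone-shaped art.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.special import beta as beta_fn

from .biomech import ConfigurationState, LigamentDefinition, LigamentFiber
from .geometry import PointCloud, RigidTransform, make_mesh
from .image_io import BinaryMask, VoxelVolume, mask_to_points
from .registration import BONE_IDS, BoneModel, SegmentHierarchy, default_hierarchy

__all__ = [
    "PhantomSpec",
    "PhantomBone",
    "FootPhantom",
    "generate_bone",
    "generate_foot_phantom",
    "apply_load_case",
    "voxelize",
    "superellipsoid_volume",
    "generate_bone_pairs",
]

DEFAULT_SPACING = (0.66, 0.66, 1.0)

# bone catalogue: centre (mm), superellipsoid radii (mm), exponents (e1, e2).
# Laid out for a right foot: +x anterior, +y medial, +z superior.
_BONE_CATALOGUE: dict[str, tuple[tuple[float, float, float], tuple[float, float, float], tuple[float, float]]] = {
    "tibia": ((55, 0, 104), (13, 13, 40), (1.0, 1.0)),
    "fibula": ((52, -24, 102), (6, 6, 36), (1.0, 1.0)),
    "talus": ((55, 0, 46), (22, 14, 13), (1.0, 1.0)),
    "calcaneus": ((28, -2, 18), (34, 16, 14), (1.0, 1.0)),
    "navicular": ((88, 2, 42), (9, 12, 11), (1.0, 1.0)),
    "cuboid": ((72, -18, 20), (13, 10, 10), (1.0, 1.0)),
    "cuneiform_medial": ((107, 17, 38), (8, 8, 9), (1.0, 1.0)),
    "cuneiform_intermediate": ((105, -1, 36), (7, 6, 8), (1.0, 1.0)),
    "cuneiform_lateral": ((101, -16, 32), (9, 6, 8), (1.0, 1.0)),
    "metatarsal_1": ((142, 16, 32), (27, 7.5, 7.5), (1.0, 1.0)),
    "metatarsal_2": ((144, 0, 33), (28, 6, 6.5), (1.0, 1.0)),
    "metatarsal_3": ((142, -14, 31), (27, 6, 6), (1.0, 1.0)),
    "metatarsal_4": ((140, -28, 28), (26, 5.5, 5.5), (1.0, 1.0)),
    "metatarsal_5": ((136, -42, 25), (25, 5.5, 5.5), (1.0, 1.0)),
    "sesamoid_medial": ((164, 20, 17), (4.5, 3.5, 3.5), (1.0, 1.0)),
    "sesamoid_lateral": ((164, 11, 17), (4.5, 3.5, 3.5), (1.0, 1.0)),
    "prox_phalanx_1": ((184, 16, 30), (11, 6, 6), (1.0, 1.0)),
    "prox_phalanx_2": ((186, 0, 32), (9.5, 4.5, 5), (1.0, 1.0)),
    "prox_phalanx_3": ((184, -14, 30), (9, 4.5, 4.5), (1.0, 1.0)),
    "prox_phalanx_4": ((181, -27, 27), (8.5, 4.5, 4.5), (1.0, 1.0)),
    "prox_phalanx_5": ((176, -41, 24), (8, 4, 4), (1.0, 1.0)),
    "mid_phalanx_2": ((204, 0, 31), (6, 4, 4), (1.0, 1.0)),
    "mid_phalanx_3": ((201, -14, 29), (6, 4, 4), (1.0, 1.0)),
    "mid_phalanx_4": ((197, -27, 26), (5.5, 3.5, 3.5), (1.0, 1.0)),
    "mid_phalanx_5": ((191, -41, 23), (5, 3.5, 3.5), (1.0, 1.0)),
    "dist_phalanx_1": ((204, 16, 29), (7, 5, 4.5), (1.0, 1.0)),
    "dist_phalanx_2": ((218, 0, 30), (5.5, 3.5, 3.5), (1.0, 1.0)),
    "dist_phalanx_3": ((214, -14, 28), (5, 3.5, 3.5), (1.0, 1.0)),
    "dist_phalanx_4": ((210, -27, 25), (5, 3, 3), (1.0, 1.0)),
    "dist_phalanx_5": ((203, -41, 22), (4.5, 3, 3), (1.0, 1.0)),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the synthetic foot."""

    seed: int = 42
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    #: cap (mm) on the smooth radial surface perturbation; each bone uses
    #: min(cap, 0.12 x geometric-mean radius) so small bones stay smooth
    #: while large bones carry the tubercle/facet-scale asphericity real
    #: bones have (a near-surface-of-revolution would leave axial spin
    #: unobservable to any surface-distance cost)
    noise_amplitude: float = 1.2
    subdivisions: int = 3  # icosphere refinement of bone meshes
    #: generic-model meshes are finer than the bone meshes: morphing needs
    #: source edges well below the landmark spacing, as with real
    #: segmented surfaces
    generic_subdivisions: int = 5
    generic_scale: float = 1.05
    generic_deform_amplitude: float = 1.0  # mm per sinusoidal component (|disp| up to ~1.7 mm)
    dilate: bool = False  # one-voxel dilation to interconnect joints

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")


class _RadialNoise:
    """Smooth pseudo-random perturbation of a star-shaped radial function.

    Sum of a few sinusoids of random direction and phase evaluated on the
    unit direction vector; bounded by ``amplitude`` mm.
    """

    def __init__(self, amplitude: float, rng: np.random.Generator, n_modes: int = 4):
        self.amplitude = amplitude
        self.dirs = rng.normal(size=(n_modes, 3))
        self.dirs /= np.linalg.norm(self.dirs, axis=1, keepdims=True)
        self.freqs = rng.uniform(1.0, 3.0, size=n_modes)
        self.phases = rng.uniform(0, 2 * np.pi, size=n_modes)
        self.weights = rng.uniform(0.5, 1.0, size=n_modes)
        self.weights *= 1.0 / self.weights.sum()  # sum of |weights| == 1

    def __call__(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        s = np.zeros(len(u))
        for w, d, f, p in zip(self.weights, self.dirs, self.freqs, self.phases):
            s += w * np.sin(f * np.pi * (u @ d) + p)
        return self.amplitude * s


@dataclass
class PhantomBone:
    """One synthetic bone: analytic star-shaped solid plus its mesh."""

    bone_id: str
    center: np.ndarray
    radii: np.ndarray
    exponents: tuple[float, float]
    noise: _RadialNoise
    mesh: trimesh.Trimesh

    def radial(self, directions: np.ndarray) -> np.ndarray:
        """Surface radius along unit directions (bone-local)."""
        return _superellipsoid_radius(directions, self.radii, self.exponents) + self.noise(directions)

    def surface_point(self, direction: np.ndarray) -> np.ndarray:
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        return self.center + float(self.radial(u[None, :])[0]) * u

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - self.center
        r = np.linalg.norm(p, axis=1)
        out = np.zeros(len(p), dtype=bool)
        nz = r > 1e-12
        u = p[nz] / r[nz, None]
        out[nz] = r[nz] <= self.radial(u)
        out[~nz] = True
        return out


def _superellipsoid_radius(
    u: np.ndarray, radii: np.ndarray, exponents: tuple[float, float]
) -> np.ndarray:
    """Distance from centre to the superellipsoid surface along unit directions.

    For the implicit form F(x) = ((|x/a|^(2/e2) + |y/b|^(2/e2))^(e2/e1)
    + |z/c|^(2/e1)), F scales as r^(2/e1) along rays, so the surface radius
    is F(u)^(-e1/2).
    """
    e1, e2 = exponents
    a, b, c = radii
    u = np.atleast_2d(u)
    eps = 1e-12
    xy = (np.abs(u[:, 0] / a) + eps) ** (2 / e2) + (np.abs(u[:, 1] / b) + eps) ** (2 / e2)
    f = xy ** (e2 / e1) + (np.abs(u[:, 2] / c) + eps) ** (2 / e1)
    return f ** (-e1 / 2)


def superellipsoid_volume(radii: np.ndarray, exponents: tuple[float, float]) -> float:
    """Closed-form superellipsoid volume 2 a b c e1 e2 B(e1/2 + 1, e1) B(e2/2, e2/2)."""
    a, b, c = radii
    e1, e2 = exponents
    return float(2 * a * b * c * e1 * e2
                 * beta_fn(e1 / 2 + 1, e1) * beta_fn(e2 / 2, e2 / 2))


def generate_bone(
    radii: tuple[float, float, float],
    exponents: tuple[float, float] = (1.0, 1.0),
    noise_amplitude: float = 0.0,
    seed: int = 0,
    subdivisions: int = 3,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    bone_id: str = "bone",
) -> PhantomBone:
    """Closed genus-0 bone mesh: superellipsoid with smooth radial noise.

    Deterministic per seed; the radial map of an icosphere keeps the mesh
    watertight with Euler characteristic 2.
    """
    rng = np.random.default_rng(seed)
    noise = _RadialNoise(noise_amplitude, rng)
    base = trimesh.creation.icosphere(subdivisions=subdivisions)
    u = np.asarray(base.vertices, dtype=float)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = _superellipsoid_radius(u, np.asarray(radii, dtype=float), exponents) + noise(u)
    verts = np.asarray(center, dtype=float) + r[:, None] * u
    mesh = make_mesh(verts, np.asarray(base.faces))
    return PhantomBone(bone_id, np.asarray(center, dtype=float),
                       np.asarray(radii, dtype=float), exponents, noise, mesh)


# ---------------------------------------------------------------------------
# Voxelization (z-column parity)
# ---------------------------------------------------------------------------


def voxelize(
    meshes: list[trimesh.Trimesh],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    shape: tuple[int, int, int] | None = None,
) -> BinaryMask:
    """Binary mask of the union of closed meshes: voxel true iff its centre
    lies inside any mesh (even-odd parity of z-column crossings)."""
    if not meshes:
        raise ValueError("empty mesh list")
    for m in meshes:
        if not m.is_watertight:
            raise ValueError("voxelize requires closed (watertight) meshes")
    sp = np.asarray(spacing, dtype=float)
    org = np.asarray(origin, dtype=float)
    if shape is None:
        lo = np.min([m.bounds[0] for m in meshes], axis=0)
        hi = np.max([m.bounds[1] for m in meshes], axis=0)
        org = np.floor((lo - sp) / sp) * sp
        shape = tuple(np.ceil((hi + sp - org) / sp).astype(int) + 1)
    nx, ny, nz = shape
    mask = np.zeros(shape, dtype=bool)

    # tiny irrational offset so columns avoid triangle edges exactly
    jx, jy = 1.23456789e-6 * sp[0], 0.98765431e-6 * sp[1]

    for mesh in meshes:
        crossings_col: list[np.ndarray] = []
        crossings_z: list[np.ndarray] = []
        tris = np.asarray(mesh.vertices, dtype=float)[np.asarray(mesh.faces)]
        # index-space triangle bounding boxes in x, y
        txy = tris[:, :, :2]
        i0 = np.floor((txy[:, :, 0].min(axis=1) - org[0] - jx) / sp[0]).astype(int)
        i1 = np.ceil((txy[:, :, 0].max(axis=1) - org[0] - jx) / sp[0]).astype(int)
        j0 = np.floor((txy[:, :, 1].min(axis=1) - org[1] - jy) / sp[1]).astype(int)
        j1 = np.ceil((txy[:, :, 1].max(axis=1) - org[1] - jy) / sp[1]).astype(int)
        i0, i1 = np.clip(i0, 0, nx - 1), np.clip(i1, 0, nx - 1)
        j0, j1 = np.clip(j0, 0, ny - 1), np.clip(j1, 0, ny - 1)
        wi, wj = i1 - i0 + 1, j1 - j0 + 1
        wmax_i, wmax_j = int(wi.max()), int(wj.max())

        di, dj = np.meshgrid(np.arange(wmax_i), np.arange(wmax_j), indexing="ij")
        di, dj = di.ravel(), dj.ravel()

        chunk = max(1, int(4e6 // max(1, len(di))))
        for s in range(0, len(tris), chunk):
            tt = tris[s:s + chunk]
            ii = i0[s:s + chunk, None] + di[None, :]
            jj = j0[s:s + chunk, None] + dj[None, :]
            valid = (ii <= i1[s:s + chunk, None]) & (jj <= j1[s:s + chunk, None])
            px = org[0] + jx + ii * sp[0]
            py = org[1] + jy + jj * sp[1]
            ax, ay = tt[:, 0, 0, None], tt[:, 0, 1, None]
            bx, by = tt[:, 1, 0, None], tt[:, 1, 1, None]
            cx, cy = tt[:, 2, 0, None], tt[:, 2, 1, None]
            d = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
            with np.errstate(divide="ignore", invalid="ignore"):
                l1 = ((by - cy) * (px - cx) + (cx - bx) * (py - cy)) / d
                l2 = ((cy - ay) * (px - cx) + (ax - cx) * (py - cy)) / d
            l3 = 1.0 - l1 - l2
            inside = valid & (np.abs(d) > 1e-12) & (l1 >= 0) & (l2 >= 0) & (l3 >= 0)
            if not inside.any():
                continue
            z = (l1 * tt[:, 0, 2, None] + l2 * tt[:, 1, 2, None] + l3 * tt[:, 2, 2, None])
            cols = (ii * ny + jj)[inside]
            crossings_col.append(cols)
            crossings_z.append(z[inside])

        if not crossings_col:
            continue
        cols = np.concatenate(crossings_col)
        zs = np.concatenate(crossings_z)
        order = np.lexsort((zs, cols))
        cols, zs = cols[order], zs[order]
        starts = np.flatnonzero(np.r_[True, cols[1:] != cols[:-1]])
        ends = np.r_[starts[1:], len(cols)]
        for s0, s1 in zip(starts, ends):
            col = cols[s0]
            zvals = zs[s0:s1]
            if len(zvals) % 2:
                zvals = zvals[:-1]  # robustness against grazing hits
            i, j = divmod(int(col), ny)
            for z_in, z_out in zip(zvals[0::2], zvals[1::2]):
                k0 = int(np.ceil((z_in - org[2]) / sp[2]))
                k1 = int(np.floor((z_out - org[2]) / sp[2]))
                if k1 >= 0 and k0 < nz and k0 <= k1:
                    mask[i, j, max(k0, 0):min(k1, nz - 1) + 1] = True

    return VoxelVolume(mask, tuple(sp), tuple(org))


# ---------------------------------------------------------------------------
# Foot phantom assembly
# ---------------------------------------------------------------------------


@dataclass
class FootPhantom:
    """A complete synthetic study input set with ground truth."""

    spec: PhantomSpec
    bones: dict[str, PhantomBone]
    hierarchy: SegmentHierarchy
    ligaments: list[LigamentDefinition]
    reference_masks: dict[str, BinaryMask]
    generic_meshes: dict[str, trimesh.Trimesh]
    generic_attachments: dict[str, np.ndarray]  # fiber endpoint per (fiber, end) key
    attachment_truth: dict[str, np.ndarray]  # patient-space ground truth
    grid_origin: np.ndarray
    grid_shape: tuple[int, int, int]

    def bone_models(self) -> list[BoneModel]:
        """Registration inputs: surface point clouds from the reference masks."""
        return [
            BoneModel(b, mask_to_points(self.reference_masks[b], surface_only=True),
                      self.bones[b].mesh)
            for b in self.bones
        ]

    def reference_com(self) -> dict[str, np.ndarray]:
        return {b: self.bones[b].mesh.center_mass for b in self.bones}


def _generic_deformation(rng: np.random.Generator, amplitude: float):
    """Smooth vector field p -> p + sum of sinusoidal modes (about 40 mm wavelength)."""
    freqs = rng.uniform(0.1, 0.16, size=(3, 3))  # rad/mm, wavelengths 39-63 mm
    phases = rng.uniform(0, 2 * np.pi, size=3)

    def disp(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        out = np.empty_like(p, dtype=float)
        for axis in range(3):
            out[:, axis] = amplitude * np.sin(p @ freqs[axis] + phases[axis])
        return out

    return disp


def _fiber_endpoints(a: PhantomBone, b: PhantomBone) -> tuple[np.ndarray, np.ndarray]:
    """Facing surface points of two bones, along the line of centres."""
    u = b.center - a.center
    u = u / np.linalg.norm(u)
    return a.surface_point(u), b.surface_point(-u)


def _build_ligaments(bones: dict[str, PhantomBone]) -> list[LigamentDefinition]:
    defs: list[LigamentDefinition] = []

    def fiber(name: str, a: str, b: str, group: str, qa=None, qb=None) -> LigamentFiber:
        pa, pb = _fiber_endpoints(bones[a], bones[b])
        if qa is not None:
            pa = qa
        if qb is not None:
            pb = qb
        return LigamentFiber(name, a, tuple(pa), b, tuple(pb), group)

    # plantar aponeurosis: calcaneus plantar tuberosity to each ray
    cal = bones["calcaneus"]
    heel = cal.surface_point(np.array([-0.3, 0.0, -1.0]))
    pa_fibers = []
    for k in range(1, 6):
        head = bones[f"metatarsal_{k}"]
        target = head.surface_point(np.array([0.8, 0.0, -0.6]))
        pa_fibers.append(LigamentFiber(
            f"plantar_aponeurosis_{k}", "calcaneus", tuple(heel),
            f"metatarsal_{k}", tuple(target), "plantar_aponeurosis"))
    defs.append(LigamentDefinition("plantar_aponeurosis", pa_fibers, "plantar_aponeurosis"))

    # long plantar: calcaneus to metatarsal 2-5 bases
    lp_fibers = []
    plantar = cal.surface_point(np.array([0.5, 0.0, -1.0]))
    for k in range(2, 6):
        base = bones[f"metatarsal_{k}"].surface_point(np.array([-0.8, 0.0, -0.6]))
        lp_fibers.append(LigamentFiber(
            f"long_plantar_{k}", "calcaneus", tuple(plantar),
            f"metatarsal_{k}", tuple(base), "long_plantar"))
    defs.append(LigamentDefinition("long_plantar", lp_fibers, "long_plantar"))

    # deltoid complex
    defs.append(LigamentDefinition("deltoid", [
        fiber("tibiocalcaneal", "tibia", "calcaneus", "deltoid"),
        fiber("anterior_tibiotalar", "tibia", "talus", "deltoid"),
    ], "deltoid"))

    # capsule-like fibres along adjacent articulating bones
    pairs = [
        ("calcaneus", "talus"), ("calcaneus", "cuboid"), ("talus", "navicular"),
        ("navicular", "cuneiform_medial"), ("navicular", "cuneiform_intermediate"),
        ("navicular", "cuneiform_lateral"), ("cuneiform_medial", "metatarsal_1"),
        ("cuneiform_intermediate", "metatarsal_2"), ("cuneiform_lateral", "metatarsal_3"),
        ("cuboid", "metatarsal_4"), ("cuboid", "metatarsal_5"),
    ] + [(f"metatarsal_{k}", f"prox_phalanx_{k}") for k in range(1, 6)]
    joint = [fiber(f"{a}__{b}", a, b, "joint") for a, b in pairs]
    defs.append(LigamentDefinition("joint_capsules", joint, "joint"))
    return defs


def generate_foot_phantom(spec: PhantomSpec = PhantomSpec()) -> FootPhantom:
    """Build the full synthetic foot: bones, hierarchy, ligaments, reference
    masks, and the generic source model with known attachment truth."""
    rng = np.random.default_rng(spec.seed)
    bones: dict[str, PhantomBone] = {}
    for idx, bone_id in enumerate(BONE_IDS):
        center, radii, exps = _BONE_CATALOGUE[bone_id]
        amp = min(spec.noise_amplitude, 0.12 * float(np.prod(radii)) ** (1 / 3))
        bones[bone_id] = generate_bone(
            radii, exps, amp, seed=spec.seed * 1000 + idx,
            subdivisions=spec.subdivisions, center=center, bone_id=bone_id,
        )

    _check_overlaps(bones)

    hierarchy = default_hierarchy()
    ligaments = _build_ligaments(bones)

    # global grid covering the reference foot with margin
    sp = np.asarray(spec.spacing)
    lo = np.min([b.mesh.bounds[0] for b in bones.values()], axis=0) - 5
    hi = np.max([b.mesh.bounds[1] for b in bones.values()], axis=0) + 5
    origin = np.floor(lo / sp) * sp
    shape = tuple(np.ceil((hi - origin) / sp).astype(int) + 1)

    # per-bone reference masks on grid-aligned tight boxes
    masks: dict[str, BinaryMask] = {}
    for bone_id, bone in bones.items():
        blo = bone.mesh.bounds[0] - 2
        bhi = bone.mesh.bounds[1] + 2
        borigin = origin + np.floor((blo - origin) / sp) * sp
        bshape = tuple(np.ceil((bhi - borigin) / sp).astype(int) + 1)
        masks[bone_id] = voxelize([bone.mesh], tuple(sp), tuple(borigin), bshape)

    # generic source model: per-bone resampled mesh carried through a known
    # smooth map (isotropic scale + sinusoidal displacement field)
    generic_meshes: dict[str, trimesh.Trimesh] = {}
    generic_attachments: dict[str, np.ndarray] = {}
    attachment_truth: dict[str, np.ndarray] = {}
    resample_rot = trimesh.transformations.rotation_matrix(
        np.radians(10.0), [1, 1, 1])[:3, :3]
    base = trimesh.creation.icosphere(subdivisions=spec.generic_subdivisions)
    base_dirs = np.asarray(base.vertices, dtype=float)
    base_dirs /= np.linalg.norm(base_dirs, axis=1, keepdims=True)

    fibers = [f for lig in ligaments for f in lig.fibers]
    per_bone_points: dict[str, list[tuple[str, np.ndarray]]] = {b: [] for b in bones}
    for f in fibers:
        per_bone_points[f.origin_bone].append((f"{f.name}:origin", np.asarray(f.origin_point)))
        per_bone_points[f.insertion_bone].append((f"{f.name}:insertion", np.asarray(f.insertion_point)))

    for bone_idx, (bone_id, bone) in enumerate(bones.items()):
        deform = _generic_deformation(
            np.random.default_rng(spec.seed * 2000 + bone_idx),
            spec.generic_deform_amplitude)

        def phi(p: np.ndarray) -> np.ndarray:
            p = np.atleast_2d(p)
            scaled = bone.center + spec.generic_scale * (p - bone.center)
            return scaled + deform(p - bone.center)

        dirs = base_dirs @ resample_rot.T
        r = bone.radial(dirs)
        patient_pts = bone.center + r[:, None] * dirs
        generic_meshes[bone_id] = make_mesh(phi(patient_pts), np.asarray(base.faces))
        for key, q in per_bone_points[bone_id]:
            generic_attachments[key] = phi(q)[0]
            attachment_truth[key] = np.asarray(q, dtype=float)

    return FootPhantom(spec, bones, hierarchy, ligaments, masks,
                       generic_meshes, generic_attachments, attachment_truth,
                       origin, shape)


def _check_overlaps(bones: dict[str, PhantomBone]) -> None:
    names = list(bones)
    for i, a in enumerate(names):
        va = np.asarray(bones[a].mesh.vertices)
        for b in names[i + 1:]:
            bb = bones[b]
            # cheap reject on bounding spheres
            gap = np.linalg.norm(bb.center - bones[a].center)
            if gap > bones[a].radii.max() + bb.radii.max() + 2:
                continue
            if bb.contains(va).any() or bones[a].contains(np.asarray(bb.mesh.vertices)).any():
                raise RuntimeError(f"phantom bones overlap: {a} / {b}")


def random_load_transforms(
    bones: dict[str, PhantomBone],
    seed: int,
    whole_foot_rot_deg: float = 2.5,
    whole_foot_trans_mm: float = 2.5,
    per_bone_rot_deg: float = 3.0,
    per_bone_trans_mm: float = 1.5,
    local_scale: float = 1.0,
) -> dict[str, RigidTransform]:
    """Ground-truth load-case transforms: one whole-foot rigid motion about
    the foot centroid composed with small per-bone perturbations about each
    bone centre.

    ``local_scale`` multiplies the per-bone component only, with identical
    random draws for any value — so a scaled-down run models the same load
    case with stiffer relative bone motion (e.g. a shod counterpart of a
    bare configuration).
    """
    rng = np.random.default_rng(seed)
    centroid = np.mean([b.center for b in bones.values()], axis=0)

    def about(center: np.ndarray, euler: np.ndarray, trans: np.ndarray) -> RigidTransform:
        rot = RigidTransform(tuple(euler)).rotation_matrix
        return RigidTransform.from_matrix(rot, center + trans - rot @ center)

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(whole_foot_rot_deg)
    euler_global = _axis_angle_to_zyx(axis, ang)
    t_global = rng.uniform(-1, 1, 3)
    t_global *= whole_foot_trans_mm / max(np.linalg.norm(t_global), 1e-9)
    global_tf = about(centroid, euler_global, t_global)

    out: dict[str, RigidTransform] = {}
    from .geometry import compose as _compose
    for bone_id, bone in bones.items():
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        a = np.radians(rng.uniform(0.5, per_bone_rot_deg)) * local_scale
        tr = rng.uniform(-1, 1, 3)
        tr *= rng.uniform(0.2, per_bone_trans_mm) * local_scale / max(np.linalg.norm(tr), 1e-9)
        local = about(bone.center, _axis_angle_to_zyx(ax, a), tr)
        out[bone_id] = _compose(global_tf, local)
    return out


def _axis_angle_to_zyx(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(angle * np.asarray(axis)).as_euler("ZYX")


def apply_load_case(
    phantom: FootPhantom,
    transforms: dict[str, RigidTransform],
    config_id: str = "load",
    orientation: str = "N",
    load_ratio: float = 1.0,
    footwear: str = "bare",
) -> tuple[ConfigurationState, BinaryMask]:
    """Move every bone by its truth transform and voxelize the union into
    one skeleton mask (the loaded-configuration threshold output)."""
    for bone_id, tf in transforms.items():
        rot_angle = np.degrees(np.arccos(np.clip(
            (np.trace(tf.rotation_matrix) - 1) / 2, -1, 1)))
        disp = np.linalg.norm(
            tf.apply(phantom.bones[bone_id].center) - phantom.bones[bone_id].center)
        if rot_angle > 20 or disp > 15:
            raise ValueError(
                f"{bone_id}: transform outside plausibility bounds "
                f"({rot_angle:.1f} deg, {disp:.1f} mm)")

    moved = []
    for bone_id, bone in phantom.bones.items():
        m = bone.mesh.copy()
        m.vertices = transforms[bone_id].apply(np.asarray(m.vertices))
        moved.append(m)

    sp = np.asarray(phantom.spec.spacing)
    lo = np.min([m.bounds[0] for m in moved], axis=0) - 3
    hi = np.max([m.bounds[1] for m in moved], axis=0) + 3
    origin = phantom.grid_origin + np.floor((lo - phantom.grid_origin) / sp) * sp
    shape = tuple(np.ceil((hi - origin) / sp).astype(int) + 1)
    mask = voxelize(moved, tuple(sp), tuple(origin), shape)
    if phantom.spec.dilate:
        arr = ndimage.binary_dilation(
            mask.array, structure=ndimage.generate_binary_structure(3, 1))
        mask = VoxelVolume(arr, mask.spacing, mask.origin)

    state = ConfigurationState(config_id, dict(transforms), orientation,
                               load_ratio, footwear)
    return state, mask


# ---------------------------------------------------------------------------
# Morphing test pairs
# ---------------------------------------------------------------------------


def generate_bone_pairs(
    n: int = 10,
    seed: int = 42,
    subdivisions: int = 5,
    scale_mm: tuple[float, float] = (15.0, 40.0),
    deform_amplitude: float = 1.0,
    scale_factor: float = 1.05,
) -> list[dict]:
    """Generic/patient bone pairs with a known analytic generic->patient map.

    The patient bone is a perturbed superellipsoid; the generic source is
    the same surface resampled at rotated directions and carried through a
    known smooth deformation (about 1–2 mm) plus an isotropic scale.  Each
    dict holds source/target meshes, the truth map, and one attachment
    point with its patient-space truth.  Pair 0 is calcaneus-scale (the
    largest bone), the rest sample the size range.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    base = trimesh.creation.icosphere(subdivisions=subdivisions)
    base_dirs = np.asarray(base.vertices, dtype=float)
    base_dirs /= np.linalg.norm(base_dirs, axis=1, keepdims=True)
    rot = trimesh.transformations.rotation_matrix(np.radians(10.0), [1, 1, 1])[:3, :3]

    for i in range(n):
        if i == 0:
            radii = np.array([40.0, 22.0, 18.0])  # calcaneus scale, ~80 mm long
        else:
            long = rng.uniform(*scale_mm)
            radii = np.array([long, long * rng.uniform(0.45, 0.85),
                              long * rng.uniform(0.4, 0.8)])
        bone = generate_bone(tuple(radii), (1.0, 1.0), 0.3,
                             seed=seed * 100 + i, subdivisions=subdivisions)
        deform = _generic_deformation(np.random.default_rng(seed * 300 + i),
                                      deform_amplitude)

        def phi(p: np.ndarray, _d=deform) -> np.ndarray:
            p = np.atleast_2d(p)
            return scale_factor * p + _d(p)

        dirs = base_dirs @ rot.T
        r = bone.radial(dirs)
        patient_pts = r[:, None] * dirs
        source = make_mesh(phi(patient_pts), np.asarray(base.faces))

        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        attach_truth = bone.surface_point(u)
        pairs.append({
            "source": source,
            "target": bone.mesh,
            "phi": phi,
            "attachment_source": phi(attach_truth)[0],
            "attachment_truth": attach_truth,
        })
    return pairs
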