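"""Volume I/O and conversions between voxel masks, point clouds and meshes.

Volumes are stored with the array indexed ``[x, y, z]``; the voxel centre at
index ``(i, j, k)`` sits at ``origin + index * spacing`` in world mm.  Only
axis-aligned volumes are supported: files carrying a non-identity direction
matrix are rejected rather than silently reoriented.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage import measure
import trimesh

from .geometry import PointCloud, make_mesh

__all__ = [
    "VoxelVolume",
    "FormatError",
    "read_volume",
    "write_volume",
    "threshold_skeleton",
    "mask_to_points",
    "mask_to_mesh",
]

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


class FormatError(ValueError):
    """Unreadable file or unsupported volume format."""


@dataclass
class VoxelVolume:
    """3D scalar grid with spacing and origin metadata (mm).

    A boolean ``array`` makes the volume a binary mask; the same metadata
    conventions apply.
    """

    array: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError("volume array must be 3D with nonzero extent")
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError("spacing must be three positive mm values")
        self.array = arr
        self.spacing = tuple(sp)
        self.origin = tuple(np.asarray(self.origin, dtype=float))

    @property
    def is_mask(self) -> bool:
        return self.array.dtype == bool

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(self.spacing)


# same type is used for binary masks; alias for signature clarity
BinaryMask = VoxelVolume


def _matches(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(ext) for ext in _EXTENSIONS)


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not _matches(path):
        raise FormatError(f"unsupported volume extension: {path.name}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises RuntimeError on corrupt files
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError(
            f"{path.name}: non-identity direction matrix; axis-aligned volumes only"
        )
    # sitk arrays are [z, y, x]; transpose to [x, y, z]
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    if arr.dtype == np.uint8 and set(np.unique(arr)).issubset({0, 1}):
        arr = arr.astype(bool)
    return VoxelVolume(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume; masks are stored as uint8 0/1. Gzip is inferred from the name."""
    path = Path(path)
    if not _matches(path):
        raise FormatError(f"unsupported volume extension: {path.name}")
    arr = vol.array
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def threshold_skeleton(vol: VoxelVolume, threshold: float) -> BinaryMask:
    """Binary skeleton mask: voxel true iff intensity >= threshold.

    One threshold applied to a loaded-configuration CT separates bone from
    soft tissue without separating individual bones.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = np.asarray(vol.array) >= threshold
    if not mask.any():
        raise ValueError(f"no voxels at or above threshold {threshold}")
    return VoxelVolume(mask, vol.spacing, vol.origin)


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def mask_to_points(mask: BinaryMask, surface_only: bool = True) -> PointCloud:
    """World coordinates of true-voxel centres.

    With ``surface_only`` (the default for registration speed) only voxels
    with at least one false 6-neighbour are kept — the interface voxels the
    closest-point cost actually probes.
    """
    arr = np.asarray(mask.array, dtype=bool)
    if not arr.any():
        raise ValueError("empty mask")
    if surface_only:
        interior = ndimage.binary_erosion(arr, structure=_FACE_STRUCTURE, border_value=0)
        arr = arr & ~interior
    idx = np.argwhere(arr)
    return PointCloud(mask.world_coordinates(idx))


def mask_to_mesh(mask: BinaryMask) -> trimesh.Trimesh:
    """Marching-cubes isosurface of a binary mask at level 0.5, world mm.

    The mask is padded by one voxel so surfaces touching the array border
    still close.
    """
    arr = np.asarray(mask.array, dtype=bool)
    if not arr.any():
        raise ValueError("empty mask")
    padded = np.pad(arr, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    verts = verts + np.asarray(mask.origin) - np.asarray(mask.spacing)
    mesh = make_mesh(verts, faces)
    if mesh.volume < 0:  # orient faces outward
        mesh = make_mesh(verts, faces[:, ::-1])
    return mesh
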