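"""Biomechanical measures derived from per-configuration bone transforms.

Given the rigid transform of every bone from the unloaded reference pose
into a loaded configuration, this module derives:

* **motion amplitudes** — displacement of a bone's centre of mass and the
  geodesic rotation angle, expressed relative to a frame bone (tibia to
  include whole-foot motion, calcaneus to remove it);
* **projected joint angles** — signed angles between bone centres of mass
  projected onto the anatomical planes (e.g. tibia–talus–calcaneus in the
  sagittal plane for plantar/dorsal flexion);
* **ligament strains** — engineering strain of straight-line fibres whose
  attachment points move rigidly with their bones.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import RigidTransform, compose, invert

__all__ = [
    "ConfigurationState",
    "AnatomicalFrame",
    "LigamentFiber",
    "LigamentDefinition",
    "AngleDefinition",
    "DEFAULT_ANGLES",
    "relative_transform",
    "translation_amplitude",
    "rotation_amplitude",
    "build_anatomical_frame",
    "projected_angle",
    "measure_angles",
    "ligament_length",
    "ligament_strain",
    "measure_table",
]

ORIENTATIONS = ("N", "PF", "DF", "EV", "IV")
PLANES = ("sagittal", "coronal", "transverse")


@dataclass
class ConfigurationState:
    """One loaded configuration: metadata plus per-bone transforms from reference."""

    config_id: str
    transforms: dict[str, RigidTransform]
    orientation: str = "N"
    load_ratio: float = 0.0
    footwear: str = "bare"
    #: identifies the load case independently of footwear, so bare and shod
    #: acquisitions of the same case pair up in the statistics layer;
    #: defaults to config_id
    case_id: str | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.footwear not in ("bare", "shod"):
            raise ValueError("footwear must be 'bare' or 'shod'")
        if self.load_ratio < 0:
            raise ValueError("load ratio must be >= 0")

    def transform(self, bone_id: str) -> RigidTransform:
        try:
            return self.transforms[bone_id]
        except KeyError:
            raise KeyError(f"bone {bone_id!r} not present in configuration {self.config_id!r}")


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal anatomical axes in reference-pose world space."""

    anterior: np.ndarray
    superior: np.ndarray
    medial: np.ndarray
    origin: np.ndarray
    side: str = "right"

    def plane_axes(self, plane: str) -> tuple[np.ndarray, np.ndarray]:
        """In-plane basis (u, v) for a named anatomical plane."""
        if plane == "sagittal":
            return self.anterior, self.superior
        if plane == "coronal":
            return self.medial, self.superior
        if plane == "transverse":
            return self.anterior, self.medial
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")


@dataclass(frozen=True)
class LigamentFiber:
    """One straight-line fibre between two bone-fixed attachment points.

    Attachment coordinates are reference-pose world mm; they move rigidly
    with their bones.
    """

    name: str
    origin_bone: str
    origin_point: tuple[float, float, float]
    insertion_bone: str
    insertion_point: tuple[float, float, float]
    group: str = ""

    def __post_init__(self) -> None:
        if self.origin_bone == self.insertion_bone:
            raise ValueError(f"fiber {self.name}: origin and insertion on the same bone")


@dataclass
class LigamentDefinition:
    """A named ligament: one or more fibres plus a group label."""

    name: str
    fibers: list[LigamentFiber]
    group: str = ""


@dataclass(frozen=True)
class AngleDefinition:
    """An angle at vertex bone B between rays B->A and B->C, in a named plane."""

    name: str
    bones: tuple[str, str, str]
    plane: str

    def __post_init__(self) -> None:
        if len(set(self.bones)) != 3:
            raise ValueError("angle definition needs three distinct bones")
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")


#: the two tracked angles, each in its two clinically meaningful planes:
#: tibia-talus-calcaneus (plantar/dorsal flexion, varus/valgus) and
#: calcaneus-talus-medial sesamoid (arch sagging, abduction/adduction)
DEFAULT_ANGLES: tuple[AngleDefinition, ...] = (
    AngleDefinition("TibTalCal", ("tibia", "talus", "calcaneus"), "sagittal"),
    AngleDefinition("TibTalCal", ("tibia", "talus", "calcaneus"), "coronal"),
    AngleDefinition("CalTalSM", ("calcaneus", "talus", "sesamoid_medial"), "sagittal"),
    AngleDefinition("CalTalSM", ("calcaneus", "talus", "sesamoid_medial"), "transverse"),
)


def relative_transform(bone_tf: RigidTransform, frame_tf: RigidTransform) -> RigidTransform:
    """Motion of a bone expressed in the (moving) frame bone: inv(frame) o bone."""
    return compose(invert(frame_tf), bone_tf)


def translation_amplitude(
    state: ConfigurationState, bone_id: str, frame_bone_id: str,
    reference_com: dict[str, np.ndarray],
) -> float:
    """Displacement (mm) of the bone's reference centre of mass under the
    relative transform with respect to the frame bone."""
    rel = relative_transform(state.transform(bone_id), state.transform(frame_bone_id))
    com = np.asarray(reference_com[bone_id], dtype=float)
    return float(np.linalg.norm(rel.apply(com) - com))


def rotation_amplitude(state: ConfigurationState, bone_id: str, frame_bone_id: str) -> float:
    """Geodesic rotation angle (degrees) of the relative transform."""
    rel = relative_transform(state.transform(bone_id), state.transform(frame_bone_id))
    tr = np.trace(rel.rotation_matrix)
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def build_anatomical_frame(
    reference_com: dict[str, np.ndarray],
    tibia_axis: np.ndarray,
    side: str = "right",
) -> AnatomicalFrame:
    """Anatomical frame from reference-pose landmarks.

    Superior is the tibia long axis (pointing up the shaft), anterior the
    calcaneus-to-second-metatarsal direction orthogonalized against
    superior, medial their cross product with a side-dependent sign.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    superior = np.asarray(tibia_axis, dtype=float)
    ns = np.linalg.norm(superior)
    if ns < 1e-12:
        raise ValueError("degenerate tibia axis")
    superior = superior / ns

    cal = np.asarray(reference_com["calcaneus"], dtype=float)
    met2 = np.asarray(reference_com["metatarsal_2"], dtype=float)
    raw_ant = met2 - cal
    anterior = raw_ant - (raw_ant @ superior) * superior
    na = np.linalg.norm(anterior)
    if na < 1e-9:
        raise ValueError("collinear anatomical landmarks: anterior axis undefined")
    anterior = anterior / na

    medial = np.cross(superior, anterior)
    if side == "left":
        medial = -medial
    return AnatomicalFrame(anterior, superior, medial, origin=cal, side=side)


def projected_angle(
    com_a: np.ndarray, com_b: np.ndarray, com_c: np.ndarray,
    frame: AnatomicalFrame, plane: str,
) -> float:
    """Signed angle (degrees, in (-180, 180]) at B between B->A and B->C,
    after projecting all three centres of mass onto the named plane."""
    u, v = frame.plane_axes(plane)

    def proj(p: np.ndarray) -> np.ndarray:
        q = np.asarray(p, dtype=float) - frame.origin
        return np.array([q @ u, q @ v])

    a2, b2, c2 = proj(com_a), proj(com_b), proj(com_c)
    ra, rc = a2 - b2, c2 - b2
    if np.linalg.norm(ra) < 1e-12 or np.linalg.norm(rc) < 1e-12:
        raise ValueError("projected centres of mass coincide; angle undefined")
    ang = np.arctan2(rc[1], rc[0]) - np.arctan2(ra[1], ra[0])
    deg = np.degrees(ang)
    deg = (deg + 180.0) % 360.0 - 180.0
    if deg == -180.0:
        deg = 180.0
    return float(deg)


def _moved_com(state: ConfigurationState, bone: str, reference_com: dict[str, np.ndarray]) -> np.ndarray:
    return state.transform(bone).apply(np.asarray(reference_com[bone], dtype=float))


def measure_angles(
    states: list[ConfigurationState],
    frame: AnatomicalFrame,
    reference_com: dict[str, np.ndarray],
    definitions: tuple[AngleDefinition, ...] = DEFAULT_ANGLES,
    reference_state: ConfigurationState | None = None,
) -> pd.DataFrame:
    """Angle table: one row per configuration per definition.

    ``amplitude_deg`` is the change from the reference (step-0) state,
    which is the quantity the statistics layer compares.
    """
    ref_angles: dict[tuple[str, str], float] = {}
    if reference_state is not None:
        for d in definitions:
            a, b, c = d.bones
            ref_angles[(d.name, d.plane)] = projected_angle(
                _moved_com(reference_state, a, reference_com),
                _moved_com(reference_state, b, reference_com),
                _moved_com(reference_state, c, reference_com),
                frame, d.plane,
            )
    rows = []
    for st in states:
        for d in definitions:
            a, b, c = d.bones
            ang = projected_angle(
                _moved_com(st, a, reference_com),
                _moved_com(st, b, reference_com),
                _moved_com(st, c, reference_com),
                frame, d.plane,
            )
            ref = ref_angles.get((d.name, d.plane))
            rows.append({
                "config_id": st.config_id,
                "footwear": st.footwear,
                "angle": d.name,
                "plane": d.plane,
                "angle_deg": ang,
                "amplitude_deg": ang - ref if ref is not None else np.nan,
            })
    return pd.DataFrame(rows)


def ligament_length(state: ConfigurationState, fiber: LigamentFiber) -> float:
    """Straight-line distance between the world-space attachment points."""
    o = state.transform(fiber.origin_bone).apply(np.asarray(fiber.origin_point))
    i = state.transform(fiber.insertion_bone).apply(np.asarray(fiber.insertion_point))
    return float(np.linalg.norm(i - o))


def ligament_strain(
    state: ConfigurationState, reference: ConfigurationState, fiber: LigamentFiber
) -> float:
    """Engineering strain in percent: 100 (L - L_ref) / L_ref."""
    l_ref = ligament_length(reference, fiber)
    if l_ref < 1e-6:
        raise ValueError(f"fiber {fiber.name}: reference length below 1e-6 mm")
    return 100.0 * (ligament_length(state, fiber) - l_ref) / l_ref


def measure_table(
    states: list[ConfigurationState],
    reference: ConfigurationState,
    reference_com: dict[str, np.ndarray],
    frame: AnatomicalFrame,
    ligaments: list[LigamentDefinition] | None = None,
    angle_definitions: tuple[AngleDefinition, ...] = DEFAULT_ANGLES,
    frame_bones: tuple[str, ...] = ("tibia", "calcaneus"),
) -> pd.DataFrame:
    """Long-form measure table consumed by the statistics layer.

    Columns: config_id, footwear, metric_type, entity, frame_bone, value.
    metric_type is one of translation_mm, rotation_deg, angle_deg, strain_pct.
    """
    rows = []
    for st in states:
        for frame_bone in frame_bones:
            for bone in st.transforms:
                if bone == frame_bone:
                    continue
                rows.append({
                    "config_id": st.case_id or st.config_id,
                    "footwear": st.footwear,
                    "metric_type": "translation_mm", "entity": bone,
                    "frame_bone": frame_bone,
                    "value": translation_amplitude(st, bone, frame_bone, reference_com),
                })
                rows.append({
                    "config_id": st.case_id or st.config_id,
                    "footwear": st.footwear,
                    "metric_type": "rotation_deg", "entity": bone,
                    "frame_bone": frame_bone,
                    "value": rotation_amplitude(st, bone, frame_bone),
                })
    angles = measure_angles(states, frame, reference_com, angle_definitions, reference)
    case_of = {st.config_id: st.case_id or st.config_id for st in states}
    for _, r in angles.iterrows():
        rows.append({
            "config_id": case_of[r.config_id], "footwear": r.footwear,
            "metric_type": "angle_deg", "entity": f"{r.angle}_{r.plane}",
            "frame_bone": "", "value": r.amplitude_deg,
        })
    for lig in ligaments or []:
        for st in states:
            for fiber in lig.fibers:
                rows.append({
                    "config_id": st.case_id or st.config_id,
                    "footwear": st.footwear,
                    "metric_type": "strain_pct", "entity": fiber.name,
                    "frame_bone": "", "value": ligament_strain(st, reference, fiber),
                })
    return pd.DataFrame(rows)
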