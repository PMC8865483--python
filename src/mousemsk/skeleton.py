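"""Kinematic skeleton: rigid segments, rotational joints, forward kinematics.

The skeleton is a rooted tree of rigid segments connected by rotational
joints with 1-3 degrees of freedom (DoFs) each.  Every joint has a fixed
rotation center expressed in the parent segment's frame; DoF rotations are
composed about that center in the joint's declared DoF order.  The
*zero-pose* is the configuration with every joint angle at zero; segment
``local_frame`` transforms are the parent-relative placements at zero-pose.

Angles are radians internally; model files use degrees (converted at the
I/O boundary by :mod:`mousemsk.model_io`).  Lengths are millimetres except
where noted (inertial estimation is SI).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Segment",
    "DoF",
    "Joint",
    "SkeletonModel",
    "Pose",
    "ModelValidationError",
    "MeshIntegrityError",
    "build_skeleton",
    "forward_kinematics",
    "limit_torque",
    "hull_inertia",
]

# Joint-limit defaults: small-animal scale; overridable per DoF in config.
DEFAULT_LIMIT_STIFFNESS = 0.5  # N*m/rad
DEFAULT_LIMIT_DAMPING = 0.01  # N*m*s/rad
DEFAULT_TRANSITION_WIDTH = math.radians(2.0)  # rad


class ModelValidationError(ValueError):
    """Raised when a model description violates the schema or tree property."""


class MeshIntegrityError(ValueError):
    """Raised when a mesh is open, degenerate, or inconsistently oriented."""


@dataclass
class Inertial:
    mass: float  # kg
    com: np.ndarray  # 3-vector, m
    inertia: np.ndarray  # 3x3, kg*m^2, about COM

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)
        self.inertia = np.asarray(self.inertia, dtype=float)
        if self.mass < 0:
            raise ValueError("mass must be >= 0")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-9):
            raise ValueError("inertia tensor must be symmetric")
        if np.linalg.eigvalsh(self.inertia).min() < -1e-9:
            raise ValueError("inertia tensor must be positive semi-definite")


@dataclass
class Segment:
    name: str
    parent_joint: str | None = None
    local_frame: np.ndarray = field(default_factory=lambda: np.eye(4))
    mesh_ref: str | None = None
    inertial: Inertial | None = None

    def __post_init__(self) -> None:
        self.local_frame = np.asarray(self.local_frame, dtype=float)
        if self.local_frame.shape != (4, 4):
            raise ValueError(f"segment {self.name!r}: local_frame must be 4x4")


@dataclass
class DoF:
    """One rotational degree of freedom of a joint.

    ``axis`` is a unit vector in the joint frame (the parent frame at the
    rotation center); ``range`` is (min, max) in radians.  Positive rotation
    follows the right-hand rule about the axis.
    """

    name: str
    axis: np.ndarray
    range: tuple[float, float]
    limit_stiffness: float = DEFAULT_LIMIT_STIFFNESS
    limit_damping: float = DEFAULT_LIMIT_DAMPING
    transition_width: float = DEFAULT_TRANSITION_WIDTH

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if not math.isclose(n, 1.0, rel_tol=1e-6):
            if n == 0:
                raise ValueError(f"DoF {self.name!r}: axis must be non-zero")
            self.axis = self.axis / n
        lo, hi = self.range
        if not lo < hi:
            raise ValueError(f"DoF {self.name!r}: range min must be < max")


@dataclass
class Joint:
    name: str
    parent_segment: str
    child_segment: str
    rotation_center: np.ndarray
    dofs: list[DoF]

    def __post_init__(self) -> None:
        self.rotation_center = np.asarray(self.rotation_center, dtype=float)
        if not 1 <= len(self.dofs) <= 3:
            raise ValueError(f"joint {self.name!r}: needs 1-3 DoFs")
        for a, b in zip(self.dofs, self.dofs[1:]):
            cross = np.cross(a.axis, b.axis)
            if np.linalg.norm(cross) < 1e-9:
                raise ValueError(
                    f"joint {self.name!r}: DoF axes {a.name!r} and {b.name!r} are parallel"
                )


class Pose:
    """Assignment of angles (rad) to DoF names; unspecified DoFs are zero."""

    def __init__(self, angles: dict[str, float] | None = None):
        self.angles = dict(angles or {})

    def __getitem__(self, dof_name: str) -> float:
        return self.angles.get(dof_name, 0.0)

    def with_angle(self, dof_name: str, angle: float) -> "Pose":
        new = dict(self.angles)
        new[dof_name] = angle
        return Pose(new)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Pose({self.angles!r})"


class SkeletonModel:
    """Rooted tree of segments and joints with lookup tables."""

    def __init__(self, segments: list[Segment], joints: list[Joint]):
        self.segments = {s.name: s for s in segments}
        self.joints = {j.name: j for j in joints}
        if len(self.segments) != len(segments):
            seen: set[str] = set()
            dup = next(s.name for s in segments if s.name in seen or seen.add(s.name))
            raise ModelValidationError(f"duplicate segment name: {dup!r}")
        if len(self.joints) != len(joints):
            seen = set()
            dup = next(j.name for j in joints if j.name in seen or seen.add(j.name))
            raise ModelValidationError(f"duplicate joint name: {dup!r}")
        self._validate_tree()
        self._dof_to_joint: dict[str, Joint] = {}
        for j in self.joints.values():
            for d in j.dofs:
                if d.name in self._dof_to_joint:
                    raise ModelValidationError(f"duplicate DoF name: {d.name!r}")
                self._dof_to_joint[d.name] = j

    def _validate_tree(self) -> None:
        child_of: dict[str, str] = {}
        for j in self.joints.values():
            for ref in (j.parent_segment, j.child_segment):
                if ref not in self.segments:
                    raise ModelValidationError(
                        f"joint {j.name!r} references unknown segment {ref!r}"
                    )
            if j.child_segment in child_of:
                raise ModelValidationError(
                    f"segment {j.child_segment!r} has multiple parent joints"
                )
            child_of[j.child_segment] = j.parent_segment
        roots = [s for s in self.segments if s not in child_of]
        if len(roots) != 1:
            raise ModelValidationError(
                f"model must have exactly one root segment, found {sorted(roots)!r}"
            )
        self.root = roots[0]
        # cycle check: walk each segment to the root
        for start in self.segments:
            seen = {start}
            cur = start
            while cur in child_of:
                cur = child_of[cur]
                if cur in seen:
                    raise ModelValidationError(f"cycle involving segment {cur!r}")
                seen.add(cur)
        self._parent_segment = child_of
        self._parent_joint = {j.child_segment: j for j in self.joints.values()}

    # -- lookups -------------------------------------------------------
    def parent_joint_of(self, segment: str) -> Joint | None:
        return self._parent_joint.get(segment)

    def joint_of_dof(self, dof_name: str) -> Joint:
        try:
            return self._dof_to_joint[dof_name]
        except KeyError:
            raise KeyError(f"unknown DoF {dof_name!r}") from None

    def dof(self, dof_name: str) -> DoF:
        j = self.joint_of_dof(dof_name)
        return next(d for d in j.dofs if d.name == dof_name)

    def dof_names(self) -> list[str]:
        return list(self._dof_to_joint)

    def descendants(self, segment: str) -> set[str]:
        """Segment and everything distal to it in the tree."""
        children: dict[str, list[str]] = {}
        for j in self.joints.values():
            children.setdefault(j.parent_segment, []).append(j.child_segment)
        out, stack = set(), [segment]
        while stack:
            s = stack.pop()
            out.add(s)
            stack.extend(children.get(s, []))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SkeletonModel({len(self.segments)} segments, "
            f"{len(self.joints)} joints, root={self.root!r})"
        )


def build_skeleton(config: dict) -> SkeletonModel:
    """Build a validated :class:`SkeletonModel` from a model-description dict.

    The dict follows the model YAML schema (see :mod:`mousemsk.model_io`):
    ``segments`` is a list of segment entries and ``joints`` a list of joint
    entries with nested DoF definitions.  Angles in the config are degrees
    and are converted to radians here.
    """
    segments = []
    for s in config.get("segments", []):
        frame = np.eye(4)
        if "origin_mm" in s:
            frame[:3, 3] = np.asarray(s["origin_mm"], dtype=float)
        if "rotation_deg" in s:
            frame[:3, :3] = Rotation.from_euler(
                "xyz", s["rotation_deg"], degrees=True
            ).as_matrix()
        inertial = None
        if "inertial" in s:
            i = s["inertial"]
            inertial = Inertial(i["mass_kg"], i["com_m"], i["inertia_kg_m2"])
        segments.append(
            Segment(
                name=s["name"],
                local_frame=frame,
                mesh_ref=s.get("mesh"),
                inertial=inertial,
            )
        )
    joints = []
    for j in config.get("joints", []):
        dofs = []
        for d in j["dofs"]:
            lo, hi = d["range_deg"]
            dofs.append(
                DoF(
                    name=d["name"],
                    axis=d["axis"],
                    range=(math.radians(lo), math.radians(hi)),
                    limit_stiffness=d.get("limit_stiffness", DEFAULT_LIMIT_STIFFNESS),
                    limit_damping=d.get("limit_damping", DEFAULT_LIMIT_DAMPING),
                    transition_width=math.radians(
                        d.get("transition_width_deg", 2.0)
                    ),
                )
            )
        joints.append(
            Joint(
                name=j["name"],
                parent_segment=j["parent"],
                child_segment=j["child"],
                rotation_center=np.asarray(j.get("center_mm", (0, 0, 0)), dtype=float),
                dofs=dofs,
            )
        )
    return SkeletonModel(segments, joints)


def _joint_rotation(joint: Joint, pose: Pose) -> np.ndarray:
    """4x4 rotation about the joint center, DoFs composed in declared order."""
    R = np.eye(3)
    for d in joint.dofs:
        ang = pose[d.name]
        if ang != 0.0:
            R = R @ Rotation.from_rotvec(ang * d.axis).as_matrix()
    T = np.eye(4)
    T[:3, :3] = R
    c = joint.rotation_center
    T[:3, 3] = c - R @ c
    return T


def forward_kinematics(
    model: SkeletonModel, pose: Pose, segment: str
) -> np.ndarray:
    """World-frame 4x4 rigid transform of ``segment`` at ``pose``.

    Composes parent transforms root-to-leaf; each joint contributes a
    rotation about its fixed center followed by the child's zero-pose
    ``local_frame``.
    """
    if segment not in model.segments:
        raise KeyError(f"unknown segment {segment!r}")
    chain = []
    cur = segment
    while cur is not None:
        chain.append(cur)
        cur = model._parent_segment.get(cur)
    T = np.eye(4)
    for name in reversed(chain):
        joint = model.parent_joint_of(name)
        if joint is not None:
            T = T @ _joint_rotation(joint, pose)
        T = T @ model.segments[name].local_frame
    return T


def segment_point_world(
    model: SkeletonModel, pose: Pose, segment: str, local_point
) -> np.ndarray:
    """Map a segment-local point (mm) to world coordinates at ``pose``."""
    T = forward_kinematics(model, pose, segment)
    p = np.asarray(local_point, dtype=float)
    return T[:3, :3] @ p + T[:3, 3]


def limit_torque(dof: DoF, angle: float, angular_velocity: float = 0.0) -> float:
    """Joint-limit torque (N*m): a torsional spring-damper engaging past the range.

    Zero strictly inside [min, max].  Past a limit the spring stiffness ramps
    linearly from zero over ``transition_width`` (quadratic torque), then
    becomes linear; the damper engages with the same ramp so the total torque
    is continuous at the boundary.  The sign always opposes penetration.
    """
    lo, hi = dof.range
    if lo <= angle <= hi:
        return 0.0
    if angle > hi:
        pen = angle - hi
        sign = -1.0
    else:
        pen = lo - angle
        sign = 1.0
    k, d, w = dof.limit_stiffness, dof.limit_damping, dof.transition_width
    if w > 0 and pen < w:
        spring = k * pen * pen / (2.0 * w)
        ramp = pen / w
    else:
        spring = k * (pen - w / 2.0)
        ramp = 1.0
    return sign * spring - d * ramp * angular_velocity


def _as_trimesh(mesh, repair: bool = True):
    import trimesh

    if not isinstance(mesh, trimesh.Trimesh):
        mesh = trimesh.Trimesh(
            vertices=np.asarray(mesh[0], dtype=float),
            faces=np.asarray(mesh[1], dtype=int),
            process=True,
        )
    if not mesh.is_watertight and repair:
        mesh = mesh.copy()
        trimesh.repair.fill_holes(mesh)
        trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        raise MeshIntegrityError("mesh is not closed (watertight) and could not be repaired")
    if mesh.volume <= 0:
        raise MeshIntegrityError("mesh has non-positive volume (degenerate or inverted)")
    return mesh


def hull_inertia(mesh, density: float = 1000.0) -> Inertial:
    """Mass properties of the convex hull of ``mesh`` at uniform density.

    ``mesh`` is a :class:`trimesh.Trimesh` or a ``(vertices, faces)`` pair in
    metres.  The hull stands in for the soft-tissue volume around a bone; the
    default density is that of water (1000 kg/m^3).  Mass properties come
    from exact divergence-theorem integrals over the hull polyhedron.
    """
    m = _as_trimesh(mesh)
    hull = m.convex_hull
    hull.density = float(density)
    # trimesh.moment_inertia is the exact polyhedral integral about the COM
    return Inertial(mass=hull.mass, com=hull.center_mass, inertia=hull.moment_inertia)
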