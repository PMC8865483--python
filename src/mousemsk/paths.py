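"""Polyline muscle paths: muscle-tendon length, moment arms, joint moments.

A muscle path is an ordered list of attachment points (origin, waypoints,
insertion), each fixed in a segment-local frame.  Muscle-tendon length is
the sum of straight-line distances between consecutive world-frame points:

    lmt(pose) = sum_n || P_{n+1} - P_n ||

The moment arm of a muscle about a DoF is the tendon-excursion derivative
r = d lmt / d theta, evaluated by central differences (the perturbation
method).  Sign convention: positive r means lmt grows with positive
rotation, i.e. the muscle resists positive rotation of that DoF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .muscle import MuscleParams, muscle_force
from .skeleton import Pose, SkeletonModel, forward_kinematics

__all__ = [
    "AttachmentPoint",
    "MusclePath",
    "NoCrossingError",
    "muscle_tendon_length",
    "moment_arm",
    "crossing_segment",
    "joint_moment",
]

DEFAULT_PERTURBATION_STEP = 1e-4  # rad


class NoCrossingError(ValueError):
    """The path does not span the requested DoF's joint."""


@dataclass(frozen=True)
class AttachmentPoint:
    segment: str
    local_position: tuple[float, float, float]  # mm, segment frame
    role: str = "waypoint"  # origin | waypoint | insertion


@dataclass(frozen=True)
class MusclePath:
    muscle: str
    points: tuple[AttachmentPoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(f"{self.muscle}: path needs >= 2 points")
        if self.points[0].role != "origin" or self.points[-1].role != "insertion":
            raise ValueError(
                f"{self.muscle}: first point must be origin, last insertion"
            )

    @property
    def segments_used(self) -> set[str]:
        return {p.segment for p in self.points}


def _world_points(model: SkeletonModel, pose: Pose, path: MusclePath) -> np.ndarray:
    """(N, 3) world coordinates of the path points; FK cached per segment."""
    transforms: dict[str, np.ndarray] = {}
    out = np.empty((len(path.points), 3))
    for i, ap in enumerate(path.points):
        T = transforms.get(ap.segment)
        if T is None:
            if ap.segment not in model.segments:
                raise KeyError(
                    f"{path.muscle}: unknown segment {ap.segment!r} in path"
                )
            T = forward_kinematics(model, pose, ap.segment)
            transforms[ap.segment] = T
        out[i] = T[:3, :3] @ np.asarray(ap.local_position, float) + T[:3, 3]
    return out


def muscle_tendon_length(model: SkeletonModel, pose: Pose, path: MusclePath) -> float:
    """Total polyline length lmt (mm) at ``pose``."""
    pts = _world_points(model, pose, path)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def moment_arm(
    model: SkeletonModel,
    pose: Pose,
    path: MusclePath,
    dof: str,
    step: float = DEFAULT_PERTURBATION_STEP,
) -> float:
    """Moment arm r = d lmt / d theta (mm) about ``dof``, central difference."""
    if step <= 0:
        raise ValueError("step must be > 0")
    model.joint_of_dof(dof)  # raises KeyError for unknown DoF
    if not spans_dof(model, path, dof):
        return 0.0  # rotation leaves every inter-point distance unchanged
    theta = pose[dof]
    lp = muscle_tendon_length(model, pose.with_angle(dof, theta + step), path)
    lm = muscle_tendon_length(model, pose.with_angle(dof, theta - step), path)
    return (lp - lm) / (2.0 * step)


def spans_dof(model: SkeletonModel, path: MusclePath, dof: str) -> bool:
    """True if rotating ``dof`` can change any inter-point distance."""
    joint = model.joint_of_dof(dof)
    child_side = model.descendants(joint.child_segment)
    membership = [p.segment in child_side for p in path.points]
    return any(a != b for a, b in zip(membership, membership[1:]))


def crossing_segment(
    model: SkeletonModel, path: MusclePath, dof: str
) -> tuple[AttachmentPoint, AttachmentPoint]:
    """The unique adjacent point pair (P_WO, P_WI) whose connecting segment
    changes length under rotation of ``dof``.

    P_WO is the last path point attached on the parent side of the joint,
    P_WI the first on the child side.  Raises :class:`NoCrossingError` if
    the path does not span the DoF's joint.
    """
    joint = model.joint_of_dof(dof)
    child_side = model.descendants(joint.child_segment)
    membership = [p.segment in child_side for p in path.points]
    crossings = [
        i for i, (a, b) in enumerate(zip(membership, membership[1:])) if a != b
    ]
    if not crossings:
        raise NoCrossingError(f"{path.muscle}: path does not span DoF {dof!r}")
    i = crossings[0]
    a, b = path.points[i], path.points[i + 1]
    # orient so P_WO is parent-side
    return (a, b) if not membership[i] else (b, a)


def joint_moment(
    model: SkeletonModel,
    pose: Pose,
    path: MusclePath,
    params: MuscleParams,
    dof: str,
    activation: float = 1.0,
    step: float = DEFAULT_PERTURBATION_STEP,
) -> float:
    """Isometric muscle moment magnitude r * F about ``dof`` (N*mm), a = 1 default."""
    r = moment_arm(model, pose, path, dof, step=step)
    lmt = muscle_tendon_length(model, pose, path)
    force = muscle_force(params, activation, lmt, vmt=0.0)
    return r * force
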