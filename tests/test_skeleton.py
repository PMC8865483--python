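"""Kinematic tree construction, forward kinematics, joint limits, inertia."""

import math

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from mousemsk.skeleton import (
    DoF,
    MeshIntegrityError,
    ModelValidationError,
    Pose,
    build_skeleton,
    forward_kinematics,
    hull_inertia,
    limit_torque,
)
from mousemsk.whole_body import whole_body_config


def _hinge_config(**joint_extra):
    return {
        "segments": [{"name": "a"}, {"name": "b"}],
        "joints": [
            {
                "name": "j",
                "parent": "a",
                "child": "b",
                "center_mm": [0, 0, 0],
                "dofs": [{"name": "q", "axis": [0, 0, 1], "range_deg": [-90, 90]}],
                **joint_extra,
            }
        ],
    }


class TestBuildSkeleton:
    def test_whole_body_composition(self):
        model = build_skeleton(whole_body_config())
        assert len(model.segments) == 108
        assert len(model.joints) == 107  # tree: |joints| = |segments| - 1
        assert model.root == "pelvis"

    def test_degenerate_single_segment(self):
        model = build_skeleton({"segments": [{"name": "only"}], "joints": []})
        assert len(model.segments) == 1 and len(model.joints) == 0

    def test_minimal_hinge_chain(self):
        model = build_skeleton(_hinge_config())
        assert len(model.segments) == 2
        assert len(model.joints) == 1
        assert len(model.joints["j"].dofs) == 1

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda c: c["segments"].append({"name": "a"}), "duplicate"),
            (lambda c: c["joints"][0].update(parent="nope"), "unknown segment"),
            (lambda c: c["joints"].append(
                {"name": "j2", "parent": "b", "child": "a",
                 "center_mm": [0, 0, 0],
                 "dofs": [{"name": "q2", "axis": [0, 0, 1],
                           "range_deg": [-1, 1]}]}), "root|cycle|multiple"),
        ],
    )
    def test_invalid_configs_rejected(self, mutate, match):
        cfg = _hinge_config()
        mutate(cfg)
        with pytest.raises(ModelValidationError, match=match):
            build_skeleton(cfg)

    def test_parallel_axes_rejected(self):
        cfg = _hinge_config()
        cfg["joints"][0]["dofs"].append(
            {"name": "q2", "axis": [0, 0, -1], "range_deg": [-1, 1]}
        )
        with pytest.raises(ValueError, match="parallel"):
            build_skeleton(cfg)


class TestForwardKinematics:
    def test_zero_pose_is_composed_local_frames(self):
        cfg = whole_body_config()
        model = build_skeleton(cfg)
        # spot-check a deep chain segment: translations accumulate
        T = forward_kinematics(model, Pose(), "head")
        expected = 6 * 2.5 + 13 * 2.5 + 8 * 2.0 + 8.0  # lumbar+thoracic+cervical+head
        assert T[0, 3] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(T[:3, :3], np.eye(3), atol=1e-12)

    def test_quarter_turn_about_z(self):
        model = build_skeleton(_hinge_config())
        T = forward_kinematics(model, Pose({"q": math.pi / 2}), "b")
        p = T[:3, :3] @ np.array([1.0, 0, 0]) + T[:3, 3]
        assert np.allclose(p, [0, 1, 0], atol=1e-12)

    def test_unknown_segment_raises(self):
        model = build_skeleton(_hinge_config())
        with pytest.raises(KeyError):
            forward_kinematics(model, Pose(), "nope")

    def test_transforms_orthonormal_and_reversible(self, rng):
        model = build_skeleton(whole_body_config())
        names = model.dof_names()
        pose = Pose({n: rng.uniform(-0.5, 0.5) for n in rng.choice(names, 20)})
        for seg in ("head", "left_hind_phalange_3", "right_fore_phalange_1"):
            T = forward_kinematics(model, pose, seg)
            R = T[:3, :3]
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-12)
        # applying a pose then its negation in reverse DoF order is identity
        from mousemsk.skeleton import _joint_rotation

        joint = model.joints["left_femur_joint"]  # 3-DoF ball joint
        fwd = _joint_rotation(joint, pose)
        rev_joint = type(joint)(
            joint.name + "_rev", joint.parent_segment, joint.child_segment,
            joint.rotation_center, list(reversed(joint.dofs)),
        )
        back = _joint_rotation(rev_joint, Pose({n: -pose[n] for n in pose.angles}))
        assert np.allclose(fwd @ back, np.eye(4), atol=1e-12)


class TestLimitTorque:
    DOF = DoF("q", (0, 0, 1), (-1.0, 1.0), limit_stiffness=1.0,
              limit_damping=0.0, transition_width=0.0)

    def test_zero_inside_range(self):
        assert limit_torque(self.DOF, 0.0, 5.0) == 0.0
        assert limit_torque(self.DOF, 0.999, -3.0) == 0.0

    def test_linear_spring_past_limit(self):
        assert limit_torque(self.DOF, 1.1, 0.0) == pytest.approx(-0.1)
        assert limit_torque(self.DOF, -1.1, 0.0) == pytest.approx(0.1)

    def test_monotone_in_penetration(self):
        d = DoF("q", (0, 0, 1), (-1.0, 1.0), limit_stiffness=2.0,
                limit_damping=0.0, transition_width=math.radians(2))
        pens = np.linspace(1.0001, 1.5, 40)
        taus = [abs(limit_torque(d, p, 0.0)) for p in pens]
        assert all(b >= a for a, b in zip(taus, taus[1:]))

    def test_continuous_at_boundary_with_transition(self):
        d = DoF("q", (0, 0, 1), (-1.0, 1.0), limit_stiffness=5.0,
                limit_damping=0.5, transition_width=math.radians(2))
        just_out = limit_torque(d, 1.0 + 1e-9, 10.0)
        assert abs(just_out) < 1e-6  # matches the zero inside value

    def test_damping_opposes_velocity(self):
        d = DoF("q", (0, 0, 1), (-1.0, 1.0), limit_stiffness=0.0,
                limit_damping=1.0, transition_width=0.0)
        assert limit_torque(d, 1.5, 2.0) == pytest.approx(-2.0)


class TestHullInertia:
    def test_unit_cube_analytic(self):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        props = hull_inertia(cube, density=1000.0)
        assert props.mass == pytest.approx(1000.0)
        assert np.allclose(props.com, 0.0, atol=1e-9)
        assert np.allclose(props.inertia, np.eye(3) * 1000.0 / 6.0, atol=1e-6)

    def test_translation_invariance(self):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        moved = cube.copy()
        moved.apply_translation([1.0, 2.0, 3.0])
        p0, p1 = hull_inertia(cube), hull_inertia(moved)
        assert p1.mass == pytest.approx(p0.mass)
        assert np.allclose(p1.com - p0.com, [1, 2, 3], atol=1e-9)
        assert np.allclose(p1.inertia, p0.inertia, atol=1e-6)

    def test_rotation_conjugates_inertia(self, rng):
        box = trimesh.creation.box(extents=(0.2, 0.5, 1.1))
        R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        rotated = box.copy()
        T = np.eye(4)
        T[:3, :3] = R
        rotated.apply_transform(T)
        I0 = hull_inertia(box).inertia
        I1 = hull_inertia(rotated).inertia
        assert np.allclose(I1, R @ I0 @ R.T, rtol=1e-9, atol=1e-12)

    def test_random_tetrahedron_vs_monte_carlo(self, rng):
        verts = rng.uniform(-1.0, 1.0, (4, 3))
        faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
        tet = trimesh.Trimesh(vertices=verts, faces=faces)
        tet.fix_normals()
        props = hull_inertia(tet, density=1000.0)
        # rejection-sampling oracle over the bounding box
        from scipy.spatial import Delaunay

        lo, hi = verts.min(axis=0), verts.max(axis=0)
        pts = rng.uniform(lo, hi, (1_000_000, 3))
        inside = Delaunay(verts).find_simplex(pts) >= 0
        vol_mc = inside.mean() * np.prod(hi - lo)
        assert props.mass == pytest.approx(1000.0 * vol_mc, rel=5e-3)
        com_mc = pts[inside].mean(axis=0)
        assert np.allclose(props.com, com_mc, atol=5e-3 * np.linalg.norm(hi - lo))

    def test_open_mesh_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        one_face = trimesh.Trimesh(vertices=verts, faces=[[0, 1, 2]])
        with pytest.raises(MeshIntegrityError):
            hull_inertia(one_face, density=1000.0)
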