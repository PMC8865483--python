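"""Polyline path geometry: lengths, moment arms, crossings, moments."""

import math

import numpy as np
import pytest

from mousemsk.fixtures import pendulum_fixture
from mousemsk.model_io import parse_model
from mousemsk.muscle import MuscleParams
from mousemsk.paths import (
    AttachmentPoint,
    MusclePath,
    NoCrossingError,
    crossing_segment,
    joint_moment,
    moment_arm,
    muscle_tendon_length,
)
from mousemsk.skeleton import Pose


def straight_path(points, muscle="m"):
    roles = ["origin"] + ["waypoint"] * (len(points) - 2) + ["insertion"]
    return MusclePath(
        muscle,
        tuple(
            AttachmentPoint(seg, tuple(xyz), role)
            for (seg, xyz), role in zip(points, roles)
        ),
    )


class TestMuscleTendonLength:
    def test_straight_single_segment(self, pendulum):
        path = straight_path([("parent", (0, 0, 0)), ("parent", (0, 0, 5))])
        assert muscle_tendon_length(pendulum.model, Pose(), path) == pytest.approx(5.0)

    def test_collinear_waypoint_preserves_length(self, pendulum):
        path = straight_path(
            [("parent", (0, 0, 0)), ("parent", (0, 0, 2.5)), ("parent", (0, 0, 5))]
        )
        assert muscle_tendon_length(pendulum.model, Pose(), path) == pytest.approx(5.0)

    def test_pendulum_law_of_cosines(self, pendulum):
        th = math.radians(90.0)
        lmt = muscle_tendon_length(pendulum.model, Pose({"theta": th}), pendulum.path)
        assert lmt == pytest.approx(math.sqrt(200.0), rel=1e-12)
        assert lmt == pytest.approx(14.1421, abs=5e-5)

    def test_matches_reference_across_rom(self, pendulum):
        for th in np.linspace(math.radians(1), math.radians(179), 100):
            lmt = muscle_tendon_length(
                pendulum.model, Pose({"theta": th}), pendulum.path
            )
            assert lmt == pytest.approx(pendulum.lmt_ref(th), abs=1e-12)

    def test_lower_bounded_by_endpoint_distance(self, chain, rng):
        from mousemsk.skeleton import segment_point_world

        path = chain.path
        for _ in range(20):
            pose = Pose({"q1": rng.uniform(-1, 1), "q2": rng.uniform(-1, 1)})
            lmt = muscle_tendon_length(chain.model, pose, path)
            p0 = segment_point_world(
                chain.model, pose, path.points[0].segment,
                path.points[0].local_position,
            )
            p1 = segment_point_world(
                chain.model, pose, path.points[-1].segment,
                path.points[-1].local_position,
            )
            assert lmt >= np.linalg.norm(p1 - p0) - 1e-12

    def test_unknown_segment_raises(self, pendulum):
        path = straight_path([("parent", (0, 0, 0)), ("ghost", (1, 1, 1))])
        with pytest.raises(KeyError, match="ghost"):
            muscle_tendon_length(pendulum.model, Pose(), path)


class TestMomentArm:
    def test_non_spanning_path_zero(self, pendulum):
        path = straight_path([("parent", (0, 0, 0)), ("parent", (5, 0, 0))])
        r = moment_arm(pendulum.model, Pose({"theta": 0.7}), pendulum.path, "theta")
        r0 = moment_arm(pendulum.model, Pose({"theta": 0.7}), path, "theta")
        assert abs(r0) < 1e-12 and abs(r) > 1.0

    def test_matches_analytic_derivative(self, pendulum):
        for th in np.linspace(math.radians(5), math.radians(175), 60):
            r = moment_arm(pendulum.model, Pose({"theta": th}), pendulum.path, "theta")
            assert r == pytest.approx(pendulum.r_ref(th), rel=1e-6)

    def test_second_order_convergence(self, pendulum):
        th = math.radians(70.0)
        exact = pendulum.r_ref(th)
        errs = [
            abs(
                moment_arm(
                    pendulum.model, Pose({"theta": th}), pendulum.path, "theta",
                    step=d,
                )
                - exact
            )
            for d in (4e-3, 2e-3, 1e-3)
        ]
        # halving the step divides the error by ~4
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.15)

    def test_through_rotation_center_zero_lever(self):
        fx = pendulum_fixture(10.0, 10.0)
        path = straight_path(
            [("parent", (-10, 0, 0)), ("child", (0, 0, 0))], "to_center"
        )
        r = moment_arm(fx.model, Pose({"theta": 1.0}), path, "theta")
        assert abs(r) < 1e-9

    def test_invariant_to_collinear_waypoint(self, pendulum):
        # waypoint placed on the origin-insertion line at this pose
        th = math.radians(120.0)
        mid = (
            (-10.0 + 10.0 * math.cos(th)) / 2.0,
            (10.0 * math.sin(th)) / 2.0,
            0.0,
        )
        path = straight_path(
            [("parent", (-10, 0, 0)), ("parent", mid), ("child", (10, 0, 0))]
        )
        # small step: the invariance is exact for the true derivative, so the
        # residual is only finite-difference truncation
        r2 = moment_arm(
            pendulum.model, Pose({"theta": th}), pendulum.path, "theta", step=1e-5
        )
        r3 = moment_arm(pendulum.model, Pose({"theta": th}), path, "theta", step=1e-5)
        assert r3 == pytest.approx(r2, abs=1e-9)

    def test_sign_convention_resists_positive_rotation(self, pendulum):
        # lmt shrinks as theta grows from straight: r < 0 throughout (0, pi)
        for th in (0.3, 1.5, 2.8):
            assert moment_arm(
                pendulum.model, Pose({"theta": th}), pendulum.path, "theta"
            ) < 0

    def test_unknown_dof_raises(self, pendulum):
        with pytest.raises(KeyError):
            moment_arm(pendulum.model, Pose(), pendulum.path, "nope")


class TestCrossingSegment:
    def test_two_point_muscle(self, pendulum):
        p_wo, p_wi = crossing_segment(pendulum.model, pendulum.path, "theta")
        assert p_wo.segment == "parent" and p_wo.role == "origin"
        assert p_wi.segment == "child" and p_wi.role == "insertion"

    def test_knee_extensor_style_path(self):
        """Waypointed path: only the waypoint pair bridging the joint crosses."""
        fx = pendulum_fixture(10.0, 10.0)
        path = straight_path(
            [
                ("parent", (-10, 1, 0)),
                ("parent", (-4, 1, 0)),  # P_WO
                ("child", (4, 1, 0)),  # P_WI
                ("child", (10, 1, 0)),
            ]
        )
        p_wo, p_wi = crossing_segment(fx.model, path, "theta")
        assert p_wo.local_position == (-4, 1, 0)
        assert p_wi.local_position == (4, 1, 0)

    def test_brute_force_distance_scan_agrees(self, chain):
        """Oracle: perturb each DoF and find the one inter-point distance
        that changes; it must be the returned crossing pair."""
        from mousemsk.paths import _world_points

        for dof in ("q1", "q2"):
            p_wo, p_wi = crossing_segment(chain.model, chain.path, dof)
            base = _world_points(chain.model, Pose(), chain.path)
            pert = _world_points(chain.model, Pose({dof: 0.2}), chain.path)
            d0 = np.linalg.norm(np.diff(base, axis=0), axis=1)
            d1 = np.linalg.norm(np.diff(pert, axis=0), axis=1)
            changed = np.flatnonzero(np.abs(d1 - d0) > 1e-9)
            assert len(changed) == 1
            i = changed[0]
            assert chain.path.points[i] == p_wo
            assert chain.path.points[i + 1] == p_wi

    def test_no_crossing_raises(self, pendulum):
        path = straight_path([("parent", (0, 0, 0)), ("parent", (5, 0, 0))])
        with pytest.raises(NoCrossingError):
            crossing_segment(pendulum.model, path, "theta")


class TestJointMoment:
    def test_product_contract(self, pendulum):
        th = math.radians(90.0)
        pose = Pose({"theta": th})
        r = moment_arm(pendulum.model, pose, pendulum.path, "theta")
        from mousemsk.muscle import muscle_force

        lmt = muscle_tendon_length(pendulum.model, pose, pendulum.path)
        f = muscle_force(pendulum.params, 1.0, lmt)
        tau = joint_moment(pendulum.model, pose, pendulum.path, pendulum.params, "theta")
        assert tau == pytest.approx(r * f, rel=1e-12)

    def test_zero_activation_short_fiber_no_moment(self, pendulum):
        # fold far enough that l~m < 1: no active, no passive force
        pose = Pose({"theta": math.radians(150.0)})
        tau = joint_moment(
            pendulum.model, pose, pendulum.path, pendulum.params, "theta",
            activation=0.0,
        )
        assert tau == 0.0

    def test_moment_linear_in_f_max(self, pendulum):
        pose = Pose({"theta": math.radians(60.0)})
        p2 = MuscleParams(
            name="m2", f_max=2 * pendulum.params.f_max,
            l_opt=pendulum.params.l_opt, l_slack=pendulum.params.l_slack,
        )
        t1 = joint_moment(pendulum.model, pose, pendulum.path, pendulum.params, "theta")
        t2 = joint_moment(pendulum.model, pose, pendulum.path, p2, "theta")
        assert t2 == pytest.approx(2.0 * t1, rel=1e-12)
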