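"""Loop-closure residuals, Newton solving, continuation sweeps, and the
1-D grid-search oracle."""

import numpy as np
import pytest

import myograsp as mg
from myograsp.errors import NoSolutionError
from myograsp.kinematics import (
    FingerPose,
    LinkageGeometry,
    construct_consistent_pose,
    loop_residual,
    make_reference_geometry,
    reference_sweep_range,
    solve_pose,
    sweep_trajectory,
)

FREE = dict(r1=35.0, r2=8.0, r3=42.0, r4=25.0, r5=26.0, r7=12.5,
            delta=np.radians(4.0), beta=np.radians(26.0),
            theta2=np.radians(177.0))
NOMINAL = dict(theta1=np.radians(-50.0), theta3=np.radians(-128.0),
               theta4=np.radians(-25.0))


def grid_oracle(geom, theta1, n_grid=40_000):
    """Independent solver: reduce the four closure equations to one
    scalar equation in theta3 via closed-form two-link geometry, then
    dense grid search + bisection.

    Returns the list of (theta3, theta4, theta5, theta7) roots.
    """
    t2 = geom.theta2

    def branch_angles(theta3, elbow):
        c1 = (geom.r3 * np.array([np.cos(theta1), np.sin(theta1)])
              + geom.r5 * np.array([np.cos(theta3), np.sin(theta3)]))
        L = np.linalg.norm(c1)
        cos_a = (geom.r4**2 + L**2 - geom.r6**2) / (2 * geom.r4 * L)
        if not -1 <= cos_a <= 1:
            return None
        phi = np.arctan2(c1[1], c1[0])
        t4a = phi + elbow * np.arccos(cos_a)
        v6 = c1 - geom.r4 * np.array([np.cos(t4a), np.sin(t4a)])
        t5 = np.arctan2(v6[1], v6[0])
        t4 = t4a - geom.delta
        return t4, t5

    def g(theta3, elbow):
        ang = branch_angles(theta3, elbow)
        if ang is None:
            return np.nan
        t4, t5 = ang
        c2 = (geom.r1 * np.array([np.cos(t2), np.sin(t2)])
              + geom.r2 * np.array([np.cos(t4), np.sin(t4)])
              + geom.r7 * np.array([np.cos(t5 + geom.beta), np.sin(t5 + geom.beta)])
              - geom.r3 * np.array([np.cos(theta1), np.sin(theta1)])
              - geom.r5 * np.array([np.cos(theta3), np.sin(theta3)]))
        return np.linalg.norm(c2) - geom.r8

    roots = []
    grid = np.linspace(-np.pi, np.pi, n_grid)
    for elbow in (+1, -1):
        vals = np.array([g(t, elbow) for t in grid])
        for i in range(len(grid) - 1):
            a, b = vals[i], vals[i + 1]
            if np.isnan(a) or np.isnan(b) or a * b > 0:
                continue
            lo, hi = grid[i], grid[i + 1]
            for _ in range(60):  # bisection
                midp = 0.5 * (lo + hi)
                if g(lo, elbow) * g(midp, elbow) <= 0:
                    hi = midp
                else:
                    lo = midp
            t3 = 0.5 * (lo + hi)
            t4, t5 = branch_angles(t3, elbow)
            c2 = (geom.r3 * np.array([np.cos(theta1), np.sin(theta1)])
                  + geom.r5 * np.array([np.cos(t3), np.sin(t3)]))
            w = (geom.r1 * np.array([np.cos(t2), np.sin(t2)])
                 + geom.r2 * np.array([np.cos(t4), np.sin(t4)])
                 + geom.r7 * np.array([np.cos(t5 + geom.beta),
                                       np.sin(t5 + geom.beta)]) - c2)
            t7 = np.arctan2(w[1], w[0])
            roots.append((t3, t4, t5, t7))
    return roots


class TestLoopResidual:
    def test_constructed_pose_closes(self):
        _, pose = construct_consistent_pose(FREE, **NOMINAL)
        assert pose.residual < 1e-12

    def test_perturbed_pose_violates_closure(self):
        geom, pose = construct_consistent_pose(FREE, **NOMINAL)
        theta = dict(pose.theta)
        theta["theta5"] += 0.1
        bad = FingerPose(theta=theta)
        assert np.linalg.norm(loop_residual(geom, bad)) > 1e-3

    def test_parallelogram_subloop_symmetry(self):
        """With r4 = r3, r6 = r5 and theta4a = theta1, the first loop is a
        parallelogram: theta5 = theta3 closes it exactly."""
        geom = LinkageGeometry(r1=30, r2=10, r3=40, r4=40, r5=25, r6=25,
                               r7=10, r8=20, delta=0.0)
        t1, t3 = 0.3, -0.8
        theta = {"theta1": t1, "theta2": geom.theta2, "theta3": t3,
                 "theta4": t1, "theta5": t3, "theta6": 0.0, "theta7": 0.0}
        res = loop_residual(geom, FingerPose(theta=theta))
        assert abs(res[0]) < 1e-12 and abs(res[1]) < 1e-12


class TestSolvePose:
    def test_fixed_point_of_solved_input(self):
        geom, pose = construct_consistent_pose(FREE, **NOMINAL)
        again = solve_pose(geom, pose.theta["theta1"], pose)
        for name in ("theta3", "theta4", "theta5", "theta7"):
            assert again.theta[name] == pytest.approx(pose.theta[name], abs=1e-10)

    def test_residual_postcondition(self):
        geom, pose = construct_consistent_pose(FREE, **NOMINAL)
        for dv in np.radians([-20, -5, 5, 20]):
            solved = solve_pose(geom, pose.theta["theta1"] + dv, pose)
            assert solved.residual < 1e-10

    def test_unassemblable_raises(self):
        # r4 + r6 < |r3 - r5|: the first loop's two-link pair can never
        # reach the phalanx chain, so no driven value is assemblable
        geom, pose = construct_consistent_pose(FREE, **NOMINAL)
        broken = LinkageGeometry(
            r1=geom.r1, r2=geom.r2, r3=geom.r3, r4=5.0, r5=geom.r5, r6=5.0,
            r7=geom.r7, r8=geom.r8, delta=geom.delta, beta=geom.beta,
            theta2=geom.theta2)
        with pytest.raises(NoSolutionError):
            solve_pose(broken, pose.theta["theta1"], pose)

    def test_matches_grid_search_oracle(self):
        geom, pose = construct_consistent_pose(FREE, **NOMINAL)
        for dv in np.radians([-15.0, 0.0, 10.0]):
            t1 = pose.theta["theta1"] + dv
            solved = solve_pose(geom, t1, pose)
            roots = grid_oracle(geom, t1)
            best = min(
                max(abs(np.angle(np.exp(1j * (r[i] - solved.theta[n]))))
                    for i, n in enumerate(("theta3", "theta4", "theta5", "theta7")))
                for r in roots)
            assert best < 1e-3

    def test_similarity_invariance(self):
        """Scaling every link length leaves all solved angles unchanged."""
        geom, pose = construct_consistent_pose(FREE, **NOMINAL)
        scaled = LinkageGeometry(
            **{n: 2.5 * getattr(geom, n) for n in
               ("r1", "r2", "r3", "r4", "r5", "r6", "r7", "r8")},
            delta=geom.delta, beta=geom.beta, theta2=geom.theta2)
        t1 = pose.theta["theta1"] + np.radians(8.0)
        a = solve_pose(geom, t1, pose)
        b = solve_pose(scaled, t1, pose)
        for name in ("theta3", "theta4", "theta5", "theta7"):
            assert a.theta[name] == pytest.approx(b.theta[name], abs=1e-9)


class TestSweep:
    def test_constant_range_constant_trajectory(self):
        geom, pose = construct_consistent_pose(FREE, **NOMINAL)
        t1 = pose.theta["theta1"]
        res = sweep_trajectory(geom, [t1] * 5, pose)
        assert len(res) == 5
        tips = {p.fingertip for p in res}
        assert len(tips) == 1

    def test_reference_sweep_full_and_tight(self, reference_finger):
        geom, pose = reference_finger
        res = sweep_trajectory(geom, reference_sweep_range(101), pose)
        assert len(res) == 101 and res.failed_at is None
        assert max(p.residual for p in res) < 1e-10

    def test_forward_backward_agreement(self, reference_finger):
        geom, pose = reference_finger
        rng = reference_sweep_range(51)
        fwd = sweep_trajectory(geom, rng, pose)
        bwd = sweep_trajectory(geom, rng[::-1], fwd.poses[-1])
        for f, b in zip(fwd.poses, bwd.poses[::-1]):
            for name in ("theta3", "theta4", "theta5", "theta7"):
                assert f.theta[name] == pytest.approx(b.theta[name], abs=1e-8)

    def test_fingertip_path_continuous(self, reference_finger):
        geom, pose = reference_finger
        res = sweep_trajectory(geom, reference_sweep_range(101), pose)
        tips = np.array([p.fingertip for p in res])
        steps = np.linalg.norm(np.diff(tips, axis=0), axis=1)
        driven_step = np.diff(reference_sweep_range(101))[0]
        bound = 10 * driven_step * geom.lengths.max()
        assert steps.max() < bound

    def test_proximal_excursion_matches_configured_limit(self, reference_finger):
        geom, pose = reference_finger
        df = sweep_trajectory(geom, reference_sweep_range(101), pose).to_frame()
        excursion = df["theta1_deg"].max() - df["theta1_deg"].min()
        assert excursion == pytest.approx(geom.proximal_limit_deg, abs=1.0)

    def test_partial_trajectory_on_unassemblable_range(self):
        geom, pose = construct_consistent_pose(FREE, **NOMINAL)
        rng = pose.theta["theta1"] + np.radians(np.arange(0, 200, 5.0))
        res = sweep_trajectory(geom, rng, pose)
        assert res.failed_at is not None and 0 < len(res) < len(rng)


class TestGeometryIO:
    def test_round_trip(self, tmp_path, reference_finger):
        geom, _ = reference_finger
        path = tmp_path / "finger.json"
        geom.save(path)
        loaded = LinkageGeometry.load(path)
        for name in ("r1", "r2", "r3", "r4", "r5", "r6", "r7", "r8"):
            assert getattr(loaded, name) == getattr(geom, name)
        for name in ("delta", "beta", "theta2"):
            assert getattr(loaded, name) == pytest.approx(getattr(geom, name),
                                                          abs=1e-12)
        assert loaded.driven == geom.driven

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            LinkageGeometry(r1=0, r2=1, r3=1, r4=1, r5=1, r6=1, r7=1, r8=1)
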