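"""Planar loop-closure kinematics of an underactuated linkage finger.

The finger is a compliant linkage with one actuated degree of freedom:
eight link vectors r1..r8 form two closed loops,

    loop A:  r4 + r6 = r3 + r5
    loop B:  r1 + r2 + r7 = r3 + r5 + r8,

where each link vector has a fixed length and an orientation angle.
Under the convention used throughout this module (x rightward, y upward,
angles measured counter-clockwise from +x) the link orientations are

    r1 -> theta2 (frame/actuator link, fixed)     r5 -> theta3
    r2 -> theta4                                  r6 -> theta5
    r3 -> theta1 (proximal phalanx, driven)       r7 -> theta5 + beta
    r4 -> theta4 + delta                          r8 -> theta7 (tip link)

delta and beta are constant angular offsets between rigidly coupled
links.  Writing each loop in x and y components yields four scalar
closure equations; with one angle driven (default theta1, mapped from
the 10 mm actuator stroke) and theta2 fixed to the frame, the remaining
four angles (theta3, theta4, theta5, theta7) are solved by Newton
iteration with the analytic Jacobian.  theta6 is reserved for the
passive distal coupling and takes no part in the closure.

The fingertip is located by forward chaining along the phalanges:
tip = r3 e(theta1) + r5 e(theta3) + r8 e(theta7).

Because the hand's true link dimensions are proprietary, the module
ships a *reference geometry* constructed so that a full-stroke sweep of
the driven angle spans a realistic proximal-joint excursion (84.5 deg by
default); it is illustrative, not a measured mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import NoSolutionError, SingularConfigurationError

ANGLE_NAMES = ("theta1", "theta2", "theta3", "theta4", "theta5", "theta6", "theta7")
LOOP_ANGLES = ("theta1", "theta3", "theta4", "theta5", "theta7")
SOLVER_TOL = 1e-12     # Newton convergence on the residual norm (mm)
POSE_TOL = 1e-10       # every returned pose satisfies ||residual|| < this
MAX_ITER = 100


@dataclass(frozen=True)
class LinkageGeometry:
    """Link lengths (mm), constant offsets (rad), and joint limits (deg)."""

    r1: float
    r2: float
    r3: float
    r4: float
    r5: float
    r6: float
    r7: float
    r8: float
    delta: float = 0.0            # theta4a = theta4 + delta
    beta: float = 0.0             # theta5a = theta5 + beta
    theta2: float = 0.0           # fixed frame-link orientation (rad)
    theta6: float = 0.0           # passive/reserved angle (rad)
    driven: str = "theta1"        # the actuated coordinate
    proximal_limit_deg: float = 84.5
    distal_limit_deg: float = 135.0

    def __post_init__(self):
        for name in ("r1", "r2", "r3", "r4", "r5", "r6", "r7", "r8"):
            if getattr(self, name) <= 0:
                raise ValueError(f"link length {name} must be > 0")
        for lim in (self.proximal_limit_deg, self.distal_limit_deg):
            if not 0 < lim < 180:
                raise ValueError("joint limits must lie in (0, 180) degrees")
        if self.driven not in LOOP_ANGLES:
            raise ValueError(f"driven must be one of {LOOP_ANGLES}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.r3, self.r4,
                         self.r5, self.r6, self.r7, self.r8])

    def unknown_angles(self) -> tuple:
        return tuple(a for a in LOOP_ANGLES if a != self.driven)

    # -- serialization (lengths mm, angles degrees in the file) -------
    def to_dict(self) -> dict:
        return {
            **{n: getattr(self, n) for n in
               ("r1", "r2", "r3", "r4", "r5", "r6", "r7", "r8")},
            "delta_deg": np.degrees(self.delta),
            "beta_deg": np.degrees(self.beta),
            "theta2_deg": np.degrees(self.theta2),
            "theta6_deg": np.degrees(self.theta6),
            "driven": self.driven,
            "proximal_limit_deg": self.proximal_limit_deg,
            "distal_limit_deg": self.distal_limit_deg,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LinkageGeometry":
        kwargs = {n: float(doc[n]) for n in
                  ("r1", "r2", "r3", "r4", "r5", "r6", "r7", "r8")}
        for key, name in (("delta_deg", "delta"), ("beta_deg", "beta"),
                          ("theta2_deg", "theta2"), ("theta6_deg", "theta6")):
            if key in doc:
                kwargs[name] = float(np.radians(float(doc[key])))
        for key in ("driven", "proximal_limit_deg", "distal_limit_deg"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "LinkageGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FingerPose:
    """Solved joint angles (rad), fingertip position (mm), closure error."""

    theta: dict
    fingertip: tuple = (0.0, 0.0)
    residual: float = 0.0
    driven: str = "theta1"

    def angles_deg(self) -> dict:
        return {k: float(np.degrees(v)) for k, v in self.theta.items()}


def _e(angle: float) -> np.ndarray:
    return np.array([np.cos(angle), np.sin(angle)])


def fingertip_position(geom: LinkageGeometry, theta: dict) -> tuple:
    tip = (geom.r3 * _e(theta["theta1"])
           + geom.r5 * _e(theta["theta3"])
           + geom.r8 * _e(theta["theta7"]))
    return (float(tip[0]), float(tip[1]))


def loop_residual(geom: LinkageGeometry, pose: FingerPose) -> np.ndarray:
    """The four scalar closure residuals (mm); zero iff both loops close."""
    th = pose.theta
    t1, t3, t4, t5, t7 = (th["theta1"], th["theta3"], th["theta4"],
                          th["theta5"], th["theta7"])
    t2 = th.get("theta2", geom.theta2)
    t4a = t4 + geom.delta
    t5a = t5 + geom.beta
    g = geom
    return np.array([
        g.r4 * np.cos(t4a) + g.r6 * np.cos(t5) - g.r3 * np.cos(t1) - g.r5 * np.cos(t3),
        g.r4 * np.sin(t4a) + g.r6 * np.sin(t5) - g.r3 * np.sin(t1) - g.r5 * np.sin(t3),
        g.r1 * np.cos(t2) + g.r2 * np.cos(t4) + g.r7 * np.cos(t5a)
        - g.r3 * np.cos(t1) - g.r5 * np.cos(t3) - g.r8 * np.cos(t7),
        g.r1 * np.sin(t2) + g.r2 * np.sin(t4) + g.r7 * np.sin(t5a)
        - g.r3 * np.sin(t1) - g.r5 * np.sin(t3) - g.r8 * np.sin(t7),
    ])


def _jacobian(geom: LinkageGeometry, theta: dict, unknowns: tuple) -> np.ndarray:
    """Analytic Jacobian of the four residuals w.r.t. the unknown angles."""
    g = geom
    t1, t3, t4, t5, t7 = (theta["theta1"], theta["theta3"], theta["theta4"],
                          theta["theta5"], theta["theta7"])
    t4a = t4 + g.delta
    t5a = t5 + g.beta
    cols = {
        "theta1": np.array([g.r3 * np.sin(t1), -g.r3 * np.cos(t1),
                            g.r3 * np.sin(t1), -g.r3 * np.cos(t1)]),
        "theta3": np.array([g.r5 * np.sin(t3), -g.r5 * np.cos(t3),
                            g.r5 * np.sin(t3), -g.r5 * np.cos(t3)]),
        "theta4": np.array([-g.r4 * np.sin(t4a), g.r4 * np.cos(t4a),
                            -g.r2 * np.sin(t4), g.r2 * np.cos(t4)]),
        "theta5": np.array([-g.r6 * np.sin(t5), g.r6 * np.cos(t5),
                            -g.r7 * np.sin(t5a), g.r7 * np.cos(t5a)]),
        "theta7": np.array([0.0, 0.0, g.r8 * np.sin(t7), -g.r8 * np.cos(t7)]),
    }
    return np.column_stack([cols[u] for u in unknowns])


def _complete_pose(geom: LinkageGeometry, theta: dict) -> FingerPose:
    theta = dict(theta)
    theta.setdefault("theta2", geom.theta2)
    theta.setdefault("theta6", geom.theta6)
    pose = FingerPose(theta=theta, driven=geom.driven)
    pose.residual = float(np.linalg.norm(loop_residual(geom, pose)))
    pose.fingertip = fingertip_position(geom, theta)
    return pose


def solve_pose(geom: LinkageGeometry, driven_value: float,
               guess: FingerPose) -> FingerPose:
    """Solve the closure equations for the four unknown angles.

    Newton iteration from ``guess`` (which selects the assembly branch)
    with the analytic Jacobian, to a residual norm below ``POSE_TOL``.

    Raises
    ------
    NoSolutionError
        No convergence within 100 iterations (unassemblable input).
    SingularConfigurationError
        Jacobian singular at an iterate (mechanism dead point).
    """
    unknowns = geom.unknown_angles()
    theta = dict(guess.theta)
    theta[geom.driven] = float(driven_value)
    theta["theta2"] = geom.theta2
    theta["theta6"] = geom.theta6
    for name in unknowns:
        if name not in theta:
            raise ValueError(f"guess must provide an initial {name}")
    for _ in range(MAX_ITER):
        pose = FingerPose(theta=theta, driven=geom.driven)
        f = loop_residual(geom, pose)
        if np.linalg.norm(f) < SOLVER_TOL:
            return _complete_pose(geom, theta)
        J = _jacobian(geom, theta, unknowns)
        if np.linalg.cond(J) > 1e12:
            raise SingularConfigurationError(
                f"Jacobian singular at {geom.driven}={driven_value:.4f} rad"
            )
        step = np.linalg.solve(J, -f)
        # Damp very large steps to stay on the branch of the guess.
        norm = np.linalg.norm(step)
        if norm > 1.0:
            step *= 1.0 / norm
        for name, ds in zip(unknowns, step):
            theta[name] += ds
    pose = FingerPose(theta=theta, driven=geom.driven)
    if np.linalg.norm(loop_residual(geom, pose)) < POSE_TOL:
        return _complete_pose(geom, theta)
    raise NoSolutionError(
        f"no assemblable pose at {geom.driven}={driven_value:.4f} rad "
        f"within {MAX_ITER} iterations"
    )


@dataclass
class SweepResult:
    """Trajectory of solved poses; ``failed_at`` is set on early stop."""

    poses: list = field(default_factory=list)
    failed_at: float | None = None
    message: str = ""

    def __iter__(self):
        return iter(self.poses)

    def __len__(self):
        return len(self.poses)

    def to_frame(self):
        import pandas as pd
        rows = []
        for pose in self.poses:
            row = {"driven": pose.theta[pose.driven]}
            row.update({f"{k}_deg": v for k, v in pose.angles_deg().items()})
            row["tip_x_mm"], row["tip_y_mm"] = pose.fingertip
            row["residual"] = pose.residual
            rows.append(row)
        return pd.DataFrame(rows)


def sweep_trajectory(geom: LinkageGeometry, driven_range,
                     guess: FingerPose) -> SweepResult:
    """Solve a pose at every driven value by continuation.

    Each solved pose seeds the next guess, which keeps the sweep on a
    single assembly branch.  On the first unassemblable point the sweep
    stops, returning the partial trajectory with a diagnostic.
    """
    result = SweepResult()
    current = guess
    for value in np.asarray(driven_range, dtype=float):
        try:
            current = solve_pose(geom, value, current)
        except (NoSolutionError, SingularConfigurationError) as exc:
            result.failed_at = float(value)
            result.message = str(exc)
            break
        result.poses.append(current)
    return result


# ---------------------------------------------------------------------------
# Actuator mapping and the packaged reference geometry.

@dataclass(frozen=True)
class ActuatorMap:
    """Maps linear actuator extension (mm) to the driven angle (rad).

    ``linear`` distributes the angular excursion uniformly over the
    stroke; ``slider_crank`` uses the arcsine relation of a crank of
    radius ``crank_radius_mm`` pushed by the slider.
    """

    stroke_mm: float = 10.0
    angle_start: float = 0.0
    angle_end: float = np.radians(84.5)
    mode: str = "linear"
    crank_radius_mm: float = 12.0

    def angle(self, extension_mm: float) -> float:
        s = np.clip(extension_mm, 0.0, self.stroke_mm)
        if self.mode == "linear":
            frac = s / self.stroke_mm
        elif self.mode == "slider_crank":
            if self.stroke_mm > self.crank_radius_mm:
                raise ValueError("stroke cannot exceed the crank radius")
            span = np.arcsin(self.stroke_mm / self.crank_radius_mm)
            frac = np.arcsin(s / self.crank_radius_mm) / span
        else:
            raise ValueError(f"unknown actuator map mode {self.mode!r}")
        return float(self.angle_start + frac * (self.angle_end - self.angle_start))

    def angles(self, extensions_mm) -> np.ndarray:
        return np.array([self.angle(s) for s in np.asarray(extensions_mm, dtype=float)])


def construct_consistent_pose(geom_free: dict, theta1: float, theta3: float,
                              theta4: float) -> tuple:
    """Build a geometry + pose pair that satisfies closure exactly.

    Given the free link lengths/angles in ``geom_free`` (r1, r2, r3, r4,
    r5, r7, delta, beta, theta2) and three chosen angles, loop A fixes
    r6 and theta5 by vector subtraction, and loop B fixes r8 and theta7.
    The returned ``(geometry, pose)`` closes both loops to rounding
    error, which makes this the natural generator of consistent test
    poses and of the reference geometry.
    """
    g = dict(geom_free)
    t4a = theta4 + g.get("delta", 0.0)
    vA = (g["r3"] * _e(theta1) + g["r5"] * _e(theta3) - g["r4"] * _e(t4a))
    r6 = float(np.linalg.norm(vA))
    theta5 = float(np.arctan2(vA[1], vA[0]))
    t5a = theta5 + g.get("beta", 0.0)
    vB = (g["r1"] * _e(g.get("theta2", 0.0)) + g["r2"] * _e(theta4)
          + g["r7"] * _e(t5a) - g["r3"] * _e(theta1) - g["r5"] * _e(theta3))
    r8 = float(np.linalg.norm(vB))
    theta7 = float(np.arctan2(vB[1], vB[0]))
    geom = LinkageGeometry(
        r1=g["r1"], r2=g["r2"], r3=g["r3"], r4=g["r4"], r5=g["r5"],
        r6=r6, r7=g["r7"], r8=r8,
        delta=g.get("delta", 0.0), beta=g.get("beta", 0.0),
        theta2=g.get("theta2", 0.0),
        driven=g.get("driven", "theta1"),
        proximal_limit_deg=g.get("proximal_limit_deg", 84.5),
        distal_limit_deg=g.get("distal_limit_deg", 135.0),
    )
    theta = {"theta1": theta1, "theta2": geom.theta2, "theta3": theta3,
             "theta4": theta4, "theta5": theta5, "theta6": geom.theta6,
             "theta7": theta7}
    return geom, _complete_pose(geom, theta)


#: Nominal mid-sweep angles of the reference geometry (rad).
_REF_NOMINAL = dict(theta1=np.radians(-50.0), theta3=np.radians(-128.0),
                    theta4=np.radians(-25.0))
_REF_FREE = dict(r1=35.0, r2=8.0, r3=42.0, r4=25.0, r5=26.0, r7=12.5,
                 delta=np.radians(4.0), beta=np.radians(26.0),
                 theta2=np.radians(177.0))


def make_reference_geometry() -> tuple:
    """The packaged illustrative finger geometry and its nominal pose.

    Constructed (not measured): link lengths are plausible for a
    palm-sized finger, and the driven-angle sweep of the full actuator
    stroke spans the configured 84.5 deg proximal excursion.
    """
    return construct_consistent_pose(_REF_FREE, **_REF_NOMINAL)


def reference_sweep_range(n_points: int = 101) -> np.ndarray:
    """Driven-angle range spanning the proximal excursion, centred on the
    reference nominal pose."""
    geom, _ = make_reference_geometry()
    half = np.radians(geom.proximal_limit_deg) / 2.0
    centre = _REF_NOMINAL["theta1"]
    return np.linspace(centre - half, centre + half, n_points)
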