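"""Controlled objects: point mass, muscle-filtered point mass, two-joint planar arm.

All dynamics are deterministic continuous-time derivatives; integration,
noise and feedback live elsewhere.  Conventions: shoulder at the origin,
x rightward, y forward, angles in radians internally (configs may supply
degrees), direction 0 deg along +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PointMassSpec",
    "FilteredPointSpec",
    "PlanarArmSpec",
    "point_mass_derivative",
    "muscle_filter_derivative",
    "muscle_torques",
    "mass_matrix",
    "coriolis_torque",
    "arm_dynamics",
    "arm_state_derivative",
    "arm_state_jacobians",
    "hand_kinematics",
    "inverse_kinematics",
    "apparent_mass",
    "object_iiia",
    "object_iiib",
    "SHADMEHR_FIELD",
    "plant_from_config",
]


class DimensionError(ValueError):
    """Raised when a state or control vector has the wrong shape."""


@dataclass(frozen=True)
class PointMassSpec:
    """Unidimensional inertial point driven directly by force (h(u) = u)."""

    m: float = 1.0

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError(f"mass must be positive, got {self.m}")

    #: (position, velocity)
    state_dim = 2
    control_dim = 1


@dataclass(frozen=True)
class FilteredPointSpec:
    """Point mass actuated through a second-order linear muscle filter.

    The control excites a cascade e -> a with time constant ``tau``;
    force = ``gain * a``.
    """

    m: float = 1.0
    tau: float = 0.04
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError(f"mass must be positive, got {self.m}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")

    #: (position, velocity, activation, excitation)
    state_dim = 4
    control_dim = 1


#: Velocity-dependent force-field matrix (N s/m) from the classic
#: robot-mediated adaptation experiment; force = D @ hand_velocity.
SHADMEHR_FIELD = np.array([[-10.1, -11.2], [-11.2, 11.1]])

#: Default moment-arm matrix (m): columns are shoulder flexor/extensor,
#: elbow flexor/extensor.  Signs give antagonist pairs at each joint.
_DEFAULT_MOMENT_ARMS = np.array(
    [[0.04, -0.04, 0.0, 0.0], [0.0, 0.0, 0.025, -0.025]]
)

_DEFAULT_FMAX = np.array([700.0, 382.0, 572.0, 449.0])


@dataclass(frozen=True)
class PlanarArmSpec:
    """Two-joint (shoulder/elbow) planar arm with 2 antagonist muscle pairs.

    Segment parameters: lengths ``l1, l2`` (m), moments of inertia
    ``I1, I2`` (kg m^2), masses ``m1, m2`` (kg), centre-of-mass distances
    ``c1, c2`` (m).  ``fmax`` (N) are maximal muscle forces (diagonal use),
    ``moment_arms`` (m) is the 2x4 moment-arm matrix, ``tau`` (s) the muscle
    filter time constant and ``field`` an optional velocity-dependent
    force-field matrix (N s/m) acting on the hand.
    """

    l1: float
    l2: float
    I1: float
    I2: float
    m1: float
    m2: float
    c1: float
    c2: float
    fmax: np.ndarray = field(default_factory=lambda: _DEFAULT_FMAX.copy())
    moment_arms: np.ndarray = field(
        default_factory=lambda: _DEFAULT_MOMENT_ARMS.copy()
    )
    tau: float = 0.04
    force_field: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "I1", "I2", "m1", "m2", "c1", "c2", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        fmax = np.asarray(self.fmax, dtype=float)
        if fmax.shape != (4,) or np.any(fmax <= 0):
            raise ValueError("fmax must be 4 positive forces")
        arms = np.asarray(self.moment_arms, dtype=float)
        if arms.shape != (2, 4):
            raise ValueError("moment_arms must be 2x4")
        object.__setattr__(self, "fmax", fmax)
        object.__setattr__(self, "moment_arms", arms)
        if self.force_field is not None:
            ff = np.asarray(self.force_field, dtype=float)
            if ff.shape != (2, 2):
                raise ValueError("force_field must be 2x2")
            object.__setattr__(self, "force_field", ff)
        # inertia-matrix building blocks
        d1 = self.I1 + self.I2 + self.m1 * self.c1**2 + self.m2 * (
            self.l1**2 + self.c2**2
        )
        d2 = self.I2 + self.m2 * self.c2**2
        d3 = self.m2 * self.l1 * self.c2
        object.__setattr__(self, "_d", (d1, d2, d3))
        # torque map T = moment_arms @ diag(fmax)
        object.__setattr__(self, "_R", arms * fmax[None, :])

    #: (theta[2], omega[2], activation[4], excitation[4])
    state_dim = 12
    control_dim = 4


def inertia_matched_moment_arms(
    spec: "PlanarArmSpec",
    theta_ref_deg=(75.0, 75.0),
    torque_scale: float = 120.0,
) -> np.ndarray:
    """Moment arms giving muscle torque capacities aligned with the arm's
    inertia ellipse at a reference posture.

    With G = moment_arms @ diag(fmax), minimum-norm muscle effort for a
    torque tau is tau' (G G')^-1 tau; choosing G G' proportional to
    M(theta_ref) makes the effort of hand movements proportional to the
    direction-dependent apparent endpoint mass, reproducing the observed
    duration/inertia anisotropy.  Columns come in antagonist pairs.
    """
    M = mass_matrix(spec, np.deg2rad(theta_ref_deg))
    lam, V = np.linalg.eigh(M)
    G = np.zeros((2, 4))
    G[:, 0] = torque_scale * np.sqrt(lam[1]) * V[:, 1]
    G[:, 1] = -G[:, 0]
    G[:, 2] = torque_scale * np.sqrt(lam[0]) * V[:, 0]
    G[:, 3] = -G[:, 2]
    return G / np.asarray(spec.fmax)[None, :]


def _matched_arm(theta_ref_deg, force_field=None, **params) -> PlanarArmSpec:
    from dataclasses import replace

    base = PlanarArmSpec(force_field=force_field, **params)
    return replace(
        base,
        moment_arms=inertia_matched_moment_arms(base, theta_ref_deg),
    )


def object_iiia(force_field: Optional[np.ndarray] = None) -> PlanarArmSpec:
    """Arm parameterisation used for target-jump style simulations."""
    return _matched_arm(
        (75.0, 75.0), force_field,
        l1=0.30, l2=0.33, I1=0.025, I2=0.045,
        m1=1.4, m2=1.1, c1=0.11, c2=0.16,
    )


def object_iiib(force_field: Optional[np.ndarray] = None) -> PlanarArmSpec:
    """Arm parameterisation used for force-field simulations."""
    return _matched_arm(
        (15.0, 100.0), force_field,
        l1=0.33, l2=0.34, I1=0.0141, I2=0.0188,
        m1=1.93, m2=1.52, c1=0.165, c2=0.19,
    )


# ---------------------------------------------------------------------------
# point-mass objects
# ---------------------------------------------------------------------------

def point_mass_derivative(
    spec: PointMassSpec, state: np.ndarray, control: np.ndarray
) -> np.ndarray:
    """d/dt (p, v) for the force-driven point: (v, u/m)."""
    state = np.asarray(state, dtype=float)
    control = np.atleast_1d(np.asarray(control, dtype=float))
    if state.shape != (2,):
        raise DimensionError(f"point mass state must be (2,), got {state.shape}")
    if control.shape != (1,):
        raise DimensionError(f"point mass control must be (1,), got {control.shape}")
    return np.array([state[1], control[0] / spec.m])


def muscle_filter_derivative(tau: float, a, e, u):
    """Second-order cascade: de/dt = (u - e)/tau, da/dt = (e - a)/tau."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (a.shape == e.shape == u.shape):
        raise DimensionError("a, e, u must share a shape")
    return (e - a) / tau, (u - e) / tau


def filtered_point_derivative(
    spec: FilteredPointSpec, state: np.ndarray, control: np.ndarray
) -> np.ndarray:
    """d/dt (p, v, a, e) for the muscle-filtered point mass."""
    state = np.asarray(state, dtype=float)
    control = np.atleast_1d(np.asarray(control, dtype=float))
    if state.shape != (4,):
        raise DimensionError(f"state must be (4,), got {state.shape}")
    if control.shape != (1,):
        raise DimensionError(f"control must be (1,), got {control.shape}")
    p, v, a, e = state
    da, de = muscle_filter_derivative(spec.tau, a, e, control[0])
    return np.array([v, spec.gain * a / spec.m, da, de])


# ---------------------------------------------------------------------------
# planar arm
# ---------------------------------------------------------------------------

def mass_matrix(spec: PlanarArmSpec, theta: np.ndarray) -> np.ndarray:
    """Configuration-dependent inertia matrix M(theta), symmetric PD."""
    d1, d2, d3 = spec._d
    c2 = np.cos(np.asarray(theta, dtype=float)[1])
    return np.array(
        [[d1 + 2.0 * d3 * c2, d2 + d3 * c2], [d2 + d3 * c2, d2]]
    )


def coriolis_torque(
    spec: PlanarArmSpec, theta: np.ndarray, omega: np.ndarray
) -> np.ndarray:
    """Velocity-dependent (Coriolis/centripetal) joint torque C(theta, omega) omega."""
    _, _, d3 = spec._d
    s2 = np.sin(np.asarray(theta, dtype=float)[1])
    w1, w2 = np.asarray(omega, dtype=float)
    return d3 * s2 * np.array([-w2 * (2.0 * w1 + w2), w1 * w1])


def muscle_torques(spec: PlanarArmSpec, a: np.ndarray) -> np.ndarray:
    """Joint torques T = moment_arms @ diag(fmax) @ a (linear in a)."""
    a = np.asarray(a, dtype=float)
    if a.shape != (4,):
        raise DimensionError(f"activation must be (4,), got {a.shape}")
    return spec._R @ a


def arm_dynamics(
    spec: PlanarArmSpec,
    theta: np.ndarray,
    omega: np.ndarray,
    torques: np.ndarray,
    field_on: bool = False,
) -> np.ndarray:
    """Joint accelerations M(theta)^-1 (T + W omega - C(theta, omega) omega).

    ``W = J' D J`` maps the Cartesian velocity-dependent field to joint
    space when ``field_on`` (torque = J' F, F = D * hand velocity = D J omega).
    """
    theta = np.asarray(theta, dtype=float)
    omega = np.asarray(omega, dtype=float)
    torques = np.asarray(torques, dtype=float)
    if theta.shape != (2,) or omega.shape != (2,) or torques.shape != (2,):
        raise DimensionError("theta, omega, torques must all be (2,)")
    rhs = torques - coriolis_torque(spec, theta, omega)
    if field_on:
        if spec.force_field is None:
            raise ValueError("field_on=True but spec has no force_field")
        J = hand_jacobian(spec, theta)
        rhs = rhs + J.T @ spec.force_field @ (J @ omega)
    M = mass_matrix(spec, theta)
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    assert det > 0, "inertia matrix must be positive definite"
    return np.array(
        [
            (M[1, 1] * rhs[0] - M[0, 1] * rhs[1]) / det,
            (M[0, 0] * rhs[1] - M[1, 0] * rhs[0]) / det,
        ]
    )


def arm_state_derivative(
    spec: PlanarArmSpec,
    state: np.ndarray,
    control: np.ndarray,
    field_on: bool = False,
) -> np.ndarray:
    """Full 12-dim state derivative: (theta, omega, a, e) under control u.

    Muscle filter is the linear cascade; activations are left unclamped so
    the forward model used for planning matches the simulated plant.
    """
    state = np.asarray(state, dtype=float)
    control = np.asarray(control, dtype=float)
    if state.shape != (12,):
        raise DimensionError(f"arm state must be (12,), got {state.shape}")
    if control.shape != (4,):
        raise DimensionError(f"arm control must be (4,), got {control.shape}")
    theta, omega, a, e = state[:2], state[2:4], state[4:8], state[8:12]
    torques = muscle_torques(spec, a)
    domega = arm_dynamics(spec, theta, omega, torques, field_on=field_on)
    da, de = muscle_filter_derivative(spec.tau, a, e, control)
    return np.concatenate([omega, domega, da, de])


def arm_state_jacobians(
    spec: PlanarArmSpec,
    state: np.ndarray,
    field_on: bool = False,
):
    """Analytic (df/dx, df/du) of :func:`arm_state_derivative`.

    Used by the adjoint pass of the trajectory optimiser; validated against
    finite differences in the test-suite.
    """
    state = np.asarray(state, dtype=float)
    theta, omega, a = state[:2], state[2:4], state[4:8]
    d1, d2, d3 = spec._d
    s2, c2 = np.sin(theta[1]), np.cos(theta[1])
    w1, w2 = omega
    M = mass_matrix(spec, theta)
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    Minv = np.array([[M[1, 1], -M[0, 1]], [-M[1, 0], M[0, 0]]]) / det

    rhs = muscle_torques(spec, a) - coriolis_torque(spec, theta, omega)
    drhs_dth2 = -d3 * c2 * np.array([-w2 * (2.0 * w1 + w2), w1 * w1])
    dM_dth2 = np.array([[-2.0 * d3 * s2, -d3 * s2], [-d3 * s2, 0.0]])
    dc_dw = d3 * s2 * np.array(
        [[-2.0 * w2, -2.0 * (w1 + w2)], [2.0 * w1, 0.0]]
    )
    drhs_dw = -dc_dw
    if field_on and spec.force_field is not None:
        J = hand_jacobian(spec, theta)
        W = J.T @ spec.force_field @ J
        rhs = rhs + W @ omega
        drhs_dw = drhs_dw + W
        dJ_dth1 = _hand_jacobian_dtheta1(spec, theta)
        dJ_dth2 = _hand_jacobian_dtheta2(spec, theta)
        D = spec.force_field
        dW1 = dJ_dth1.T @ D @ J + J.T @ D @ dJ_dth1
        dW2 = dJ_dth2.T @ D @ J + J.T @ D @ dJ_dth2
        drhs_dth1_extra = dW1 @ omega
        drhs_dth2 = drhs_dth2 + dW2 @ omega
    else:
        drhs_dth1_extra = np.zeros(2)

    domega = Minv @ rhs
    # d(M^-1 rhs)/dtheta2 = M^-1 (drhs/dtheta2 - dM/dtheta2 M^-1 rhs)
    ddw_dth2 = Minv @ (drhs_dth2 - dM_dth2 @ domega)
    ddw_dth1 = Minv @ drhs_dth1_extra
    ddw_dw = Minv @ drhs_dw
    ddw_da = Minv @ spec._R

    fx = np.zeros((12, 12))
    fx[0:2, 2:4] = np.eye(2)
    fx[2:4, 0] = ddw_dth1
    fx[2:4, 1] = ddw_dth2
    fx[2:4, 2:4] = ddw_dw
    fx[2:4, 4:8] = ddw_da
    fx[4:8, 4:8] = -np.eye(4) / spec.tau
    fx[4:8, 8:12] = np.eye(4) / spec.tau
    fx[8:12, 8:12] = -np.eye(4) / spec.tau

    fu = np.zeros((12, 4))
    fu[8:12, :] = np.eye(4) / spec.tau
    return fx, fu


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def hand_jacobian(spec: PlanarArmSpec, theta: np.ndarray) -> np.ndarray:
    t1 = theta[0]
    t12 = theta[0] + theta[1]
    return np.array(
        [
            [-spec.l1 * np.sin(t1) - spec.l2 * np.sin(t12), -spec.l2 * np.sin(t12)],
            [spec.l1 * np.cos(t1) + spec.l2 * np.cos(t12), spec.l2 * np.cos(t12)],
        ]
    )


def _hand_jacobian_dtheta1(spec: PlanarArmSpec, theta):
    t1, t12 = theta[0], theta[0] + theta[1]
    return np.array(
        [
            [-spec.l1 * np.cos(t1) - spec.l2 * np.cos(t12), -spec.l2 * np.cos(t12)],
            [-spec.l1 * np.sin(t1) - spec.l2 * np.sin(t12), -spec.l2 * np.sin(t12)],
        ]
    )


def _hand_jacobian_dtheta2(spec: PlanarArmSpec, theta):
    t12 = theta[0] + theta[1]
    return np.array(
        [
            [-spec.l2 * np.cos(t12), -spec.l2 * np.cos(t12)],
            [-spec.l2 * np.sin(t12), -spec.l2 * np.sin(t12)],
        ]
    )


def hand_kinematics(spec: PlanarArmSpec, theta: np.ndarray, omega=None):
    """Forward kinematics: hand position, hand velocity, Jacobian."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (2,):
        raise DimensionError(f"theta must be (2,), got {theta.shape}")
    t1 = theta[0]
    t12 = theta[0] + theta[1]
    pos = np.array(
        [
            spec.l1 * np.cos(t1) + spec.l2 * np.cos(t12),
            spec.l1 * np.sin(t1) + spec.l2 * np.sin(t12),
        ]
    )
    J = hand_jacobian(spec, theta)
    vel = J @ np.asarray(omega, dtype=float) if omega is not None else np.zeros(2)
    return pos, vel, J


def inverse_kinematics(
    spec: PlanarArmSpec, hand: np.ndarray, elbow_up: bool = True
) -> np.ndarray:
    """Joint angles reaching a hand position (elbow-up branch by default)."""
    x, y = np.asarray(hand, dtype=float)
    d2 = x * x + y * y
    c2 = (d2 - spec.l1**2 - spec.l2**2) / (2.0 * spec.l1 * spec.l2)
    if not -1.0 <= c2 <= 1.0:
        raise ValueError(f"hand position {hand} out of reach")
    t2 = np.arccos(np.clip(c2, -1.0, 1.0))
    if not elbow_up:
        t2 = -t2
    k1 = spec.l1 + spec.l2 * np.cos(t2)
    k2 = spec.l2 * np.sin(t2)
    t1 = np.arctan2(y, x) - np.arctan2(k2, k1)
    return np.array([t1, t2])


def apparent_mass(
    spec: PlanarArmSpec, theta: np.ndarray, direction: np.ndarray
) -> float:
    """Effective endpoint mass along a unit Cartesian direction.

    1 / (d' (J M^-1 J') d): the scalar inertia the hand presents to a force
    applied along ``direction`` at posture ``theta``.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    J = hand_jacobian(spec, theta)
    M = mass_matrix(spec, theta)
    mobility = J @ np.linalg.solve(M, J.T)
    return 1.0 / float(direction @ mobility @ direction)


# ---------------------------------------------------------------------------
# config plumbing
# ---------------------------------------------------------------------------

_ARM_FACTORIES = {"arm_a": object_iiia, "arm_b": object_iiib}


def plant_from_config(cfg: dict):
    """Build a plant spec from a config mapping.

    ``{"type": "point_mass"|"filtered_point"|"arm_a"|"arm_b"|"arm", ...}``;
    remaining keys override spec fields.  ``force_field: "default"`` selects
    the built-in velocity-dependent field matrix.
    """
    cfg = dict(cfg)
    kind = cfg.pop("type")
    ff = cfg.pop("force_field", None)
    if isinstance(ff, str):
        if ff != "default":
            raise ValueError(f"unknown force_field {ff!r}")
        ff = SHADMEHR_FIELD.copy()
    elif ff is not None:
        ff = np.asarray(ff, dtype=float)
    if kind == "point_mass":
        return PointMassSpec(**cfg)
    if kind == "filtered_point":
        return FilteredPointSpec(**cfg)
    if kind in _ARM_FACTORIES:
        base = _ARM_FACTORIES[kind](force_field=ff)
        if cfg:
            from dataclasses import replace

            return replace(base, **cfg)
        return base
    if kind == "arm":
        return PlanarArmSpec(force_field=ff, **cfg)
    raise ValueError(f"unknown plant type {kind!r}")
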