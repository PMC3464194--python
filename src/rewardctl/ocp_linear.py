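"""Finite-horizon optimal control with discounted effort for linear plants.

The problem: minimise  eps * int_0^T exp(-s/gamma) ||u(s)||^2 ds  subject to
xdot = A x + B u, x(0) = x0, x(T) = xstar.  Pontryagin stationarity gives
u*(s) = -exp(s/gamma) B' lam(s) / (2 eps) with lamdot = -A' lam, so the
boundary problem reduces to a discounted controllability Gramian

    N(T) = int_0^T exp(Ahat s) B B' exp(Ahat' s) ds,   Ahat = A - I/(2 gamma),

parameterised by the terminal costate (the Ahat direction keeps every
exponential stable) and computed with Van Loan block exponentials plus an
incremental recursion for dense time tables.  For the 1-D point mass everything
collapses to scalar closed forms in z = T/gamma, which also yield the
optimal-duration and two-condition identification routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .plants import FilteredPointSpec, PointMassSpec

__all__ = [
    "LTISystem",
    "OptimalTrajectory",
    "NoViableAction",
    "IdentificationError",
    "ConditioningError",
    "discounted_gramian",
    "solve_finite_horizon_linear",
    "objecti_effort",
    "objecti_stationarity",
    "closed_form_duration_objectI",
    "closed_form_utility_objectI",
    "identify_parameters",
    "GramianTable",
]


class NoViableAction(Exception):
    """Every prospective duration yields non-positive utility."""


class IdentificationError(Exception):
    """No (vigor, gamma) pair reproduces the supplied durations."""


class ConditioningError(Exception):
    """Boundary solve is numerically infeasible (horizon too short)."""


# ---------------------------------------------------------------------------
# generic LTI machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LTISystem:
    """Controllable pair (A, B) built from a plant spec or given directly."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        B = np.asarray(self.B, dtype=float)
        if B.ndim == 1:
            B = B[:, None]
        n = A.shape[0]
        if A.shape != (n, n) or B.shape[0] != n:
            raise ValueError("A must be square and B conformable")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        # controllability-matrix rank check (columns normalised so widely
        # scaled dynamics do not defeat the rank tolerance)
        blocks = [B]
        for _ in range(n - 1):
            blocks.append(A @ blocks[-1])
        C = np.hstack(blocks)
        norms = np.linalg.norm(C, axis=0)
        C = C[:, norms > 0] / norms[norms > 0]
        if np.linalg.matrix_rank(C) < n:
            raise ValueError("(A, B) is not controllable")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]

    @classmethod
    def from_point_mass(cls, spec: PointMassSpec) -> "LTISystem":
        return cls(np.array([[0.0, 1.0], [0.0, 0.0]]),
                   np.array([[0.0], [1.0 / spec.m]]))

    @classmethod
    def from_filtered_point(cls, spec: FilteredPointSpec) -> "LTISystem":
        t = spec.tau
        A = np.array(
            [
                [0.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, spec.gain / spec.m, 0.0],
                [0.0, 0.0, -1.0 / t, 1.0 / t],
                [0.0, 0.0, 0.0, -1.0 / t],
            ]
        )
        B = np.array([[0.0], [0.0], [0.0], [1.0 / t]])
        return cls(A, B)


@dataclass
class OptimalTrajectory:
    """Time-gridded optimal state/control path with its discounted effort."""

    time: np.ndarray
    states: np.ndarray
    controls: np.ndarray
    effort: float
    horizon: float
    info: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        n, m = self.states.shape[1], self.controls.shape[1]
        data = {"t": self.time}
        for j in range(n):
            data[f"x{j}"] = self.states[:, j]
        for j in range(m):
            data[f"u{j}"] = self.controls[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _ahat(system: LTISystem, gamma: float) -> np.ndarray:
    return system.A - np.eye(system.n) / (2.0 * gamma)


def _vanloan_gramian(Ah: np.ndarray, Q: np.ndarray, h: float) -> np.ndarray:
    n = Ah.shape[0]
    C = np.zeros((2 * n, 2 * n))
    C[:n, :n] = -Ah
    C[:n, n:] = Q
    C[n:, n:] = Ah.T
    F = expm(C * h)
    return F[n:, n:].T @ F[:n, n:]


def discounted_gramian(system: LTISystem, gamma: float, T: float) -> np.ndarray:
    """N(T) = int_0^T exp(Ahat s) B B' exp(Ahat' s) ds, Ahat = A - I/(2 gamma).

    Van Loan block exponentials over substeps short enough to stay
    well-conditioned, accumulated with
    N(t + h) = N(t) + exp(Ahat t) N(h) exp(Ahat t)'.
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    n = system.n
    if T == 0:
        return np.zeros((n, n))
    Ah = _ahat(system, gamma)
    Q = system.B @ system.B.T
    n_sub = max(1, int(np.ceil(T * np.linalg.norm(Ah, 2) / 0.5)))
    h = T / n_sub
    Nh = _vanloan_gramian(Ah, Q, h)
    if n_sub == 1:
        return Nh
    Eh = expm(Ah * h)
    N = np.zeros((n, n))
    Qt = np.eye(n)
    for _ in range(n_sub):
        N = N + Qt @ Nh @ Qt.T
        Qt = Qt @ Eh
    return N


def _boundary_solve(system, gamma, eps, x0, xstar, T):
    """Solve for the terminal costate.

    Returns (lamT, N, P) with P = expm(A T); the costate along the path is
    lam(s) = exp(A'(T-s)) lamT and u(s) = -exp(s/gamma) B' lam(s) / (2 eps).
    Raises :class:`ConditioningError` when the Gramian solve is unreliable.
    """
    N = discounted_gramian(system, gamma, T)
    P = expm(system.A * T)
    d = P @ np.asarray(x0, dtype=float) - np.asarray(xstar, dtype=float)
    scale = max(np.linalg.norm(d), 1.0)
    try:
        Nd = np.linalg.solve(N, d)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(f"boundary solve failed at T={T}") from exc
    resid = np.linalg.norm(N @ Nd - d)
    if not np.isfinite(Nd).all() or resid > 1e-6 * scale:
        raise ConditioningError(
            f"boundary solve ill-conditioned at T={T} (residual {resid:.3g})"
        )
    lamT = 2.0 * eps * np.exp(-T / gamma) * Nd
    return lamT, N, P


def linear_effort(system, x0, xstar, T, gamma, eps=1.0) -> float:
    """Discounted effort J_u = eps exp(-T/gamma) d' N(T)^-1 d of the
    optimal finite-horizon connection (d = exp(AT) x0 - xstar)."""
    lamT, N, _ = _boundary_solve(system, gamma, eps, x0, xstar, T)
    return float(np.exp(T / gamma) * lamT @ N @ lamT) / (4.0 * eps)


def solve_finite_horizon_linear(
    system: LTISystem,
    x0: np.ndarray,
    xstar: np.ndarray,
    T: float,
    gamma: float,
    eps: float = 1.0,
    n_steps: int = 200,
) -> OptimalTrajectory:
    """Closed-form optimal trajectory between fixed boundary states.

    The state path is evaluated exactly on the grid via the incremental
    Gramian recursion; no ODE integration error is incurred.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if gamma <= 0 or eps <= 0:
        raise ValueError("gamma and eps must be positive")
    x0 = np.asarray(x0, dtype=float)
    xstar = np.asarray(xstar, dtype=float)
    h = T / n_steps
    time = np.linspace(0.0, T, n_steps + 1)

    if np.allclose(x0, xstar, atol=1e-14):
        states = np.tile(x0, (n_steps + 1, 1))
        controls = np.zeros((n_steps + 1, system.m))
        return OptimalTrajectory(time, states, controls, 0.0, T)

    lamT, N, _ = _boundary_solve(system, gamma, eps, x0, xstar, T)
    effort = float(np.exp(T / gamma) * lamT @ N @ lamT) / (4.0 * eps)

    Eh = expm(_ahat(system, gamma) * h)
    Nh = discounted_gramian(system, gamma, h)
    Ph = expm(system.A * h)

    n = system.n
    # R_k = exp(A'(T - t_k)), built backward (stable direction)
    R = np.empty((n_steps + 1, n, n))
    R[n_steps] = np.eye(n)
    PhT = Ph.T
    for i in range(n_steps - 1, -1, -1):
        R[i] = PhT @ R[i + 1]

    states = np.empty((n_steps + 1, n))
    controls = np.empty((n_steps + 1, system.m))
    Nt = np.zeros((n, n))
    Qt = np.eye(n)   # exp(Ahat t)
    Pt = np.eye(n)   # exp(A t)
    for i in range(n_steps + 1):
        t = time[i]
        w = np.exp(t / gamma) / (2.0 * eps)
        states[i] = Pt @ x0 - w * (Nt @ (R[i] @ lamT))
        controls[i] = -w * (system.B.T @ (R[i] @ lamT))
        if i < n_steps:
            Nt = Nt + Qt @ Nh @ Qt.T
            Qt = Qt @ Eh
            Pt = Pt @ Ph
    return OptimalTrajectory(
        time, states, controls, effort, T, info={"lamT": lamT}
    )


# ---------------------------------------------------------------------------
# dense time tables for receding-horizon control
# ---------------------------------------------------------------------------


class GramianTable:
    """Per-index (T = i*dt) Gramians and boundary-solve matrices.

    Backs the receding-horizon controller: evaluating the discounted effort
    or the first control increment at any gridded horizon is a handful of
    small matrix products.
    """

    def __init__(self, system: LTISystem, gamma: float, dt: float,
                 max_T: float = 12.0, max_z: float = 250.0):
        self.system = system
        self.gamma = gamma
        self.dt = dt
        n_idx = max(int(round(min(max_T, max_z * gamma) / dt)), 2)
        n = system.n
        Eh = expm(_ahat(system, gamma) * dt)
        Nh = discounted_gramian(system, gamma, dt)
        Ph = expm(system.A * dt)
        self.P = np.empty((n_idx + 1, n, n))
        self.N = np.empty((n_idx + 1, n, n))
        self.P[0] = np.eye(n)
        self.N[0] = 0.0
        Qt = np.eye(n)
        for i in range(n_idx):
            self.N[i + 1] = self.N[i] + Qt @ Nh @ Qt.T
            Qt = Qt @ Eh
            self.P[i + 1] = self.P[i] @ Ph
        self.n_idx = n_idx
        self._ninv: dict = {}

    def _ninv_at(self, i: int) -> np.ndarray:
        cached = self._ninv.get(i)
        if cached is not None:
            return cached
        try:
            Ninv = np.linalg.inv(self.N[i])
        except np.linalg.LinAlgError as exc:
            raise ConditioningError(f"singular Gramian at index {i}") from exc
        if not np.isfinite(Ninv).all():
            raise ConditioningError(f"singular Gramian at index {i}")
        self._ninv[i] = Ninv
        return Ninv

    def effort(self, i: int, x0: np.ndarray, xstar: np.ndarray,
               eps: float = 1.0) -> float:
        """J_u over horizon i*dt: eps exp(-T/gamma) d' N^-1 d."""
        Ninv = self._ninv_at(i)
        d = self.P[i] @ x0 - xstar
        return eps * np.exp(-i * self.dt / self.gamma) * float(d @ Ninv @ d)

    def first_control(self, i: int, x0: np.ndarray, xstar: np.ndarray) -> np.ndarray:
        """u(0) of the optimal plan over horizon i*dt (eps-independent)."""
        Ninv = self._ninv_at(i)
        d = self.P[i] @ x0 - xstar
        return -np.exp(-i * self.dt / self.gamma) * (
            self.system.B.T @ (self.P[i].T @ (Ninv @ d))
        )


# ---------------------------------------------------------------------------
# 1-D point mass closed forms
# ---------------------------------------------------------------------------

# All scalars below are expressed in z = T/gamma.  The effort of the optimal
# connection of amplitude A (rest to rest) is
#     J_u = eps A^2 expm1(z) / (gamma^3 E(z)),   E(z) = expm1(z)^2 - z^2 e^z,
# and the interior stationarity condition of the utility
#     J(T) = rho r exp(-z) - J_u(T)  reads  m(z) = sqrt(vigor r gamma^3) / A
# with m(z) = e^z (e^z - z - 1) / E(z), strictly decreasing from +inf to 1.


def _E(z: float) -> float:
    if z < 0.02:
        # series: leading orders of expm1^2 - z^2 e^z cancel to z^4/12
        return (z**4 / 12.0 + z**5 / 12.0 + 2.0 * z**6 / 45.0
                + z**7 / 60.0 + 11.0 * z**8 / 2240.0)
    return np.expm1(z) ** 2 - z * z * np.exp(z)


def objecti_stationarity(z: float) -> float:
    """m(z): reward level (in units sqrt(vigor r gamma^3)/A) whose optimal
    duration is exactly z*gamma.  Strictly decreasing, m(0+)=inf, m(inf)=1."""
    if z <= 0:
        return np.inf
    if z > 300.0:  # avoid overflow; divide through by e^{2z}
        ez = np.exp(-z)
        return (1.0 - (z + 1.0) * ez) ** 2 / (1.0 - (z * z + 2.0) * ez + ez * ez)
    return np.exp(z) * (np.expm1(z) - z) / _E(z)


def objecti_effort(T: float, A: float, gamma: float, eps: float = 1.0) -> float:
    """Closed-form discounted effort for the 1-D point mass, rest to rest."""
    if T <= 0:
        raise ValueError("T must be positive")
    z = T / gamma
    if z > 300.0:
        ez = np.exp(-z)
        return eps * A * A * (ez - ez * ez) / (
            gamma**3 * (1.0 - (z * z + 2.0) * ez + ez * ez)
        )
    return eps * A * A * np.expm1(z) / (gamma**3 * _E(z))


def _zstar(c: float) -> float:
    """Invert m(z) = c for c > 1."""
    lo, hi = 1e-12, 1.0
    while objecti_stationarity(hi) > c:
        hi *= 2.0
        if hi > 1e7:
            raise NoViableAction("stationarity unreachable (c ~ 1)")
    return brentq(lambda z: objecti_stationarity(z) - c, lo, hi,
                  xtol=1e-15, rtol=4 * np.finfo(float).eps)


def closed_form_duration_objectI(
    A: float, r: float, vigor: float, gamma: float
) -> float:
    """Optimal movement duration T*(A, r, vigor, gamma) for the point mass.

    Raises :class:`NoViableAction` when the utility is non-positive for
    every duration (vigor * r * gamma^3 <= A^2).
    """
    if A < 0 or r <= 0 or vigor <= 0 or gamma <= 0:
        raise ValueError("require A >= 0 and positive r, vigor, gamma")
    if A == 0.0:
        return 0.0
    c = np.sqrt(vigor * r * gamma**3) / A
    if not c > 1.0:
        raise NoViableAction(
            f"no positive-utility duration (vigor*r*gamma^3={vigor*r*gamma**3:.3g}"
            f" <= A^2={A*A:.3g})"
        )
    return gamma * _zstar(c)


def closed_form_utility_objectI(
    A: float, r: float, vigor: float, gamma: float
) -> Tuple[float, float]:
    """(utility, T*) at the optimal duration; utility is in units of eps
    (i.e. computed with eps = 1, rho = vigor)."""
    if A == 0.0:
        return vigor * r, 0.0
    T = closed_form_duration_objectI(A, r, vigor, gamma)
    z = T / gamma
    return vigor * r * np.exp(-z) - objecti_effort(T, A, gamma), T


def _log_m(z: float) -> float:
    return float(np.log(objecti_stationarity(z)))


def identify_parameters(
    cond1: Tuple[float, float, float],
    cond2: Tuple[float, float, float],
    gamma_bracket: Tuple[float, float] = (1e-3, 1e5),
) -> Tuple[float, float]:
    """Invert two (amplitude, reward, duration) conditions to (vigor, gamma).

    Uses the exact reduction: at an interior optimum
    vigor = A^2 m(T/gamma)^2 / (r gamma^3), so equating the two conditions
    leaves a single monotone root in log(gamma).
    """
    (A1, r1, T1), (A2, r2, T2) = cond1, cond2
    if T1 <= 0 or T2 <= 0:
        raise ValueError("durations must be positive")
    if (A1, r1) == (A2, r2):
        raise ValueError("conditions must differ in (amplitude, reward)")

    def resid(lg: float) -> float:
        g = np.exp(lg)
        return (np.log(A1 * A1 / r1) + 2.0 * _log_m(T1 / g)
                - np.log(A2 * A2 / r2) - 2.0 * _log_m(T2 / g))

    lo, hi = np.log(gamma_bracket[0]), np.log(gamma_bracket[1])
    flo, fhi = resid(lo), resid(hi)
    if not (np.isfinite(flo) and np.isfinite(fhi)) or flo * fhi > 0:
        raise IdentificationError(
            f"no (vigor, gamma) root in bracket for T1={T1:.4g}, T2={T2:.4g}"
        )
    lg = brentq(resid, lo, hi, xtol=1e-14)
    gamma = float(np.exp(lg))
    vigor = A1 * A1 * objecti_stationarity(T1 / gamma) ** 2 / (r1 * gamma**3)
    return float(vigor), gamma
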