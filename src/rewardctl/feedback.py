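"""Closed-loop simulation: receding-horizon controller, delayed Kalman
estimator, signal-dependent motor noise and perturbation events.

At every timestep the controller re-derives the optimal control from the
current state estimate (for the linear plants the whole policy reduces to
cached Gramian tables, so replanning is a few small matrix products; the
emergent-duration search is refreshed on a coarser cadence for cost
control).  Observations are delayed by ``delay_s``; the estimator keeps a
delayed corrected estimate plus a forward prediction through a ring
buffer of commanded controls, so the current estimate is exact in the
zero-noise limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .horizon import InternalParams, TaskParams, golden_section_max
from .ocp_linear import ConditioningError, GramianTable, LTISystem
from .plants import (
    FilteredPointSpec,
    PlanarArmSpec,
    PointMassSpec,
)

__all__ = [
    "NoiseSpec",
    "PerturbationEvent",
    "Trace",
    "TrialOutcome",
    "DelayedKalman",
    "detect_movement_end",
    "first_arrival",
    "simulate_trial",
]


@dataclass(frozen=True)
class NoiseSpec:
    """sdn: multiplicative (signal-dependent) motor noise factor;
    sin: additive observation noise s.d."""

    sdn: float = 0.0
    sin: float = 0.0

    def __post_init__(self) -> None:
        if self.sdn < 0 or self.sin < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass(frozen=True)
class PerturbationEvent:
    """Scheduled mid-trial perturbation.

    ``target_jump`` moves the rewarded state; the controller perceives it
    only one sensory delay after onset.  ``force_field_on`` switches the
    plant's velocity-dependent field on; the controller's internal model
    never includes it.
    """

    time: float
    kind: str  # "target_jump" | "force_field_on"
    xstar: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be non-negative")
        if self.kind not in ("target_jump", "force_field_on"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "target_jump" and self.xstar is None:
            raise ValueError("target_jump requires xstar")


@dataclass
class Trace:
    time: np.ndarray
    states: np.ndarray
    estimates: np.ndarray
    controls: np.ndarray
    speed: np.ndarray
    planned_T: np.ndarray
    utility: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        data = {"t": self.time, "speed": self.speed,
                "planned_T": self.planned_T, "utility": self.utility}
        for j in range(self.states.shape[1]):
            data[f"x{j}"] = self.states[:, j]
            data[f"xhat{j}"] = self.estimates[:, j]
        for j in range(self.controls.shape[1]):
            data[f"u{j}"] = self.controls[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class TrialOutcome:
    duration: float
    endpoint: np.ndarray
    success: bool
    flags: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "endpoint": np.asarray(self.endpoint).tolist(),
            "success": self.success,
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# movement-end detection
# ---------------------------------------------------------------------------


def detect_movement_end(
    time: np.ndarray,
    speed: np.ndarray,
    threshold: float = 0.03,
    hold: float = 0.05,
):
    """Movement duration from the speed profile.

    Duration is the time of the final downward crossing of ``threshold``
    after which the speed stays below it for at least ``hold`` seconds
    (or to the end of the trace); mid-movement dips are thereby skipped.
    Returns (duration, index, moved_flag).
    """
    time = np.asarray(time, dtype=float)
    speed = np.asarray(speed, dtype=float)
    above = speed >= threshold
    if not above.any():
        return 0.0, 0, False
    dt = time[1] - time[0] if len(time) > 1 else hold
    hold_n = max(int(round(hold / dt)), 1)
    below = ~above
    # candidate down-crossings: above at k-1, below at k
    idx = np.flatnonzero(above[:-1] & below[1:]) + 1
    for k in idx[::-1]:
        seg = below[k:min(k + hold_n, len(below))]
        if seg.all():
            return float(time[k]), int(k), True
    # speed still above threshold at the end of the trace
    return float(time[-1]), len(time) - 1, True


def first_arrival(
    time: np.ndarray,
    speed: np.ndarray,
    threshold: float = 0.03,
    hold: float = 0.05,
):
    """First sustained drop of the speed below threshold.

    Companion to :func:`detect_movement_end`: under motor noise the
    controller keeps station-keeping after arrival, which re-converges the
    endpoint; the spread of endpoints at *first* arrival is the quantity
    that carries the speed/accuracy trade-off.  Returns
    (arrival_time, index, moved_flag).
    """
    time = np.asarray(time, dtype=float)
    speed = np.asarray(speed, dtype=float)
    above = speed >= threshold
    if not above.any():
        return 0.0, 0, False
    dt = time[1] - time[0] if len(time) > 1 else hold
    hold_n = max(int(round(hold / dt)), 1)
    below = ~above
    idx = np.flatnonzero(above[:-1] & below[1:]) + 1
    for k in idx:
        if below[k:min(k + hold_n, len(below))].all():
            return float(time[k]), int(k), True
    return float(time[-1]), len(time) - 1, True


# ---------------------------------------------------------------------------
# delayed Kalman estimator (linear plants)
# ---------------------------------------------------------------------------


class DelayedKalman:
    """Kalman filter on delayed observations plus forward re-prediction.

    The corrected estimate refers to time t - delay; the current-time
    estimate is maintained by an exact forward model over the buffered
    commanded controls, with each innovation mapped to the present through
    Ad^delay_steps.  With zero noise and an exact model the current
    estimate converges to the true state.
    """

    def __init__(
        self,
        Ad: np.ndarray,
        Bd: np.ndarray,
        H: np.ndarray,
        x0: np.ndarray,
        delay_steps: int,
        dt: float,
        noise: NoiseSpec,
        gain_override: Optional[np.ndarray] = None,
    ):
        self.Ad, self.Bd, self.H = Ad, Bd, H
        self.dt = dt
        self.noise = noise
        self.delay_steps = delay_steps
        n = Ad.shape[0]
        self.x_delayed = np.asarray(x0, dtype=float).copy()
        self.x_now = np.asarray(x0, dtype=float).copy()
        self.P = np.eye(n) * 1e-8
        self.R = np.eye(H.shape[0]) * max(noise.sin**2, 1e-14)
        self._Ad_delay = np.linalg.matrix_power(Ad, delay_steps)
        self._buffer: List[np.ndarray] = []
        self.gain_override = gain_override

    def _process_noise(self, u: np.ndarray) -> np.ndarray:
        s2 = (self.noise.sdn**2) * float(u @ u)
        n = self.Ad.shape[0]
        return s2 * (self.Bd @ self.Bd.T) + 1e-14 * np.eye(n)

    def step(self, u: np.ndarray, y: Optional[np.ndarray]) -> np.ndarray:
        """Advance one step with commanded control u and (possibly absent)
        delayed observation y = H x(t - delay) + noise; returns the
        current-time estimate."""
        u = np.asarray(u, dtype=float)
        self._buffer.append(u)
        # advance current-time prediction
        self.x_now = self.Ad @ self.x_now + self.Bd @ u
        if len(self._buffer) > self.delay_steps:
            u_old = self._buffer.pop(0)
            self.x_delayed = self.Ad @ self.x_delayed + self.Bd @ u_old
            self.P = self.Ad @ self.P @ self.Ad.T + self._process_noise(u_old)
            if y is not None:
                H = self.H
                if self.gain_override is not None:
                    K = self.gain_override
                else:
                    S = H @ self.P @ H.T + self.R
                    K = self.P @ H.T @ np.linalg.inv(S)
                innov = K @ (y - H @ self.x_delayed)
                self.x_delayed = self.x_delayed + innov
                self.P = (np.eye(len(self.x_now)) - K @ H) @ self.P
                self.P = 0.5 * (self.P + self.P.T)
                self.x_now = self.x_now + self._Ad_delay @ innov
        return self.x_now


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------


def _discrete_lti(system: LTISystem, dt: float):
    n, m = system.n, system.m
    C = np.zeros((n + m, n + m))
    C[:n, :n] = system.A * dt
    C[:n, n:] = system.B * dt
    F = expm(C)
    return F[:n, :n], F[:n, n:]


def _linear_system_for(plant) -> LTISystem:
    if isinstance(plant, PointMassSpec):
        return LTISystem.from_point_mass(plant)
    if isinstance(plant, FilteredPointSpec):
        return LTISystem.from_filtered_point(plant)
    raise TypeError(f"not a linear plant: {type(plant).__name__}")


class _LinearPolicy:
    """Receding-horizon policy over cached Gramian tables.

    The emergent duration is refreshed from scratch on a fixed cadence
    while at least ``correction_floor`` of the plan remains; below that
    the policy commits to the remaining schedule (a re-search would be
    forced above the floor and artificially stretch the end of the
    movement).  Once the plan is spent the policy holds with zero control
    at the goal, or launches a corrective re-search when the estimate has
    drifted — re-planned corrections never use horizons shorter than the
    floor, which prevents a delay-driven limit cycle of high-gain,
    noise-amplifying micro-plans around the target.
    """

    def __init__(self, system, task, internal, dt, bracket, table=None,
                 correction_floor=0.25, min_exec=0.05,
                 goal_pos_tol=5e-3, speed_threshold=0.03):
        self.system = system
        self.internal = internal
        self.xstar = np.asarray(task.xstar, dtype=float)
        self.r = task.r
        self.dt = dt
        self.table = table or GramianTable(system, internal.gamma, dt)
        lo = max(int(round(bracket[0] / dt)), 2)
        hi = min(int(round(bracket[1] / dt)), self.table.n_idx)
        self.idx_bracket = (lo, hi)
        self.i_floor = max(int(round(correction_floor / dt)), lo)
        self.i_min_exec = max(int(round(min_exec / dt)), 2)
        self.goal_pos_tol = goal_pos_tol
        self.speed_threshold = speed_threshold
        self.i_rem = None
        self.utility = None
        self.holding = False

    def objective(self, i: int, xhat: np.ndarray) -> float:
        T = i * self.dt
        reward = self.internal.rho * self.r * np.exp(-T / self.internal.gamma)
        try:
            eff = self.table.effort(i, xhat, self.xstar, self.internal.eps)
        except ConditioningError:
            return -np.inf
        return reward - eff

    def _search(self, xhat, lo):
        hi = self.idx_bracket[1]
        grid = np.unique(np.linspace(lo, hi, 25).astype(int))
        vals = [self.objective(i, xhat) for i in grid]
        k = int(np.argmax(vals))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, len(grid) - 1)]
        f = lambda x: self.objective(int(round(x)), xhat)
        xbest, ubest = golden_section_max(f, a, b, 1.0)
        return max(int(round(xbest)), lo), ubest

    def _settled(self, xhat) -> bool:
        """Tight criterion to enter the hold state: truly stopped at the
        goal (a frictionless plant drifts if held while moving, and
        residual muscle activation keeps pushing it)."""
        quiet = True
        if len(xhat) > 2:
            quiet = np.abs(xhat[2:] - self.xstar[2:]).max() <= 0.01
        return (abs(xhat[0] - self.xstar[0]) <= 0.4 * self.goal_pos_tol
                and abs(xhat[1]) <= 0.01 * self.speed_threshold
                and quiet)

    def _at_goal(self, xhat) -> bool:
        """Loose criterion to remain in the hold state."""
        return (abs(xhat[0] - self.xstar[0]) <= self.goal_pos_tol
                and abs(xhat[1]) <= self.speed_threshold)

    def refresh(self, xhat, force=False):
        """Periodic duration refresh; returns (T, utility)."""
        if force:
            self.holding = False
            self.i_rem, self.utility = self._search(
                xhat, self.idx_bracket[0])
            return self.i_rem * self.dt, self.utility
        if self.holding:
            if not self._at_goal(xhat):
                self.holding = False
                self.i_rem, self.utility = self._search(xhat, self.i_floor)
            return self.i_rem * self.dt, self.utility
        self.i_rem, self.utility = self._search(xhat, self.idx_bracket[0])
        return self.i_rem * self.dt, self.utility

    def control(self, xhat: np.ndarray) -> np.ndarray:
        if self.holding or self.utility is None or not self.utility > 0:
            return np.zeros(self.system.m)
        # horizons shorter than the safety floor would turn estimation
        # error into unbounded corrective gains; receding at the floor
        # still converges to the goal
        i = max(self.i_rem, self.i_min_exec)
        try:
            return self.table.first_control(i, xhat, self.xstar)
        except ConditioningError:
            return np.zeros(self.system.m)

    def tick(self, xhat):
        if self.holding:
            if not self._at_goal(xhat):
                self.holding = False
                self.i_rem, self.utility = self._search(xhat, self.i_floor)
            return
        if self.i_rem > 1:
            self.i_rem -= 1
        if self.i_rem <= self.i_min_exec and self._settled(xhat):
            self.holding = True


def simulate_trial(
    plant,
    task: TaskParams,
    internal: InternalParams,
    noise: NoiseSpec = NoiseSpec(),
    events: Sequence[PerturbationEvent] = (),
    horizon_max: float = 5.0,
    x0: Optional[np.ndarray] = None,
    dt: float = 0.001,
    delay: float = 0.13,
    rng: Optional[np.random.Generator] = None,
    duration_refresh: float = 0.01,
    speed_threshold: float = 0.03,
    bracket=(0.01, 10.0),
    correction_floor: float = 0.25,
    **arm_options,
):
    """Simulate one closed-loop trial; returns (Trace, TrialOutcome).

    Euler-Maruyama integration at ``dt`` with multiplicative motor noise
    and additive observation noise; target jumps reach the controller one
    sensory delay after onset; a force field acts on the plant only.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(plant, PlanarArmSpec):
        from .feedback_arm import simulate_arm_trial

        return simulate_arm_trial(
            plant, task, internal, noise=noise, events=events,
            horizon_max=horizon_max, x0=x0, dt=dt, delay=delay, rng=rng,
            speed_threshold=speed_threshold, **arm_options,
        )
    system = _linear_system_for(plant)
    n, m = system.n, system.m
    if x0 is None:
        x0 = np.zeros(n)
    x0 = np.asarray(x0, dtype=float)
    Ad, Bd = _discrete_lti(system, dt)
    H = np.zeros((2, n))
    H[0, 0] = 1.0
    H[1, 1] = 1.0
    delay_steps = int(round(delay / dt))
    est = DelayedKalman(Ad, Bd, H, x0, delay_steps, dt, noise)
    noisy = noise.sdn > 0 or noise.sin > 0
    policy = _LinearPolicy(system, task, internal, dt, bracket,
                           correction_floor=correction_floor,
                           min_exec=0.25 if noisy else 0.05,
                           speed_threshold=speed_threshold)
    refresh_steps = max(int(round(duration_refresh / dt)), 1)

    jumps = sorted(
        [e for e in events if e.kind == "target_jump"], key=lambda e: e.time
    )
    n_steps = int(round(horizon_max / dt))
    time = np.arange(n_steps + 1) * dt
    X = np.empty((n_steps + 1, n))
    Xh = np.empty((n_steps + 1, n))
    U = np.zeros((n_steps + 1, m))
    Tpl = np.empty(n_steps + 1)
    Util = np.empty(n_steps + 1)
    x = x0.copy()
    X[0] = x
    Xh[0] = x
    x_hist = [x.copy()]
    no_viable = False
    T_cur, u_cur = policy.refresh(x0, force=True)
    Tpl[0], Util[0] = T_cur, u_cur
    for k in range(n_steps):
        t = time[k]
        # delayed perception of target jumps
        while jumps and t >= jumps[0].time + delay - 0.5 * dt:
            policy.xstar = np.asarray(jumps.pop(0).xstar, dtype=float)
            T_cur, u_cur = policy.refresh(Xh[k], force=True)
        if k % refresh_steps == 0:
            T_cur, u_cur = policy.refresh(Xh[k])
        if not u_cur > 0:
            no_viable = True
        u = policy.control(Xh[k])
        U[k] = u
        # plant step; multiplicative noise follows the discrete-time
        # convention u_applied = u + sdn*|u|*xi per step
        xi = rng.standard_normal(m)
        u_applied = u + noise.sdn * np.abs(u) * xi
        x = Ad @ x + Bd @ u_applied
        x_hist.append(x.copy())
        # delayed observation
        y = None
        if k + 1 > delay_steps:
            xd = x_hist[k + 1 - delay_steps]
            y = H @ xd + noise.sin * rng.standard_normal(2)
        xh = est.step(u, y)
        X[k + 1] = x
        Xh[k + 1] = xh
        policy.tick(xh)
        Tpl[k + 1], Util[k + 1] = policy.i_rem * dt, u_cur
    speed = np.abs(X[:, 1])
    trace = Trace(time, X, Xh, U, speed, Tpl, Util)
    dur, idx, moved = detect_movement_end(time, speed, speed_threshold)
    flags = []
    if not moved:
        flags.append("no_movement")
    if no_viable:
        flags.append("no_viable_action")
    if moved and idx == n_steps:
        flags.append("unfinished")
    endpoint = X[idx, 0]
    success = moved and "unfinished" not in flags
    return trace, TrialOutcome(dur, np.atleast_1d(endpoint), success, flags)
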