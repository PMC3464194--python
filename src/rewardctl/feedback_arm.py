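"""Closed-loop control of the planar arm.

The receding-horizon contract is the same as for the linear plants but the
per-step re-solve is iterative, so the loop warm-starts each re-solve from
the previous plan shifted by the elapsed time and refreshes the emergent
duration with a local search (full golden-section searches run at movement
start, whenever a target jump is perceived, and whenever the current plan
runs out while the hand is still away from the goal).
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .horizon import InternalParams, TaskParams
from .ocp_nonlinear import (
    ArmEffortModel,
    _forward,
    _step_jacobians,
    solve_finite_horizon_arm,
)
from .plants import PlanarArmSpec, hand_jacobian, hand_kinematics

__all__ = ["simulate_arm_trial"]


class _ArmPlan:
    def __init__(self, t0: float, u: np.ndarray, dt: float, T: float, w: float):
        self.t0 = t0
        self.u = u
        self.dt = dt
        self.T = T           # horizon measured from t0
        self.penalty = w

    def control_at(self, t: float) -> np.ndarray:
        k = int((t - self.t0) / self.dt)
        if k < 0:
            k = 0
        if k >= len(self.u):
            return np.zeros(4)
        return self.u[k]

    def shifted_init(self, t: float, n_target: int) -> Optional[np.ndarray]:
        k = int(round((t - self.t0) / self.dt))
        if k >= len(self.u):
            return None
        rest = self.u[k:]
        src = np.linspace(0.0, 1.0, len(rest))
        dst = np.linspace(0.0, 1.0, n_target)
        return np.stack([np.interp(dst, src, rest[:, j]) for j in range(4)], axis=1)


def _full_duration_search(spec, x0, xstar, task_r, internal, dt_plan,
                          bracket, step=0.05, tol=5e-3, max_iter=200):
    """Emergent-duration search by an ascending warm-started sweep plus
    golden-section refinement, snapped to the plan grid."""
    from .horizon import DurationResult, golden_section_max

    model = ArmEffortModel(spec, x0, xstar, internal.gamma, dt=dt_plan,
                          max_iter=max_iter)
    grid = np.arange(bracket[0], bracket[1] + 1e-9, step)
    efforts = model.sweep(grid)
    J = (internal.rho * task_r * np.exp(-grid / internal.gamma)
         - internal.eps * efforts)
    k = int(np.argmax(J))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]

    def obj(T):
        try:
            e = model(T)
        except Exception:
            return -np.inf
        return internal.rho * task_r * np.exp(-T / internal.gamma) \
            - internal.eps * e

    Tb, ub = golden_section_max(obj, lo, hi, tol)
    # snap the horizon to the plan grid so every subsequent shifted replan
    # reuses the same transcription step exactly
    T_snap = max(int(round(Tb / dt_plan)), 4) * dt_plan
    traj = model.solve(T_snap)
    utility = (internal.rho * task_r * np.exp(-T_snap / internal.gamma)
               - internal.eps * traj.effort)
    status = "ok" if utility > 0 else "no_viable"
    return DurationResult(T_snap, utility, status), traj


def _usable(traj, tol=3e-3) -> bool:
    """A replanned trajectory is usable if converged or nearly so."""
    it = traj.info["iterate"]
    return it.status in ("converged", "warm_ok") or it.terminal_error < tol


def _hand_speed(spec, state) -> float:
    J = hand_jacobian(spec, state[:2])
    return float(np.linalg.norm(J @ state[2:4]))


class _ArmEKF:
    """Delayed EKF: corrected delayed estimate + forward re-prediction."""

    def __init__(self, spec, x0, delay_steps, dt, noise):
        self.spec = spec
        self.dt = dt
        self.delay_steps = delay_steps
        self.noise = noise
        self.xd = np.asarray(x0, dtype=float).copy()
        self.P = np.eye(12) * 1e-10
        self.H = np.zeros((4, 12))
        self.H[:4, :4] = np.eye(4)
        self.R = np.eye(4) * max(noise.sin**2, 1e-14)
        self._buffer: List[np.ndarray] = []

    def step(self, u, y):
        self._buffer.append(np.asarray(u, dtype=float))
        if len(self._buffer) > self.delay_steps:
            u_old = self._buffer.pop(0)
            F = _step_jacobians(self.spec, self.xd[None, :], self.dt)[0]
            self.xd = _forward(self.spec, self.xd, u_old[None, :], self.dt)[-1]
            q = (self.noise.sdn**2) * float(u_old @ u_old) * self.dt**2
            Q = np.zeros((12, 12))
            Q[8:12, 8:12] = np.eye(4) * (q / self.spec.tau**2 + 1e-14)
            self.P = F @ self.P @ F.T + Q
            if y is not None:
                S = self.H @ self.P @ self.H.T + self.R
                K = self.P @ self.H.T @ np.linalg.inv(S)
                self.xd = self.xd + K @ (y - self.H @ self.xd)
                self.P = (np.eye(12) - K @ self.H) @ self.P
                self.P = 0.5 * (self.P + self.P.T)
        # forward re-prediction through the buffer
        x = self.xd.copy()
        if self._buffer:
            x = _forward(self.spec, x, np.asarray(self._buffer), self.dt)[-1]
        return x


def simulate_arm_trial(
    spec: PlanarArmSpec,
    task: TaskParams,
    internal: InternalParams,
    noise=None,
    events: Sequence = (),
    horizon_max: float = 2.5,
    x0: Optional[np.ndarray] = None,
    dt: float = 0.001,
    delay: float = 0.13,
    rng: Optional[np.random.Generator] = None,
    speed_threshold: float = 0.03,
    dt_plan: float = 0.01,
    replan_interval: float = 0.01,
    duration_refresh: float = 0.02,
    bracket=(0.15, 2.0),
    warm_iter: int = 40,
):
    """Closed-loop arm trial; returns (Trace, TrialOutcome).

    ``task.xstar`` must be the 12-dim rest state at the target posture.
    Events: target jumps carry a new 12-dim goal (perceived after one
    delay); a force-field event switches the plant's field on, invisible
    to the controller's model.
    """
    from .feedback import NoiseSpec, Trace, TrialOutcome, detect_movement_end

    if noise is None:
        noise = NoiseSpec()
    if rng is None:
        rng = np.random.default_rng()
    if x0 is None:
        raise ValueError("x0 (12-dim rest state) is required for the arm")
    x0 = np.asarray(x0, dtype=float)
    noisy = noise.sdn > 0 or noise.sin > 0
    delay_steps = int(round(delay / dt))
    ekf = _ArmEKF(spec, x0, delay_steps, dt, noise) if noisy else None

    xstar_ctrl = np.asarray(task.xstar, dtype=float).copy()
    res, traj = _full_duration_search(
        spec, x0, xstar_ctrl, task.r, internal, dt_plan, bracket
    )
    plan = _ArmPlan(0.0, traj.info["iterate"].u, dt_plan, res.T,
                    traj.info["penalty"])
    cur_util = res.utility

    jumps = sorted([e for e in events if e.kind == "target_jump"],
                   key=lambda e: e.time)
    field_events = [e for e in events if e.kind == "force_field_on"]
    field_start = min((e.time for e in field_events), default=np.inf)

    n_steps = int(round(horizon_max / dt))
    time = np.arange(n_steps + 1) * dt
    X = np.empty((n_steps + 1, 12))
    Xh = np.empty((n_steps + 1, 12))
    U = np.zeros((n_steps + 1, 4))
    Tpl = np.empty(n_steps + 1)
    Util = np.empty(n_steps + 1)
    speed = np.empty(n_steps + 1)
    x = x0.copy()
    X[0] = Xh[0] = x
    speed[0] = _hand_speed(spec, x)
    Tpl[0], Util[0] = res.T, cur_util
    x_hist = [x.copy()]

    replan_steps = max(int(round(replan_interval / dt)), 1)
    refresh_steps = max(int(round(duration_refresh / dt)), 1)
    flags: List[str] = []

    def replan(t_now, xh, T_rem, max_iter=warm_iter, penalty0=None):
        n_grid = max(int(round(T_rem / dt_plan)), 4)
        T_snap = n_grid * dt_plan
        init = plan.shifted_init(t_now, n_grid)
        traj = solve_finite_horizon_arm(
            spec, xh, xstar_ctrl, T_snap, internal.gamma,
            init=init, dt=dt_plan, max_iter=max_iter,
            penalty0=penalty0 or plan.penalty,
        )
        return traj

    for k in range(n_steps):
        t = time[k]
        xh = Xh[k]
        # perceived target jump: fresh full search from the current estimate
        while jumps and t >= jumps[0].time + delay - 0.5 * dt:
            xstar_ctrl = np.asarray(jumps.pop(0).xstar, dtype=float).copy()
            res2, traj2 = _full_duration_search(
                spec, xh, xstar_ctrl, task.r, internal, dt_plan, bracket
            )
            plan = _ArmPlan(t, traj2.info["iterate"].u, dt_plan, res2.T,
                            traj2.info["penalty"])
            cur_util = res2.utility
        T_rem = plan.t0 + plan.T - t
        hand_err = np.linalg.norm(
            hand_kinematics(spec, xh[:2])[0]
            - hand_kinematics(spec, xstar_ctrl[:2])[0]
        )
        # corrective replans never use horizons shorter than this: the
        # emergent duration of a residual correction is bounded below by
        # the effort blow-up of very fast movements, and solving for
        # near-zero horizons amplifies noise instead
        T_floor = max(6 * dt_plan, 0.06)
        if T_rem < 0.5 * dt_plan:
            at_goal = (hand_err <= 0.01
                       and _hand_speed(spec, xh) <= speed_threshold)
            if at_goal:
                # goal attained: hold with zero control until disturbed
                plan = _ArmPlan(t, np.zeros((1, 4)), dt_plan, 0.0,
                                plan.penalty)
            else:
                # plan exhausted but goal not attained: re-decide from here
                res2, traj2 = _full_duration_search(
                    spec, xh, xstar_ctrl, task.r, internal, dt_plan,
                    (T_floor, max(bracket[1], 1.0)), step=0.1,
                )
                plan = _ArmPlan(t, traj2.info["iterate"].u, dt_plan, res2.T,
                                traj2.info["penalty"])
                cur_util = res2.utility
                T_rem = plan.T
        elif k % replan_steps == 0 and k > 0:
            if k % refresh_steps == 0:
                # local refinement of the emergent duration
                delta = max(2 * dt_plan, 0.02)
                best = None
                for Tc in (T_rem - delta, T_rem, T_rem + delta):
                    if Tc < T_floor:
                        continue
                    trj = replan(t, xh, Tc)
                    if not _usable(trj):
                        continue
                    util = (internal.rho * task.r * np.exp(-Tc / internal.gamma)
                            - internal.eps * trj.effort)
                    if best is None or util > best[0]:
                        best = (util, Tc, trj)
                if best is not None:
                    cur_util, T_new, trj = best
                    plan = _ArmPlan(t, trj.info["iterate"].u, dt_plan,
                                    trj.horizon, trj.info["penalty"])
            else:
                trj = replan(t, xh, T_rem)
                if _usable(trj):
                    plan = _ArmPlan(t, trj.info["iterate"].u, dt_plan,
                                    trj.horizon, trj.info["penalty"])
        u = plan.control_at(t) if cur_util > 0 else np.zeros(4)
        U[k] = u
        # plant step (Euler-Maruyama)
        field_on = (t >= field_start) and spec.force_field is not None
        x_next = _forward(spec, x, u[None, :], dt, field_on=field_on)[-1]
        if noise.sdn > 0:
            # discrete-time multiplicative noise on the applied control
            xi = rng.standard_normal(4)
            x_next[8:12] += dt * noise.sdn * np.abs(u) * xi / spec.tau
        x = x_next
        x_hist.append(x.copy())
        if ekf is not None:
            y = None
            if k + 1 >= delay_steps:
                xd = x_hist[k + 1 - delay_steps]
                y = xd[:4] + noise.sin * rng.standard_normal(4)
            xh_next = ekf.step(u, y)
        else:
            xh_next = x
        X[k + 1] = x
        Xh[k + 1] = xh_next
        speed[k + 1] = _hand_speed(spec, x)
        Tpl[k + 1] = plan.t0 + plan.T - time[k + 1]
        Util[k + 1] = cur_util

    trace = Trace(time, X, Xh, U, speed, Tpl, Util)
    dur, idx, moved = detect_movement_end(time, speed, speed_threshold)
    if not np.any(Util > 0):
        flags.append("no_viable_action")
    if not moved:
        flags.append("no_movement")
    if moved and idx == n_steps:
        flags.append("unfinished")
    endpoint = hand_kinematics(spec, X[idx, :2])[0]
    success = moved and "unfinished" not in flags
    return trace, TrialOutcome(dur, endpoint, success, flags)
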