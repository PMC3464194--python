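"""Infinite-horizon objective: discounted reward minus discounted effort.

Given a finite-horizon effort solver for a plant, the objective as a
function of prospective duration is

    J(T) = rho * r * exp(-T/gamma) - eps * Ju(T)

and the emergent movement duration T* is its argmax, located with a
coarse pre-scan plus golden-section refinement (the pre-scan guards the
unimodality assumption of the golden search).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from . import ocp_linear
from .ocp_linear import ConditioningError, LTISystem
from .plants import (
    FilteredPointSpec,
    PlanarArmSpec,
    PointMassSpec,
)

__all__ = [
    "TaskParams",
    "InternalParams",
    "UtilityCurve",
    "DurationResult",
    "make_effort_model",
    "utility_of_duration",
    "optimal_duration",
    "utility_curve",
    "golden_section_max",
]


@dataclass(frozen=True)
class TaskParams:
    """Goal state and the reward attached to reaching it."""

    xstar: np.ndarray
    r: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("reward must be non-negative")
        object.__setattr__(self, "xstar", np.asarray(self.xstar, dtype=float))


@dataclass(frozen=True)
class InternalParams:
    """Subjective valuation of reward (rho), effort (eps) and time (gamma).

    Behaviour depends on rho and eps only through vigor = rho/eps.
    """

    rho: float = 1.0
    eps: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.eps <= 0 or self.gamma <= 0:
            raise ValueError("rho, eps, gamma must all be positive")

    @property
    def vigor(self) -> float:
        return self.rho / self.eps


@dataclass
class DurationResult:
    T: float
    utility: float
    status: str  # "ok" | "no_viable" | "boundary"


@dataclass
class UtilityCurve:
    T: np.ndarray
    reward: np.ndarray
    effort: np.ndarray
    objective: np.ndarray
    Tstar: float
    utility: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"T": self.T, "reward": self.reward,
             "effort": self.effort, "objective": self.objective}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# effort models (unit eps; the eps weight is applied exactly once, below)
# ---------------------------------------------------------------------------


def make_effort_model(
    plant,
    x0: np.ndarray,
    xstar: np.ndarray,
    gamma: float,
    **options,
) -> Callable[[float], float]:
    """Return Ju(T) (computed at eps = 1) for the plant and boundary states.

    For the point objects this is the analytic linear solution; for the
    planar arm it wraps the iterative solver with a warm-start cache so
    that neighbouring durations are cheap.
    """
    x0 = np.asarray(x0, dtype=float)
    xstar = np.asarray(xstar, dtype=float)
    if isinstance(plant, PointMassSpec):
        at_rest = x0[1] == 0.0 and xstar[1] == 0.0
        if at_rest:
            A_amp = abs(xstar[0] - x0[0])
            return lambda T: ocp_linear.objecti_effort(T, A_amp, gamma)
        system = LTISystem.from_point_mass(plant)
        return lambda T: ocp_linear.linear_effort(system, x0, xstar, T, gamma)
    if isinstance(plant, FilteredPointSpec):
        system = LTISystem.from_filtered_point(plant)
        return lambda T: ocp_linear.linear_effort(system, x0, xstar, T, gamma)
    if isinstance(plant, PlanarArmSpec):
        from .ocp_nonlinear import ArmEffortModel

        return ArmEffortModel(plant, x0, xstar, gamma, **options)
    if isinstance(plant, LTISystem):
        return lambda T: ocp_linear.linear_effort(plant, x0, xstar, T, gamma)
    raise TypeError(f"unsupported plant {type(plant).__name__}")


def utility_of_duration(
    plant, x0, task: TaskParams, internal: InternalParams, T: float,
    effort_model: Optional[Callable[[float], float]] = None,
) -> float:
    """rho r exp(-T/gamma) - eps Ju(T) for a single prospective duration."""
    if T < 0:
        raise ValueError("T must be non-negative")
    if effort_model is None:
        effort_model = make_effort_model(plant, x0, task.xstar, internal.gamma)
    reward = internal.rho * task.r * np.exp(-T / internal.gamma)
    if T == 0.0:
        return reward
    return reward - internal.eps * effort_model(T)


# ---------------------------------------------------------------------------
# duration search
# ---------------------------------------------------------------------------

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def golden_section_max(
    f: Callable[[float], float], a: float, b: float, tol: float
) -> Tuple[float, float]:
    """Golden-section maximisation of a unimodal f on [a, b]."""
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    x = 0.5 * (a + b)
    return x, f(x)


def optimal_duration(
    plant,
    x0,
    task: TaskParams,
    internal: InternalParams,
    bracket: Tuple[float, float] = (1e-3, 10.0),
    tol: float = 1e-3,
    n_prescan: int = 25,
    effort_model: Optional[Callable[[float], float]] = None,
) -> DurationResult:
    """Emergent optimal duration: argmax of the discounted objective.

    A coarse scan over the bracket locates the bracketing triple before
    golden-section refinement; if the best scanned value sits on a bracket
    edge the result is flagged ``boundary``.  When the maximal utility is
    non-positive the status is ``no_viable`` (values still returned).
    """
    Tmin, Tmax = bracket
    if not (0 < Tmin < Tmax):
        raise ValueError("invalid bracket")
    if effort_model is None:
        effort_model = make_effort_model(plant, x0, task.xstar, internal.gamma)

    def J(T: float) -> float:
        try:
            return (internal.rho * task.r * np.exp(-T / internal.gamma)
                    - internal.eps * effort_model(T))
        except (ConditioningError, FloatingPointError, OverflowError):
            return -np.inf

    grid = np.linspace(Tmin, Tmax, n_prescan)
    vals = np.array([J(T) for T in grid])
    k = int(np.argmax(vals))
    if k == 0 or k == n_prescan - 1:
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, n_prescan - 1)]
        T, u = golden_section_max(J, lo, hi, tol)
        return DurationResult(T, u, "no_viable" if not u > 0 else "boundary")
    T, u = golden_section_max(J, grid[k - 1], grid[k + 1], tol)
    return DurationResult(T, u, "ok" if u > 0 else "no_viable")


def utility_curve(
    plant, x0, task: TaskParams, internal: InternalParams,
    Ts: Optional[Sequence[float]] = None,
    bracket: Tuple[float, float] = (1e-3, 10.0),
    effort_model: Optional[Callable[[float], float]] = None,
) -> UtilityCurve:
    """Tabulated reward / effort / objective over durations, with argmax."""
    if effort_model is None:
        effort_model = make_effort_model(plant, x0, task.xstar, internal.gamma)
    if Ts is None:
        Ts = np.linspace(bracket[0], bracket[1], 200)
    Ts = np.asarray(Ts, dtype=float)
    reward = internal.rho * task.r * np.exp(-Ts / internal.gamma)
    effort = np.empty_like(Ts)
    for i, T in enumerate(Ts):
        try:
            effort[i] = internal.eps * effort_model(T)
        except (ConditioningError, FloatingPointError, OverflowError):
            effort[i] = np.inf
    obj = reward - effort
    res = optimal_duration(plant, x0, task, internal,
                           bracket=(Ts[0], Ts[-1]),
                           effort_model=effort_model)
    return UtilityCurve(Ts, reward, effort, obj, res.T, res.utility)
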