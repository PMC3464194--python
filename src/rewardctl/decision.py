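"""Utility-based choice: option utilities, indifference points, softmax
choice probabilities, and the synthetic-cohort spatial-discounting pipeline.

An option is a (distance, reward) pair executed by the 1-D point mass;
its utility is the maximal discounted reward-minus-effort over prospective
durations, available in closed form.  Cohorts of synthetic subjects are
sampled from printed duration statistics, their (vigor, discount) pairs
identified from two conditions, and preference-reversal distances derived
from the per-subject utilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .ocp_linear import (
    IdentificationError,
    NoViableAction,
    closed_form_duration_objectI,
    closed_form_utility_objectI,
    identify_parameters,
)

__all__ = [
    "Option",
    "ChoiceModel",
    "CohortSpec",
    "MonkeyParams",
    "StevensResult",
    "option_utility",
    "indifference_point",
    "choice_probability",
    "sample_cohort",
    "identify_cohort",
    "stevens_pipeline",
    "MARMOSET",
    "TAMARIN",
    "STEVENS_GRID",
]


@dataclass(frozen=True)
class Option:
    """A reward r at travel distance A (m)."""

    A: float
    r: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.r < 0:
            raise ValueError("distance and reward must be non-negative")


@dataclass(frozen=True)
class ChoiceModel:
    """Two-option softmax with temperature beta."""

    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class MonkeyParams:
    vigor: float
    gamma: float

    def __post_init__(self) -> None:
        if self.vigor <= 0 or self.gamma <= 0:
            raise ValueError("vigor and gamma must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Two-condition duration statistics defining a synthetic cohort.

    Conditions are (distance m, reward, mean duration s, s.e.m. s); the
    sampling s.d. is s.e.m. * sqrt(n_animals).
    """

    cond1: Tuple[float, float, float, float]
    cond2: Tuple[float, float, float, float]
    n_animals: int = 4
    n: int = 100

    def __post_init__(self) -> None:
        for c in (self.cond1, self.cond2):
            if c[2] <= 0 or c[3] <= 0:
                raise ValueError("mean durations and s.e.m.s must be positive")
        if self.n < 1 or self.n_animals < 1:
            raise ValueError("cohort sizes must be >= 1")

    @property
    def sds(self) -> Tuple[float, float]:
        s = np.sqrt(self.n_animals)
        return self.cond1[3] * s, self.cond2[3] * s


#: Displacement statistics printed for the two species (distance m,
#: reward, mean duration s, s.e.m. s), N = 4 animals each.
MARMOSET = CohortSpec((0.35, 1.0, 0.75, 0.061), (2.45, 3.0, 1.84, 0.082))
TAMARIN = CohortSpec((0.35, 1.0, 0.66, 0.047), (2.45, 3.0, 1.32, 0.050))

#: test distances (m): 35 cm steps out to 245 cm
STEVENS_GRID = tuple(np.round(np.arange(1, 8) * 0.35, 10))


def option_utility(internal_or_params, option: Option) -> float:
    """Utility of an option: max_T of discounted reward minus effort.

    Accepts either :class:`MonkeyParams` or anything with ``vigor`` and
    ``gamma`` attributes (e.g. :class:`~rewardctl.horizon.InternalParams`);
    utilities are expressed in units of the effort weight eps.
    """
    p = internal_or_params
    try:
        return closed_form_utility_objectI(option.A, option.r, p.vigor, p.gamma)[0]
    except NoViableAction:
        return 0.0


def indifference_point(
    params,
    reference: Option,
    test_reward: float,
    search_range: Tuple[float, float],
    tol: float = 1e-3,
) -> Optional[float]:
    """Distance at which the test option's utility crosses the reference's.

    Bisection on utility_test(A) - utility_reference over the range;
    ``None`` when there is no sign change (no preference reversal inside).
    """
    from scipy.optimize import brentq

    u_ref = option_utility(params, reference)
    f = lambda A: option_utility(params, Option(A, test_reward)) - u_ref
    lo, hi = search_range
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        return None
    return float(brentq(f, lo, hi, xtol=tol))


def choice_probability(j_large: float, j_small: float,
                       model: ChoiceModel) -> float:
    """Softmax probability of picking the large-reward option."""
    z = np.clip((j_large - j_small) / model.beta, -700.0, 700.0)
    return float(1.0 / (1.0 + np.exp(-z)))


def _boundary_refit(cond1, cond2, gamma_hi: float) -> MonkeyParams:
    """Best-fit parameters when no exact (vigor, gamma) root exists.

    Duration pairs whose ratio lies below the model's identifiable limit
    admit no interior solution; the squared duration error is then
    minimised on the gamma boundary (effectively the undiscounted limit),
    fitting vigor alone.
    """
    from scipy.optimize import minimize_scalar

    (A1, r1, T1), (A2, r2, T2) = cond1, cond2

    def err(logk: float) -> float:
        k = np.exp(logk)
        try:
            e1 = closed_form_duration_objectI(A1, r1, k, gamma_hi) - T1
            e2 = closed_form_duration_objectI(A2, r2, k, gamma_hi) - T2
        except NoViableAction:
            return 1e6
        return e1 * e1 + e2 * e2

    res = minimize_scalar(err, bounds=(-20.0, 40.0), method="bounded",
                          options={"xatol": 1e-10})
    return MonkeyParams(float(np.exp(res.x)), gamma_hi)


def sample_cohort(
    spec: CohortSpec,
    rng: np.random.Generator,
    gamma_bracket: Tuple[float, float] = (1e-3, 1e5),
    on_failure: str = "refit",
):
    """Sample n duration pairs and identify (vigor, gamma) for each.

    Pairs are drawn i.i.d. from Gaussians (sd = s.e.m. * sqrt(n_animals));
    non-positive draws are always resampled.  Duration pairs outside the
    identifiable region are handled per ``on_failure``:

    - ``"refit"`` (default): keep the pair with boundary best-fit
      parameters, so the cohort is an uncensored sample of the duration
      distribution;
    - ``"resample"``: draw a fresh pair (censors low-ratio pairs, which
      measurably biases the cohort's median preference behaviour).

    Returns (durations (n, 2), params list, n_unidentifiable).
    """
    if on_failure not in ("refit", "resample"):
        raise ValueError(f"unknown on_failure policy {on_failure!r}")
    A1, r1, m1, _ = spec.cond1
    A2, r2, m2, _ = spec.cond2
    s1, s2 = spec.sds
    durations = np.empty((spec.n, 2))
    params: List[MonkeyParams] = []
    unidentifiable = 0
    tries = 0
    while len(params) < spec.n:
        tries += 1
        if tries > 100 * spec.n:
            raise RuntimeError(
                f"resampling exceeded {100 * spec.n} draws "
                f"({len(params)} accepted)"
            )
        t1 = rng.normal(m1, s1)
        t2 = rng.normal(m2, s2)
        if t1 <= 0 or t2 <= 0:
            continue
        cond1 = (A1, r1, t1)
        cond2 = (A2, r2, t2)
        try:
            vigor, gamma = identify_parameters(cond1, cond2, gamma_bracket)
            monkey = MonkeyParams(vigor, gamma)
        except IdentificationError:
            unidentifiable += 1
            if on_failure == "resample":
                continue
            monkey = _boundary_refit(cond1, cond2, gamma_bracket[1])
        durations[len(params)] = (t1, t2)
        params.append(monkey)
    return durations, params, unidentifiable


def identify_cohort(durations: np.ndarray, spec: CohortSpec,
                    gamma_bracket=(1e-3, 1e5)) -> List[MonkeyParams]:
    """Identify (vigor, gamma) for externally supplied duration pairs."""
    A1, r1 = spec.cond1[:2]
    A2, r2 = spec.cond2[:2]
    out = []
    for t1, t2 in np.asarray(durations, dtype=float):
        vigor, gamma = identify_parameters((A1, r1, t1), (A2, r2, t2),
                                           gamma_bracket)
        out.append(MonkeyParams(vigor, gamma))
    return out


@dataclass
class StevensResult:
    durations: np.ndarray            # (n, 2) sampled duration pairs
    params: List[MonkeyParams]
    utilities: np.ndarray            # (n, n_grid) large-option utilities
    reference: np.ndarray            # (n,) reference-option utilities
    grid: np.ndarray                 # test distances (m)
    reversal_cm: Optional[float]     # smallest grid distance (cm) at which
                                     # the median monkey stops preferring
                                     # the large option; None if never
    indifference: np.ndarray         # (n,) per-monkey crossover (m; nan if none)
    n_unidentifiable: int

    def to_dataframe(self):
        import pandas as pd

        data = {
            "monkey": np.arange(len(self.params)),
            "T1": self.durations[:, 0],
            "T2": self.durations[:, 1],
            "vigor": [p.vigor for p in self.params],
            "gamma": [p.gamma for p in self.params],
            "u_reference": self.reference,
            "indifference_m": self.indifference,
        }
        for j, A in enumerate(self.grid):
            data[f"u_large_{int(round(A * 100))}cm"] = self.utilities[:, j]
        return pd.DataFrame(data)


def _species_result(spec, rng, grid, gamma_bracket,
                    on_failure) -> StevensResult:
    durations, params, unident = sample_cohort(spec, rng, gamma_bracket,
                                               on_failure)
    reference = Option(spec.cond1[0], spec.cond1[1])
    test_r = spec.cond2[1]
    grid = np.asarray(grid, dtype=float)
    utilities = np.empty((spec.n, len(grid)))
    u_ref = np.empty(spec.n)
    indiff = np.full(spec.n, np.nan)
    for i, p in enumerate(params):
        u_ref[i] = option_utility(p, reference)
        for j, A in enumerate(grid):
            utilities[i, j] = option_utility(p, Option(A, test_r))
        x = indifference_point(p, reference, test_r, (grid[0], grid[-1]))
        if x is not None:
            indiff[i] = x
    reversal = None
    for j, A in enumerate(grid):
        if not np.median(utilities[:, j] - u_ref) > 0:
            reversal = float(round(A * 100.0, 6))
            break
    return StevensResult(durations, params, utilities, u_ref, grid,
                         reversal, indiff, unident)


def stevens_pipeline(
    marmoset: CohortSpec = MARMOSET,
    tamarin: CohortSpec = TAMARIN,
    grid: Sequence[float] = STEVENS_GRID,
    seed: int = 0,
    gamma_bracket: Tuple[float, float] = (1e-3, 1e5),
    on_failure: str = "refit",
):
    """Full spatial-discounting pipeline for both species.

    Returns {"marmoset": StevensResult, "tamarin": StevensResult}.
    """
    rng = np.random.default_rng(seed)
    return {
        "marmoset": _species_result(marmoset, rng, grid, gamma_bracket,
                                    on_failure),
        "tamarin": _species_result(tamarin, rng, grid, gamma_bracket,
                                   on_failure),
    }
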