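"""Config-driven experiment reproductions.

Each runner takes a config mapping (missing keys fall back to the
defaults below), consumes a seed, and returns tables plus a JSON-ready
summary.  The CLI in :mod:`rewardctl.cli` wraps these with serialization
and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .decision import (
    MARMOSET,
    TAMARIN,
    ChoiceModel,
    CohortSpec,
    choice_probability,
    stevens_pipeline,
)
from .feedback import NoiseSpec, PerturbationEvent, first_arrival, simulate_trial
from .horizon import InternalParams, TaskParams
from .ocp_nonlinear import arm_rest_state
from .plants import (
    FilteredPointSpec,
    SHADMEHR_FIELD,
    apparent_mass,
    hand_kinematics,
    inverse_kinematics,
    object_iiia,
    object_iiib,
)

__all__ = [
    "ExperimentResult",
    "run_scaling",
    "run_target_jump",
    "run_force_field",
    "run_fitts",
    "run_stevens",
    "config_manifest",
]


@dataclass
class ExperimentResult:
    name: str
    tables: Dict[str, pd.DataFrame]
    summary: dict
    traces: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for key, df in self.tables.items():
            df.to_csv(os.path.join(outdir, f"{self.name}_{key}.csv"),
                      index=False)
        with open(os.path.join(outdir, f"{self.name}_summary.json"), "w") as f:
            json.dump(self.summary, f, indent=2, default=float)


def config_manifest(config: dict, seed: int) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "version": __version__,
        "numpy": np.__version__,
    }


def _merged(defaults: dict, config: Optional[dict]) -> dict:
    out = dict(defaults)
    if config:
        unknown = set(config) - set(defaults)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        out.update(config)
    return out


# Internal parameters used for the arm motor tasks: chosen to produce
# arm-movement velocities in the physiological range.
_ARM_INTERNAL = {"r": 40.0, "vigor": 1.0 / 300.0, "gamma": 0.5}


def _arm_trial(spec, posture_deg, amplitude, direction_deg, internal, rng,
               events=(), horizon_max=None, **kw):
    theta0 = np.deg2rad(posture_deg)
    x0 = arm_rest_state(theta0)
    p0, _, _ = hand_kinematics(spec, theta0)
    ang = np.deg2rad(direction_deg)
    target = p0 + amplitude * np.array([np.cos(ang), np.sin(ang)])
    theta1 = inverse_kinematics(spec, target, elbow_up=theta0[1] > 0)
    xstar = arm_rest_state(theta1)
    task = TaskParams(xstar, internal["r"])
    ip = InternalParams(rho=internal["vigor"], eps=1.0,
                        gamma=internal["gamma"])
    if horizon_max is None:
        horizon_max = 2.0
    trace, out = simulate_trial(
        spec, task, ip, events=events, horizon_max=horizon_max,
        x0=x0, rng=rng, **kw,
    )
    return trace, out, p0, target


def _hand_path(spec, trace):
    return np.array([hand_kinematics(spec, s[:2])[0] for s in trace.states])


def run_scaling(config: Optional[dict] = None, seed: int = 0) -> ExperimentResult:
    """Amplitude/duration scaling and direction anisotropy of arm reaches."""
    cfg = _merged(
        {
            "posture_deg": (75.0, 75.0),
            "amplitudes": (0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
            # direction chosen so the largest amplitude stays inside the
            # reachable workspace from the initial posture
            "scaling_direction_deg": 315.0,
            "directions_deg": tuple(np.arange(0.0, 360.0, 45.0)),
            "direction_amplitude": 0.10,
            "internal": _ARM_INTERNAL,
            "keep_traces": False,
        },
        config,
    )
    rng = np.random.default_rng(seed)
    spec = object_iiia()
    rows = []
    traces = {}
    for A in cfg["amplitudes"]:
        trace, out, p0, tgt = _arm_trial(
            spec, cfg["posture_deg"], A, cfg["scaling_direction_deg"],
            cfg["internal"], rng,
        )
        rows.append({"amplitude": A, "direction": cfg["scaling_direction_deg"],
                     "duration": out.duration,
                     "emergent_duration": float(trace.planned_T[0]),
                     "peak_speed": float(trace.speed.max()),
                     "endpoint_err": float(np.linalg.norm(out.endpoint - tgt)),
                     "finished": out.success})
        if cfg["keep_traces"]:
            traces[f"A{A:.2f}"] = trace
    amp_table = pd.DataFrame(rows)

    rows = []
    theta0 = np.deg2rad(cfg["posture_deg"])
    for d in cfg["directions_deg"]:
        trace, out, p0, tgt = _arm_trial(
            spec, cfg["posture_deg"], cfg["direction_amplitude"], d,
            cfg["internal"], rng,
        )
        ang = np.deg2rad(d)
        rows.append({"direction": d, "duration": out.duration,
                     "emergent_duration": float(trace.planned_T[0]),
                     "peak_speed": float(trace.speed.max()),
                     "apparent_mass": apparent_mass(
                         spec, theta0, np.array([np.cos(ang), np.sin(ang)])),
                     "finished": out.success})
        if cfg["keep_traces"]:
            traces[f"dir{d:.0f}"] = trace
    dir_table = pd.DataFrame(rows)
    from scipy.stats import spearmanr

    # the anisotropy of the emergent duration is tens of ms: use the
    # planned optimum, which the threshold-based measurement (endgame
    # noise of the same order) would mask
    rho = float(spearmanr(dir_table["emergent_duration"],
                          dir_table["apparent_mass"]).statistic)
    summary = {
        "duration_increases_with_amplitude": bool(
            np.all(np.diff(amp_table["duration"]) > 0)),
        "spearman_duration_inertia": rho,
    }
    return ExperimentResult("scaling", {"amplitude": amp_table,
                                        "direction": dir_table},
                            summary, traces)


def run_target_jump(config: Optional[dict] = None, seed: int = 0) -> ExperimentResult:
    """Mid-movement target jumps: arrival time vs perturbation time."""
    cfg = _merged(
        {
            "posture_deg": (15.0, 120.0),
            "amplitude": 0.15,
            "direction_deg": 90.0,
            "jump_offset": 0.05,        # m, lateral (+x) displacement
            "jump_times": (0.1, 0.2, 0.3),
            "internal": _ARM_INTERNAL,
            "horizon_max": 2.5,
            "keep_traces": False,
        },
        config,
    )
    rng = np.random.default_rng(seed)
    spec = object_iiia()
    theta0 = np.deg2rad(cfg["posture_deg"])
    p0, _, _ = hand_kinematics(spec, theta0)
    ang = np.deg2rad(cfg["direction_deg"])
    base_target = p0 + cfg["amplitude"] * np.array([np.cos(ang), np.sin(ang)])
    rows = []
    traces = {}

    def jumped_xstar(sign):
        tgt = base_target + np.array([sign * cfg["jump_offset"], 0.0])
        return arm_rest_state(inverse_kinematics(spec, tgt,
                                                 elbow_up=theta0[1] > 0))

    # unperturbed control run
    trace0, out0, _, _ = _arm_trial(spec, cfg["posture_deg"], cfg["amplitude"],
                                    cfg["direction_deg"], cfg["internal"],
                                    rng, horizon_max=cfg["horizon_max"])
    rows.append({"jump_time": np.nan, "jump_sign": 0,
                 "arrival_time": out0.duration, "finished": out0.success})
    if cfg["keep_traces"]:
        traces["control"] = trace0
    for tj in cfg["jump_times"]:
        for sign in (+1, -1):
            ev = [PerturbationEvent(tj, "target_jump",
                                    xstar=jumped_xstar(sign))]
            trace, out, _, _ = _arm_trial(
                spec, cfg["posture_deg"], cfg["amplitude"],
                cfg["direction_deg"], cfg["internal"], rng,
                events=ev, horizon_max=cfg["horizon_max"],
            )
            rows.append({"jump_time": tj, "jump_sign": sign,
                         "arrival_time": out.duration,
                         "finished": out.success})
            if cfg["keep_traces"]:
                traces[f"t{tj:.1f}s{sign:+d}"] = trace
    table = pd.DataFrame(rows)
    mean_arrival = (table.dropna(subset=["jump_time"])
                    .groupby("jump_time")["arrival_time"].mean())
    summary = {
        "arrival_times": mean_arrival.to_dict(),
        "monotone_in_jump_time": bool(
            np.all(np.diff(mean_arrival.values) > 0)),
        "control_duration": float(out0.duration),
    }
    return ExperimentResult("target_jump", {"arrival": table}, summary, traces)


def _count_speed_peaks(speed, min_height_frac=0.1):
    """Local maxima of a speed profile above a fraction of the global max."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(speed, height=min_height_frac * speed.max(),
                          distance=50)
    return int(len(peaks))


def run_force_field(config: Optional[dict] = None, seed: int = 0) -> ExperimentResult:
    """Velocity-dependent force field with a field-naive controller."""
    cfg = _merged(
        {
            "posture_deg": (15.0, 100.0),
            "amplitude": 0.10,
            "directions_deg": (0.0, 90.0, 180.0, 270.0),
            "internal": _ARM_INTERNAL,
            "field": "default",
            "horizon_max": 2.5,
            "keep_traces": False,
        },
        config,
    )
    rng = np.random.default_rng(seed)
    field_mat = SHADMEHR_FIELD if cfg["field"] == "default" else np.asarray(
        cfg["field"], dtype=float)
    rows = []
    traces = {}
    for field_on in (False, True):
        spec = object_iiib(force_field=field_mat if field_on else None)
        events = ([PerturbationEvent(0.0, "force_field_on")]
                  if field_on else [])
        for d in cfg["directions_deg"]:
            trace, out, p0, tgt = _arm_trial(
                spec, cfg["posture_deg"], cfg["amplitude"], d,
                cfg["internal"], rng, events=events,
                horizon_max=cfg["horizon_max"],
            )
            path = _hand_path(spec, trace)
            v = (tgt - p0) / np.linalg.norm(tgt - p0)
            lateral = (path - p0) @ np.array([-v[1], v[0]])
            end_idx = max(int(out.duration * 1000), 1)
            rows.append({
                "direction": d,
                "field": field_on,
                "duration": out.duration,
                "n_speed_peaks": _count_speed_peaks(
                    trace.speed[:end_idx + 1]),
                "max_lateral_dev": float(np.abs(lateral[:end_idx]).max()),
                "endpoint_err": float(np.linalg.norm(out.endpoint - tgt)),
                "finished": out.success,
            })
            if cfg["keep_traces"]:
                traces[f"{'field' if field_on else 'null'}_dir{d:.0f}"] = trace
    table = pd.DataFrame(rows)
    null_peaks = table.loc[~table["field"], "n_speed_peaks"]
    field_peaks = table.loc[table["field"], "n_speed_peaks"]
    summary = {
        "null_single_peaked": int((null_peaks == 1).sum()),
        "field_multi_peaked": int((field_peaks >= 2).sum()),
        "n_directions": len(cfg["directions_deg"]),
    }
    return ExperimentResult("force_field", {"trials": table}, summary, traces)


def run_fitts(config: Optional[dict] = None, seed: int = 0) -> ExperimentResult:
    """Speed/accuracy trade-off: duration vs index of difficulty.

    Conditions vary distance, vigor and discount; endpoint width W is the
    95% interval of the endpoint distribution along the movement axis over
    repeated noisy trials.
    """
    cfg = _merged(
        {
            "distances": (0.1, 0.2, 0.3),
            "conditions": (
                {"vigor": 100.0, "gamma": 2.0},
                {"vigor": 30.0, "gamma": 2.0},
                {"vigor": 100.0, "gamma": 1.0},
            ),
            "r": 1.0,
            "n_trials": 200,
            "sdn": 1.0,
            "sin": 0.001,
            "horizon_max": 2.5,
        },
        config,
    )
    rng = np.random.default_rng(seed)
    spec = FilteredPointSpec()
    noise = NoiseSpec(sdn=cfg["sdn"], sin=cfg["sin"])
    if noise.sdn == 0 and noise.sin == 0:
        raise ValueError("Fitts pipeline requires noise (W would be 0)")
    rows = []
    sd_profiles = {}
    for ci, cond in enumerate(cfg["conditions"]):
        internal = InternalParams(rho=cond["vigor"], eps=1.0,
                                  gamma=cond["gamma"])
        for A in cfg["distances"]:
            task = TaskParams([A, 0.0, 0.0, 0.0], cfg["r"])
            endpoints = np.empty(cfg["n_trials"])
            durations = np.empty(cfg["n_trials"])
            positions = []
            for t in range(cfg["n_trials"]):
                trace, out = simulate_trial(
                    spec, task, internal, noise=noise,
                    horizon_max=cfg["horizon_max"], rng=rng,
                )
                # endpoint and duration at first sustained arrival: the
                # post-arrival station-keeping phase re-converges the
                # endpoint and would erase the speed/accuracy trade-off
                t_arr, k_arr, moved = first_arrival(trace.time, trace.speed)
                endpoints[t] = trace.states[k_arr, 0]
                durations[t] = t_arr
                positions.append(trace.states[:, 0])
            positions = np.asarray(positions)
            W = float(np.percentile(endpoints, 97.5)
                      - np.percentile(endpoints, 2.5))
            if W <= 0:
                raise ValueError(
                    f"degenerate endpoint width at A={A}; check noise config")
            rows.append({
                "condition": ci, "vigor": cond["vigor"],
                "gamma": cond["gamma"], "amplitude": A,
                "W": W, "ID": float(np.log2(2 * A / W)),
                "mean_duration": float(durations.mean()),
                "sd_duration": float(durations.std()),
            })
            sd_profiles[(ci, A)] = positions.std(axis=0)
    table = pd.DataFrame(rows)
    from scipy.stats import linregress

    fit = linregress(table["ID"], table["mean_duration"])
    # representative spatiotemporal variability profile
    key = (0, max(cfg["distances"]))
    prof = sd_profiles[key]
    sd_table = pd.DataFrame({"t": np.arange(len(prof)) * 0.001,
                             "position_sd": prof})
    summary = {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
    }
    return ExperimentResult("fitts", {"records": table,
                                      "sd_profile": sd_table}, summary)


def run_stevens(config: Optional[dict] = None, seed: int = 0) -> ExperimentResult:
    """Cohort pipeline plus softmax choice curves."""
    cfg = _merged({"beta": 1.0, "n": 100}, config)
    res = stevens_pipeline(
        marmoset=CohortSpec(MARMOSET.cond1, MARMOSET.cond2,
                            MARMOSET.n_animals, cfg["n"]),
        tamarin=CohortSpec(TAMARIN.cond1, TAMARIN.cond2,
                           TAMARIN.n_animals, cfg["n"]),
        seed=seed,
    )
    model = ChoiceModel(beta=cfg["beta"])
    tables = {}
    summary = {}
    for species, r in res.items():
        tables[species] = r.to_dataframe()
        pchoice = np.array([
            [choice_probability(r.utilities[i, j], r.reference[i], model)
             for j in range(len(r.grid))]
            for i in range(len(r.params))
        ])
        curve = pd.DataFrame({
            "distance_cm": np.round(np.asarray(r.grid) * 100).astype(int),
            "p_large_mean": pchoice.mean(axis=0),
            "p_large_lo": np.percentile(pchoice, 2.5, axis=0),
            "p_large_hi": np.percentile(pchoice, 97.5, axis=0),
        })
        tables[f"{species}_choice"] = curve
        summary[species] = {
            "reversal_cm": r.reversal_cm,
            "median_indifference_m": float(np.nanmedian(r.indifference))
            if np.isfinite(r.indifference).any() else None,
            "frac_reversing": float(np.mean(np.isfinite(r.indifference))),
            "n_unidentifiable": r.n_unidentifiable,
        }
    return ExperimentResult("stevens", tables, summary)
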