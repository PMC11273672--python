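"""Surrogate calibration against printed kinematic landmarks.

The rigid-body surrogate cannot inherit the reference model's geometry, so
its free parameters — per-joint rotational stiffness scales, the activation
plateau, the damping ratio — are fitted to reproduce a small set of
kinematic landmarks: the upper-cervical (C0-C2) flexion peak window of the
active-muscle run, the cross-scenario percent reductions at the end of the
event, and the qualitative curvature sequence (inverted-S early, mirrored-C
late, inverted-U upper-cervical history under active muscles).

The search is a deterministic bounded coordinate descent with a fixed
evaluation budget; every candidate is scored by running the three scenario
simulations and measuring the landmarks, so the fit is on exactly the
quantities the analysis layer reports.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .anatomy import Anatomy, AnatomyConfig, generate_anatomy
from .dynamics import assemble_system, simulate
from .loading import AccelerationProfile
from .muscle import ActivationSchedule, MuscleParams, default_muscle_table
from .analysis import (
    SEGMENTS,
    curvature_timeline,
    peak_analysis,
    reduction_table,
    segmental_rotations,
)

__all__ = ["Landmarks", "SearchConfig", "CalibrationResult", "calibrate",
           "evaluate_landmarks", "landmark_loss", "default_landmarks"]

log = logging.getLogger(__name__)


@dataclass
class Landmarks:
    """Target kinematic landmarks for the calibrated surrogate."""

    peak_deg_window: tuple[float, float] = (8.0, 9.0)
    peak_ms_window: tuple[float, float] = (95.0, 105.0)
    at_time_ms: float = 150.0
    # (segment, test scenario, reference scenario, percent reduction)
    reductions: list[tuple[str, str, str, float]] = field(
        default_factory=lambda: [
            ("C1-C2", "active", "passive", 43.2),
            ("C5-C6", "active", "passive", 7.0),
            ("C0-C1", "active", "none", 55.0),
        ]
    )
    reduction_scale_pp: float = 5.0
    require_inverted_s_before_ms: float = 110.0
    require_mirrored_c_at_end: bool = True
    require_inverted_u_active: bool = True
    require_end_peak_scenarios: tuple[str, ...] = ("none", "passive")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Landmarks":
        d = dict(d)
        if "reductions" in d:
            d["reductions"] = [tuple(r) for r in d["reductions"]]
        for k in ("peak_deg_window", "peak_ms_window", "require_end_peak_scenarios"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def default_landmarks() -> Landmarks:
    path = Path(resources.files("neckdyn") / "data" / "landmarks.yaml")
    return Landmarks.from_dict(yaml.safe_load(path.read_text()))


def evaluate_landmarks(
    anatomy: Anatomy,
    muscles: list[MuscleParams] | None = None,
    schedule: ActivationSchedule | None = None,
    profile: AccelerationProfile | None = None,
    dt: float = 0.02,
    scenarios: tuple[str, ...] = ("none", "passive", "active"),
) -> dict[str, Any]:
    """Run the scenario simulations and measure every landmark quantity."""
    muscles = muscles if muscles is not None else default_muscle_table()
    schedule = schedule or ActivationSchedule()
    profile = profile or AccelerationProfile()
    rots = {}
    for scen in scenarios:
        system = assemble_system(anatomy, muscles, scen, schedule)
        traj = simulate(system, profile, dt=dt)
        rots[scen] = segmental_rotations(traj, anatomy)

    out: dict[str, Any] = {"rotations": rots}
    if "active" in rots:
        pk = peak_analysis(rots["active"]["C0-C2"])
        out["active_c0c2_peak_deg"] = pk["peak_deg"]
        out["active_c0c2_peak_ms"] = pk["peak_time_ms"]
        out["active_c0c2_inverted_u"] = pk["inverted_u"]
    tab = reduction_table(rots, 150.0).set_index("segment")
    out["reduction_table"] = tab
    for seg, test, ref, _tgt in default_landmarks().reductions:
        col = f"reduction_{test}_vs_{ref}_pct"
        if col in tab.columns:
            out[f"red_{seg}_{test}_vs_{ref}"] = float(tab.loc[seg, col])
    for scen, rr in rots.items():
        tl = curvature_timeline(rr)
        lab = tl["label"].to_numpy()
        t = tl["t_ms"].to_numpy()
        out[f"{scen}_inverted_s_before_110"] = bool(
            np.any(lab[t < 110.0] == "inverted-S")
        )
        out[f"{scen}_label_at_150"] = str(lab[-1])
        out[f"{scen}_min_seg_at_150"] = float(
            min(rr[s].angle_deg[-1] for s in SEGMENTS)
        )
        pk = peak_analysis(rr["C0-C2"])
        out[f"{scen}_c0c2_peak_ms"] = pk["peak_time_ms"]
    return out


def _window_dist(x: float, lo: float, hi: float) -> float:
    if x < lo:
        return lo - x
    if x > hi:
        return x - hi
    return 0.0


def landmark_loss(metrics: Mapping[str, Any], landmarks: Landmarks) -> float:
    """Weighted squared-error landmark mismatch; 0 when everything is met."""
    L = 0.0
    if "active_c0c2_peak_deg" in metrics:
        L += (_window_dist(metrics["active_c0c2_peak_deg"], *landmarks.peak_deg_window) / 0.5) ** 2
        L += (_window_dist(metrics["active_c0c2_peak_ms"], *landmarks.peak_ms_window) / 5.0) ** 2
        if landmarks.require_inverted_u_active and not metrics.get("active_c0c2_inverted_u"):
            L += 10.0
    for seg, test, ref, tgt in landmarks.reductions:
        v = metrics.get(f"red_{seg}_{test}_vs_{ref}")
        if v is None or not np.isfinite(v):
            L += 25.0
        else:
            L += ((v - tgt) / landmarks.reduction_scale_pp) ** 2
    for scen in ("none", "passive", "active"):
        if f"{scen}_label_at_150" not in metrics:
            continue
        if not metrics.get(f"{scen}_inverted_s_before_110", False):
            L += 10.0
        if landmarks.require_mirrored_c_at_end:
            # smooth margin: want every segment comfortably flexed at the end
            margin = metrics.get(f"{scen}_min_seg_at_150", -1.0)
            L += (max(0.0, (0.25 - margin) / 0.25)) ** 2 * 4.0
    for scen in landmarks.require_end_peak_scenarios:
        pk_ms = metrics.get(f"{scen}_c0c2_peak_ms")
        if pk_ms is not None and pk_ms < 149.0:
            L += 10.0
    return float(L)


@dataclass
class SearchConfig:
    """Deterministic coordinate-descent settings.

    ``knobs`` maps a knob name to a dict with keys ``kind`` ("mult" or
    "add"), ``step`` (initial step: factor for mult, increment for add) and
    ``bounds``.  Supported knob names: ``joint_scale[j]`` for j in 0..7,
    ``plateau``, ``damping_ratio``.
    """

    budget: int = 60
    dt_ms: float = 0.02
    shrink: float = 0.5
    sweeps: int = 3
    loss_ceiling: float = 5.0
    knobs: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {
            **{
                f"joint_scale[{j}]": {"kind": "mult", "step": 1.5, "bounds": (0.05, 500.0)}
                for j in range(8)
            },
            "plateau": {"kind": "add", "step": 0.1, "bounds": (0.0, 1.0)},
            "rise_time": {"kind": "add", "step": 10.0, "bounds": (5.0, 60.0)},
            "damping_ratio": {"kind": "mult", "step": 1.3, "bounds": (0.1, 3.0)},
        }
    )


@dataclass
class CalibrationResult:
    anatomy: Anatomy
    schedule: ActivationSchedule
    loss: float
    initial_loss: float
    evaluations: int
    scales: dict[str, float]
    converged: bool
    metrics: dict[str, Any]

    @property
    def report(self) -> dict[str, Any]:
        return {
            "loss": self.loss,
            "initial_loss": self.initial_loss,
            "evaluations": self.evaluations,
            "scales": self.scales,
            "converged": self.converged,
        }


def _get_knob(cfg: AnatomyConfig, schedule: ActivationSchedule, name: str) -> float:
    if name == "plateau":
        return schedule.plateau
    if name == "rise_time":
        return schedule.rise_time
    if name == "damping_ratio":
        return cfg.damping_ratio
    if name.startswith("joint_scale["):
        return cfg.joint_scale[int(name[12:-1])]
    raise KeyError(f"unknown calibration knob {name!r}")


def _set_knob(cfg: AnatomyConfig, schedule: ActivationSchedule, name: str, value: float):
    if name in ("plateau", "rise_time"):
        return cfg, ActivationSchedule(
            reflex_time=schedule.reflex_time,
            rise_time=value if name == "rise_time" else schedule.rise_time,
            plateau=value if name == "plateau" else schedule.plateau,
            shape=schedule.shape,
        )
    cfg = copy.deepcopy(cfg)
    if name == "damping_ratio":
        cfg.damping_ratio = value
    else:
        cfg.joint_scale[int(name[12:-1])] = value
    return cfg, schedule


def calibrate(
    anatomy: Anatomy,
    landmarks: Landmarks | None = None,
    search_config: SearchConfig | None = None,
    schedule: ActivationSchedule | None = None,
    muscles: list[MuscleParams] | None = None,
    profile: AccelerationProfile | None = None,
) -> CalibrationResult:
    """Fit joint-stiffness scales, plateau and damping to the landmarks.

    Runs a bounded coordinate descent (fixed sweep order, fixed budget) from
    the supplied anatomy's configuration; every evaluation regenerates the
    anatomy deterministically from the same seed.  With ``budget = 0`` or an
    already-satisfied landmark set, the input is returned unchanged (all
    scale factors 1).  A final loss above ``loss_ceiling`` flags the result
    as non-converged; the best-effort anatomy is still returned.
    """
    lm = landmarks or default_landmarks()
    sc = search_config or SearchConfig()
    sched = schedule or ActivationSchedule()
    muscles = muscles if muscles is not None else default_muscle_table()
    profile = profile or AccelerationProfile()

    cfg0 = copy.deepcopy(anatomy.config)
    seed = anatomy.seed

    evals = 0

    def run(cfg: AnatomyConfig, s: ActivationSchedule):
        nonlocal evals
        evals += 1
        anat = generate_anatomy(seed, cfg, muscles)
        m = evaluate_landmarks(anat, muscles, s, profile, dt=sc.dt_ms)
        return landmark_loss(m, lm), m

    best_cfg, best_sched = copy.deepcopy(cfg0), sched
    best_loss, best_metrics = run(best_cfg, best_sched)
    initial_loss = best_loss
    log.info("calibration: initial loss %.3f", initial_loss)

    if sc.budget > 0 and best_loss > 0.0:
        steps = {k: v["step"] for k, v in sc.knobs.items()}
        for sweep in range(sc.sweeps):
            improved = False
            for name, spec in sc.knobs.items():
                if evals >= sc.budget:
                    break
                cur = _get_knob(best_cfg, best_sched, name)
                lo, hi = spec["bounds"]
                cands = []
                if spec["kind"] == "mult":
                    cands = [cur * steps[name], cur / steps[name]]
                else:
                    cands = [cur + steps[name], cur - steps[name]]
                for cand in cands:
                    if evals >= sc.budget:
                        break
                    cand = min(hi, max(lo, cand))
                    if abs(cand - cur) < 1e-12:
                        continue
                    cfg_c, sched_c = _set_knob(best_cfg, best_sched, name, cand)
                    loss_c, m_c = run(cfg_c, sched_c)
                    if loss_c < best_loss - 1e-9:
                        best_cfg, best_sched = cfg_c, sched_c
                        best_loss, best_metrics = loss_c, m_c
                        cur = cand
                        improved = True
            for name in steps:
                if sc.knobs[name]["kind"] == "mult":
                    steps[name] = 1.0 + (steps[name] - 1.0) * sc.shrink
                else:
                    steps[name] *= sc.shrink
            if evals >= sc.budget or (not improved and sweep > 0):
                break

    best_anat = generate_anatomy(seed, best_cfg, muscles)
    scales = {
        f"joint_scale[{j}]": best_cfg.joint_scale[j] / cfg0.joint_scale[j]
        for j in range(8)
    }
    scales["plateau"] = (
        best_sched.plateau / sched.plateau if sched.plateau else best_sched.plateau
    )
    scales["rise_time"] = (
        best_sched.rise_time / sched.rise_time if sched.rise_time else best_sched.rise_time
    )
    scales["damping_ratio"] = best_cfg.damping_ratio / cfg0.damping_ratio
    best_metrics = {k: v for k, v in best_metrics.items() if k != "rotations"}
    result = CalibrationResult(
        anatomy=best_anat,
        schedule=best_sched,
        loss=best_loss,
        initial_loss=initial_loss,
        evaluations=evals,
        scales=scales,
        converged=best_loss <= sc.loss_ceiling,
        metrics=best_metrics,
    )
    if not result.converged:
        log.warning("calibration did not reach the loss ceiling: %.3f", best_loss)
    return result
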