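"""Planar multibody dynamics of the head-neck chain under base excitation.

Maximal-coordinate formulation: every body C0-C7 carries (x, y, theta) and
their rates; the T1 base is kinematically prescribed from the closed-form
integrals of the loading profile (infinite-mass constraint).  Joints are
penalty bushings — translational springs/dampers acting between coincident
attachment points (resolved in the lower body's frame: shear = local x,
axial = local y) plus rotational springs/dampers on the relative angle.
Muscle bundles apply equal-and-opposite tensions along their straight lines
of action.  Integration is fixed-step classical Runge-Kutta (4th order).

Sign conventions: +x anterior, +y up, theta positive counterclockwise, so
flexion (superior body tipping anteriorly) is a *negative* relative theta;
the analysis layer maps to flexion-positive degrees.  Muscle velocity is the
lengthening rate (positive when stretching), which is exactly the
shortening-negative convention of the force-velocity curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .anatomy import Anatomy
from .loading import AccelerationProfile, base_state
from .muscle import ActivationSchedule, MuscleParams, active_state

__all__ = ["System", "Trajectory", "assemble_system", "simulate", "assemble_forces"]

SCENARIOS = ("none", "passive", "active")
_G = 9.81


@dataclass
class _MuscleArrays:
    """Stacked per-bundle parameters for the vectorised force evaluation."""

    names: list[str]
    o_body: np.ndarray      # index into the (n+1)-body array, base = n
    i_body: np.ndarray
    r_o: np.ndarray         # local attachment, m (body frame at assembly)
    r_i: np.ndarray
    lo: np.ndarray          # mm
    vmax: np.ndarray        # mm/s (already scaled by sv)
    fmax: np.ndarray        # mN, already scaled by the bilateral factor
    fpe_scale: np.ndarray
    lmax: np.ndarray
    ksh: np.ndarray
    fl_width: np.ndarray
    fv_curvature: np.ndarray
    fv_plateau: np.ndarray
    fv_shape: np.ndarray

    def __len__(self) -> int:
        return len(self.names)

    def tension_mn(self, na: float, length_mm: np.ndarray, ldot_mm_s: np.ndarray) -> np.ndarray:
        """Total bundle tension (contractile + parallel-elastic), mN, >= 0."""
        x = (length_mm / self.lo - 1.0) / self.fl_width
        fl = np.maximum(0.0, 1.0 - x * x)
        u = ldot_mm_s / self.vmax
        conc = np.maximum(0.0, (1.0 + u) / (1.0 - u / self.fv_curvature))
        ecc = self.fv_plateau - (self.fv_plateau - 1.0) * self.fv_shape / (
            self.fv_shape + np.maximum(u, 0.0)
        )
        fv = np.where(u <= 0.0, conc, ecc)
        active = na * self.fmax * fl * fv
        strain = np.maximum(0.0, length_mm / self.lo - 1.0)
        passive = (
            self.fpe_scale
            * self.fmax
            * np.expm1((self.ksh / self.lmax) * strain)
            / np.expm1(self.ksh)
        )
        return np.maximum(0.0, active) + passive


@dataclass
class System:
    """Assembled mechanical system for one scenario."""

    anatomy: Anatomy
    scenario: str
    schedule: ActivationSchedule
    gravity: bool
    n: int
    masses: np.ndarray
    inertias: np.ndarray
    com0: np.ndarray            # (n, 2) assembly centroids, m
    base_com0: np.ndarray
    # joints (one per body, chained to the base)
    j_up: np.ndarray
    j_low: np.ndarray
    r_up: np.ndarray
    r_low: np.ndarray
    k_flex: np.ndarray
    k_ext: np.ndarray
    c_rot: np.ndarray
    k_shear: np.ndarray
    k_axial: np.ndarray
    c_trans: np.ndarray
    neutral: np.ndarray
    muscles: _MuscleArrays | None
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_muscles(self) -> int:
        return 0 if self.muscles is None else len(self.muscles)

    def initial_state(self) -> np.ndarray:
        """Flat state [pos (2n), theta (n), vel (2n), omega (n)] at rest."""
        state = np.zeros(6 * self.n)
        state[: 2 * self.n] = self.com0.ravel()
        return state


def assemble_system(
    anatomy: Anatomy,
    muscle_set: list[MuscleParams] | None,
    scenario: str,
    schedule: ActivationSchedule | None = None,
    gravity: bool | None = None,
) -> System:
    """Build a :class:`System` for one of the three muscle scenarios.

    ``none``: no muscle elements.  ``passive``: all bundles present with the
    neural drive identically zero and the parallel-elastic element enabled
    (``fpe_scale = 1``).  ``active``: neural drive per ``schedule`` and the
    parallel-elastic scale as tabulated (0 by default).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    sched = schedule or ActivationSchedule()
    if scenario == "passive":
        sched = ActivationSchedule(
            reflex_time=sched.reflex_time,
            rise_time=sched.rise_time,
            plateau=0.0,
            shape=sched.shape,
        )
    cfg = anatomy.config
    grav = cfg.gravity if gravity is None else gravity

    n = len(anatomy.bodies)
    masses = np.array([b.mass for b in anatomy.bodies])
    inertias = np.array([b.inertia for b in anatomy.bodies])
    com0 = np.array([b.com for b in anatomy.bodies])
    base_com0 = np.asarray(anatomy.base.com, float)
    coms_ext = np.vstack([com0, base_com0])

    idx = {b.label: i for i, b in enumerate(anatomy.bodies)}
    idx[anatomy.base.label] = n

    nj = len(anatomy.joints)
    j_up = np.array([idx[j.upper] for j in anatomy.joints])
    j_low = np.array([idx[j.lower] for j in anatomy.joints])
    # the force accumulator relies on the serial-chain ordering
    if not (np.array_equal(j_up, np.arange(n)) and np.array_equal(j_low, np.arange(1, n + 1))):
        raise ValueError("joints must chain each body to the one below, top first")
    pts = np.array([j.point for j in anatomy.joints])
    r_up = pts - coms_ext[j_up]
    r_low = pts - coms_ext[j_low]

    muscles = None
    if scenario != "none" and anatomy.routes:
        if muscle_set is None:
            raise ValueError(f"scenario {scenario!r} requires a muscle table")
        by_name = {m.name: m for m in muscle_set}
        rts = [r for r in anatomy.routes if r.bundle in by_name]
        ms = [by_name[r.bundle] for r in rts]
        fpe = (
            np.ones(len(ms))
            if scenario == "passive"
            else np.array([m.fpe_scale for m in ms])
        )
        muscles = _MuscleArrays(
            names=[m.name for m in ms],
            o_body=np.array([idx[r.origin_body] for r in rts]),
            i_body=np.array([idx[r.insertion_body] for r in rts]),
            r_o=np.array([r.origin_point for r in rts]) - coms_ext[
                np.array([idx[r.origin_body] for r in rts])
            ],
            r_i=np.array([r.insertion_point for r in rts]) - coms_ext[
                np.array([idx[r.insertion_body] for r in rts])
            ],
            lo=np.array([m.lo for m in ms]),
            vmax=np.array([m.sv * m.vmax for m in ms]),
            fmax=np.array([m.fmax for m in ms]) * cfg.bilateral_factor,
            fpe_scale=fpe,
            lmax=np.array([m.lmax for m in ms]),
            ksh=np.array([m.ksh for m in ms]),
            fl_width=np.array([m.fl_width for m in ms]),
            fv_curvature=np.array([m.fv_curvature for m in ms]),
            fv_plateau=np.array([m.fv_plateau for m in ms]),
            fv_shape=np.array([m.fv_shape for m in ms]),
        )

    return System(
        anatomy=anatomy,
        scenario=scenario,
        schedule=sched,
        gravity=grav,
        n=n,
        masses=masses,
        inertias=inertias,
        com0=com0,
        base_com0=base_com0,
        j_up=j_up,
        j_low=j_low,
        r_up=r_up,
        r_low=r_low,
        k_flex=np.array([j.k_flex for j in anatomy.joints]),
        k_ext=np.array([j.k_ext for j in anatomy.joints]),
        c_rot=np.array([j.c_rot for j in anatomy.joints]),
        k_shear=np.array([j.k_shear for j in anatomy.joints]),
        k_axial=np.array([j.k_axial for j in anatomy.joints]),
        c_trans=np.array([j.c_trans for j in anatomy.joints]),
        neutral=np.array([j.neutral for j in anatomy.joints]),
        muscles=muscles,
    )


def _body_kinematics(sys: System, t_ms: float, state: np.ndarray, profile: AccelerationProfile):
    """Extended (n+1)-body pose/rate arrays with the prescribed base last."""
    n = sys.n
    pos = np.empty((n + 1, 2))
    th = np.empty(n + 1)
    vel = np.zeros((n + 1, 2))
    om = np.zeros(n + 1)
    pos[:n] = state[: 2 * n].reshape(n, 2)
    th[:n] = state[2 * n : 3 * n]
    vel[:n] = state[3 * n : 5 * n].reshape(n, 2)
    om[:n] = state[5 * n : 6 * n]
    _, v_b, y_b = base_state(t_ms, profile)
    pos[n] = sys.base_com0 + (0.0, y_b)
    th[n] = 0.0
    vel[n] = (0.0, v_b)
    return pos, th, vel, om


def _rot(th: np.ndarray, r: np.ndarray) -> np.ndarray:
    c, s = np.cos(th), np.sin(th)
    return np.stack([c * r[:, 0] - s * r[:, 1], s * r[:, 0] + c * r[:, 1]], axis=1)


def assemble_forces(
    sys: System,
    profile: AccelerationProfile,
    t_ms: float,
    state: np.ndarray,
    include_gravity: bool | None = None,
):
    """Generalised forces on all bodies (base row included) at one instant.

    Returns ``(F, T)``: force (n+1, 2) N and torque about each centroid
    (n+1,) N m.  The base row accumulates the reactions the chain exerts on
    the prescribed base.  Used by the integrator and, directly, by the
    momentum-balance and energy checks.
    """
    n = sys.n
    pos, th, vel, om = _body_kinematics(sys, t_ms, state, profile)
    F = np.zeros((n + 1, 2))
    T = np.zeros(n + 1)

    # ---- bushing joints ----
    up, low = sys.j_up, sys.j_low
    ru_w = _rot(th[up], sys.r_up)
    rl_w = _rot(th[low], sys.r_low)
    p_u = pos[up] + ru_w
    p_l = pos[low] + rl_w
    v_u = vel[up] + np.stack([-om[up] * ru_w[:, 1], om[up] * ru_w[:, 0]], axis=1)
    v_l = vel[low] + np.stack([-om[low] * rl_w[:, 1], om[low] * rl_w[:, 0]], axis=1)
    d = p_u - p_l
    dv = v_u - v_l
    cl, sl = np.cos(th[low]), np.sin(th[low])
    # into lower frame
    d_loc = np.stack([cl * d[:, 0] + sl * d[:, 1], -sl * d[:, 0] + cl * d[:, 1]], axis=1)
    dv_loc = np.stack([cl * dv[:, 0] + sl * dv[:, 1], -sl * dv[:, 0] + cl * dv[:, 1]], axis=1)
    f_loc = np.empty_like(d_loc)
    f_loc[:, 0] = -sys.k_shear * d_loc[:, 0] - sys.c_trans * dv_loc[:, 0]
    f_loc[:, 1] = -sys.k_axial * d_loc[:, 1] - sys.c_trans * dv_loc[:, 1]
    f_w = np.stack(
        [cl * f_loc[:, 0] - sl * f_loc[:, 1], sl * f_loc[:, 0] + cl * f_loc[:, 1]],
        axis=1,
    )
    th_rel = th[up] - th[low] - sys.neutral
    k_rot = np.where(th_rel < 0.0, sys.k_flex, sys.k_ext)
    tau = -k_rot * th_rel - sys.c_rot * (om[up] - om[low])
    # the bushing force acts at the midpoint of the two (displaced)
    # attachment points so the equal-and-opposite pair carries no net moment
    # even when the force is not central (anisotropic stiffness, damping)
    r_mid_u = ru_w - 0.5 * d
    r_mid_l = rl_w + 0.5 * d
    # chain topology: up = 0..n-1, low = 1..n — plain slicing accumulates
    F[:-1] += f_w
    F[1:] -= f_w
    T[:-1] += r_mid_u[:, 0] * f_w[:, 1] - r_mid_u[:, 1] * f_w[:, 0] + tau
    T[1:] -= r_mid_l[:, 0] * f_w[:, 1] - r_mid_l[:, 1] * f_w[:, 0] + tau

    # ---- muscle bundles ----
    mus = sys.muscles
    if mus is not None:
        ob, ib = mus.o_body, mus.i_body
        ro_w = _rot(th[ob], mus.r_o)
        ri_w = _rot(th[ib], mus.r_i)
        p_o = pos[ob] + ro_w
        p_i = pos[ib] + ri_w
        v_o = vel[ob] + np.stack([-om[ob] * ro_w[:, 1], om[ob] * ro_w[:, 0]], axis=1)
        v_i = vel[ib] + np.stack([-om[ib] * ri_w[:, 1], om[ib] * ri_w[:, 0]], axis=1)
        dm = p_i - p_o
        length = np.hypot(dm[:, 0], dm[:, 1])
        if np.any(length < 1e-9):
            raise FloatingPointError("degenerate muscle geometry (coincident points)")
        u_vec = dm / length[:, None]
        ldot = np.einsum("ij,ij->i", v_i - v_o, u_vec)
        na = float(active_state(max(t_ms, 0.0), sys.schedule))
        tension_n = 1e-3 * mus.tension_mn(na, length * 1e3, ldot * 1e3)
        f_m = tension_n[:, None] * u_vec          # on origin, toward insertion
        nb = n + 1
        F[:, 0] += np.bincount(ob, f_m[:, 0], nb) - np.bincount(ib, f_m[:, 0], nb)
        F[:, 1] += np.bincount(ob, f_m[:, 1], nb) - np.bincount(ib, f_m[:, 1], nb)
        T += np.bincount(ob, ro_w[:, 0] * f_m[:, 1] - ro_w[:, 1] * f_m[:, 0], nb)
        T -= np.bincount(ib, ri_w[:, 0] * f_m[:, 1] - ri_w[:, 1] * f_m[:, 0], nb)

    grav = sys.gravity if include_gravity is None else include_gravity
    if grav:
        F[:n, 1] -= sys.masses * _G
    return F, T


def _deriv(sys: System, profile: AccelerationProfile, t_ms: float, state: np.ndarray) -> np.ndarray:
    n = sys.n
    F, T = assemble_forces(sys, profile, t_ms, state)
    out = np.empty_like(state)
    out[: 2 * n] = state[3 * n : 5 * n]           # d pos = vel
    out[2 * n : 3 * n] = state[5 * n : 6 * n]     # d theta = omega
    out[3 * n : 5 * n] = (F[:n] / sys.masses[:, None]).ravel()
    out[5 * n : 6 * n] = T[:n] / sys.inertias
    # time unit: state rates are per second, integrator steps in ms
    return out


@dataclass
class Trajectory:
    """Uniformly sampled planar states of the free bodies over the event."""

    t_ms: np.ndarray            # (ns,)
    pos: np.ndarray             # (ns, n, 2) m
    theta: np.ndarray           # (ns, n) rad
    vel: np.ndarray             # (ns, n, 2) m/s
    omega: np.ndarray           # (ns, n) rad/s
    base_y: np.ndarray          # (ns,) m
    scenario: str
    body_labels: list[str]
    dt_ms: float
    meta: dict[str, Any] = field(default_factory=dict)
    energy: dict[str, np.ndarray] | None = None

    def to_frame(self):
        """Wide CSV layout: t_ms then per-body x_m, y_m, theta_rad triples."""
        import pandas as pd

        data: dict[str, np.ndarray] = {"t_ms": self.t_ms}
        for i, lab in enumerate(self.body_labels):
            data[f"{lab}_x_m"] = self.pos[:, i, 0]
            data[f"{lab}_y_m"] = self.pos[:, i, 1]
            data[f"{lab}_theta_rad"] = self.theta[:, i]
        data["base_y_m"] = self.base_y
        return pd.DataFrame(data)


def _elastic_energy(sys: System, t_ms: float, state: np.ndarray, profile: AccelerationProfile) -> float:
    n = sys.n
    pos, th, _, _ = _body_kinematics(sys, t_ms, state, profile)
    up, low = sys.j_up, sys.j_low
    p_u = pos[up] + _rot(th[up], sys.r_up)
    p_l = pos[low] + _rot(th[low], sys.r_low)
    d = p_u - p_l
    cl, sl = np.cos(th[low]), np.sin(th[low])
    dx = cl * d[:, 0] + sl * d[:, 1]
    dy = -sl * d[:, 0] + cl * d[:, 1]
    th_rel = th[up] - th[low] - sys.neutral
    k_rot = np.where(th_rel < 0.0, sys.k_flex, sys.k_ext)
    return float(
        np.sum(0.5 * sys.k_shear * dx * dx + 0.5 * sys.k_axial * dy * dy)
        + np.sum(0.5 * k_rot * th_rel * th_rel)
    )


def simulate(
    system: System,
    profile: AccelerationProfile,
    dt: float = 0.01,
    total: float | None = None,
    sample_interval: float = 0.5,
    track_energy: bool = False,
    energy_drift_tol: float | None = None,
) -> Trajectory:
    """Integrate the system over the event with fixed-step RK4.

    ``dt`` and ``sample_interval`` are in ms; ``total`` defaults to the
    profile duration.  Raises on non-finite states (instability) and, when
    ``energy_drift_tol`` is given in the undamped test mode, on relative
    energy drift beyond the tolerance.
    """
    if dt > 0.02:
        raise ValueError("dt must be <= 0.02 ms (penalty-bushing stability guard)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if sample_interval > 1.0 + 1e-12:
        raise ValueError("sample_interval must be <= 1 ms")
    total = profile.total_duration if total is None else total
    steps_per_sample = max(1, int(round(sample_interval / dt)))
    sample_interval = steps_per_sample * dt
    n_samples = int(round(total / sample_interval))
    n = system.n

    state = system.initial_state()
    t = 0.0
    ts = np.empty(n_samples + 1)
    pos = np.empty((n_samples + 1, n, 2))
    th = np.empty((n_samples + 1, n))
    vel = np.empty((n_samples + 1, n, 2))
    om = np.empty((n_samples + 1, n))
    base_y = np.empty(n_samples + 1)

    e_kin = e_pot = w_base = None
    if track_energy:
        e_kin = np.empty(n_samples + 1)
        e_pot = np.empty(n_samples + 1)
        w_base = np.empty(n_samples + 1)
    work_acc = 0.0

    def record(k: int) -> None:
        ts[k] = t
        pos[k] = state[: 2 * n].reshape(n, 2)
        th[k] = state[2 * n : 3 * n]
        vel[k] = state[3 * n : 5 * n].reshape(n, 2)
        om[k] = state[5 * n : 6 * n]
        base_y[k] = system.base_com0[1] + base_state(t, profile)[2]
        if track_energy:
            e_kin[k] = float(
                0.5 * np.sum(system.masses[:, None] * vel[k] ** 2)
                + 0.5 * np.sum(system.inertias * om[k] ** 2)
            )
            e_pot[k] = _elastic_energy(system, t, state, profile)
            w_base[k] = work_acc

    record(0)
    dts = dt * 1e-3  # state rates are per second
    for k in range(1, n_samples + 1):
        for _ in range(steps_per_sample):
            if track_energy:
                fb, _ = assemble_forces(system, profile, t, state)
                v0 = base_state(t, profile)[1]
            k1 = _deriv(system, profile, t, state)
            k2 = _deriv(system, profile, t + dt / 2, state + 0.5 * dts * k1)
            k3 = _deriv(system, profile, t + dt / 2, state + 0.5 * dts * k2)
            k4 = _deriv(system, profile, t + dt, state + dts * k3)
            state = state + (dts / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
            if track_energy:
                fb2, _ = assemble_forces(system, profile, t, state)
                v1 = base_state(t, profile)[1]
                # F[n] is the force the chain exerts on the base; the base
                # drives the chain with its negative, working at v_base
                work_acc += 0.5 * dts * ((-fb[n, 1]) * v0 + (-fb2[n, 1]) * v1)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"non-finite state at t = {t:.3f} ms ({system.scenario})")
        record(k)

    energy = None
    if track_energy:
        energy = {"kinetic": e_kin, "elastic": e_pot, "base_work": w_base}
        if energy_drift_tol is not None:
            total_e = e_kin + e_pot - w_base
            scale = max(np.max(e_kin), np.max(e_pot), np.max(np.abs(w_base)), 1e-12)
            drift = np.max(np.abs(total_e - total_e[0])) / scale
            if drift > energy_drift_tol:
                raise FloatingPointError(
                    f"energy drift {drift:.2e} exceeds tolerance {energy_drift_tol:.2e}"
                )

    return Trajectory(
        t_ms=ts,
        pos=pos,
        theta=th,
        vel=vel,
        omega=om,
        base_y=base_y,
        scenario=system.scenario,
        body_labels=[b.label for b in system.anatomy.bodies],
        dt_ms=dt,
        meta={
            "method": "rk4-fixed",
            "dt_ms": dt,
            "steps": n_samples * steps_per_sample,
            "sample_interval_ms": sample_interval,
            "scenario": system.scenario,
            "gravity": system.gravity,
        },
        energy=energy,
    )
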