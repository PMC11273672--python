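"""Prescribed base (T1) acceleration for the ejection event.

The default profile ramps linearly from rest at 125 G/s for 80 ms, reaching
a 10 G plateau that is held for the remaining 70 ms of the 150 ms event.
The base is kinematically driven: its velocity and position are the exact
piecewise-polynomial integrals of the piecewise-linear acceleration, so the
dynamics layer can evaluate the base state at arbitrary solver times without
quadrature error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AccelerationProfile", "acceleration_at", "base_motion", "base_state"]


@dataclass(frozen=True)
class AccelerationProfile:
    """Ramp-then-plateau vertical acceleration, expressed in G.

    ``ramp_rate`` G/s over ``ramp_end`` ms, then constant ``plateau`` G up
    to ``total_duration`` ms.  ``g_value`` converts G to m/s^2.
    """

    ramp_rate: float = 125.0
    ramp_end: float = 80.0
    plateau: float = 10.0
    total_duration: float = 150.0
    g_value: float = 9.81

    def __post_init__(self) -> None:
        if self.ramp_end < 0 or self.total_duration < self.ramp_end:
            raise ValueError("require 0 <= ramp_end <= total_duration")
        if self.g_value <= 0:
            raise ValueError("g_value must be positive")


def acceleration_at(t, profile: AccelerationProfile):
    """Base acceleration in G at time ``t`` (ms); scalar or array.

    Raises for times outside [0, total_duration].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > profile.total_duration):
        raise ValueError(
            f"time outside [0, {profile.total_duration}] ms in acceleration_at"
        )
    out = np.where(
        t <= profile.ramp_end, profile.ramp_rate * t * 1e-3, profile.plateau
    )
    return float(out) if out.ndim == 0 else out


def base_state(t_ms, profile: AccelerationProfile):
    """Exact (a, v, y) of the driven base at ``t_ms``, in SI units.

    During the ramp the acceleration is linear in t, so v is quadratic and
    y cubic; past the ramp both continue analytically under the constant
    plateau.  Accepts scalars or arrays.
    """
    t = np.asarray(t_ms, dtype=float) * 1e-3          # s
    te = profile.ramp_end * 1e-3                      # s
    r = profile.ramp_rate * profile.g_value           # m/s^3
    ap = profile.plateau * profile.g_value            # m/s^2
    ramp = t <= te
    tc = np.minimum(t, te)
    a = np.where(ramp, r * t, ap)
    v_ramp_end = 0.5 * r * te * te
    y_ramp_end = r * te**3 / 6.0
    dt = t - te
    v = np.where(ramp, 0.5 * r * tc * tc, v_ramp_end + ap * dt)
    y = np.where(
        ramp, r * tc**3 / 6.0, y_ramp_end + v_ramp_end * dt + 0.5 * ap * dt * dt
    )
    if a.ndim == 0:
        return float(a), float(v), float(y)
    return a, v, y


def base_motion(profile: AccelerationProfile, dt: float) -> pd.DataFrame:
    """Sampled base kinematics on a uniform grid of spacing ``dt`` ms.

    Columns: ``t_ms``, ``a_G``, ``a_m_s2``, ``v_m_s``, ``y_m``.  Values are
    closed-form, not numerically integrated.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(profile.total_duration / dt))
    t = np.linspace(0.0, n * dt, n + 1)
    t = t[t <= profile.total_duration + 1e-12]
    a, v, y = base_state(t, profile)
    return pd.DataFrame(
        {
            "t_ms": t,
            "a_G": a / profile.g_value,
            "a_m_s2": a,
            "v_m_s": v,
            "y_m": y,
        }
    )
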