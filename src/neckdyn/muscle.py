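"""Hill-type discrete muscle-bundle mechanics.

Each neck muscle group is represented by one or more straight-line
spring-damper bundles.  The active (contractile) tension of a bundle is

    F_CE(t) = fmax * Na(t) * F_L(L) * F_v(V)

where ``Na`` is the neural active state (zero during the reflex latency),
``F_L`` the normalised active force-length curve and ``F_v`` the normalised
force-velocity curve.  A parallel elastic element adds passive tension when
the bundle is stretched beyond its rest length ``lo``; it is disabled
(``fpe_scale = 0``) by default, matching the spring-damper muscle material
this module emulates.

Units follow the tabulated material convention: lengths mm, velocities mm/s,
forces kg*mm/s^2 (i.e. millinewtons).  The dynamics layer converts to SI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "MuscleParams",
    "ActivationSchedule",
    "active_state",
    "force_length",
    "force_velocity",
    "contractile_force",
    "passive_force",
    "bundle_force_on_bodies",
    "load_muscle_table",
    "default_muscle_table",
]

log = logging.getLogger(__name__)

# Ratio vmax/lo shared by every packaged bundle except one (see
# load_muscle_table); used only to emit a validation warning.
_VMAX_LO_RATIO = 11.0


@dataclass(frozen=True)
class MuscleParams:
    """Parameter record for one muscle bundle.

    ``fmax`` is the peak isometric force in kg*mm/s^2 (millinewtons); ``lo``
    the rest (optimum) length in mm; ``vmax`` the maximum contractile
    shortening velocity in mm/s.  ``pcsa`` (mm^2) is carried as metadata
    only: the tabulated ``fmax`` fully determines force.
    """

    name: str
    lo: float
    vmax: float
    fmax: float
    pcsa: float
    sv: float = 1.0
    fpe_scale: float = 0.0
    lmax: float = 0.8
    ksh: float = 2.0
    fl_width: float = 0.5
    fv_curvature: float = 0.25
    fv_plateau: float = 1.3
    fv_shape: float = 0.15
    group: str = ""

    def __post_init__(self) -> None:
        if not (self.lo > 0 and self.vmax > 0 and self.fmax > 0 and self.pcsa > 0):
            raise ValueError(
                f"muscle {self.name!r}: lo, vmax, fmax, pcsa must be positive"
            )
        if self.fpe_scale < 0 or self.lmax <= 0 or self.ksh <= 0:
            raise ValueError(
                f"muscle {self.name!r}: require fpe_scale >= 0, lmax > 0, ksh > 0"
            )
        if self.fl_width <= 0 or self.fv_curvature <= 0 or self.fv_plateau < 1:
            raise ValueError(f"muscle {self.name!r}: invalid curve-shape constants")


@dataclass(frozen=True)
class ActivationSchedule:
    """Neural active-state profile Na(t).

    Zero before ``reflex_time`` (ms), then rises over ``rise_time`` (ms) to
    ``plateau`` and stays there.  ``shape`` selects a linear ramp or an
    exponential-saturation ramp (both reach ``plateau`` exactly at
    ``reflex_time + rise_time``).
    """

    reflex_time: float = 80.0
    rise_time: float = 20.0
    plateau: float = 1.0
    shape: str = "linear"
    exp_rate: float = 3.0  # only for shape="exponential-saturation"

    def __post_init__(self) -> None:
        if self.reflex_time < 0 or self.rise_time < 0:
            raise ValueError("reflex_time and rise_time must be >= 0")
        if not 0.0 <= self.plateau <= 1.0:
            raise ValueError("plateau must lie in [0, 1]")
        if self.shape not in ("linear", "exponential-saturation"):
            raise ValueError(f"unknown activation shape {self.shape!r}")


def active_state(t, schedule: ActivationSchedule):
    """Active state Na(t) in [0, plateau] at time ``t`` (ms).

    Accepts scalars or arrays; raises for negative times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("active_state: t must be >= 0")
    if schedule.rise_time == 0:
        u = (t >= schedule.reflex_time).astype(float)
    else:
        u = np.clip((t - schedule.reflex_time) / schedule.rise_time, 0.0, 1.0)
        if schedule.shape == "exponential-saturation":
            k = schedule.exp_rate
            u = -np.expm1(-k * u) / -math.expm1(-k)
    out = schedule.plateau * u
    return float(out) if out.ndim == 0 else out


def force_length(length, params: MuscleParams):
    """Normalised active force-length factor: quadratic bell, 1 at lo.

    Zero outside ``lo * (1 +/- fl_width)``.
    """
    length = np.asarray(length, dtype=float)
    x = (length / params.lo - 1.0) / params.fl_width
    out = np.maximum(0.0, 1.0 - x * x)
    return float(out) if out.ndim == 0 else out


def force_velocity(velocity, params: MuscleParams, activation: float = 1.0):
    """Normalised force-velocity factor.

    ``velocity`` is the bundle lengthening rate in mm/s (shortening
    negative).  Classic Hill hyperbola on the concentric side — zero at the
    maximum shortening velocity ``-sv*vmax`` — and a saturating eccentric
    branch bounded by ``fv_plateau``.  ``activation`` is accepted for
    interface symmetry; with the default ``sv`` the curve does not depend
    on it.
    """
    velocity = np.asarray(velocity, dtype=float)
    u = velocity / (params.sv * params.vmax)
    c = params.fv_curvature
    p = params.fv_plateau
    b = params.fv_shape
    conc = np.maximum(0.0, (1.0 + u) / (1.0 - u / c))
    ecc = p - (p - 1.0) * b / (b + np.maximum(u, 0.0))
    out = np.where(u <= 0.0, conc, ecc)
    return float(out) if out.ndim == 0 else out


def contractile_force(
    t, length, velocity, params: MuscleParams, schedule: ActivationSchedule
):
    """Contractile-element tension fmax * Na(t) * F_L * F_v, in mN (>= 0)."""
    na = active_state(t, schedule)
    out = (
        params.fmax
        * na
        * force_length(length, params)
        * force_velocity(velocity, params, na)
    )
    out = np.maximum(0.0, out)
    return float(out) if np.ndim(out) == 0 else out


def passive_force(length, params: MuscleParams):
    """Parallel-elastic tension in mN.

    Slack at and below the rest length; exponential rise beyond it, scaled so
    the tension equals ``fpe_scale * fmax`` exactly at relative stretch
    ``lmax`` (i.e. at length ``lo * (1 + lmax)``).
    """
    length = np.asarray(length, dtype=float)
    strain = np.maximum(0.0, length / params.lo - 1.0)
    out = (
        params.fpe_scale
        * params.fmax
        * np.expm1((params.ksh / params.lmax) * strain)
        / math.expm1(params.ksh)
    )
    return float(out) if out.ndim == 0 else out


def bundle_force_on_bodies(
    point_a: Sequence[float],
    point_b: Sequence[float],
    params: MuscleParams,
    schedule: ActivationSchedule,
    t: float,
    vel_a: Sequence[float] = (0.0, 0.0),
    vel_b: Sequence[float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-and-opposite tension forces on the two attachment points.

    Points and velocities are world-frame, in mm and mm/s.  Returns
    ``(force_on_a, force_on_b)`` in mN; the pair pulls the points together,
    so its net force and net moment on the system are zero.
    """
    pa = np.asarray(point_a, dtype=float)
    pb = np.asarray(point_b, dtype=float)
    d = pb - pa
    length = float(np.hypot(*d))
    if length < 1e-9:
        raise ValueError(f"muscle {params.name!r}: coincident attachment points")
    u = d / length
    # lengthening rate = projection of relative velocity on the line of action
    ldot = float(np.dot(np.asarray(vel_b, float) - np.asarray(vel_a, float), u))
    tension = contractile_force(t, length, ldot, params, schedule) + passive_force(
        length, params
    )
    f_on_a = tension * u       # pulls a toward b
    return f_on_a, -f_on_a


def _default_table_path() -> Path:
    return Path(resources.files("neckdyn") / "data" / "muscles.yaml")


def load_muscle_table(path: str | Path | None = None) -> list[MuscleParams]:
    """Load a muscle parameter file; with no path, the packaged defaults.

    The file carries one record per bundle (keys ``lo_mm``, ``vmax_mm_s``,
    ``fmax_kg_mm_s2``, ``pcsa_mm2``) plus the shared globals.  Bundle names
    are ``<group>_<lo>mm``; a validation warning is logged for any record
    whose vmax deviates from the 11/ms * lo pattern shared by the rest of
    the packaged table (the 60 mm longus colli row is tabulated as 650 mm/s
    and is kept as printed).
    """
    raw = yaml.safe_load(Path(path or _default_table_path()).read_text())
    if raw.get("schema") != "neckdyn-muscles-1":
        raise ValueError("unrecognised muscle table schema")
    g = raw["globals"]
    bundles: list[MuscleParams] = []
    for row in raw["bundles"]:
        lo = float(row["lo_mm"])
        vmax = float(row["vmax_mm_s"])
        rec = MuscleParams(
            name=f"{row['group']}_{lo:g}mm",
            group=row["group"],
            lo=lo,
            vmax=vmax,
            fmax=float(row["fmax_kg_mm_s2"]),
            pcsa=float(row["pcsa_mm2"]),
            sv=float(g["sv"]),
            fpe_scale=float(g["fpe_scale"]),
            lmax=float(g["lmax"]),
            ksh=float(g["ksh"]),
            fl_width=float(g["fl_width"]),
            fv_curvature=float(g["fv_curvature"]),
            fv_plateau=float(g["fv_plateau"]),
            fv_shape=float(g["fv_shape"]),
        )
        if abs(vmax - _VMAX_LO_RATIO * lo) > 1e-9:
            log.warning(
                "muscle %s: vmax %.6g mm/s deviates from the %.1f/ms * lo pattern "
                "(kept as tabulated)",
                rec.name,
                vmax,
                _VMAX_LO_RATIO,
            )
        bundles.append(rec)
    names = [b.name for b in bundles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate bundle names in muscle table")
    return bundles


def default_muscle_table() -> list[MuscleParams]:
    """The packaged 19-bundle / 13-group default table."""
    return load_muscle_table(None)


def muscle_groups(bundles: Iterable[MuscleParams]) -> list[str]:
    """Distinct group labels, in first-appearance order."""
    seen: dict[str, None] = {}
    for b in bundles:
        seen.setdefault(b.group or b.name, None)
    return list(seen)
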