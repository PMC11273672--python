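"""Synthetic sagittal-plane anatomy: the rigid-body surrogate skeleton.

The head-neck complex is modelled as a chain of rigid bodies — the skull
(C0) and vertebrae C1-C7 — stacked above a kinematically driven T1 base.
Adjacent bodies are coupled by visco-elastic bushing joints that lump the
compliance of the disc, ligaments and facets of one motion segment, and the
muscle bundles run as straight lines between attachment sites on the bodies.

No subject geometry is imported: masses, inertias, spacings and attachment
sites are literature-typical adult-male surrogate values declared in
:class:`AnatomyConfig`.  Two geometric choices carry the qualitative
physics:

* the head centre of mass sits anterior of the C0-C1 pivot, so a vertical
  base acceleration produces a head flexion moment;
* each joint pivot is placed relative to the mass line of the bodies it
  supports (``joint_arm_mm``, anterior positive), giving the upper joints a
  flexion bias and the lower joints a small extension bias — the planar
  analogue of a lordotic column loaded in axial compression, which is what
  produces the early inverted-S curvature.

Muscle attachment x-offsets are solved at assembly so that every bundle's
straight-line length equals its tabulated rest length exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .muscle import MuscleParams, default_muscle_table

__all__ = [
    "AnatomyConfig",
    "RigidBodySpec",
    "JointSpec",
    "MuscleRoute",
    "Anatomy",
    "generate_anatomy",
    "BODY_LABELS",
    "JOINT_LABELS",
]

BODY_LABELS = ["C0", "C1", "C2", "C3", "C4", "C5", "C6", "C7"]
BASE_LABEL = "T1"
JOINT_LABELS = [
    "C0-C1", "C1-C2", "C2-C3", "C3-C4", "C4-C5", "C5-C6", "C6-C7", "C7-T1",
]


@dataclass
class AnatomyConfig:
    """Tunable surrogate parameters (mm / kg / SI as suffixed).

    ``joint_arm_mm[j]`` is the anterior offset of the supported-mass centroid
    line from joint pivot ``j`` (order C0-C1 ... C7-T1): positive arms give
    that joint a flexion moment under upward base acceleration, negative
    arms an extension moment.  ``joint_stiffness_nm_rad`` are the base
    rotational stiffnesses, multiplied elementwise by ``joint_scale`` (the
    product of calibration).
    """

    spacing_c0_c2_mm: float = 22.0
    spacing_c2_c7_mm: float = 19.0
    lordosis_apex_mm: float = 4.0
    head_mass_kg: float = 4.5
    head_com_anterior_mm: float = 10.0
    head_com_up_mm: float = 60.0
    head_inertia_kg_m2: float = 0.018
    vertebra_mass_kg: float = 0.25
    vertebra_inertia_kg_m2: float = 5.0e-4
    joint_arm_mm: list[float] = field(
        default_factory=lambda: [8.5, 9.0, 2.0, 1.2, -1.2, -2.0, -1.8, -0.9]
    )
    joint_stiffness_nm_rad: list[float] = field(
        default_factory=lambda: [1.5, 1.5, 1.9, 2.1, 2.4, 2.6, 2.8, 3.0]
    )
    joint_scale: list[float] = field(default_factory=lambda: [1.0] * 8)
    extension_stiffness_ratio: float = 1.0
    damping_ratio: float = 1.0
    k_axial_n_m: float = 6.0e5
    k_shear_n_m: float = 4.0e5
    c_trans_n_s_m: float = 600.0
    bilateral_factor: float = 2.0
    attachment_jitter_mm: float = 0.25
    gravity: bool = False

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnatomyConfig":
        cfg = cls(**dict(d))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if len(self.joint_arm_mm) != 8 or len(self.joint_stiffness_nm_rad) != 8:
            raise ValueError("joint_arm_mm and joint_stiffness_nm_rad need 8 entries")
        if len(self.joint_scale) != 8:
            raise ValueError("joint_scale needs 8 entries")
        if any(k <= 0 for k in self.joint_stiffness_nm_rad):
            raise ValueError("joint stiffnesses must be positive")
        if any(s <= 0 for s in self.joint_scale):
            raise ValueError("joint scales must be positive")
        if self.head_mass_kg <= 0 or self.vertebra_mass_kg <= 0:
            raise ValueError("masses must be positive")
        if self.damping_ratio < 0:
            raise ValueError("damping_ratio must be >= 0")


@dataclass
class RigidBodySpec:
    label: str
    mass: float          # kg
    inertia: float       # kg m^2 about the centroid, sagittal axis
    com: np.ndarray      # world (x anterior, y up), m, at assembly

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)
        if self.mass <= 0 or self.inertia <= 0:
            raise ValueError(f"body {self.label}: mass and inertia must be positive")


@dataclass
class JointSpec:
    label: str
    upper: str
    lower: str
    point: np.ndarray    # world pivot, m, at assembly
    k_flex: float        # N m / rad
    k_ext: float
    c_rot: float         # N m s / rad
    k_axial: float       # N / m
    k_shear: float
    c_trans: float       # N s / m
    neutral: float = 0.0

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        for v in (self.k_flex, self.k_ext, self.k_axial, self.k_shear):
            if v < 0:
                raise ValueError(f"joint {self.label}: stiffness must be >= 0")


@dataclass
class MuscleRoute:
    bundle: str
    origin_body: str       # T1 or a vertebra label
    origin_point: np.ndarray    # world, m, at assembly
    insertion_body: str
    insertion_point: np.ndarray

    def __post_init__(self) -> None:
        self.origin_point = np.asarray(self.origin_point, dtype=float)
        self.insertion_point = np.asarray(self.insertion_point, dtype=float)

    @property
    def length_m(self) -> float:
        return float(np.hypot(*(self.insertion_point - self.origin_point)))


@dataclass
class Anatomy:
    """Complete surrogate: bodies (C0 superior ... C7), T1 base, joints, routes."""

    bodies: list[RigidBodySpec]
    base: RigidBodySpec
    joints: list[JointSpec]
    routes: list[MuscleRoute]
    seed: int
    config: AnatomyConfig
    meta: dict[str, Any] = field(default_factory=dict)

    def body_index(self, label: str) -> int:
        if label == self.base.label:
            return len(self.bodies)
        for i, b in enumerate(self.bodies):
            if b.label == label:
                return i
        raise KeyError(f"unknown body {label!r}")

    def joint(self, label: str) -> JointSpec:
        for j in self.joints:
            if j.label == label:
                return j
        raise KeyError(f"unknown joint {label!r}")

    def validate(self, muscles: Sequence[MuscleParams] | None = None) -> None:
        labels = [b.label for b in self.bodies]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate body labels")
        if len(self.joints) != len(self.bodies):
            raise ValueError("expect one joint per body (chain to base)")
        if muscles is not None:
            by_name = {m.name: m for m in muscles}
            for r in self.routes:
                if r.bundle not in by_name:
                    raise ValueError(f"route for unknown bundle {r.bundle!r}")
                lo_m = by_name[r.bundle].lo * 1e-3
                if abs(r.length_m - lo_m) > 0.02 * lo_m:
                    raise ValueError(
                        f"bundle {r.bundle}: assembled length {r.length_m * 1e3:.2f} mm "
                        f"deviates >2% from lo {lo_m * 1e3:.2f} mm"
                    )

    # ---------------- serialisation ----------------

    def to_dict(self) -> dict[str, Any]:
        def arr(a: np.ndarray) -> list[float]:
            return [round(float(v), 9) for v in a]

        return {
            "schema": "neckdyn-anatomy-1",
            "seed": int(self.seed),
            "config": self.config.to_dict(),
            "meta": self.meta,
            "base": {
                "label": self.base.label,
                "mass": self.base.mass,
                "inertia": self.base.inertia,
                "com": arr(self.base.com),
            },
            "bodies": [
                {
                    "label": b.label,
                    "mass": round(float(b.mass), 9),
                    "inertia": round(float(b.inertia), 12),
                    "com": arr(b.com),
                }
                for b in self.bodies
            ],
            "joints": [
                {
                    "label": j.label,
                    "upper": j.upper,
                    "lower": j.lower,
                    "point": arr(j.point),
                    "k_flex": round(float(j.k_flex), 9),
                    "k_ext": round(float(j.k_ext), 9),
                    "c_rot": round(float(j.c_rot), 9),
                    "k_axial": float(j.k_axial),
                    "k_shear": float(j.k_shear),
                    "c_trans": float(j.c_trans),
                    "neutral": float(j.neutral),
                }
                for j in self.joints
            ],
            "routes": [
                {
                    "bundle": r.bundle,
                    "origin_body": r.origin_body,
                    "origin_point": arr(r.origin_point),
                    "insertion_body": r.insertion_body,
                    "insertion_point": arr(r.insertion_point),
                }
                for r in self.routes
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=None)
        )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Anatomy":
        if d.get("schema") != "neckdyn-anatomy-1":
            raise ValueError("unrecognised anatomy schema")
        cfg = AnatomyConfig.from_dict(d["config"])
        base = RigidBodySpec(**{k: d["base"][k] for k in ("label", "mass", "inertia", "com")})
        bodies = [
            RigidBodySpec(b["label"], b["mass"], b["inertia"], b["com"])
            for b in d["bodies"]
        ]
        joints = [
            JointSpec(
                j["label"], j["upper"], j["lower"], j["point"], j["k_flex"],
                j["k_ext"], j["c_rot"], j["k_axial"], j["k_shear"], j["c_trans"],
                j.get("neutral", 0.0),
            )
            for j in d["joints"]
        ]
        routes = [
            MuscleRoute(
                r["bundle"], r["origin_body"], r["origin_point"],
                r["insertion_body"], r["insertion_point"],
            )
            for r in d["routes"]
        ]
        return cls(bodies, base, joints, routes, int(d["seed"]), cfg, dict(d.get("meta", {})))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Anatomy":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def attachment_table(self):
        """Per-route world attachment coordinates, for inspection dumps."""
        import pandas as pd

        rows = []
        for r in self.routes:
            rows.append(
                {
                    "bundle": r.bundle,
                    "origin_body": r.origin_body,
                    "origin_x_mm": r.origin_point[0] * 1e3,
                    "origin_y_mm": r.origin_point[1] * 1e3,
                    "insertion_body": r.insertion_body,
                    "insertion_x_mm": r.insertion_point[0] * 1e3,
                    "insertion_y_mm": r.insertion_point[1] * 1e3,
                    "length_mm": r.length_m * 1e3,
                }
            )
        return pd.DataFrame(rows)


# Default straight-line routing, one entry per packaged bundle:
# (origin body, origin dy mm, origin x mm, insertion body, insertion dy mm,
#  insertion x mm).  dy is measured from the body centroid (for C0, from the
#  head centre of mass); x values are nominal world offsets (anterior +).
# At assembly the horizontal span is re-solved so the bundle length equals
# its tabulated rest length exactly, keeping the nominal midline and the
# nominal anterior/posterior slant direction.
_DEFAULT_ROUTES: dict[str, tuple[str, float, float, str, float, float]] = {
    "sternocleidomastoid_180mm": ("T1", -18.0, 51.91, "C0", 13.0, 23.91),
    "longus_colli_60mm": ("T1", 0.0, 12.5, "C5", 0.0, -4.5),
    "longus_colli_15mm": ("C2", 8.0, 7.5, "C1", -8.0, -5.5),
    "longus_colli_40mm": ("C4", 0.0, 29.0, "C2", 0.0, 41.0),
    "longus_capitis_85mm": ("C4", 0.0, 34.0, "C0", 8.0, 3.0),
    "longus_capitis_55mm": ("C2", -10.0, -6.5, "C0", 8.0, 14.5),
    "scalenus_anterior_110mm": ("T1", -30.0, 3.82, "C4", 0.0, 32.82),
    "scalenus_anterior_80mm": ("T1", -20.0, -7.0, "C5", 0.0, 15.0),
    "scalenus_medius_65mm": ("T1", -5.0, -8.0, "C5", 0.0, 12.0),
    "scalenus_posterior_60mm": ("T1", 0.0, -32.5, "C6", 18.0, -11.5),
    "trapezius_160mm": ("T1", 0.0, 5.26, "C0", 8.0, -34.74),
    "semispinalis_capitis_120mm": ("C6", 0.0, -6.31, "C0", 8.0, -33.31),
    "semispinalis_capitis_90mm": ("C4", 0.0, -39.13, "C0", 8.0, 3.87),
    "semispinalis_cervicis_80mm": ("T1", 0.0, -42.5, "C4", 0.0, -17.5),
    "longissimus_capitis_115mm": ("C6", 10.0, 1.97, "C0", 8.0, -40.03),
    "longissimus_capitis_75mm": ("C3", -10.0, -49.5, "C0", 8.0, -22.5),
    "longissimus_cervicis_75mm": ("T1", -30.0, -22.0, "C6", 0.0, -54.0),
    "splenius_capitis_175mm": ("T1", -15.0, -0.73, "C0", 8.0, -41.73),
    "splenius_cervicis_110mm": ("T1", 0.0, -22.5, "C2", -8.0, 6.5),
}


def _config_hash(cfg: AnatomyConfig, seed: int) -> str:
    payload = json.dumps({"seed": seed, "config": cfg.to_dict()}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def generate_anatomy(
    seed: int,
    config: AnatomyConfig | None = None,
    muscles: Sequence[MuscleParams] | None = None,
    route_table: Mapping[str, tuple] | None = None,
) -> Anatomy:
    """Build the surrogate anatomy; deterministic for a given (seed, config).

    The seed drives only a small jitter (``attachment_jitter_mm``) on the
    muscle side offsets, emulating subject-to-subject attachment scatter
    without perturbing the solved bundle lengths.
    """
    cfg = config or AnatomyConfig()
    cfg.validate()
    muscles = list(muscles) if muscles is not None else default_muscle_table()
    rng = np.random.default_rng(seed)

    mm = 1e-3
    # centroid heights, T1 = 0 (y up)
    y = {"T1": 0.0}
    for i, lab in enumerate(["C7", "C6", "C5", "C4", "C3", "C2"]):
        y[lab] = (i + 1) * cfg.spacing_c2_c7_mm
    y["C1"] = y["C2"] + cfg.spacing_c0_c2_mm

    # mild lordotic arc for the vertebral centroids (anterior = +x)
    arc_labels = ["T1", "C7", "C6", "C5", "C4", "C3", "C2", "C1"]
    x = {
        lab: cfg.lordosis_apex_mm * np.sin(np.pi * i / (len(arc_labels) - 1))
        for i, lab in enumerate(arc_labels)
    }

    pivot_c0c1_y = y["C1"] + cfg.spacing_c0_c2_mm / 2.0
    # C0-C1 pivot x comes from the joint-arm rule below; head com hangs off it
    # provisionally above C1, corrected after pivots are known.
    masses = {lab: cfg.vertebra_mass_kg for lab in BODY_LABELS[1:]}
    masses["C0"] = cfg.head_mass_kg
    inertias = {lab: cfg.vertebra_inertia_kg_m2 for lab in BODY_LABELS[1:]}
    inertias["C0"] = cfg.head_inertia_kg_m2

    # Joint pivots: y midway between neighbouring centroids; x placed so that
    # the supported-mass centroid line sits joint_arm_mm anterior of the
    # pivot.  The head com is defined relative to the C0-C1 pivot, which is
    # itself defined by the arm rule; solve that pair first.
    # x_head = x_pivot(C0-C1) + head_com_anterior and
    # x_pivot(C0-C1) = x_head - arm[0]  =>  arm[0] is head_com_anterior by
    # construction unless overridden; reconcile by anchoring the pivot above C1.
    pivot = {}
    pivot_y = {}
    lower_of = {"C0-C1": "C1", "C1-C2": "C2", "C2-C3": "C3", "C3-C4": "C4",
                "C4-C5": "C5", "C5-C6": "C6", "C6-C7": "C7", "C7-T1": "T1"}
    upper_of = {j: j.split("-")[0] for j in JOINT_LABELS}

    pivot_x_c0c1 = x["C1"]  # condyles above C1
    x["C0"] = pivot_x_c0c1 + cfg.head_com_anterior_mm
    y["C0"] = pivot_c0c1_y + cfg.head_com_up_mm

    # supported mass line per joint
    above: dict[str, list[str]] = {}
    for j, lab in enumerate(JOINT_LABELS):
        above[lab] = BODY_LABELS[: j + 1]

    for j, lab in enumerate(JOINT_LABELS):
        labs = above[lab]
        m_tot = sum(masses[b] for b in labs)
        xbar = sum(masses[b] * x[b] for b in labs) / m_tot
        pivot[lab] = xbar - cfg.joint_arm_mm[j]
        lo_lab, up_lab = lower_of[lab], upper_of[lab]
        if lab == "C0-C1":
            pivot_y[lab] = pivot_c0c1_y
        else:
            pivot_y[lab] = 0.5 * (y[lo_lab] + y[up_lab])

    bodies = [
        RigidBodySpec(lab, masses[lab], inertias[lab], np.array([x[lab], y[lab]]) * mm)
        for lab in BODY_LABELS
    ]
    base = RigidBodySpec(BASE_LABEL, 1.0, 1.0, np.array([x["T1"], y["T1"]]) * mm)

    # effective rotational inertia seen by each joint (bodies above, about
    # the pivot) -> near-critical damping c = 2 zeta sqrt(k I)
    joints: list[JointSpec] = []
    for j, lab in enumerate(JOINT_LABELS):
        k = cfg.joint_stiffness_nm_rad[j] * cfg.joint_scale[j]
        i_eff = 0.0
        for b in above[lab]:
            d2 = ((x[b] - pivot[lab]) ** 2 + (y[b] - pivot_y[lab]) ** 2) * mm * mm
            i_eff += inertias[b] + masses[b] * d2
        c_rot = 2.0 * cfg.damping_ratio * np.sqrt(k * i_eff)
        joints.append(
            JointSpec(
                label=lab,
                upper=upper_of[lab],
                lower=lower_of[lab],
                point=np.array([pivot[lab], pivot_y[lab]]) * mm,
                k_flex=k,
                k_ext=k * cfg.extension_stiffness_ratio,
                c_rot=c_rot,
                k_axial=cfg.k_axial_n_m,
                k_shear=cfg.k_shear_n_m,
                c_trans=cfg.c_trans_n_s_m,
            )
        )

    # muscle routing: solve horizontal offsets for exact rest lengths
    by_name = {m.name: m for m in muscles}
    routes: list[MuscleRoute] = []
    table = dict(route_table) if route_table is not None else _DEFAULT_ROUTES
    for name, (ob, o_dy, o_x, ib, i_dy, i_x) in table.items():
        if name not in by_name:
            continue
        lo = by_name[name].lo  # mm
        # C0 attachment heights are measured from the C0-C1 pivot (the
        # skull-base region), so they do not move with head_com_up_mm
        y_ref = {"C0": pivot_c0c1_y}
        yo = y_ref.get(ob, y[ob]) + o_dy
        yi = y_ref.get(ib, y[ib]) + i_dy
        dz = abs(yi - yo)
        if dz >= lo:
            raise ValueError(
                f"bundle {name}: vertical span {dz:.1f} mm exceeds rest length "
                f"{lo:.1f} mm — routing infeasible for this posture"
            )
        dx = float(np.sqrt(lo * lo - dz * dz))
        jitter = rng.normal(0.0, cfg.attachment_jitter_mm) if cfg.attachment_jitter_mm else 0.0
        mid = 0.5 * (o_x + i_x) + jitter
        sign = 1.0 if i_x >= o_x else -1.0
        xo = mid - sign * dx / 2.0
        xi = mid + sign * dx / 2.0
        routes.append(
            MuscleRoute(
                bundle=name,
                origin_body=ob,
                origin_point=np.array([xo, yo]) * mm,
                insertion_body=ib,
                insertion_point=np.array([xi, yi]) * mm,
            )
        )
    missing = set(by_name) - {r.bundle for r in routes}
    if missing:
        raise ValueError(f"no routing defined for bundles: {sorted(missing)}")

    anat = Anatomy(
        bodies=bodies,
        base=base,
        joints=joints,
        routes=routes,
        seed=int(seed),
        config=cfg,
        meta={"config_hash": _config_hash(cfg, seed), "provenance": "synthetic surrogate"},
    )
    anat.validate(muscles)
    return anat
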