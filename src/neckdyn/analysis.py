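"""Kinematic post-processing: segmental rotations, curvature labels, peaks,
and cross-scenario reduction tables.

Rotations are reported flexion-positive in degrees: flexion is the anterior
rotation of the superior body relative to its inferior neighbour.  Seven
per-joint series (C0-C1 ... C6-C7) are derived from each trajectory, plus
the compound C0-C2 (skull relative to C2 — the unit the upper-cervical peak
claims refer to) and the whole-column C0-C7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anatomy import Anatomy
from .dynamics import Trajectory

__all__ = [
    "RotationTimeSeries",
    "SEGMENTS",
    "segmental_rotations",
    "classify_curvature",
    "curvature_timeline",
    "peak_analysis",
    "reduction_table",
]

SEGMENTS = ["C0-C1", "C1-C2", "C2-C3", "C3-C4", "C4-C5", "C5-C6", "C6-C7"]
COMPOUND = ["C0-C2", "C0-C7"]

#: below this magnitude (degrees) a segment counts as neutral for curvature
#: classification, and a reduction against it is flagged undefined
DELTA_DEG = 0.1


@dataclass
class RotationTimeSeries:
    """One segment's relative sagittal rotation over the event."""

    segment: str
    t_ms: np.ndarray
    angle_deg: np.ndarray       # flexion positive

    def at(self, t: float) -> float:
        """Angle at time ``t`` ms (linear interpolation on the sample grid)."""
        return float(np.interp(t, self.t_ms, self.angle_deg))


def segmental_rotations(
    trajectory: Trajectory, anatomy: Anatomy
) -> dict[str, RotationTimeSeries]:
    """Flexion-positive rotation series for all segments of one run.

    Relative angle of segment ``A-B`` is theta_A - theta_B mapped to
    flexion-positive degrees (anterior tip of the superior body is a
    *negative* counterclockwise angle under the solver's convention).
    """
    labels = trajectory.body_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    out: dict[str, RotationTimeSeries] = {}
    for seg in SEGMENTS + COMPOUND:
        sup, inf = seg.split("-")
        if sup not in idx or inf not in idx:
            raise KeyError(f"trajectory lacks body {sup!r} or {inf!r} for segment {seg}")
        rel = trajectory.theta[:, idx[sup]] - trajectory.theta[:, idx[inf]]
        out[seg] = RotationTimeSeries(
            segment=seg,
            t_ms=trajectory.t_ms.copy(),
            angle_deg=-np.degrees(rel),
        )
    return out


def classify_curvature(
    rotations: Mapping[str, float], delta: float = DELTA_DEG
) -> str:
    """Label the instantaneous spine shape from the seven segmental angles.

    ``inverted-S``: both upper segments (C0-C1, C1-C2) flexed beyond +delta
    while at least one lower segment (C4-C5, C5-C6, C6-C7) is extended
    beyond -delta.  ``mirrored-C``: all seven segments flexed beyond +delta.
    Anything else is ``other``.
    """
    missing = [s for s in SEGMENTS if s not in rotations]
    if missing:
        raise KeyError(f"missing segments for classification: {missing}")
    vals = {s: float(rotations[s]) for s in SEGMENTS}
    upper_flexed = vals["C0-C1"] > delta and vals["C1-C2"] > delta
    lower_extended = any(vals[s] < -delta for s in ("C4-C5", "C5-C6", "C6-C7"))
    if upper_flexed and lower_extended:
        return "inverted-S"
    if all(vals[s] > delta for s in SEGMENTS):
        return "mirrored-C"
    return "other"


def curvature_timeline(
    rotations: Mapping[str, RotationTimeSeries], delta: float = DELTA_DEG
) -> pd.DataFrame:
    """Curvature label per sample time: columns ``t_ms``, ``label``."""
    t = rotations[SEGMENTS[0]].t_ms
    labels = [
        classify_curvature({s: rotations[s].angle_deg[k] for s in SEGMENTS}, delta)
        for k in range(len(t))
    ]
    return pd.DataFrame({"t_ms": t, "label": labels})


def peak_analysis(series: RotationTimeSeries) -> dict:
    """Global maximum of one series and its inverted-U character.

    The peak is the global maximum (earliest sample on ties).  The series is
    flagged inverted-U when that peak is interior to the window and the
    final value has dropped below 90% of it.
    """
    a = np.asarray(series.angle_deg, float)
    if a.size == 0:
        raise ValueError("empty rotation series")
    k = int(np.argmax(a))            # argmax returns the first maximum
    peak = float(a[k])
    interior = 0 < k < a.size - 1
    inverted_u = bool(interior and a[-1] < 0.9 * peak)
    return {
        "segment": series.segment,
        "peak_deg": peak,
        "peak_time_ms": float(series.t_ms[k]),
        "inverted_u": inverted_u,
    }


def _percent_reduction(ref: float, test: float) -> tuple[float, bool]:
    """(|ref| - |test|) / |ref| * 100; flagged undefined for tiny reference."""
    if abs(ref) < DELTA_DEG:
        return float("nan"), False
    return 100.0 * (abs(ref) - abs(test)) / abs(ref), True


def reduction_table(
    rotations_by_scenario: Mapping[str, Mapping[str, RotationTimeSeries]],
    at_time: float,
    pairs: Sequence[tuple[str, str]] = (
        ("active", "none"),
        ("passive", "none"),
        ("active", "passive"),
    ),
    segments: Sequence[str] = tuple(SEGMENTS),
) -> pd.DataFrame:
    """Per-segment rotations at ``at_time`` and pairwise percent reductions.

    Each ``(test, reference)`` pair contributes a column
    ``reduction_<test>_vs_<reference>_pct``; reductions compare rotation
    magnitudes, and are NaN (flagged) when the reference magnitude is below
    the neutral threshold.  Scenario runs must share anatomy: trajectories
    are compared on the same sampling grid.
    """
    scen = dict(rotations_by_scenario)
    grids = {k: v[segments[0]].t_ms for k, v in scen.items()}
    g0 = next(iter(grids.values()))
    for k, g in grids.items():
        if g.shape != g0.shape or not np.allclose(g, g0):
            raise ValueError(f"scenario {k!r} sampled on a different time grid")
    rows = []
    for seg in segments:
        row: dict[str, object] = {"segment": seg}
        for name, rot in scen.items():
            row[f"{name}_deg"] = rot[seg].at(at_time)
        for test, ref in pairs:
            if test not in scen or ref not in scen:
                continue
            red, ok = _percent_reduction(
                float(row[f"{ref}_deg"]), float(row[f"{test}_deg"])
            )
            row[f"reduction_{test}_vs_{ref}_pct"] = red
            row[f"reduction_{test}_vs_{ref}_defined"] = ok
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["at_time_ms"] = float(at_time)
    return df


def plot_rotations(
    rotations_by_scenario: Mapping[str, Mapping[str, RotationTimeSeries]],
    path: str,
    segments: Sequence[str] = tuple(SEGMENTS + COMPOUND),
) -> None:
    """Write a grid of rotation-time plots, one panel per segment, with one
    line per scenario.  Requires matplotlib (``pip install neckdyn[plot]``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncol = 3
    nrow = -(-len(segments) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.6 * nrow),
                             sharex=True, squeeze=False)
    for k, seg in enumerate(segments):
        ax = axes[k // ncol][k % ncol]
        for scen, rots in rotations_by_scenario.items():
            ax.plot(rots[seg].t_ms, rots[seg].angle_deg, label=scen, lw=1.2)
        ax.axhline(0.0, color="0.8", lw=0.6)
        ax.set_title(seg, fontsize=9)
    for k in range(len(segments), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    axes[0][0].legend(fontsize=8)
    fig.supxlabel("time (ms)")
    fig.supylabel("rotation (deg, flexion +)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
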