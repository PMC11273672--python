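"""Kinematic post-processing: rotations, curvature labels, peaks, reductions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neckdyn.analysis import (
    DELTA_DEG,
    SEGMENTS,
    RotationTimeSeries,
    classify_curvature,
    curvature_timeline,
    peak_analysis,
    reduction_table,
    segmental_rotations,
)
from neckdyn.dynamics import Trajectory


def make_traj(theta_by_body: dict[str, np.ndarray], t=None) -> Trajectory:
    labels = list(theta_by_body)
    t = np.arange(0.0, 151.0, 1.0) if t is None else t
    ns, n = len(t), len(labels)
    th = np.column_stack([np.broadcast_to(theta_by_body[k], ns) for k in labels])
    z = np.zeros((ns, n, 2))
    return Trajectory(
        t_ms=t, pos=z, theta=th, vel=z.copy(), omega=np.zeros((ns, n)),
        base_y=np.zeros(ns), scenario="none", body_labels=labels, dt_ms=0.01,
    )


BODIES = ["C0", "C1", "C2", "C3", "C4", "C5", "C6", "C7"]


class TestSegmentalRotations:
    def test_shared_orientation_gives_zero(self):
        traj = make_traj({b: np.linspace(0, 0.3, 151) for b in BODIES})
        rot = segmental_rotations(traj, anatomy=None)
        for seg in SEGMENTS + ["C0-C2", "C0-C7"]:
            assert np.allclose(rot[seg].angle_deg, 0.0)

    def test_sign_convention_flexion_positive(self):
        # C0 tipped 2 deg anterior (negative ccw), C1 tipped 0.5 deg anterior
        th = {b: np.zeros(151) for b in BODIES}
        th["C0"] = np.full(151, -np.radians(2.0))
        th["C1"] = np.full(151, -np.radians(0.5))
        rot = segmental_rotations(make_traj(th), anatomy=None)
        assert rot["C0-C1"].angle_deg[0] == pytest.approx(1.5)
        assert rot["C1-C2"].angle_deg[0] == pytest.approx(0.5)
        assert rot["C0-C2"].angle_deg[0] == pytest.approx(2.0)

    def test_compound_is_sum_of_joints(self):
        rng = np.random.default_rng(3)
        th = {b: rng.normal(0, 0.05, 151) for b in BODIES}
        rot = segmental_rotations(make_traj(th), anatomy=None)
        assert np.allclose(
            rot["C0-C2"].angle_deg,
            rot["C0-C1"].angle_deg + rot["C1-C2"].angle_deg,
        )
        assert np.allclose(
            rot["C0-C7"].angle_deg,
            sum(rot[s].angle_deg for s in SEGMENTS),
        )

    def test_missing_body_raises(self):
        traj = make_traj({b: np.zeros(5) for b in BODIES[:-1]}, t=np.arange(5.0))
        with pytest.raises(KeyError):
            segmental_rotations(traj, anatomy=None)


def brute_force_label(vals: dict[str, float], delta: float = DELTA_DEG) -> str:
    """Independent re-statement of the classification rule."""
    up = vals["C0-C1"] > delta and vals["C1-C2"] > delta
    low_ext = (
        vals["C4-C5"] < -delta or vals["C5-C6"] < -delta or vals["C6-C7"] < -delta
    )
    if up and low_ext:
        return "inverted-S"
    if min(vals.values()) > delta:
        return "mirrored-C"
    return "other"


class TestClassifyCurvature:
    def test_characteristic_patterns(self):
        vals = dict(zip(SEGMENTS, [1.0, 1.0, 0.2, 0.2, 0.2, -0.5, 0.2]))
        assert classify_curvature(vals) == "inverted-S"
        assert classify_curvature(dict.fromkeys(SEGMENTS, 0.5)) == "mirrored-C"
        assert classify_curvature(dict.fromkeys(SEGMENTS, 0.0)) == "other"

    def test_exhaustive_sign_patterns_match_brute_force(self):
        # every {-1, 0, +1} pattern over the seven segments
        for code in range(3**7):
            vals, c = {}, code
            for s in SEGMENTS:
                vals[s] = (c % 3 - 1) * 1.0
                c //= 3
            assert classify_curvature(vals) == brute_force_label(vals), vals

    @given(st.lists(st.floats(-10, 10), min_size=7, max_size=7),
           st.floats(1.5, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, vals, factor):
        d = dict(zip(SEGMENTS, vals))
        # scaling all angles by a factor > 1 cannot change the label when no
        # angle sits inside the +/- delta dead band before or after scaling
        if any(abs(v) <= DELTA_DEG * 1.5 for v in vals):
            return
        scaled = {k: v * factor for k, v in d.items()}
        assert classify_curvature(d) == classify_curvature(scaled)

    def test_missing_segment_raises(self):
        with pytest.raises(KeyError):
            classify_curvature({"C0-C1": 1.0})


class TestPeakAnalysis:
    def test_monotone_series_peaks_at_end(self):
        s = RotationTimeSeries("C0-C2", np.arange(0, 151.0), np.linspace(0, 9, 151))
        out = peak_analysis(s)
        assert out["peak_time_ms"] == 150.0 and not out["inverted_u"]

    def test_triangular_series_is_inverted_u(self):
        t = np.arange(0, 151.0)
        a = np.where(t <= 100, t * 0.09, 9.0 - (t - 100) * 0.05)
        out = peak_analysis(RotationTimeSeries("C0-C2", t, a))
        assert out["peak_time_ms"] == 100.0
        assert out["peak_deg"] == pytest.approx(9.0)
        assert out["inverted_u"]

    def test_constant_series_tie_breaks_to_first(self):
        s = RotationTimeSeries("x", np.arange(5.0), np.ones(5))
        out = peak_analysis(s)
        assert out["peak_time_ms"] == 0.0 and not out["inverted_u"]

    def test_interior_peak_with_small_drop_not_inverted_u(self):
        t = np.arange(0, 151.0)
        a = np.where(t <= 100, t * 0.09, 9.0 - (t - 100) * 0.001)
        assert not peak_analysis(RotationTimeSeries("x", t, a))["inverted_u"]

    @given(st.lists(st.floats(-20, 20), min_size=2, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_brute_force_scan(self, vals):
        a = np.array(vals)
        t = np.arange(float(len(a)))
        out = peak_analysis(RotationTimeSeries("x", t, a))
        best_k, best = 0, a[0]
        for k, v in enumerate(a):
            if v > best:
                best_k, best = k, v
        assert out["peak_deg"] == best
        assert out["peak_time_ms"] == t[best_k]


def series_map(values_by_scenario):
    t = np.arange(0, 151.0)
    out = {}
    for scen, segvals in values_by_scenario.items():
        out[scen] = {
            seg: RotationTimeSeries(seg, t, np.full(len(t), v))
            for seg, v in segvals.items()
        }
    return out


class TestReductionTable:
    def test_identical_scenarios_reduce_zero(self):
        vals = dict(zip(SEGMENTS, [3, 2, 1, 1, 1, 1, 1.0]))
        rots = series_map({"none": vals, "active": vals, "passive": vals})
        tab = reduction_table(rots, 150.0).set_index("segment")
        assert np.allclose(tab["reduction_active_vs_none_pct"], 0.0)

    def test_halving_gives_fifty_percent(self):
        ref = dict.fromkeys(SEGMENTS, 10.0)
        test = dict.fromkeys(SEGMENTS, 5.0)
        rots = series_map({"none": ref, "active": test, "passive": ref})
        tab = reduction_table(rots, 150.0).set_index("segment")
        assert np.allclose(tab["reduction_active_vs_none_pct"], 50.0)

    def test_magnitude_comparison_for_opposite_signs(self):
        rots = series_map({
            "none": dict.fromkeys(SEGMENTS, -2.0),
            "active": dict.fromkeys(SEGMENTS, 1.0),
            "passive": dict.fromkeys(SEGMENTS, -2.0),
        })
        tab = reduction_table(rots, 150.0).set_index("segment")
        assert np.allclose(tab["reduction_active_vs_none_pct"], 50.0)

    def test_tiny_reference_flagged_undefined(self):
        rots = series_map({
            "none": dict.fromkeys(SEGMENTS, 0.05),
            "active": dict.fromkeys(SEGMENTS, 0.01),
            "passive": dict.fromkeys(SEGMENTS, 1.0),
        })
        tab = reduction_table(rots, 150.0).set_index("segment")
        assert not tab["reduction_active_vs_none_defined"].any()
        assert np.isnan(tab["reduction_active_vs_none_pct"]).all()

    def test_antisymmetry_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ref, test = rng.uniform(0.5, 10.0, 2)
            rots = series_map({
                "none": dict.fromkeys(SEGMENTS, ref),
                "active": dict.fromkeys(SEGMENTS, test),
                "passive": dict.fromkeys(SEGMENTS, ref),
            })
            tab = reduction_table(
                rots, 150.0, pairs=(("active", "none"), ("none", "active"))
            ).set_index("segment")
            r = tab.loc["C3-C4", "reduction_active_vs_none_pct"]
            r_swapped = tab.loc["C3-C4", "reduction_none_vs_active_pct"]
            assert r_swapped == pytest.approx(100.0 * (1 - 1 / (1 - r / 100.0)))

    def test_mismatched_grids_rejected(self):
        t1 = np.arange(0, 151.0)
        t2 = np.arange(0, 151.0, 0.5)
        rots = {
            "none": {s: RotationTimeSeries(s, t1, np.ones(len(t1))) for s in SEGMENTS},
            "active": {s: RotationTimeSeries(s, t2, np.ones(len(t2))) for s in SEGMENTS},
        }
        with pytest.raises(ValueError):
            reduction_table(rots, 150.0, pairs=(("active", "none"),))


class TestCurvatureTimeline:
    def test_labels_follow_series(self):
        t = np.arange(0, 3.0)
        rots = {}
        for seg in SEGMENTS:
            vals = np.array([0.0, 1.0, 1.0])
            if seg == "C5-C6":
                vals = np.array([0.0, -1.0, 1.0])
            rots[seg] = RotationTimeSeries(seg, t, vals)
        tl = curvature_timeline(rots)
        assert list(tl["label"]) == ["other", "inverted-S", "mirrored-C"]
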