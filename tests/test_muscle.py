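"""Hill-type muscle mechanics: curve contracts and tabulated-parameter checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neckdyn.muscle import (
    ActivationSchedule,
    MuscleParams,
    active_state,
    bundle_force_on_bodies,
    contractile_force,
    default_muscle_table,
    force_length,
    force_velocity,
    muscle_groups,
    passive_force,
)


@pytest.fixture(scope="module")
def table():
    return default_muscle_table()


@pytest.fixture
def scm(table):
    return next(m for m in table if m.group == "sternocleidomastoid")


@pytest.fixture
def sched():
    return ActivationSchedule(reflex_time=80.0, rise_time=20.0, plateau=1.0)


class TestMuscleTable:
    def test_counts(self, table):
        assert len(table) == 19
        assert len(muscle_groups(table)) == 13

    def test_tabulated_values_spot(self, table):
        by = {m.name: m for m in table}
        scm = by["sternocleidomastoid_180mm"]
        assert (scm.lo, scm.vmax, scm.fmax, scm.pcsa) == (180, 1980, 44825, 358.6)
        trap = by["trapezius_160mm"]
        assert (trap.lo, trap.vmax, trap.fmax) == (160, 1760, 87500)

    def test_shared_globals(self, table):
        for m in table:
            assert (m.sv, m.fpe_scale, m.lmax, m.ksh) == (1.0, 0.0, 0.8, 2.0)

    def test_vmax_lo_ratio_pattern(self, table):
        off = [m for m in table if abs(m.vmax - 11.0 * m.lo) > 1e-9]
        assert [m.name for m in off] == ["longus_colli_60mm"]
        assert off[0].vmax == 650  # kept exactly as tabulated

    def test_deviating_row_logs_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="neckdyn.muscle"):
            default_muscle_table()
        assert any("longus_colli_60mm" in r.message for r in caplog.records)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MuscleParams(name="bad", lo=-1, vmax=1, fmax=1, pcsa=1)
        with pytest.raises(ValueError):
            MuscleParams(name="bad", lo=1, vmax=1, fmax=1, pcsa=1, ksh=0.0)


class TestActiveState:
    def test_zero_before_reflex(self, sched):
        assert active_state(40.0, sched) == 0.0
        assert active_state(0.0, sched) == 0.0
        assert active_state(79.999, sched) == 0.0

    def test_linear_midpoint(self, sched):
        assert active_state(90.0, sched) == pytest.approx(0.5)

    def test_plateau_reached(self, sched):
        assert active_state(100.0, sched) == 1.0
        assert active_state(150.0, sched) == 1.0

    def test_negative_time_rejected(self, sched):
        with pytest.raises(ValueError):
            active_state(-1.0, sched)

    def test_exponential_shape_hits_plateau_exactly(self):
        s = ActivationSchedule(rise_time=20.0, shape="exponential-saturation")
        assert active_state(100.0, s) == pytest.approx(1.0)
        assert active_state(80.0, s) == 0.0

    @given(st.floats(0, 200), st.floats(0.1, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_nondecreasing(self, t, plateau):
        s = ActivationSchedule(plateau=plateau)
        na = active_state(t, s)
        assert 0.0 <= na <= plateau
        assert active_state(t + 1.0, s) >= na


class TestForceLength:
    def test_unity_at_optimum(self, scm):
        assert force_length(scm.lo, scm) == 1.0

    def test_zero_at_support_boundary(self, scm):
        assert force_length(scm.lo * (1 + scm.fl_width), scm) == 0.0
        assert force_length(scm.lo * (1 - scm.fl_width), scm) == 0.0

    def test_quadratic_value_at_half_width(self, scm):
        # 1 - ((L/lo - 1)/w)^2 evaluated by hand at L = lo (1 + w/2)
        assert force_length(scm.lo * (1 + scm.fl_width / 2), scm) == pytest.approx(0.75)

    @given(st.floats(0, 500))
    @settings(max_examples=60, deadline=None)
    def test_nonnegative_and_symmetric(self, length):
        p = MuscleParams(name="t", lo=100, vmax=1100, fmax=1000, pcsa=10)
        v = force_length(length, p)
        assert v >= 0.0
        mirrored = 2 * p.lo - length
        if mirrored >= 0:
            assert force_length(mirrored, p) == pytest.approx(v, abs=1e-12)


class TestForceVelocity:
    def test_isometric_unity(self, scm):
        assert force_velocity(0.0, scm) == pytest.approx(1.0)

    def test_zero_at_max_shortening(self, scm):
        assert force_velocity(-scm.vmax, scm) == 0.0
        assert force_velocity(-2 * scm.vmax, scm) == 0.0

    def test_eccentric_value_by_hand(self, scm):
        # p - (p-1) b / (b + 1) at u = +1 with p = 1.3, b = 0.15
        expect = 1.3 - 0.3 * 0.15 / 1.15
        assert force_velocity(scm.vmax, scm) == pytest.approx(expect)
        assert 1.0 < force_velocity(scm.vmax, scm) <= scm.fv_plateau

    @given(st.floats(-3000, 3000), st.floats(-3000, 3000))
    @settings(max_examples=80, deadline=None)
    def test_monotone_and_bounded(self, v1, v2):
        p = MuscleParams(name="t", lo=100, vmax=1100, fmax=1000, pcsa=10)
        lo_v, hi_v = min(v1, v2), max(v1, v2)
        f_lo, f_hi = force_velocity(lo_v, p), force_velocity(hi_v, p)
        assert f_lo <= f_hi + 1e-12
        assert 0.0 <= f_lo and f_hi <= p.fv_plateau


class TestContractileForce:
    def test_isometric_optimum_equals_fmax_all_bundles(self, table, sched):
        for m in table:
            f = contractile_force(150.0, m.lo, 0.0, m, sched)
            assert f == pytest.approx(m.fmax)

    def test_sternocleidomastoid_value(self, scm, sched):
        assert contractile_force(150.0, 180.0, 0.0, scm, sched) == pytest.approx(44825)

    def test_zero_before_reflex(self, scm, sched):
        assert contractile_force(40.0, scm.lo, 0.0, scm, sched) == 0.0

    def test_trapezius_zero_at_max_shortening(self, table, sched):
        trap = next(m for m in table if m.group == "trapezius")
        assert contractile_force(150.0, trap.lo, -trap.vmax, trap, sched) == 0.0

    def test_bounded_by_eccentric_plateau(self, scm, sched):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.uniform(0, 150)
            L = rng.uniform(0, 2 * scm.lo)
            V = rng.uniform(-2 * scm.vmax, 2 * scm.vmax)
            f = contractile_force(t, L, V, scm, sched)
            assert 0.0 <= f <= scm.fmax * scm.fv_plateau + 1e-9


class TestPassiveForce:
    def test_disabled_by_default(self, scm):
        assert passive_force(2 * scm.lo, scm) == 0.0

    def test_slack_at_rest_length(self, scm):
        p = MuscleParams(name="t", lo=100, vmax=1100, fmax=5000, pcsa=10, fpe_scale=1.0)
        assert passive_force(p.lo, p) == 0.0
        assert passive_force(0.5 * p.lo, p) == 0.0

    def test_reaches_fmax_at_lmax_stretch(self):
        p = MuscleParams(name="t", lo=100, vmax=1100, fmax=5000, pcsa=10, fpe_scale=1.0)
        assert passive_force(p.lo * (1 + p.lmax), p) == pytest.approx(p.fmax)

    def test_closed_form(self):
        p = MuscleParams(name="t", lo=100, vmax=1100, fmax=5000, pcsa=10, fpe_scale=1.0)
        L = 130.0
        expect = 5000 * math.expm1((2.0 / 0.8) * 0.3) / math.expm1(2.0)
        assert passive_force(L, p) == pytest.approx(expect)

    def test_strictly_increasing_and_convex_beyond_rest(self):
        p = MuscleParams(name="t", lo=100, vmax=1100, fmax=5000, pcsa=10, fpe_scale=1.0)
        L = np.linspace(101, 200, 50)
        f = passive_force(L, p)
        assert np.all(np.diff(f) > 0)
        assert np.all(np.diff(f, 2) > -1e-9)


class TestBundleForce:
    def test_isometric_at_optimum_gives_fmax_along_line(self, scm, sched):
        a = (0.0, 0.0)
        b = (0.0, scm.lo)
        fa, fb = bundle_force_on_bodies(a, b, scm, sched, t=150.0)
        assert fa == pytest.approx([0.0, scm.fmax])
        assert fb == pytest.approx([0.0, -scm.fmax])

    def test_pre_reflex_zero(self, scm, sched):
        fa, fb = bundle_force_on_bodies((0, 0), (0, scm.lo), scm, sched, t=10.0)
        assert np.allclose(fa, 0) and np.allclose(fb, 0)

    def test_passive_stretch_gives_fmax(self, sched):
        p = MuscleParams(name="t", lo=100, vmax=1100, fmax=5000, pcsa=10, fpe_scale=1.0)
        fa, fb = bundle_force_on_bodies((0, 0), (0, p.lo * 1.8), p, sched, t=10.0)
        assert fa[1] == pytest.approx(p.fmax)

    def test_net_force_and_moment_vanish(self, scm, sched):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.uniform(-100, 100, 2), rng.uniform(-100, 100, 2)
            if np.hypot(*(b - a)) < 1e-6:
                continue
            va, vb = rng.uniform(-50, 50, 2), rng.uniform(-50, 50, 2)
            fa, fb = bundle_force_on_bodies(a, b, scm, sched, 120.0, va, vb)
            assert np.allclose(fa + fb, 0.0, atol=1e-9)
            moment = a[0] * fa[1] - a[1] * fa[0] + b[0] * fb[1] - b[1] * fb[0]
            assert abs(moment) < 1e-6 * (np.linalg.norm(fa) + 1e-9) * 200

    def test_coincident_points_rejected(self, scm, sched):
        with pytest.raises(ValueError):
            bundle_force_on_bodies((1.0, 2.0), (1.0, 2.0), scm, sched, 100.0)
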