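"""Implicit strain interpolation, active tension and consistent stiffness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from musasi import (HalfSarcomereEnsemble, MusAsiParams, RodModel,
                    active_stiffness, active_tension, default_model,
                    explicit_active_tension, implicit_strain, num_mc_steps)
from musasi.musasi_scheme import TensionEvaluator

PARAMS = MusAsiParams()
ROD = RodModel()


class TestNumMcSteps:
    @pytest.mark.parametrize("DT,expected", [(1.25, 250), (0.625, 125),
                                             (0.3125, 63), (0.005, 1)])
    def test_reference_step_counts(self, DT, expected):
        assert num_mc_steps(DT, 0.005) == expected

    @given(st.floats(0.01, 10.0), st.floats(0.001, 0.1))
    def test_micro_step_stays_near_baseline(self, DT, dt0):
        n = num_mc_steps(DT, dt0)
        assert n >= 1
        if DT >= dt0:
            # the realised micro step DT/n is within half a step of dt0
            assert abs(DT / n - dt0) <= 0.51 * dt0 * max(1.0, dt0 / (DT / n))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            num_mc_steps(-1.0, 0.005)


def _single_bound_record(record_factory, x_a=4.0, n=1, lam_T=1.0,
                         lam_a=1.0, k_a=0, s=0.0):
    nt = 16 * 38
    delta = np.zeros((n, nt), dtype=np.uint8)
    delta[:, 0] = 1
    arr = lambda v: np.full((n, nt), v)
    ka = np.zeros((n, nt), dtype=np.int32)
    ka[:, 0] = k_a
    return record_factory(delta, arr(x_a), arr(s), arr(lam_a), ka,
                          lam_T=lam_T, n=n)


class TestImplicitStrain:
    def test_fresh_attachment_has_no_sliding_term(self, record_factory):
        rec = _single_bound_record(record_factory, x_a=1.5, n=1, k_a=1)
        x = implicit_strain(rec, 1, 1, 1, 1.0, 1.05, PARAMS)
        assert x == pytest.approx(1.5)

    def test_hand_value_pre_attached(self, record_factory):
        # lam 1 -> 1.002, n=2, k=2, x_A=1, attached before the interval:
        # x = 1 + 950*0.002 = 2.9 nm
        nt = 16 * 38
        delta = np.zeros((2, nt), dtype=np.uint8)
        delta[:, 0] = 1
        rec = record_factory(delta, np.full((2, nt), 1.0),
                             np.zeros((2, nt)), np.ones((2, nt)),
                             np.zeros((2, nt), dtype=np.int32), lam_T=1.0)
        x = implicit_strain(rec, 2, 1, 1, 1.0, 1.002, PARAMS)
        assert x == pytest.approx(2.9)
        # a large trial stretch pushes the strain beyond the domain; the
        # tension evaluator then clamps it (forced-detachment regime)
        x_big = implicit_strain(rec, 2, 1, 1, 1.0, 1.02, PARAMS)
        assert x_big == pytest.approx(20.0)
        assert x_big > ROD.x_max

    def test_interpolation_matches_extrapolation_on_linear_path(self):
        # when lam_{T+DT} = lam_T + DT*lam_dot the implicit strains equal
        # the explicit ones, so the two tensions coincide exactly
        hs = HalfSarcomereEnsemble(default_model(N_F=4), seed=4)
        lam_dot = -2e-4
        hs.lam_dot[:] = lam_dot
        for _ in range(160):
            rec = hs.run_interval(ca=2.0, lam_dot=lam_dot)
            lam_lin = hs.lam + rec.n * rec.dt * lam_dot
            hs.finalize_interval(rec, lam_lin)
        g = hs.model.geom
        T_impl = active_tension(rec, rec.lam_T, lam_lin, g, hs.model.rod)
        T_expl = explicit_active_tension(rec, g, hs.model.rod)
        assert T_impl == pytest.approx(T_expl, rel=1e-12, abs=1e-15)
        assert T_impl > 0.0

    def test_bookkeeping_violation_detected(self, record_factory):
        rec = _single_bound_record(record_factory, n=2, k_a=0)
        rec.k_a[0, 0] = 2  # claims attachment after the current step
        with pytest.raises(ValueError):
            implicit_strain(rec, 1, 1, 1, 1.0, 1.0, PARAMS)


class TestActiveTension:
    def test_no_bound_heads_zero(self, record_factory):
        nt = 16 * 38
        z = np.zeros((1, nt))
        rec = record_factory(z.astype(np.uint8), z, z, z,
                             z.astype(np.int32))
        assert active_tension(rec, 1.0, 1.0, PARAMS, ROD) == 0.0
        assert active_stiffness(rec, 1.0, 1.0, PARAMS, ROD) == 0.0

    def test_single_bound_head_hand_value(self, record_factory):
        # dW/dx = 2*4 = 8 pN; prefactor 2*0.5/(693*16*1) -> 0.7215 kPa
        rec = _single_bound_record(record_factory, x_a=4.0)
        T = active_tension(rec, 1.0, 1.0, PARAMS, ROD)
        assert T == pytest.approx(8.0 / 11088.0, rel=1e-6)
        assert T * 1e3 == pytest.approx(0.7215, rel=1e-3)

    def test_full_binding_scales_linearly(self, record_factory):
        nt = 16 * 38
        one = np.ones((1, nt))
        rec = record_factory(one.astype(np.uint8), 4.0 * one, 0.0 * one,
                             one, np.zeros((1, nt), dtype=np.int32))
        T = active_tension(rec, 1.0, 1.0, PARAMS, ROD)
        assert T == pytest.approx(608 * 8.0 / 11088.0, rel=1e-6)
        assert T * 1e3 == pytest.approx(438.7, rel=1e-3)

    def test_time_average_impulse_matching(self, record_factory):
        # the k-sum divided by n equals the average of per-step tensions
        nt = 16 * 38
        rng = np.random.default_rng(7)
        n = 5
        delta = (rng.random((n, nt)) < 0.2).astype(np.uint8)
        x_a = rng.normal(0.0, 1.5, (n, nt))
        rec = record_factory(delta, x_a, np.zeros((n, nt)),
                             np.ones((n, nt)),
                             np.zeros((n, nt), dtype=np.int32), n=n)
        T = active_tension(rec, 1.0, 1.0, PARAMS, ROD)
        per_step = []
        for k in range(n):
            sub = record_factory(delta[k:k + 1], x_a[k:k + 1],
                                 np.zeros((1, nt)), np.ones((1, nt)),
                                 np.zeros((1, nt), dtype=np.int32))
            per_step.append(active_tension(sub, 1.0, 1.0, PARAMS, ROD))
        assert T == pytest.approx(np.mean(per_step), rel=1e-12)


class TestActiveStiffness:
    def test_full_binding_recovers_axial_stiffness_coefficient(
            self, record_factory):
        # all 608 heads bound before T, linear rod, n=1:
        # dT/dlam = (2*RS/(SA0*N_F)) * 608 * k_pos * SL0/2 = 104.2 MPa
        nt = 16 * 38
        one = np.ones((1, nt))
        rec = record_factory(one.astype(np.uint8), 4.0 * one, 0.0 * one,
                             one, np.zeros((1, nt), dtype=np.int32))
        K = active_stiffness(rec, 1.0, 1.0, PARAMS, ROD)
        from musasi import axial_stiffness_coefficient
        assert K == pytest.approx(
            axial_stiffness_coefficient(PARAMS, ROD, 1.0), rel=1e-12)
        assert K == pytest.approx(104.2, abs=0.05)

    def test_literal_prefactor_mode_drops_RS(self, record_factory):
        import dataclasses
        rec = _single_bound_record(record_factory)
        params2 = dataclasses.replace(PARAMS, include_RS_in_stiffness=False)
        K_with = active_stiffness(rec, 1.0, 1.0, PARAMS, ROD)
        K_without = active_stiffness(rec, 1.0, 1.0, params2, ROD)
        assert K_without == pytest.approx(K_with / PARAMS.RS, rel=1e-12)

    def _safe_lambda(self, ev, lam, h=1e-6):
        """True when no strain sits within h of a stiffness kink or edge."""
        dl = lam - ev.lam_T[0]
        x = ev.a0 + ev.c * dl
        margin = ev.c.max() * h * 10 + 1e-9
        dist = np.minimum(np.abs(x),
                          np.minimum(np.abs(x - ROD.x_min),
                                     np.abs(x - ROD.x_max)))
        return np.all(dist > margin)

    def test_matches_finite_difference_of_tension(self):
        # randomized records from real MC runs; derivative checked away
        # from the piecewise-stiffness kink and the domain edges
        model = default_model(N_F=8)
        hs = HalfSarcomereEnsemble(model, seed=9)
        for _ in range(120):
            rec = hs.run_interval(ca=3.0, lam_dot=0.0)
            hs.finalize_interval(rec, hs.lam)
        checked = 0
        h = 1e-6
        ev = TensionEvaluator(rec, model.geom, model.rod)
        for lam in (1.0, 1.001, 0.999, 1.004, 0.996, 1.0021):
            if not self._safe_lambda(ev, lam, h):
                continue
            T0, K0 = ev.tension_stiffness(lam)
            Tp, _ = ev.tension_stiffness(lam + h)
            Tm, _ = ev.tension_stiffness(lam - h)
            fd = (Tp[0] - Tm[0]) / (2 * h)
            assert fd == pytest.approx(K0[0], rel=1e-4)
            checked += 1
        assert checked >= 3

    def test_nonnegative_on_randomized_records(self):
        model = default_model(N_F=4)
        hs = HalfSarcomereEnsemble(model, batch=3, seed=13)
        rng = np.random.default_rng(5)
        for i in range(60):
            lam_dot = rng.uniform(-5e-4, 5e-4, 3)
            rec = hs.run_interval(ca=2.0, lam_dot=lam_dot)
            lam_new = hs.lam + rec.n * rec.dt * rec.lam_dot
            for lam_try in (hs.lam, lam_new, hs.lam + 0.003, hs.lam - 0.003):
                K = active_stiffness(rec, rec.lam_T, lam_try,
                                     model.geom, model.rod)
                assert np.all(np.asarray(K) >= 0.0)
            # Eq-16-style sensitivity: every bound entry has a non-negative
            # strain derivative coefficient
            ev = TensionEvaluator(rec, model.geom, model.rod)
            assert np.all(ev.c >= 0.0)
            hs.finalize_interval(rec, lam_new)


class TestExplicitTension:
    def test_zero_without_bound_heads(self, record_factory):
        nt = 16 * 38
        z = np.zeros((2, nt))
        rec = record_factory(z.astype(np.uint8), z, z, z,
                             z.astype(np.int32), n=2)
        assert explicit_active_tension(rec, PARAMS, ROD) == 0.0

    def test_first_order_taylor_relation(self):
        # implicit tension at lam != linear-path value differs from the
        # explicit tension by ~ stiffness * path mismatch
        model = default_model(N_F=8)
        hs = HalfSarcomereEnsemble(model, seed=21)
        for _ in range(150):
            rec = hs.run_interval(ca=3.0, lam_dot=0.0)
            hs.finalize_interval(rec, hs.lam)
        g = model.geom
        T_expl = explicit_active_tension(rec, g, model.rod)
        mismatch = 5e-5
        lam_try = hs.lam + mismatch
        T_impl = active_tension(rec, rec.lam_T, lam_try, g, model.rod)
        K = active_stiffness(rec, rec.lam_T, lam_try, g, model.rod)
        assert T_impl - T_expl == pytest.approx(K * mismatch, rel=0.02)
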