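"""Stochastic engine: hazards, determinism, bookkeeping and statistics."""

import numpy as np
import pytest
from dataclasses import replace

from musasi import (HalfSarcomereEnsemble, default_model, count_atp,
                    run_mc_interval, strain_histogram, transition_rates,
                    transition_rate_stats)
from musasi.montecarlo_engine import (EDGE_NAMES, RateOverflowError, TT_OFF,
                                      TT_ONCA, TT_OPEN, atp_per_batch)
from musasi.sarcomere_core import (N_ATP, N_XB, P_XB, XB_POSTR1, XB_POSTR2,
                                   XB_PRER, stroke_rates)

#: admissible (from, to) transitions of the myosin state graph, including
#: the forced-detachment edge
ALLOWED_EDGES = {
    (N_XB, P_XB), (P_XB, N_XB), (P_XB, XB_PRER), (XB_PRER, P_XB),
    (XB_PRER, XB_POSTR1), (XB_POSTR1, XB_PRER),
    (XB_POSTR1, XB_POSTR2), (XB_POSTR2, XB_POSTR1),
    (XB_POSTR2, N_XB), (N_ATP, N_XB),
    (XB_PRER, N_ATP), (XB_POSTR1, N_ATP), (XB_POSTR2, N_ATP),
}
TT_EDGES = {(TT_OFF, TT_ONCA), (TT_ONCA, TT_OFF), (TT_ONCA, TT_OPEN),
            (TT_OPEN, TT_ONCA)}


class TestTransitionRates:
    def test_cooperativity_modifiers(self, default_model):
        out_n = dict(transition_rates(N_XB, TT_OPEN, 2, 0.0, 1.0,
                                      default_model))
        base = dict(transition_rates(N_XB, TT_OPEN, 0, 0.0, 1.0,
                                     default_model))
        assert out_n[P_XB] / base[P_XB] == pytest.approx(1600.0)  # 40^2
        det2 = dict(transition_rates(P_XB, TT_OPEN, 2, 0.0, 1.0,
                                     default_model))
        det0 = dict(transition_rates(P_XB, TT_OPEN, 0, 0.0, 1.0,
                                     default_model))
        assert det2[N_XB] / det0[N_XB] == pytest.approx(1.0 / 1600.0)

    def test_blocked_unit_gates_attachment(self, default_model):
        out = dict(transition_rates(N_XB, TT_OFF, 1, 0.0, 1.0, default_model))
        assert out[P_XB] == 0.0

    def test_bound_prer_edge_set(self, default_model):
        x = 1.3
        out = transition_rates(XB_PRER, TT_OPEN, 0, x, 1.0, default_model)
        targets = {t for t, _ in out}
        assert targets == {XB_POSTR1, P_XB}
        rates = dict(out)
        hf, _ = stroke_rates(default_model.rates, default_model.rod, 1, x)
        assert rates[XB_POSTR1] == pytest.approx(float(hf))
        assert rates[P_XB] == default_model.cycle.k_detach

    def test_cycle_closing_edges(self, default_model):
        out2 = dict(transition_rates(XB_POSTR2, TT_OPEN, 0, 2.0, 1.0,
                                     default_model))
        assert out2[N_XB] == default_model.cycle.k_cycle
        outa = dict(transition_rates(N_ATP, TT_OPEN, 0, 0.0, 1.0,
                                     default_model))
        assert outa[N_XB] == default_model.cycle.k_recover

    def test_unknown_state_rejected(self, default_model):
        with pytest.raises(ValueError):
            transition_rates(7, TT_OPEN, 0, 0.0, 1.0, default_model)


class TestEngineBasics:
    def test_absorbing_configuration_stays_silent(self):
        # Ca = 0, everything detached, blocked attachment rate 0:
        # no transition can ever fire
        hs = HalfSarcomereEnsemble(default_model2(), seed=1)
        rec = hs.run_interval(DT=5.0, n=1000, ca=0.0, lam_dot=0.0)
        assert rec.edge_counts.sum() == 0
        assert rec.delta.sum() == 0
        assert np.all(hs.state == N_XB)

    def test_bitwise_determinism(self):
        def run(seed):
            hs = HalfSarcomereEnsemble(default_model2(N_F=2), seed=seed)
            return hs.run_interval(DT=2.5, ca=5.0, lam_dot=-1e-4,
                                   log_events=True)

        r1, r2 = run(42), run(42)
        assert np.array_equal(r1.state, r2.state)
        assert np.array_equal(r1.x_a, r2.x_a)
        assert np.array_equal(r1.edge_counts, r2.edge_counts)
        assert np.array_equal(r1.events["k"], r2.events["k"])
        r3 = run(43)
        assert not np.array_equal(r1.state, r3.state)

    def test_state_count_conservation(self):
        hs = HalfSarcomereEnsemble(default_model2(N_F=2), seed=3)
        rec = hs.run_interval(DT=5.0, ca=5.0)
        fr = rec.state_fractions()
        assert np.allclose(fr.sum(axis=1), 1.0)
        assert np.all(hs.state_counts().sum(axis=1)
                      == hs.N_F * hs.N_M)

    def test_event_log_is_subgraph_and_bookkeeping(self):
        hs = HalfSarcomereEnsemble(default_model2(N_F=2), seed=5)
        rec = hs.run_interval(DT=5.0, ca=8.0, log_events=True)
        ev = rec.events
        n_mol = hs.n_mol
        for k, ent, fs, ts in zip(ev["k"], ev["entity"], ev["from_state"],
                                  ev["to_state"]):
            if ent < n_mol:
                assert (fs, ts) in ALLOWED_EDGES
                if (fs, ts) == (P_XB, XB_PRER):
                    # fresh attachment: the record stamps this micro step
                    assert rec.k_a[k - 1, ent] == k
                    assert rec.delta[k - 1, ent] == 1
            else:
                assert (fs, ts) in TT_EDGES

    def test_rate_overflow_error_names_value(self):
        m = default_model2()
        m = replace(m, cycle=replace(m.cycle, k_pn0=2.0e5))
        hs = HalfSarcomereEnsemble(m, seed=1)
        hs.state[0] = P_XB  # isolated, so gamma^-ng does not suppress it
        with pytest.raises(RateOverflowError, match="exit rate"):
            hs.run_interval(DT=0.05, ca=0.0)

    def test_strain_slides_linearly_with_shortening(self):
        # a bound head's recorded strain follows
        # x_A + s + (SL0/2)(lam_k - lam_A) with lam_k on the linear path
        m = default_model2(N_F=1)
        hs = HalfSarcomereEnsemble(m, seed=2)
        hs.state[0] = XB_PRER
        hs.x_a[0] = 0.5
        hs.s_off[0] = 0.0
        hs.lam_a[0] = 1.0
        lam_dot = -4e-4  # 1/ms
        rec = hs.run_interval(DT=0.1, n=20, ca=0.0, lam_dot=lam_dot)
        ks = np.arange(1, 21)
        bound = rec.delta[:, 0].astype(bool)
        x = (rec.x_a[:, 0] + rec.s_off[:, 0]
             + rec.hsl0 * (1.0 + ks * rec.dt * lam_dot - rec.lam_a[:, 0]))
        expected = 0.5 + 950.0 * ks * rec.dt * lam_dot
        sel = bound & (rec.s_off[:, 0] == 0.0)
        assert sel.sum() >= 5
        assert np.allclose(x[sel], expected[sel], atol=1e-5)


def default_model2(N_F=4):
    return default_model(N_F=N_F)


class TestEventExport:
    def test_csv_and_hdf5_roundtrip(self, tmp_path):
        import pandas as pd
        import h5py
        from musasi.montecarlo_engine import export_events
        hs = HalfSarcomereEnsemble(default_model2(N_F=2), seed=6)
        rec = hs.run_interval(DT=2.5, ca=5.0, log_events=True)
        csv = tmp_path / "events.csv"
        export_events(rec, csv)
        df = pd.read_csv(csv)
        assert set(df.columns) == {"t_ms", "k", "filament", "molecule",
                                   "from_state", "to_state"}
        assert len(df) == len(rec.events["k"]) > 0
        mol_rows = df[df.filament >= 0]
        assert mol_rows.molecule.between(0, hs.N_M - 1).all()
        h5 = tmp_path / "events.h5"
        export_events(rec, h5)
        with h5py.File(h5) as f:
            assert np.array_equal(f["k"][:], df["k"].to_numpy())

    def test_requires_event_log(self):
        from musasi.montecarlo_engine import export_events
        hs = HalfSarcomereEnsemble(default_model2(N_F=2), seed=6)
        rec = hs.run_interval(DT=0.25, ca=0.0)
        with pytest.raises(ValueError, match="log_events"):
            export_events(rec, "unused.csv")


class TestTTUnitKinetics:
    def test_two_state_equilibrium(self):
        # off <-> on_Ca reduced to a two-state unit with k12 = 100/s
        # (k_on*Ca) and k21 = 300/s; occupancy of 'off' must settle at 0.75
        m = default_model2(N_F=1)
        m = replace(m, geom=replace(m.geom, N_M=1),
                    tt=replace(m.tt, k_on_ca=100.0, k_off_ca=300.0,
                               k_open=0.0))
        hs = HalfSarcomereEnsemble(m, batch=2000, seed=8)
        # burn-in ~ 8 time constants (tau = 2.5 ms)
        hs.run_interval(DT=20.0, n=4000, ca=1.0)
        samples = []
        for _ in range(40):
            hs.run_interval(DT=2.5, n=500, ca=1.0)
            samples.append(hs.tt == TT_OFF)
        occ = np.mean(samples, axis=0)          # per-unit time average
        mean = occ.mean()
        se = occ.std(ddof=1) / np.sqrt(occ.size)
        assert abs(mean - 0.75) < 3 * max(se, 1e-4)


class TestAtpAndStats:
    def test_atp_counts_match_event_log(self):
        hs = HalfSarcomereEnsemble(default_model2(), seed=11)
        total = 0
        for _ in range(40):
            rec = hs.run_interval(ca=5.0, log_events=True)
            ev = rec.events
            from_ev = int(np.sum(((ev["from_state"] == XB_POSTR2)
                                  | (ev["from_state"] == N_ATP))
                                 & (ev["to_state"] == N_XB)
                                 & (ev["entity"] < hs.n_mol)))
            assert count_atp(rec) == from_ev
            total += count_atp(rec)
        assert total > 0

    def test_attachment_flow_conservation(self):
        # net change of the bound population equals attachments minus all
        # detachment pathways (graph-flow bookkeeping)
        hs = HalfSarcomereEnsemble(default_model2(), seed=12)
        hs.run_interval(DT=250.0, n=50_000, ca=5.0)  # develop binding
        bound0 = int(hs.bound_mask.sum())
        rec = hs.run_interval(DT=50.0, n=10_000, ca=5.0)
        bound1 = int(hs.bound_mask.sum())
        c = rec.edge_counts.sum(axis=0)
        attach = c[2]
        # exits from the strongly-bound pool: XB_PreR->P_XB, the ATP-consuming
        # XB_PostR2->N_XB completion, and forced detachment to N_ATP
        detach = c[3] + c[8] + c[10]
        assert bound1 - bound0 == attach - detach

    def test_rate_stats_arithmetic(self):
        counts = np.zeros(len(EDGE_NAMES))
        counts[4] = 100.0
        stats = transition_rate_stats(counts, n_molecules=608, duration=0.1)
        assert stats["XB_PreR->XB_PostR1"] == pytest.approx(1.645, abs=1e-3)
        assert sum(stats.values()) * 0.1 * 608 == pytest.approx(100.0)

    def test_rate_stats_from_record(self):
        hs = HalfSarcomereEnsemble(default_model2(), seed=13)
        rec = hs.run_interval(ca=5.0)
        stats = transition_rate_stats(rec)
        total = sum(stats.values()) * rec.duration * 1e-3 \
            * hs.n_mol
        assert total == pytest.approx(rec.edge_counts.sum(), rel=1e-9)

    def test_no_events_all_zero(self):
        hs = HalfSarcomereEnsemble(default_model2(), seed=14)
        rec = hs.run_interval(DT=0.05, ca=0.0)
        assert all(v == 0.0 for v in transition_rate_stats(rec).values())


class TestStrainHistogram:
    def test_empty_when_nothing_bound(self):
        hs = HalfSarcomereEnsemble(default_model2(), seed=15)
        out = strain_histogram(hs)
        assert set(out) == {"XB_PreR", "XB_PostR1", "XB_PostR2"}
        for edges, dens in out.values():
            assert np.all(dens == 0.0)

    def test_support_within_forced_detachment_window(self):
        hs = HalfSarcomereEnsemble(default_model2(N_F=8), seed=16)
        rec = None
        for _ in range(200):
            rec = hs.run_interval(ca=5.0)
            hs.finalize_interval(rec, hs.lam)
        strains = hs.rod_strains()
        strains = strains[np.isfinite(strains)]
        assert strains.size > 0
        assert strains.min() >= -10.0 and strains.max() <= 10.0
        out = strain_histogram(rec)
        for edges, dens in out.values():
            if dens.sum() > 0:
                assert np.trapezoid(dens, 0.5 * (edges[1:] + edges[:-1])) \
                    == pytest.approx(1.0, rel=0.05)

    def test_prer_density_tracks_attachment_distribution(self):
        # isometric steady state: pre-stroke heads carry (lifetime-weighted)
        # Boltzmann attachment strains; the mean must sit near the sampler's
        hs = HalfSarcomereEnsemble(default_model2(N_F=8), seed=17)
        pooled = []
        for i in range(300):
            rec = hs.run_interval(ca=5.0)
            hs.finalize_interval(rec, hs.lam)
            if i > 100:
                x = hs.rod_strains()
                pooled.append(x[hs.state == XB_PRER])
        pooled = np.concatenate(pooled)
        assert pooled.size > 200
        from musasi import sample_attachment_strain
        ref = sample_attachment_strain(hs.model.rod,
                                       np.random.default_rng(0), size=50_000)
        assert abs(pooled.mean() - ref.mean()) < 2.0  # nm, loose sanity


class TestDiastolicSuppression:
    def test_residual_binding_vanishes_at_diastolic_ca(self):
        # gamma = 40 with Ca at 10% of the transient peak: the cooperative
        # mechanism keeps the strongly-bound population (and XB_PostR2 in
        # particular) essentially empty
        hs = HalfSarcomereEnsemble(default_model2(N_F=16), seed=18)
        fr = np.zeros(6)
        nsteps = 400
        for _ in range(nsteps):
            rec = hs.run_interval(ca=0.1)
            fr += rec.state_fractions()[0]
        fr /= nsteps
        assert fr[XB_POSTR2] < 0.01
        assert fr[XB_PRER] + fr[XB_POSTR1] + fr[XB_POSTR2] < 0.02
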