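"""Stochastic state evolution of half-sarcomere ensembles.

One :class:`HalfSarcomereEnsemble` holds a batch of independent
half-sarcomere models (batch entries share parameters but have their own
stretch, Ca level and random stream), advanced one macro interval at a time.
Each interval produces a :class:`McIntervalRecord` -- the per-micro-step
event bookkeeping that the implicit macro scheme re-reads in every Newton
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import _kernels as _K
from .params import ModelParams, default_model, pack_params
from .sarcomere_core import (ATTACHED_SET, N_ATP, N_XB, P_XB, STATE_NAMES,
                             STRONG_STATES, XB_POSTR1, XB_POSTR2, XB_PRER,
                             cap_rates, stroke_rates)

__all__ = [
    "TT_OFF", "TT_ONCA", "TT_OPEN", "TT_STATE_NAMES",
    "RateOverflowError", "McIntervalRecord", "HalfSarcomereEnsemble",
    "HalfSarcomere", "transition_rates", "mc_micro_step", "run_mc_interval",
    "count_atp", "transition_rate_stats", "strain_histogram",
    "export_events", "EDGE_NAMES",
]

TT_OFF, TT_ONCA, TT_OPEN = _K.TT_OFF, _K.TT_ONCA, _K.TT_OPEN
TT_STATE_NAMES = ("off", "on_Ca", "open")

EDGE_NAMES = (
    "N_XB->P_XB", "P_XB->N_XB", "P_XB->XB_PreR", "XB_PreR->P_XB",
    "XB_PreR->XB_PostR1", "XB_PostR1->XB_PreR",
    "XB_PostR1->XB_PostR2", "XB_PostR2->XB_PostR1",
    "XB_PostR2->N_XB", "N_ATP->N_XB", "forced->N_ATP",
    "TT:off->on_Ca", "TT:on_Ca->off", "TT:on_Ca->open", "TT:open->on_Ca",
)


class RateOverflowError(RuntimeError):
    """Total exit rate * dt exceeded the validity bound of the MC step."""


# With r_max*dt0 = 0.5 by construction, the only admissible excess over 0.5
# is a small constant-rate rider (e.g. the detachment rate) on top of one
# capped stroke edge.
_MAX_RDT = 0.55


@dataclass
class McIntervalRecord:
    """Per-micro-step log of one macro interval.

    Dense arrays over (n, n_molecules): ``delta`` (1 if strongly bound after
    the step), ``state``, and for bound heads the attachment strain ``x_a``,
    stroke offset ``s_off``, attachment stretch ``lam_a`` and the attachment
    micro-step index ``k_a`` (0 = attached before the interval).
    ``edge_counts[b, e]`` counts transitions per batch entry and edge.
    """

    n: int
    dt: float                 # ms
    t0: float                 # ms, interval start time
    lam_T: np.ndarray         # (B,)
    lam_dot: np.ndarray       # (B,) 1/ms
    delta: np.ndarray         # (n, Nt) uint8
    state: np.ndarray         # (n, Nt) int8
    x_a: np.ndarray           # (n, Nt) float32
    s_off: np.ndarray         # (n, Nt) float32
    lam_a: np.ndarray         # (n, Nt) float32
    k_a: np.ndarray           # (n, Nt) int32
    edge_counts: np.ndarray   # (B, NEDGE) int64
    batch_of_mol: np.ndarray  # (Nt,) int64
    B: int
    N_F: int
    N_M: int
    hsl0: float
    max_rate_dt: float
    events: Optional[dict] = None   # arrays k, entity, from_state, to_state

    @property
    def n_molecules_per_batch(self) -> int:
        return self.N_F * self.N_M

    @property
    def duration(self) -> float:
        """Interval length in ms."""
        return self.n * self.dt

    def state_fractions(self) -> np.ndarray:
        """Time-averaged state occupancies, shape (B, 6)."""
        out = np.zeros((self.B, 6))
        npm = self.n_molecules_per_batch
        for s in range(6):
            cnt = (self.state == s).sum(axis=0)  # (Nt,)
            out[:, s] = np.bincount(self.batch_of_mol, weights=cnt,
                                    minlength=self.B)
        return out / (self.n * npm)

    def binding_ratio(self) -> np.ndarray:
        """Time-averaged strong-binding ratio R_B per batch entry."""
        return self.state_fractions()[:, list(STRONG_STATES)].sum(axis=1)


class HalfSarcomereEnsemble:
    """Batch of stochastic half-sarcomere models sharing one parameter set.

    Parameters
    ----------
    model:
        Full parameter bundle (geometry, rod, rate laws, gating).
    batch:
        Number of independent half-sarcomeres (e.g. one per chain element).
    seed:
        Single integer; together with the global micro-step counter it
        drives the counter-based random streams, so a run is bitwise
        reproducible.
    """

    def __init__(self, model: ModelParams | None = None, batch: int = 1,
                 seed: int = 0, lam0: float = 1.0):
        self.model = model if model is not None else default_model()
        g = self.model.geom
        self.B = int(batch)
        self.N_F, self.N_M = g.N_F, g.N_M
        self.n_mol = self.B * g.N_F * g.N_M
        mpt = self.model.cycle.molecules_per_tt
        self.units_per_fil = -(-g.N_M // mpt)
        self.n_unit = self.B * g.N_F * self.units_per_fil

        self.state = np.full(self.n_mol, N_XB, dtype=np.int8)
        self.x_a = np.full(self.n_mol, np.nan)
        self.s_off = np.zeros(self.n_mol)
        self.lam_a = np.full(self.n_mol, np.nan)
        self.k_a_step = np.full(self.n_mol, -1, dtype=np.int32)
        self.tt = np.full(self.n_unit, TT_OFF, dtype=np.int8)

        idx = np.arange(self.n_mol)
        fil = idx // g.N_M                       # global filament index
        self.pos_of_mol = (idx % g.N_M).astype(np.int64)
        self.batch_of_mol = (fil // g.N_F).astype(np.int64)
        self.tt_of_mol = (fil * self.units_per_fil
                          + self.pos_of_mol // mpt).astype(np.int64)
        uidx = np.arange(self.n_unit)
        self.batch_of_unit = (uidx // (g.N_F * self.units_per_fil)
                              ).astype(np.int64)

        self.lam = np.full(self.B, float(lam0))
        self.lam_dot = np.zeros(self.B)          # 1/ms
        self.seed = np.uint64(seed)
        self.step_count = 0                      # global micro-step counter
        self.time = 0.0                          # ms
        self._pk = pack_params(self.model)

    # -- bookkeeping ------------------------------------------------------
    @property
    def bound_mask(self) -> np.ndarray:
        return self.state >= XB_PRER

    def rod_strains(self) -> np.ndarray:
        """Current rod strains of bound heads (nm), NaN for detached."""
        lam_b = self.lam[self.batch_of_mol]
        x = self.x_a + self.s_off + self.model.geom.hsl0 * (lam_b - self.lam_a)
        return np.where(self.bound_mask, x, np.nan)

    def state_counts(self) -> np.ndarray:
        """(B, 6) instantaneous state counts."""
        out = np.zeros((self.B, 6), dtype=np.int64)
        for s in range(6):
            out[:, s] = np.bincount(self.batch_of_mol,
                                    weights=(self.state == s).astype(float),
                                    minlength=self.B).astype(np.int64)
        return out

    # -- advancing --------------------------------------------------------
    def run_interval(self, DT: float | None = None, n: int | None = None,
                     ca=1.0, lam_dot=None, log_events: bool = False
                     ) -> McIntervalRecord:
        """Run n micro steps covering one macro interval of length DT.

        The stretch within the interval is extrapolated as
        lam_T + k*dt*lam_dot (the micro scale only knows the start-of-step
        sliding velocity).  ``ca`` may be a scalar, an array of shape (B,),
        or a callable t_ms -> level/array evaluated at each micro step.
        """
        from .params import num_mc_steps
        g = self.model.geom
        if DT is None:
            DT = g.DT
        if n is None:
            n = num_mc_steps(DT, g.dt0)
        dt = DT / n
        if lam_dot is not None:
            self.lam_dot = np.broadcast_to(
                np.asarray(lam_dot, dtype=float), (self.B,)).copy()

        ca_steps = np.empty((n, self.B))
        if callable(ca):
            for k in range(1, n + 1):
                ca_steps[k - 1] = np.broadcast_to(
                    np.asarray(ca(self.time + k * dt), dtype=float), (self.B,))
        else:
            ca_steps[:] = np.broadcast_to(np.asarray(ca, dtype=float),
                                          (self.B,))
        if np.any(ca_steps < 0):
            raise ValueError("Ca concentration must be non-negative")

        snapshot = None
        cap = 1024 if not log_events else max(4096, self.n_mol * n // 16)
        if log_events:
            snapshot = (self.state.copy(), self.x_a.copy(), self.s_off.copy(),
                        self.lam_a.copy(), self.k_a_step.copy(),
                        self.tt.copy())

        # molecules bound since before the interval carry k_a = 0
        self.k_a_step[self.bound_mask] = 0
        self.k_a_step[~self.bound_mask] = -1

        while True:
            rec = self._alloc_record(n, dt)
            ev = self._alloc_events(cap)
            stats = np.zeros(1)
            _K.advance_interval(
                self.state, self.x_a, self.s_off, self.lam_a, self.k_a_step,
                self.tt, self.tt_of_mol, self.batch_of_mol, self.pos_of_mol,
                self.batch_of_unit, self.lam, self.lam_dot, ca_steps,
                n, dt, self._pk, self.seed, np.uint64(self.step_count),
                rec["delta"], rec["state"], rec["x_a"], rec["s_off"],
                rec["lam_a"], rec["k_a"], rec["edge_counts"],
                log_events, ev["k"], ev["ent"], ev["from"], ev["to"],
                ev["n"], stats)
            if log_events and ev["n"][0] > cap:
                # overflowed the event buffer: restore and replay (the
                # counter-based streams make the replay identical)
                (self.state[:], self.x_a[:], self.s_off[:], self.lam_a[:],
                 self.k_a_step[:], self.tt[:]) = snapshot
                cap = int(ev["n"][0]) + 16
                continue
            break

        if stats[0] > _MAX_RDT:
            raise RateOverflowError(
                f"total exit rate * dt reached {stats[0]:.3f} (> {_MAX_RDT}); "
                "reduce the micro time step or the offending rate constant")

        events = None
        if log_events:
            m = int(ev["n"][0])
            events = {"k": ev["k"][:m].copy(), "entity": ev["ent"][:m].copy(),
                      "from_state": ev["from"][:m].copy(),
                      "to_state": ev["to"][:m].copy()}

        record = McIntervalRecord(
            n=n, dt=dt, t0=self.time, lam_T=self.lam.copy(),
            lam_dot=self.lam_dot.copy(), delta=rec["delta"],
            state=rec["state"], x_a=rec["x_a"], s_off=rec["s_off"],
            lam_a=rec["lam_a"], k_a=rec["k_a"],
            edge_counts=rec["edge_counts"], batch_of_mol=self.batch_of_mol,
            B=self.B, N_F=self.N_F, N_M=self.N_M, hsl0=self.model.geom.hsl0,
            max_rate_dt=float(stats[0]), events=events)
        self.step_count += n
        self.time += n * dt
        return record

    def finalize_interval(self, record: McIntervalRecord, lam_new) -> None:
        """Commit the converged end-of-interval stretch.

        Attachment stretches of heads that attached during the interval were
        provisionally recorded on the extrapolated path; they are re-expressed
        on the interpolated path to the converged stretch, which is the value
        the implicit tension used.  Then the current stretch is advanced.
        """
        lam_new = np.broadcast_to(np.asarray(lam_new, dtype=float),
                                  (self.B,)).copy()
        fresh = self.bound_mask & (self.k_a_step >= 1)
        if np.any(fresh):
            b = self.batch_of_mol[fresh]
            frac = self.k_a_step[fresh] / record.n
            self.lam_a[fresh] = (record.lam_T[b]
                                 + frac * (lam_new[b] - record.lam_T[b]))
        self.lam = lam_new

    # -- allocation helpers ----------------------------------------------
    def _alloc_record(self, n, dt):
        nt = self.n_mol
        return {
            "delta": np.empty((n, nt), dtype=np.uint8),
            "state": np.empty((n, nt), dtype=np.int8),
            "x_a": np.empty((n, nt), dtype=np.float32),
            "s_off": np.empty((n, nt), dtype=np.float32),
            "lam_a": np.empty((n, nt), dtype=np.float32),
            "k_a": np.empty((n, nt), dtype=np.int32),
            "edge_counts": np.zeros((self.B, _K.NEDGE), dtype=np.int64),
        }

    @staticmethod
    def _alloc_events(cap):
        return {"k": np.empty(cap, dtype=np.int32),
                "ent": np.empty(cap, dtype=np.int64),
                "from": np.empty(cap, dtype=np.int8),
                "to": np.empty(cap, dtype=np.int8),
                "n": np.zeros(1, dtype=np.int64)}


#: single half-sarcomere convenience alias (batch of one)
HalfSarcomere = HalfSarcomereEnsemble


def transition_rates(state: int, tt_state: int, ng: int, x: float,
                     Ca: float, model: ModelParams):
    """All outgoing edges of one myosin head: list of (target_state, rate 1/s).

    Pure-Python mirror of the compiled kernel's hazard enumeration, used by
    tests and by master-equation oracles.  ``x`` is the current rod strain
    (required if the head is bound), ``ng`` the number of attached
    neighbours (0..2).
    """
    if Ca < 0:
        raise ValueError("Ca must be non-negative")
    if ng not in (0, 1, 2):
        raise ValueError("ng must be 0, 1 or 2")
    cyc, rm, rod = model.cycle, model.rates, model.rod
    out = []
    if state == N_XB:
        perm = 1.0 if tt_state == TT_OPEN else cyc.perm_blocked
        out.append((P_XB, cyc.k_np0 * cyc.gamma ** ng * perm))
    elif state == P_XB:
        out.append((N_XB, cyc.k_pn0 * cyc.gamma ** (-ng)))
        out.append((XB_PRER, cyc.k_attach))
    elif state == N_ATP:
        out.append((N_XB, cyc.k_recover))
    elif state == XB_PRER:
        hf, _ = stroke_rates(rm, rod, 1, x)
        out.append((XB_POSTR1, float(hf)))
        out.append((P_XB, cyc.k_detach))
    elif state == XB_POSTR1:
        _, hb = stroke_rates(rm, rod, 1, x - model.ladder.s1)
        hf2, _ = stroke_rates(rm, rod, 2, x)
        out.append((XB_PRER, float(hb)))
        out.append((XB_POSTR2, float(hf2)))
    elif state == XB_POSTR2:
        _, hb2 = stroke_rates(rm, rod, 2, x - model.ladder.s2)
        out.append((XB_POSTR1, float(hb2)))
        out.append((N_XB, cyc.k_cycle))
    else:
        raise ValueError(f"unknown myosin state {state}")
    return out


def mc_micro_step(hs: HalfSarcomereEnsemble, lambda_tilde, Ca, dt: float,
                  log_events: bool = True) -> McIntervalRecord:
    """Advance the ensemble by a single micro step at stretch lambda_tilde.

    Randomness comes from the ensemble's counter-based streams (seeded at
    construction); the step advances the global counter.
    """
    hs.lam = np.broadcast_to(np.asarray(lambda_tilde, dtype=float),
                             (hs.B,)).copy()
    return hs.run_interval(DT=dt, n=1, ca=Ca, lam_dot=0.0,
                           log_events=log_events)


def run_mc_interval(hs: HalfSarcomereEnsemble, lambda_T, lambda_dot_T,
                    DT: float, n: int, ca, log_events: bool = False
                    ) -> McIntervalRecord:
    """Explicit-argument interval runner: set (lam, lam_dot), do n steps."""
    if n < 1:
        raise ValueError("need at least one micro step")
    hs.lam = np.broadcast_to(np.asarray(lambda_T, dtype=float),
                             (hs.B,)).copy()
    return hs.run_interval(DT=DT, n=n, ca=ca, lam_dot=lambda_dot_T,
                           log_events=log_events)


def export_events(record: McIntervalRecord, path) -> None:
    """Write the interval's event log as a columnar file.

    Schema: (t_ms, k, filament, molecule, from_state, to_state), with
    filament/molecule set to -1 for T/T-unit events.  ``path`` ending in
    ``.h5``/``.hdf5`` selects an HDF5 container (one dataset per column);
    anything else writes CSV.  Requires the record to have been produced
    with ``log_events=True``.
    """
    import pandas as pd
    if record.events is None:
        raise ValueError("record carries no event log; rerun the interval "
                         "with log_events=True")
    ev = record.events
    n_mol_total = record.B * record.N_F * record.N_M
    ent = ev["entity"]
    is_mol = ent < n_mol_total
    fil = np.where(is_mol, (ent // record.N_M) % record.N_F, -1)
    mol = np.where(is_mol, ent % record.N_M, -1)
    df = pd.DataFrame({
        "t_ms": record.t0 + ev["k"] * record.dt,
        "k": ev["k"],
        "filament": fil,
        "molecule": mol,
        "from_state": ev["from_state"],
        "to_state": ev["to_state"],
    })
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py
        with h5py.File(path, "w") as f:
            for col in df.columns:
                f.create_dataset(col, data=df[col].to_numpy())
    else:
        df.to_csv(path, index=False)


def count_atp(record: McIntervalRecord) -> int:
    """ATP consumed in the interval: transitions to N_XB from XB_PostR2 or
    N_ATP, summed over the ensemble."""
    return int(record.edge_counts[:, [_K.E_R2_CYCLE, _K.E_ATP_CYCLE]].sum())


def atp_per_batch(record: McIntervalRecord) -> np.ndarray:
    return record.edge_counts[:, [_K.E_R2_CYCLE, _K.E_ATP_CYCLE]].sum(axis=1)


def transition_rate_stats(record: McIntervalRecord | np.ndarray,
                          n_molecules: int | None = None,
                          duration: float | None = None) -> dict:
    """Per-edge transition rates in 1/s per myosin molecule.

    rate(edge) = count(edge) / (duration * N_molecules), the normalisation
    used for reporting stroke statistics.  Accepts a record (duration and
    molecule count inferred, overridable) or a raw (B, NEDGE) count array
    with both given explicitly.
    """
    if isinstance(record, McIntervalRecord):
        counts = record.edge_counts.sum(axis=0)
        if n_molecules is None:
            n_molecules = record.B * record.n_molecules_per_batch
        if duration is None:
            duration = record.duration * 1e-3  # ms -> s
    else:
        counts = np.asarray(record).sum(axis=0) if np.ndim(record) == 2 \
            else np.asarray(record)
        if n_molecules is None or duration is None:
            raise ValueError("need n_molecules and duration for raw counts")
    if duration <= 0:
        raise ValueError("duration must be positive")
    denom = duration * n_molecules
    return {name: counts[e] / denom for e, name in enumerate(EDGE_NAMES)}


def strain_histogram(source, bins=80, x_range=(-10.0, 10.0)) -> dict:
    """Normalised rod-strain densities of bound heads, keyed by state name.

    ``source`` is either an ensemble (instantaneous strains) or an interval
    record (strains pooled over the micro steps of the interval, on the
    extrapolated path).  Returns {state_name: (bin_edges, density)} for the
    three strong-binding states; empty-density entries appear when a state
    is unpopulated.
    """
    if isinstance(source, HalfSarcomereEnsemble):
        x = source.rod_strains()
        states = source.state
        sel = source.bound_mask
        x, states = x[sel], states[sel]
    elif isinstance(source, McIntervalRecord):
        k = np.arange(1, source.n + 1)[:, None]
        lam_k = (source.lam_T[source.batch_of_mol][None, :]
                 + k * source.dt * source.lam_dot[source.batch_of_mol][None, :])
        xall = (source.x_a + source.s_off
                + source.hsl0 * (lam_k - source.lam_a))
        sel = source.delta.astype(bool)
        x, states = xall[sel], source.state[sel]
    else:
        raise TypeError("source must be an ensemble or an interval record")
    out = {}
    edges = np.histogram_bin_edges(np.empty(0), bins=bins, range=x_range)
    for s in STRONG_STATES:
        xs = x[states == s]
        if xs.size:
            dens, _ = np.histogram(xs, bins=edges, density=True)
        else:
            dens = np.zeros(len(edges) - 1)
        out[STATE_NAMES[s]] = (edges, dens)
    return out
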