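"""Multiple-step active-stiffness integration (MusAsi).

The macro integrator advances stretch from ``lam_T`` to a trial
``lam_{T+DT}`` inside Newton iterations.  The Monte Carlo events of the
interval are frozen, but the rod strains entering the active tension are
re-evaluated on the *interpolated* stretch path

    lam_{T+k*dt} = lam_T + (k/n) (lam_{T+DT} - lam_T),

with the attachment stretch of heads that attached at micro step k_A
re-derived on the same path.  The active tension is the impulse-matching
time average of the summed rod forces,

    T_act = 2 R_S / (SA0 N_F n) * sum_{j,i,k} delta_A dW/dx(x_{ij,k}),

and its derivative with respect to lam_{T+DT} -- the active stiffness that
enters the Newton matrix -- follows by the chain rule with
d x / d lam_{T+DT} = (SL0/2) (k/n - k_A/n) >= 0, so the stiffness is
non-negative whenever the rod potential is convex.

The explicit comparator evaluates the same sum on the frozen extrapolated
strains, is independent of the trial stretch, and therefore contributes no
active stiffness -- the source of the explicit scheme's instability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montecarlo_engine import McIntervalRecord, atp_per_batch
from .params import MusAsiParams, num_mc_steps  # re-exported here
from .sarcomere_core import RodModel

__all__ = [
    "MusAsiParams", "num_mc_steps", "ActiveTensionResult", "TensionEvaluator",
    "implicit_strain", "active_tension", "active_stiffness",
    "explicit_active_tension",
]


@dataclass
class ActiveTensionResult:
    """Active tension (MPa), its stretch derivative (MPa per unit stretch)
    and the ATP count of the interval."""

    T_act: float | np.ndarray
    dT_dlambda: float | np.ndarray
    atp: int | np.ndarray


class TensionEvaluator:
    """Fast re-evaluation of the tension/stiffness sums per Newton trial.

    Built once per macro interval from the record: every bound (micro step,
    molecule) entry reduces to an affine strain map
    ``x = a0 + c * (lam_{T+DT} - lam_T)`` with c >= 0, so each Newton
    iteration is a clip, a piecewise-linear force lookup and a segmented sum.

    Strains pushed beyond the rod's strain domain by a trial stretch are
    clamped to the domain edge (state changes are frozen during iterations):
    the force saturates at the edge value and the entry's stiffness
    contribution vanishes, keeping the residual continuous.
    """

    def __init__(self, record: McIntervalRecord, params: MusAsiParams,
                 rod: RodModel, lam_T=None):
        n = record.n
        self.record = record
        self.params = params
        self.rod = rod
        self.B = record.B
        self.n = n
        self.lam_T = record.lam_T if lam_T is None else \
            np.broadcast_to(np.asarray(lam_T, dtype=float), (record.B,))
        hsl0 = params.hsl0

        bound = record.delta.astype(bool)             # (n, Nt)
        kk, mm = np.nonzero(bound)
        k = kk + 1
        self.b = record.batch_of_mol[mm]
        ka = record.k_a[kk, mm].astype(np.int64)
        if np.any(ka > k):
            raise ValueError("record bookkeeping violated: k_A > k")
        base = (record.x_a[kk, mm] + record.s_off[kk, mm]).astype(float)
        fresh = ka >= 1
        self.c = np.where(fresh, hsl0 * (k - ka) / n, hsl0 * k / n)
        lamA_stored = record.lam_a[kk, mm].astype(float)
        self.a0 = np.where(
            fresh, base,
            base + hsl0 * (self.lam_T[self.b] - lamA_stored))
        self.pref_T = params.tension_prefactor(n)
        self.pref_K = self.pref_T if params.include_RS_in_stiffness \
            else 2.0 / (params.SA0 * params.N_F * n)

    def tension_stiffness(self, lam_TdT):
        """(T_act, dT/dlam) per batch entry at the trial stretch."""
        lam = np.broadcast_to(np.asarray(lam_TdT, dtype=float), (self.B,))
        dl = (lam - self.lam_T)[self.b]
        x = self.a0 + self.c * dl
        rod = self.rod
        xc = np.clip(x, rod.x_min, rod.x_max)
        inside = (x >= rod.x_min) & (x <= rod.x_max)
        kloc = np.where(xc >= 0.0, rod.k_pos, rod.k_neg)
        f = kloc * xc
        T = np.bincount(self.b, weights=f, minlength=self.B) * self.pref_T
        ks = kloc * self.c * inside
        K = np.bincount(self.b, weights=ks, minlength=self.B) * self.pref_K
        return T, K

    def explicit_tension(self):
        """Tension on the frozen extrapolated strains (no active stiffness).

        Identical to evaluating the implicit sum at
        lam_{T+DT} = lam_T + DT * lam_dot_T, because interpolation and
        extrapolation coincide on that linear path.
        """
        rec = self.record
        lam_expl = self.lam_T + rec.n * rec.dt * rec.lam_dot
        T, _ = self.tension_stiffness(lam_expl)
        return T


def _maybe_scalar(a, B):
    return float(a[0]) if B == 1 else a


def implicit_strain(record: McIntervalRecord, k: int, i: int, j: int,
                    lam_T: float, lam_TdT: float, params: MusAsiParams,
                    batch: int = 0) -> float:
    """Rod strain of molecule (i of filament j) at micro step k, on the
    interpolated stretch path to the trial lam_{T+DT}.

    ``i`` in 1..N_M, ``j`` in 1..N_F, ``k`` in 1..n (one-based, the
    convention of the scheme's sums).  NaN if the head is detached at k.
    """
    if not (1 <= k <= record.n):
        raise ValueError("micro-step index out of range")
    m = (batch * record.N_F + (j - 1)) * record.N_M + (i - 1)
    if not record.delta[k - 1, m]:
        return float("nan")
    ka = int(record.k_a[k - 1, m])
    if ka > k:
        raise ValueError("record bookkeeping violated: k_A > k")
    n = record.n
    hsl0 = params.hsl0
    lam_k = lam_T + (k / n) * (lam_TdT - lam_T)
    if ka >= 1:
        lam_A = lam_T + (ka / n) * (lam_TdT - lam_T)
    else:
        lam_A = float(record.lam_a[k - 1, m])
    return float(record.x_a[k - 1, m] + record.s_off[k - 1, m]
                 + hsl0 * (lam_k - lam_A))


def active_tension(record: McIntervalRecord, lam_T, lam_TdT,
                   params: MusAsiParams, rod: RodModel):
    """Implicit active tension T_act (MPa) at the trial end-of-step stretch."""
    ev = TensionEvaluator(record, params, rod, lam_T=lam_T)
    T, _ = ev.tension_stiffness(lam_TdT)
    return _maybe_scalar(T, record.B)


def active_stiffness(record: McIntervalRecord, lam_T, lam_TdT,
                     params: MusAsiParams, rod: RodModel):
    """Consistent active stiffness dT_act/dlam_{T+DT} (MPa per unit stretch).

    Non-negative for convex rod potentials, because every bound entry's
    strain sensitivity (k/n - k_A/n) is non-negative.
    """
    ev = TensionEvaluator(record, params, rod, lam_T=lam_T)
    _, K = ev.tension_stiffness(lam_TdT)
    return _maybe_scalar(K, record.B)


def explicit_active_tension(record: McIntervalRecord, params: MusAsiParams,
                            rod: RodModel):
    """Active tension on the frozen extrapolated MC strains (explicit
    comparator; independent of the trial stretch)."""
    ev = TensionEvaluator(record, params, rod)
    return _maybe_scalar(ev.explicit_tension(), record.B)


def active_result(record: McIntervalRecord, lam_T, lam_TdT,
                  params: MusAsiParams, rod: RodModel) -> ActiveTensionResult:
    ev = TensionEvaluator(record, params, rod, lam_T=lam_T)
    T, K = ev.tension_stiffness(lam_TdT)
    atp = atp_per_batch(record)
    if record.B == 1:
        return ActiveTensionResult(float(T[0]), float(K[0]), int(atp[0]))
    return ActiveTensionResult(T, K, atp)
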