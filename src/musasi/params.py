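"""Parameter bundles for the half-sarcomere model and the macro coupling.

Geometry and coupling constants (sarcomere length, cross-sectional area,
volume ratio, time steps) are the reference set of this model family;
kinetic constants without reference values are fallback defaults calibrated
as described in docs/methods.md and are all config-overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as _K
from .sarcomere_core import FreeEnergyLadder, RateModel, RodModel

__all__ = [
    "TTParams", "CycleParams", "MusAsiParams", "ModelParams",
    "num_mc_steps", "pack_params", "default_model",
]


def num_mc_steps(DT: float, dt0: float) -> int:
    """Number of MC micro steps per macro interval.

    n = floor((DT - 0.5*dt0)/dt0) + 1, so that n*dt with dt = DT/n stays
    as close as possible to the baseline micro step dt0 while covering DT
    exactly.  DT and dt0 in ms.
    """
    if DT <= 0 or dt0 <= 0:
        raise ValueError("DT and dt0 must be positive")
    # guard against representation error right below an integer boundary
    n = int(math.floor((DT - 0.5 * dt0) / dt0 + 1e-12)) + 1
    if n < 1:
        raise ValueError("macro step shorter than half a micro step")
    return n


@dataclass(frozen=True)
class TTParams:
    """Troponin/tropomyosin unit kinetics: off <-> Ca-bound <-> open.

    Ca binding is first order in [Ca2+]; only the open (permissive) state
    enables the N_XB -> P_XB transition of the myosin heads underneath.
    Attached heads feed back on the unit: while any myosin below the unit is
    in a weak- or strong-binding state, the closing rate is multiplied by
    ``hold_factor`` (steric holding of tropomyosin by bound heads), which
    stabilises activated regions against strain churn without affecting the
    relaxed state.  Defaults calibrated so half-activation of the gamma=40
    force-pCa curve sits near pCa 6 (calibrated fallbacks; docs/methods.md).
    """

    k_on_ca: float = 150.0    # 1/(uM*s)
    k_off_ca: float = 3000.0  # 1/s
    k_open: float = 1500.0    # 1/s
    k_close: float = 250.0    # 1/s
    hold_factor: float = 0.15  # k_close multiplier under attached heads


@dataclass(frozen=True)
class CycleParams:
    """Attachment/detachment cycle constants and cooperativity.

    gamma^ng boosts N_XB -> P_XB and gamma^-ng suppresses the reverse,
    with ng the number of neighbouring heads in weak- or strong-binding
    states, which is the nearest-neighbour cooperative mechanism that
    empties the bound population at diastolic Ca.
    """

    k_np0: float = 50.0       # 1/s, N_XB -> P_XB baseline (x gamma^ng x gate)
    k_pn0: float = 1850.0     # 1/s, P_XB -> N_XB baseline (x gamma^-ng)
    k_attach: float = 12.0    # 1/s, P_XB -> XB_PreR
    k_detach: float = 500.0   # 1/s, XB_PreR -> P_XB
    k_cycle: float = 200.0    # 1/s, XB_PostR2 -> N_XB (ATP consuming)
    k_recover: float = 500.0  # 1/s, N_ATP -> N_XB (ATP consuming)
    gamma: float = 40.0       # cooperativity base
    perm_blocked: float = 0.0  # N->P gate multiplier when the T/T unit is shut
    molecules_per_tt: int = 1


@dataclass(frozen=True)
class MusAsiParams:
    """Half-sarcomere geometry and macro/micro time-step coupling."""

    SL0: float = 1900.0       # nm, unloaded sarcomere length (SL0/2 = 950 nm)
    SA0: float = 693.0        # nm^2, cross-sectional area per thin filament
    RS: float = 0.5           # sarcomere volume ratio
    N_F: int = 16             # thin filaments per half-sarcomere model
    N_M: int = 38             # myosin molecules per filament
    DT: float = 1.25          # ms, macro (FE) time step
    dt0: float = 0.005        # ms, baseline MC micro step (5 us)
    include_RS_in_stiffness: bool = True

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("DT must cover at least one micro step")

    @property
    def hsl0(self) -> float:
        """Unloaded half-sarcomere length SL0/2 (nm)."""
        return 0.5 * self.SL0

    @property
    def n_steps(self) -> int:
        return num_mc_steps(self.DT, self.dt0)

    @property
    def dt(self) -> float:
        """Actual micro step DT/n (ms)."""
        return self.DT / self.n_steps

    @property
    def n_molecules(self) -> int:
        return self.N_F * self.N_M

    def tension_prefactor(self, n: int | None = None) -> float:
        """2*RS/(SA0*N_F*n): converts summed rod forces (pN) to MPa."""
        n = self.n_steps if n is None else n
        return 2.0 * self.RS / (self.SA0 * self.N_F * n)


@dataclass(frozen=True)
class ModelParams:
    """Everything the stochastic half-sarcomere needs."""

    rod: RodModel = field(default_factory=RodModel)
    ladder: FreeEnergyLadder = field(default_factory=FreeEnergyLadder)
    rates: RateModel = field(default_factory=RateModel)
    cycle: CycleParams = field(default_factory=CycleParams)
    tt: TTParams = field(default_factory=TTParams)
    geom: MusAsiParams = field(default_factory=MusAsiParams)

    def __post_init__(self):
        if self.rates.ladder != self.ladder:
            object.__setattr__(self, "rates", replace(self.rates,
                                                      ladder=self.ladder))


def default_model(kind: str = "DSE", gamma: float = 40.0,
                  N_F: int = 16, **geom_overrides) -> ModelParams:
    """Reference parameter set for the DSE or BSE stroke model.

    For the BSE flavour the stroke prefactors become (g1, g2) = (20, 0.1)/s
    and the attachment gate k_np is multiplied by 1.1 so that both flavours
    reach the same maximal activation.
    """
    geom = MusAsiParams(N_F=N_F, **geom_overrides)
    cycle = CycleParams(gamma=gamma)
    rates = RateModel()
    if kind == "BSE":
        rates = replace(rates, kind="BSE", prefactors=(20.0, 0.1))
        cycle = replace(cycle, k_np0=cycle.k_np0 * 1.1)
    elif kind != "DSE":
        raise ValueError("model kind must be 'DSE' or 'BSE'")
    return ModelParams(rates=rates, cycle=cycle, geom=geom)


def pack_params(model: ModelParams) -> np.ndarray:
    """Flatten a ModelParams bundle into the kernel parameter vector."""
    rod, lad, rm, cyc, tt = (model.rod, model.ladder, model.rates,
                             model.cycle, model.tt)
    pk = np.zeros(_K.NPARAMS)
    pk[_K.P_KPOS] = rod.k_pos
    pk[_K.P_KNEG] = rod.k_neg
    pk[_K.P_KBT] = rod.kBT
    pk[_K.P_XMIN] = rod.x_min
    pk[_K.P_XMAX] = rod.x_max
    pk[_K.P_S1] = lad.s1
    pk[_K.P_S2] = lad.s2
    pk[_K.P_E0] = lad.E0
    pk[_K.P_E1] = lad.E1
    pk[_K.P_E2] = lad.E2
    pk[_K.P_PREF1] = rm.prefactors[0]
    pk[_K.P_PREF2] = rm.prefactors[1]
    pk[_K.P_RMAX] = rm.r_max
    pk[_K.P_KIND] = 0.0 if rm.kind == "DSE" else 1.0
    pk[_K.P_KNP0] = cyc.k_np0
    pk[_K.P_KPN0] = cyc.k_pn0
    pk[_K.P_KA] = cyc.k_attach
    pk[_K.P_KD] = cyc.k_detach
    pk[_K.P_KOFF] = cyc.k_cycle
    pk[_K.P_KREC] = cyc.k_recover
    pk[_K.P_GAMMA] = cyc.gamma
    pk[_K.P_PERM_BLOCKED] = cyc.perm_blocked
    pk[_K.P_TT_KON] = tt.k_on_ca
    pk[_K.P_TT_KOFFCA] = tt.k_off_ca
    pk[_K.P_TT_KOPEN] = tt.k_open
    pk[_K.P_TT_KCLOSE] = tt.k_close
    pk[_K.P_HSL0] = model.geom.hsl0
    pk[_K.P_TT_HOLD] = tt.hold_factor
    pk[_K.P_MPT] = cyc.molecules_per_tt
    pk[_K.P_NM] = model.geom.N_M
    return pk
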