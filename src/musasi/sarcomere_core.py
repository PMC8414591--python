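"""Core half-sarcomere domain types: myosin-rod mechanics and stroke kinetics.

Internal unit system: length nm, force pN, energy pN*nm, time ms for macro
bookkeeping (rate constants are stored in 1/s, the field's convention, and
converted where probabilities are formed), concentration uM.  Note that
1 pN/nm^2 == 1 MPa, which is used throughout for tensions.

The myosin cycle has six states: three detached (``N_XB``, ``P_XB``,
``N_ATP``) and three strongly bound (``XB_PreR``, ``XB_PostR1``,
``XB_PostR2``).  The two lever-arm power strokes move the bound head by
``s1`` and ``s2`` nanometres along the filament axis, loading the elastic
myosin rod whose strain energy ``W(x)`` stores the free energy released by
the stroke.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

__all__ = [
    "N_XB", "P_XB", "N_ATP", "XB_PRER", "XB_POSTR1", "XB_POSTR2",
    "STATE_NAMES", "STRONG_STATES", "ATTACHED_SET",
    "RodModel", "FreeEnergyLadder", "RateModel", "MyosinMolecule",
    "rod_energy", "sample_attachment_strain", "stroke_rates", "cap_rates",
]

# Myosin state codes (order fixed; the MC kernel relies on these values).
N_XB = 0        # non-binding, ADP.Pi, thin filament blocked or unfavourable
P_XB = 1        # weakly bound / pre-attachment
N_ATP = 2       # post-rigor, ATP bound, detached
XB_PRER = 3     # strongly bound, pre power stroke
XB_POSTR1 = 4   # after first power stroke (+s1)
XB_POSTR2 = 5   # after second power stroke (+s1+s2)

STATE_NAMES = ("N_XB", "P_XB", "N_ATP", "XB_PreR", "XB_PostR1", "XB_PostR2")
STRONG_STATES = (XB_PRER, XB_POSTR1, XB_POSTR2)
#: states that count toward the nearest-neighbour cooperativity exponent ng
ATTACHED_SET = (P_XB, XB_PRER, XB_POSTR1, XB_POSTR2)


class StrainDomainError(ValueError):
    """Rod strain outside the allowed domain (the head should have detached)."""


@dataclass(frozen=True)
class RodModel:
    """Piecewise-quadratic elastic myosin rod.

    W(x) = 1/2 k_pos x^2 for x >= 0 and 1/2 k_neg x^2 for x < 0; convex for
    non-negative stiffnesses, with a continuous force dW/dx at the origin.
    ``strain_domain`` = [x_min, x_max] is the window outside which a bound
    head is forcibly detached.
    """

    k_pos: float = 2.0    # pN/nm, stiffness at non-negative strain
    k_neg: float = 1.0    # pN/nm, stiffness at negative strain
    kBT: float = 4.28     # pN*nm (310 K)
    x_min: float = -10.0  # nm
    x_max: float = 10.0   # nm

    def __post_init__(self):
        if self.k_pos < 0 or self.k_neg < 0:
            raise ValueError("rod stiffnesses must be non-negative (convexity)")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        if not self.x_min < 0 < self.x_max:
            raise ValueError("strain_domain must contain 0 in its interior")

    # --- unchecked evaluations (defined for all x; used by the rate laws) ---
    def energy(self, x):
        x = np.asarray(x, dtype=float)
        k = np.where(x >= 0.0, self.k_pos, self.k_neg)
        return 0.5 * k * x * x

    def force(self, x):
        """dW/dx in pN."""
        x = np.asarray(x, dtype=float)
        k = np.where(x >= 0.0, self.k_pos, self.k_neg)
        return k * x

    def stiffness(self, x):
        """d2W/dx2 in pN/nm."""
        x = np.asarray(x, dtype=float)
        return np.where(x >= 0.0, self.k_pos, self.k_neg) + 0.0 * x

    def in_domain(self, x):
        x = np.asarray(x, dtype=float)
        return (x >= self.x_min) & (x <= self.x_max)


def rod_energy(rod: RodModel, x):
    """Strain energy, force and stiffness of the rod at strain ``x`` (nm).

    Returns ``(W, dW/dx, d2W/dx2)`` in (pN*nm, pN, pN/nm).  Raises
    :class:`StrainDomainError` outside ``strain_domain``; strains beyond it
    are reserved for the forced-detachment pathway.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(rod.in_domain(x)):
        raise StrainDomainError(
            f"strain outside domain [{rod.x_min}, {rod.x_max}] nm")
    return rod.energy(x), rod.force(x), rod.stiffness(x)


def sample_attachment_strain(rod: RodModel, rng, size=None):
    """Draw initial attachment strains from exp(-W(x)/kBT) on the domain.

    The density is a two-half-Gaussian glued at 0 with standard deviations
    sqrt(kBT/k_neg) (left) and sqrt(kBT/k_pos) (right), truncated to
    ``strain_domain``.  Sampling picks the side by its probability mass and
    draws a truncated half-normal by rejection; with physiological stiffness
    the bounds sit many sigma out so rejections are vanishingly rare and the
    loop terminates almost surely (a 1000-iteration guard raises otherwise).
    """
    scalar = size is None
    n = 1 if scalar else int(np.prod(size))
    sig_p = math.sqrt(rod.kBT / rod.k_pos) if rod.k_pos > 0 else np.inf
    sig_n = math.sqrt(rod.kBT / rod.k_neg) if rod.k_neg > 0 else np.inf
    if not (np.isfinite(sig_p) and np.isfinite(sig_n)):
        raise ValueError("zero-stiffness rod has an improper Boltzmann density")
    # half-Gaussian masses, truncation correction included
    from scipy.stats import norm
    mass_p = sig_p * (norm.cdf(rod.x_max / sig_p) - 0.5)
    mass_n = sig_n * (norm.cdf(-rod.x_min / sig_n) - 0.5)
    p_pos = mass_p / (mass_p + mass_n)
    out = np.empty(n)
    for i in range(n):
        for _ in range(1000):
            if rng.random() < p_pos:
                x = abs(rng.standard_normal()) * sig_p
                if x <= rod.x_max:
                    out[i] = x
                    break
            else:
                x = -abs(rng.standard_normal()) * sig_n
                if x >= rod.x_min:
                    out[i] = x
                    break
        else:  # pragma: no cover - unreachable for sane parameters
            raise RuntimeError("attachment-strain rejection sampler stalled")
    if scalar:
        return float(out[0])
    return out.reshape(size)


@dataclass(frozen=True)
class FreeEnergyLadder:
    """Chemical free-energy levels of the bound states at zero rod strain.

    ``E0 > E1 > E2`` (each stroke releases free energy) with stroke
    distances ``s1, s2 > 0``.  The defaults are fallbacks calibrated to
    give a physiological duty ratio (see docs/methods.md) and are
    overridable via config.
    """

    E0: float = 0.0     # pN*nm, XB_PreR
    E1: float = -36.0   # pN*nm, XB_PostR1
    E2: float = -68.0   # pN*nm, XB_PostR2
    s1: float = 6.0     # nm
    s2: float = 4.0     # nm

    def __post_init__(self):
        if not (self.E0 > self.E1 > self.E2):
            raise ValueError("free energies must decrease: E0 > E1 > E2")
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("power-stroke distances must be positive")

    def levels(self, i: int):
        """(E_{i-1}, E_i, s_i) for stroke index i in {1, 2}."""
        if i == 1:
            return self.E0, self.E1, self.s1
        if i == 2:
            return self.E1, self.E2, self.s2
        raise ValueError("stroke index must be 1 or 2")


@dataclass(frozen=True)
class RateModel:
    """Power/reverse-stroke rate law, destination- or barrier-strain flavour.

    DSE (destination strain energy): the forward rate is penalised by the
    strain energy at the destination, the backward rate by the strain energy
    at the origin,

        h_f,i(x)      = h_i exp(-(W(x+s_i) - (E_{i-1} - E_i)) / kBT)
        h_b,i(x+s_i)  = h_i exp(-W(x) / kBT).

    BSE (barrier strain energy, Kramers escape picture): both rates reference
    the barrier located at the mid strain,

        h_f,i(x)      = g_i exp((E_{i-1} + W(x) - E_i - W(x+s_i/2)) / kBT)
        h_b,i(x+s_i)  = g_i exp((W(x+s_i) - W(x+s_i/2)) / kBT).

    Both satisfy the Boltzmann condition
    h_f,i(x)/h_b,i(x+s_i) = exp(-dG_i(x)/kBT) with
    dG_i(x) = E_i + W(x+s_i) - E_{i-1} - W(x), and the capping rule rescales
    a pair exceeding ``r_max`` so that the condition is preserved exactly.
    """

    kind: str = "DSE"                   # {"DSE", "BSE"}
    prefactors: tuple = (1000.0, 1000.0)  # (h1, h2) or (g1, g2), 1/s
    ladder: FreeEnergyLadder = field(default_factory=FreeEnergyLadder)
    r_max: float = 1.0e5                # 1/s

    def __post_init__(self):
        if self.kind not in ("DSE", "BSE"):
            raise ValueError(f"unknown rate-model kind {self.kind!r}")
        if len(self.prefactors) != 2 or min(self.prefactors) <= 0:
            raise ValueError("need two positive stroke prefactors")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")

    def with_kind(self, kind: str, g1: float = 20.0, g2: float = 0.1):
        if kind == self.kind:
            return self
        if kind == "BSE":
            return replace(self, kind="BSE", prefactors=(g1, g2))
        raise ValueError("can only switch DSE -> BSE with explicit prefactors")


def cap_rates(h_f, h_b, r_max):
    """Rescale a forward/backward rate pair so neither exceeds ``r_max``.

    If max(h_f, h_b) > r_max both rates are multiplied by
    r_max / max(h_f, h_b): the larger becomes exactly r_max and the ratio
    h_f/h_b -- hence detailed balance -- is preserved to machine precision.
    """
    h_f = np.asarray(h_f, dtype=float)
    h_b = np.asarray(h_b, dtype=float)
    hi = np.maximum(h_f, h_b)
    scale = np.where(hi > r_max, r_max / np.where(hi > 0, hi, 1.0), 1.0)
    return h_f * scale, h_b * scale


def stroke_rates(model: RateModel, rod: RodModel, i: int, x):
    """Capped forward/backward rates (1/s) of stroke ``i`` at origin strain x.

    Returns ``(h_f,i(x), h_b,i(x + s_i))`` -- the pair linked by the
    Boltzmann condition.  ``x`` may be an array.  The strain energy is
    evaluated by the rod's global piecewise-quadratic form; the caller is
    responsible for keeping live heads inside the strain domain (the MC
    engine detaches them otherwise).
    """
    Ei0, Ei1, si = model.ladder.levels(i)
    pref = model.prefactors[i - 1]
    kBT = rod.kBT
    x = np.asarray(x, dtype=float)
    Wx = rod.energy(x)
    Wxs = rod.energy(x + si)
    if model.kind == "DSE":
        h_f = pref * np.exp(-(Wxs - (Ei0 - Ei1)) / kBT)
        h_b = pref * np.exp(-Wx / kBT)
    else:  # BSE
        Wmid = rod.energy(x + 0.5 * si)
        h_f = pref * np.exp((Ei0 + Wx - Ei1 - Wmid) / kBT)
        h_b = pref * np.exp((Wxs - Wmid) / kBT)
    h_f = np.where(np.isfinite(h_f), h_f, 0.0)
    h_b = np.where(np.isfinite(h_b), h_b, 0.0)
    return cap_rates(h_f, h_b, model.r_max)


@dataclass
class MyosinMolecule:
    """Single myosin head, mainly for tests and illustration.

    The production engine stores ensembles as flat arrays; this object mirrors
    one entry.  ``x_A`` (attachment strain, nm), ``lambda_A`` (stretch at most
    recent attachment) and ``k_A`` (micro-step index of that attachment) are
    defined only while the head is strongly bound.
    """

    state: int = N_XB
    x_A: float = np.nan
    s: float = 0.0          # stroke offset, in {0, s1, s1+s2}
    lambda_A: float = np.nan
    k_A: int = -1

    @property
    def bound(self) -> bool:
        return self.state in STRONG_STATES

    def validate(self, ladder: FreeEnergyLadder):
        if self.bound:
            expected = {XB_PRER: 0.0, XB_POSTR1: ladder.s1,
                        XB_POSTR2: ladder.s1 + ladder.s2}[self.state]
            if self.s != expected:
                raise ValueError(
                    f"stroke offset {self.s} inconsistent with state "
                    f"{STATE_NAMES[self.state]}")
            if not np.isfinite(self.x_A) or not np.isfinite(self.lambda_A):
                raise ValueError("bound head must carry x_A and lambda_A")
        else:
            if np.isfinite(self.x_A) or np.isfinite(self.lambda_A):
                raise ValueError("detached head must not carry attachment data")
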