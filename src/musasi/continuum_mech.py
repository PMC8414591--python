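"""Continuum-side mechanics: fiber stretch operators, active stress tensor,
the Newmark-beta/Newton implicit loop, stability estimates, and two reduced
testbeds (a uniaxial strip with a single stretch degree of freedom and a
serial myofibril chain).

Macro units: stress MPa (= pN/nm^2), time ms, stretch dimensionless.  The
tissue viscosity mu_S is specified in Pa*s, the field's convention, and
converted internally (1 Pa*s = 1e-3 MPa*ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .montecarlo_engine import HalfSarcomereEnsemble, atp_per_batch
from .musasi_scheme import TensionEvaluator
from .params import ModelParams, default_model, num_mc_steps
from .sarcomere_core import RodModel

__all__ = [
    "stretch", "stretch_rate", "active_pk2", "stretch_hessian",
    "axial_stiffness_coefficient", "explicit_stability_bound",
    "newmark_newton_step", "NewmarkStepResult", "NonConvergenceError",
    "PassiveLaw", "TestbedConfig", "UniaxialStrip", "MyofibrilChain",
    "run_uniaxial_twitch", "run_myofibril_chain",
]


# ---------------------------------------------------------------------------
# fiber kinematics and active stress tensor algebra

def stretch(F, f):
    """Fiber stretch lambda = ||F f||."""
    F = np.asarray(F, dtype=float)
    f = np.asarray(f, dtype=float)
    lam = float(np.linalg.norm(F @ f))
    if lam <= 0.0 or not np.isfinite(lam):
        raise ValueError("degenerate deformation: ||F f|| must be positive")
    return lam


def stretch_rate(F, Fdot, f):
    """Material stretch rate lambda_dot = (Fdot f).(F f)/lambda."""
    F = np.asarray(F, dtype=float)
    Fdot = np.asarray(Fdot, dtype=float)
    f = np.asarray(f, dtype=float)
    Ff = F @ f
    lam = float(np.linalg.norm(Ff))
    if lam <= 0.0:
        raise ValueError("degenerate deformation: ||F f|| must be positive")
    return float((Fdot @ f) @ Ff / lam)


def active_pk2(T_act, lam, f):
    """Second Piola-Kirchhoff active stress S_act = (T_act/lambda) f (x) f."""
    if lam <= 0:
        raise ValueError("stretch must be positive")
    f = np.asarray(f, dtype=float)
    return (T_act / lam) * np.outer(f, f)


def stretch_hessian(F, f, dF):
    """Second variation of stretch along dF.

    delta^2 lambda = (1/lambda) [ (dF f).(dF f) - (a.(dF f))^2 ] with
    a = F f / lambda; non-negative for every variation (Cauchy-Schwarz),
    which is what makes the T_act * delta^2 lambda stiffness term
    positive-semidefinite for non-negative active tension.
    """
    F = np.asarray(F, dtype=float)
    f = np.asarray(f, dtype=float)
    dF = np.asarray(dF, dtype=float)
    Ff = F @ f
    lam = float(np.linalg.norm(Ff))
    if lam <= 0.0:
        raise ValueError("degenerate deformation")
    a = Ff / lam
    v = dF @ f
    return float((v @ v - (a @ v) ** 2) / lam)


# ---------------------------------------------------------------------------
# stability estimates

def axial_stiffness_coefficient(params, rod: RodModel, R_B: float) -> float:
    """Macroscopic axial active stiffness K_A (MPa) at binding ratio R_B.

    K_A = (R_S/SA0) * R_B * 2 N_M * k_rod * (SL0/2): every bound head adds a
    rod spring k_rod acting over the half-sarcomere lever SL0/2, with the
    factor 2 N_M counting the heads accessible per thin filament.
    """
    if not 0.0 <= R_B <= 1.0:
        raise ValueError("binding ratio must lie in [0, 1]")
    return (params.RS / params.SA0) * R_B * 2.0 * params.N_M \
        * rod.k_pos * params.hsl0


def explicit_stability_bound(mu_S: float, K_A: float) -> float:
    """Largest stable macro step (microseconds) of the explicit tension
    approach: DT_max ~ mu_S / K_A, with mu_S in Pa*s and K_A in MPa."""
    if K_A < 0:
        raise ValueError("stiffness must be non-negative")
    if K_A == 0.0:
        return float("inf")
    return mu_S / (K_A * 1.0e6) * 1.0e6  # s -> us


# ---------------------------------------------------------------------------
# Newmark-beta / Newton implicit step

class NonConvergenceError(RuntimeError):
    def __init__(self, msg, res_norm):
        super().__init__(msg)
        self.res_norm = res_norm


@dataclass
class NewmarkStepResult:
    U: np.ndarray
    Ud: np.ndarray
    Udd: np.ndarray
    iterations: int
    res_norm: float


def newmark_newton_step(U, Ud, Udd, DT, residual, matrices,
                        beta: float = 0.25, gamma_n: float = 0.5,
                        tol: float = 1e-9, max_iter: int = 25
                        ) -> NewmarkStepResult:
    """One implicit Newmark-beta step solved by Newton iterations.

    ``residual(U, Ud, Udd)`` returns R; ``matrices(U, Ud, Udd)`` returns
    (K, C, M) = (dR/dU, dR/dUd, dR/dUdd).  The iteration starts from the
    previous state, which does not satisfy the Newmark interpolation rules,
    so the first linear solve always runs and uses the predictor-corrected
    right-hand side and update; convergence is checked from the second
    residual on (the start-of-step residual is exactly zero whenever the
    previous step converged, so accepting on it would freeze the state).
    ``iterations`` counts linear solves; a stationary state costs one.
    """
    U0 = np.atleast_1d(np.asarray(U, dtype=float)).copy()
    Ud0 = np.atleast_1d(np.asarray(Ud, dtype=float)).copy()
    Udd0 = np.atleast_1d(np.asarray(Udd, dtype=float)).copy()
    Uk, Udk, Uddk = U0.copy(), Ud0.copy(), Udd0.copy()

    res_norm = np.inf
    for it in range(max_iter):
        R = np.atleast_1d(np.asarray(residual(Uk, Udk, Uddk), dtype=float))
        res_norm = float(np.linalg.norm(R))
        if it >= 1 and res_norm <= tol:
            return NewmarkStepResult(Uk, Udk, Uddk, it, res_norm)
        K, C, M = matrices(Uk, Udk, Uddk)
        K = np.atleast_2d(np.asarray(K, dtype=float))
        C = np.atleast_2d(np.asarray(C, dtype=float))
        M = np.atleast_2d(np.asarray(M, dtype=float))
        A = M + gamma_n * DT * C + beta * DT * DT * K
        if it == 0:
            rhs = (-R - C @ (DT * Udd0)
                   - K @ (DT * Ud0 + 0.5 * DT * DT * Udd0))
        else:
            rhs = -R
        dUdd = np.linalg.solve(A, rhs)
        if it == 0:
            Uddk = Udd0 + dUdd
            Udk = Ud0 + DT * (gamma_n * dUdd + Udd0)
            Uk = U0 + DT * Ud0 + DT * DT * (beta * dUdd + 0.5 * Udd0)
        else:
            Uddk = Uddk + dUdd
            Udk = Udk + gamma_n * DT * dUdd
            Uk = Uk + beta * DT * DT * dUdd
    # accept if the final post-solve residual meets the tolerance
    R = np.atleast_1d(np.asarray(residual(Uk, Udk, Uddk), dtype=float))
    res_norm = float(np.linalg.norm(R))
    if res_norm <= tol:
        return NewmarkStepResult(Uk, Udk, Uddk, max_iter, res_norm)
    raise NonConvergenceError(
        f"Newton did not reach ||R|| <= {tol:g} in {max_iter} iterations "
        f"(last ||R|| = {res_norm:.3e})", res_norm)


# ---------------------------------------------------------------------------
# testbeds

@dataclass(frozen=True)
class PassiveLaw:
    """Odd exponential uniaxial passive stress T_pas = c * sinh(b*(lam-1)).

    kPa-scale stiffness (c*b) at small strain; parameters are testbed
    conventions, not printed model constants.
    """

    c: float = 0.004   # MPa
    b: float = 15.0

    def tension(self, lam):
        return self.c * np.sinh(self.b * (np.asarray(lam, dtype=float) - 1.0))

    def stiffness(self, lam):
        return self.c * self.b * np.cosh(
            self.b * (np.asarray(lam, dtype=float) - 1.0))


@dataclass(frozen=True)
class TestbedConfig:
    """Mechanical constants of the reduced testbeds."""

    scheme: str = "implicit"       # {"implicit", "explicit"}
    DT: float = 1.25               # ms
    mu_S: float = 36.66            # Pa*s, half-sarcomere viscosity
    passive: PassiveLaw = field(default_factory=PassiveLaw)
    mass: float = 1.0e-7           # MPa*ms^2, tiny consistent inertia
    T_ext: float = 0.0             # MPa, external tension on the strip
    newton_tol: float = 1.0e-9     # MPa, residual norm
    max_newton: int = 25
    # lightly damped Newmark: gamma_n > 1/2 with beta = (gamma_n + 1/2)^2/4
    # suppresses velocity ringing against the Monte Carlo tension noise,
    # which would otherwise feed spurious sliding into the micro model
    beta: float = 0.3025
    gamma_n: float = 0.6
    # chain extras: nodal drag sized so tension imbalances of a few kPa
    # translate into sliding speeds of order 0.1 um/s, and a titin-like
    # stiffer element spring so an activated element stalls near 10%
    # shortening instead of creeping indefinitely
    n_half_sarcomeres: int = 40
    node_drag: float = 20.0        # MPa*ms, nodal drag per unit stretch rate
    chain_passive: PassiveLaw = field(
        default_factory=lambda: PassiveLaw(c=0.01, b=15.0))
    divergence_limit: float = 0.5  # |lam - 1| beyond which a run is divergent

    @property
    def eta(self) -> float:
        """Viscous stress coefficient in MPa*ms per unit stretch rate."""
        return self.mu_S * 1.0e-3

    def __post_init__(self):
        if self.scheme not in ("implicit", "explicit"):
            raise ValueError("scheme must be 'implicit' or 'explicit'")


class UniaxialStrip:
    """Single-stretch-DOF strip: active + passive + viscous tension balance.

    m*lam_dd + eta*lam_d + T_pas(lam) + T_act = T_ext, stepped by the
    implicit Newmark/Newton loop.  T_act comes from the half-sarcomere MC
    interval: re-evaluated at the trial stretch with its consistent
    stiffness (implicit scheme) or frozen on the extrapolated strains with
    zero stiffness (explicit scheme).
    """

    def __init__(self, model: ModelParams | None = None,
                 config: TestbedConfig | None = None, seed: int = 0):
        self.model = model if model is not None else default_model()
        self.config = config if config is not None else TestbedConfig()
        self.hs = HalfSarcomereEnsemble(self.model, batch=1, seed=seed)
        self.lam = 1.0
        self.lam_d = 0.0    # 1/ms
        self.lam_dd = 0.0
        self.time = 0.0
        self.diverged_at: Optional[float] = None

    def step(self, ca) -> dict:
        cfg = self.config
        DT = cfg.DT
        n = num_mc_steps(DT, self.model.geom.dt0)
        rec = self.hs.run_interval(DT=DT, n=n, ca=ca, lam_dot=self.lam_d)
        ev = TensionEvaluator(rec, self.model.geom, self.model.rod)
        if cfg.scheme == "explicit":
            T_expl = float(ev.explicit_tension()[0])

        def tension(lam):
            if cfg.scheme == "implicit":
                T, K = ev.tension_stiffness(lam)
                return float(T[0]), float(K[0])
            return T_expl, 0.0

        pas = cfg.passive

        def residual(U, Ud, Udd):
            T_act, _ = tension(U[0])
            return np.array([
                cfg.mass * Udd[0] + cfg.eta * Ud[0]
                + float(pas.tension(U[0])) + T_act - cfg.T_ext])

        def matrices(U, Ud, Udd):
            _, K_act = tension(U[0])
            K = np.array([[float(pas.stiffness(U[0])) + K_act]])
            C = np.array([[cfg.eta]])
            M = np.array([[cfg.mass]])
            return K, C, M

        try:
            res = newmark_newton_step(
                [self.lam], [self.lam_d], [self.lam_dd], DT,
                residual, matrices, beta=cfg.beta, gamma_n=cfg.gamma_n,
                tol=cfg.newton_tol, max_iter=cfg.max_newton)
            iters, rnorm = res.iterations, res.res_norm
            lam_new = float(res.U[0])
            self.lam_d, self.lam_dd = float(res.Ud[0]), float(res.Udd[0])
        except NonConvergenceError as err:  # reported, not fatal
            iters, rnorm = self.config.max_newton, err.res_norm
            lam_new = self.lam
        self.hs.finalize_interval(rec, [lam_new])
        self.lam = lam_new
        self.time += DT
        T_act, K_act = tension(self.lam)
        if (not np.isfinite(self.lam)
                or abs(self.lam - 1.0) > cfg.divergence_limit):
            if self.diverged_at is None:
                self.diverged_at = self.time
        return {
            "t": self.time, "lam": self.lam, "lam_dot": self.lam_d,
            "T_act": T_act, "dT_dlam": K_act,
            "atp": int(atp_per_batch(rec)[0]),
            "R_B": float(rec.binding_ratio()[0]),
            "newton_iters": iters, "res_norm": rnorm,
        }

    def run(self, duration: float, ca: Callable[[float], float] | float,
            stop_on_divergence: bool = True) -> pd.DataFrame:
        rows = []
        nsteps = int(round(duration / self.config.DT))
        for _ in range(nsteps):
            ca_val = ca(self.time) if callable(ca) else ca
            rows.append(self.step(ca_val))
            if stop_on_divergence and self.diverged_at is not None:
                break
        return pd.DataFrame(rows)


class MyofibrilChain:
    """Serial chain of half-sarcomeres with fixed ends.

    Degrees of freedom are the internal node positions in units of the
    unloaded half-sarcomere length, so element stretches are nearest-node
    differences.  Each element carries MusAsi active tension/stiffness plus
    the passive and viscous laws of the strip; nodes feel a viscous drag.
    The Newton matrix is tridiagonal.  Under partially activating constant
    Ca, the force-velocity asymmetry of the cross-bridge ensemble makes the
    homogeneous state unstable and sawtooth length oscillations (SPOC)
    emerge without any Ca oscillation.
    """

    def __init__(self, model: ModelParams | None = None,
                 config: TestbedConfig | None = None, seed: int = 0):
        self.model = model if model is not None else default_model(N_F=4)
        self.config = config if config is not None else TestbedConfig()
        N = self.config.n_half_sarcomeres
        if N < 2:
            raise ValueError("chain needs at least two half-sarcomeres")
        self.N = N
        self.hs = HalfSarcomereEnsemble(self.model, batch=N, seed=seed)
        self.U = np.arange(1, N, dtype=float)    # internal nodes, rest pos.
        self.Ud = np.zeros(N - 1)
        self.Udd = np.zeros(N - 1)
        self.time = 0.0
        self.diverged_at: Optional[float] = None

    # node-position <-> stretch helpers (ends fixed at 0 and N)
    def _lams(self, U):
        full = np.concatenate(([0.0], U, [float(self.N)]))
        return np.diff(full)

    @property
    def lams(self) -> np.ndarray:
        return self._lams(self.U)

    def step(self, ca) -> dict:
        cfg = self.config
        DT = cfg.DT
        n = num_mc_steps(DT, self.model.geom.dt0)
        lam = self._lams(self.U)
        lam_d = self._lams_rate(self.Ud)
        self.hs.lam = lam.copy()
        rec = self.hs.run_interval(DT=DT, n=n, ca=ca, lam_dot=lam_d)
        ev = TensionEvaluator(rec, self.model.geom, self.model.rod)
        if cfg.scheme == "explicit":
            T_expl = ev.explicit_tension()

        pas = cfg.chain_passive

        def element_tension(lams, lams_d):
            if cfg.scheme == "implicit":
                T_act, K_act = ev.tension_stiffness(lams)
            else:
                T_act, K_act = T_expl, np.zeros(self.N)
            T = T_act + pas.tension(lams) + cfg.eta * lams_d
            K = K_act + pas.stiffness(lams)
            return T, K

        def residual(U, Ud, Udd):
            T, _ = element_tension(self._lams(U), self._lams_rate(Ud))
            # node j feels tension difference between its two elements
            return (cfg.mass * Udd + cfg.node_drag * Ud
                    - (T[1:] - T[:-1]))

        def matrices(U, Ud, Udd):
            lams = self._lams(U)
            _, Kel = element_tension(lams, self._lams_rate(Ud))
            K = self._assemble_tridiag(Kel)
            C = (cfg.node_drag * np.eye(self.N - 1)
                 + self._assemble_tridiag(np.full(self.N, cfg.eta)))
            M = cfg.mass * np.eye(self.N - 1)
            return K, C, M

        try:
            res = newmark_newton_step(
                self.U, self.Ud, self.Udd, DT, residual, matrices,
                beta=cfg.beta, gamma_n=cfg.gamma_n,
                tol=cfg.newton_tol * np.sqrt(self.N), max_iter=cfg.max_newton)
            self.U, self.Ud, self.Udd = res.U, res.Ud, res.Udd
            iters, rnorm = res.iterations, res.res_norm
        except NonConvergenceError as err:
            iters, rnorm = cfg.max_newton, err.res_norm
        lam_new = self._lams(self.U)
        self.hs.finalize_interval(rec, lam_new)
        self.time += DT
        if (not np.all(np.isfinite(lam_new))
                or np.any(np.abs(lam_new - 1.0) > cfg.divergence_limit)):
            if self.diverged_at is None:
                self.diverged_at = self.time
        T_act, _ = (ev.tension_stiffness(lam_new)
                    if cfg.scheme == "implicit" else (T_expl, None))
        return {
            "t": self.time, "lams": lam_new,
            "T_act": np.asarray(T_act),
            "atp": atp_per_batch(rec),
            "R_B": rec.binding_ratio(),
            "edge_counts": rec.edge_counts.copy(),
            "newton_iters": iters, "res_norm": rnorm,
        }

    def _lams_rate(self, Ud):
        full = np.concatenate(([0.0], Ud, [0.0]))
        return np.diff(full)

    def _assemble_tridiag(self, Kel):
        """dR_j/dU_l for R_j = -(T_{j+1} - T_j) with T_i = T_i(U_i - U_{i-1})."""
        N = self.N
        A = np.zeros((N - 1, N - 1))
        for j in range(N - 1):
            A[j, j] = Kel[j] + Kel[j + 1]
            if j > 0:
                A[j, j - 1] = -Kel[j]
            if j < N - 2:
                A[j, j + 1] = -Kel[j + 1]
        return A

    def run(self, duration: float, ca, record_every: int = 1) -> pd.DataFrame:
        rows = []
        nsteps = int(round(duration / self.config.DT))
        for i in range(nsteps):
            ca_val = ca(self.time) if callable(ca) else ca
            out = self.step(ca_val)
            if i % record_every == 0:
                rows.append(out)
            if self.diverged_at is not None:
                break
        return pd.DataFrame(rows)


def run_uniaxial_twitch(model: ModelParams | None = None,
                        config: TestbedConfig | None = None,
                        ca: Callable[[float], float] | float = 1.0,
                        duration: float = 1000.0, seed: int = 0
                        ) -> pd.DataFrame:
    """Full-period uniaxial twitch; returns the per-macro-step time series.

    Columns: t (ms), lam, T_act (MPa), dT_dlam, atp, R_B, newton_iters.
    Explicit-scheme divergence is reported via the ``diverged_at`` attribute
    stored in ``DataFrame.attrs``; it is not an exception.
    """
    strip = UniaxialStrip(model=model, config=config, seed=seed)
    df = strip.run(duration, ca)
    df.attrs["diverged_at"] = strip.diverged_at
    return df


def run_myofibril_chain(model: ModelParams | None = None,
                        config: TestbedConfig | None = None,
                        ca: float = 0.3, duration: float = 4000.0,
                        seed: int = 0) -> pd.DataFrame:
    """Serial-chain run at constant Ca; returns per-step rows with the
    per-half-sarcomere stretch vector in column ``lams``."""
    chain = MyofibrilChain(model=model, config=config, seed=seed)
    df = chain.run(duration, ca)
    df.attrs["diverged_at"] = chain.diverged_at
    return df
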