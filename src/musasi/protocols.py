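"""Physiological protocols on the reduced testbeds.

All protocols are deterministic given a seed, return tidy DataFrames with
standard-error estimates, and use the batched ensemble so that a whole
condition grid advances in one compiled sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .continuum_mech import TestbedConfig, UniaxialStrip, run_myofibril_chain
from .montecarlo_engine import HalfSarcomereEnsemble, atp_per_batch
from .musasi_scheme import TensionEvaluator
from .params import ModelParams, default_model, num_mc_steps

__all__ = [
    "CaDriver", "ca_transient", "run_isometric", "hill_fit",
    "force_pca_curve", "force_velocity_curve", "stability_sweep",
    "detect_oscillations", "run_spoc",
]


@dataclass(frozen=True)
class CaDriver:
    """Parametric intracellular Ca2+ drive (uM).

    ``transient`` mode is a periodic double-exponential pulse riding on a
    diastolic pedestal: the pulse is normalised so the maximum equals
    ``peak`` and, with the default time constants, the minimum over a period
    stays at the diastolic fraction (about 10 % of peak) -- the residual
    Ca2+ the cooperative mechanism must ignore during relaxation.  The peak
    level is a convention, not a printed value.
    """

    mode: str = "transient"        # {"constant", "transient"}
    level: float = 0.3             # uM, constant mode
    peak: float = 1.0              # uM
    diastolic_frac: float = 0.1
    tau_rise: float = 20.0         # ms
    tau_decay: float = 150.0       # ms
    period: float = 1000.0         # ms (60 beats per minute)

    def __post_init__(self):
        if self.mode not in ("constant", "transient"):
            raise ValueError("mode must be 'constant' or 'transient'")
        if self.tau_decay <= self.tau_rise:
            raise ValueError("decay must be slower than rise")

    def __call__(self, t):
        return ca_transient(t, self)


def ca_transient(t, driver: CaDriver):
    """Ca2+ concentration (uM) at time t (ms); vectorised in t."""
    t = np.asarray(t, dtype=float)
    if driver.mode == "constant":
        out = np.full_like(t, driver.level)
        return float(out) if out.ndim == 0 else out
    tr, td = driver.tau_rise, driver.tau_decay
    tm = np.mod(t, driver.period)
    g = np.exp(-tm / td) - np.exp(-tm / tr)
    tstar = math.log(td / tr) * tr * td / (td - tr)
    gmax = math.exp(-tstar / td) - math.exp(-tstar / tr)
    dia = driver.diastolic_frac * driver.peak
    out = dia + (driver.peak - dia) * g / gmax
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# isometric steady state

def run_isometric(model: ModelParams, ca_levels, duration: float = 1200.0,
                  seed: int = 0, lam: float = 1.0):
    """Advance one batched ensemble (one entry per Ca level) isometrically.

    Returns (t, tension, binding, state_fracs): tension and binding have
    shape (n_macro, B); state_fracs is the (B, 6) time-averaged occupancy
    over the final half of the run.
    """
    ca_levels = np.atleast_1d(np.asarray(ca_levels, dtype=float))
    B = ca_levels.size
    hs = HalfSarcomereEnsemble(model, batch=B, seed=seed, lam0=lam)
    g = model.geom
    n_macro = int(round(duration / g.DT))
    tension = np.empty((n_macro, B))
    binding = np.empty((n_macro, B))
    fr_acc = np.zeros((B, 6))
    n_acc = 0
    for i in range(n_macro):
        rec = hs.run_interval(ca=ca_levels, lam_dot=0.0)
        ev = TensionEvaluator(rec, g, model.rod)
        tension[i], _ = ev.tension_stiffness(hs.lam)
        binding[i] = rec.binding_ratio()
        if i >= n_macro // 2:
            fr_acc += rec.state_fractions()
            n_acc += 1
    t = np.arange(1, n_macro + 1) * g.DT
    return t, tension, binding, fr_acc / max(n_acc, 1)


def _steady_stats(series: np.ndarray, n_blocks: int = 8):
    """Mean, block-based SE and a Mann-Kendall trend p-value over blocks."""
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    se = means.std(ddof=1) / math.sqrt(n_blocks)
    tau, p = stats.kendalltau(np.arange(n_blocks), means)
    return means.mean(), se, p


def hill_fit(ca: np.ndarray, tension: np.ndarray):
    """Fit T = T_max * Ca^n / (Ca50^n + Ca^n); returns (T_max, pCa50, n_H)."""
    ca = np.asarray(ca, dtype=float)
    tension = np.asarray(tension, dtype=float)
    tmax0 = max(tension.max(), 1e-9)
    ca50_0 = ca[np.argmin(np.abs(tension - 0.5 * tmax0))]

    def f(c, tmax, ca50, nh):
        return tmax * c ** nh / (ca50 ** nh + c ** nh)

    popt, _ = optimize.curve_fit(
        f, ca, tension, p0=[tmax0, ca50_0, 4.0],
        bounds=([0.0, 1e-3, 0.3], [10 * tmax0, 1e3, 40.0]), maxfev=20000)
    tmax, ca50, nh = popt
    return float(tmax), float(-math.log10(ca50 * 1e-6)), float(nh)


def force_pca_curve(model: ModelParams | None = None,
                    pca_grid: Sequence[float] = (6.6, 6.3, 6.1, 5.9, 5.7,
                                                 5.4, 5.0),
                    duration: float = 1200.0, seed: int = 0,
                    fit: bool = True):
    """Steady isometric tension vs pCa at unloaded sarcomere length.

    Tension is averaged over the final half of each constant-Ca run with a
    block standard error and a Mann-Kendall trend check (``steady`` False
    flags a drifting window).  Returns (DataFrame, hill) where hill is the
    fitted (T_max, pCa50, n_H) or None.
    """
    model = model if model is not None else default_model()
    pca = np.asarray(pca_grid, dtype=float)
    ca = 10.0 ** (-pca) * 1e6  # uM
    t, tension, binding, fracs = run_isometric(model, ca, duration, seed)
    half = tension.shape[0] // 2
    rows = []
    for j in range(ca.size):
        mean, se, p = _steady_stats(tension[half:, j])
        rb_mean = binding[half:, j].mean()
        rows.append({"pCa": pca[j], "Ca_uM": ca[j], "T_act": mean,
                     "T_se": se, "R_B": rb_mean,
                     "XB_PostR2_frac": fracs[j, 5],
                     "steady": bool(p > 0.05 or abs(mean) < 3 * se)})
    df = pd.DataFrame(rows)
    hill = hill_fit(df["Ca_uM"].values, df["T_act"].values) if fit else None
    return df, hill


# ---------------------------------------------------------------------------
# force-velocity

def force_velocity_curve(model: ModelParams | None = None,
                         velocities=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
                         ca: float = 0.7, activate_ms: float = 500.0,
                         max_shortening: float = 0.10, seed: int = 0):
    """Steady shortening tension vs half-sarcomere velocity at fixed Ca.

    All velocities advance as one batch: isometric activation, then a
    constant-velocity ramp per batch entry.  Tension for each velocity is
    averaged over the window where its stretch lies in
    [1 - max_shortening, 1) (excluding the first quarter of the ramp); the
    ATP consumption rate over the same window is reported alongside.
    Velocities in um/s per half-sarcomere.
    """
    model = model if model is not None else default_model()
    g = model.geom
    v = np.asarray(velocities, dtype=float)
    B = v.size
    lam_dot = -(v * 1e-3) / (g.hsl0 * 1e-3)  # um/s -> 1/ms
    hs = HalfSarcomereEnsemble(model, batch=B, seed=seed)
    n_act = int(round(activate_ms / g.DT))
    for _ in range(n_act):
        rec = hs.run_interval(ca=ca, lam_dot=0.0)
    # ramp long enough for the slowest moving entry to finish its window
    # (1 um/s equals 1 nm/ms, so ramp time = shortening distance / speed)
    v_min_pos = v[v > 0].min() if np.any(v > 0) else 1.0
    ramp_ms = max_shortening * g.hsl0 / v_min_pos if np.any(v > 0) else 500.0
    ramp_ms = min(ramp_ms, 1500.0)
    n_ramp = int(round(ramp_ms / g.DT))
    T_hist = np.empty((n_ramp, B))
    lam_hist = np.empty((n_ramp, B))
    atp_hist = np.empty((n_ramp, B))
    for i in range(n_ramp):
        rec = hs.run_interval(ca=ca, lam_dot=lam_dot)
        ev = TensionEvaluator(rec, g, model.rod)
        lam_new = hs.lam + g.DT * lam_dot
        T_hist[i], _ = ev.tension_stiffness(lam_new)
        atp_hist[i] = atp_per_batch(rec)
        hs.finalize_interval(rec, lam_new)
        lam_hist[i] = lam_new
    rows = []
    n_mol = g.n_molecules
    for j in range(B):
        in_win = lam_hist[:, j] >= 1.0 - max_shortening
        idx = np.nonzero(in_win)[0]
        idx = idx[len(idx) // 4:]  # drop the early transient of the ramp
        mean, se, _ = _steady_stats(T_hist[idx, j],
                                    n_blocks=min(8, max(2, len(idx) // 4)))
        atp_rate = atp_hist[idx, j].sum() / (len(idx) * g.DT * 1e-3) / n_mol
        rows.append({"velocity_um_s": v[j], "T_act": mean, "T_se": se,
                     "atp_per_mol_s": atp_rate, "n_window": len(idx)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# explicit/implicit stability sweep

def stability_sweep(model: ModelParams | None = None,
                    dt_grid_ms: Iterable[float] = (1.25, 0.15625, 0.0390625,
                                                   0.009765625),
                    schemes: Iterable[str] = ("implicit", "explicit"),
                    ca_driver: CaDriver | None = None,
                    duration: float = 600.0, seed: int = 0,
                    config: TestbedConfig | None = None) -> pd.DataFrame:
    """Classify uniaxial twitch runs as stable/divergent per (scheme, DT).

    A run is hard-unstable when |lam - 1| exceeds the divergence limit or
    goes non-finite; the first failure time is reported.  Because forced
    detachment saturates the cross-bridge feedback, the explicit scheme at a
    too-large macro step typically fails as a *bounded* macro-step
    oscillation (wrong results without Newton breakdown) rather than
    overflow, so two waveform metrics are reported alongside: the
    stretch-reversal rate (mean U-turn amplitude of the lam increments per
    ms) and the mean active tension over the contraction window, which the
    oscillation suppresses by stripping bound heads.
    """
    model = model if model is not None else default_model()
    ca = ca_driver if ca_driver is not None else CaDriver()
    base = config if config is not None else TestbedConfig()
    rows = []
    for scheme in schemes:
        for DT in dt_grid_ms:
            cfg = replace(base, scheme=scheme, DT=DT)
            strip = UniaxialStrip(model=model, config=cfg, seed=seed)
            df = strip.run(duration, ca)
            lam = df["lam"].to_numpy()
            t = df["t"].to_numpy()
            d = np.diff(lam)
            s = np.sign(d)
            rev = np.minimum(np.abs(d[1:]), np.abs(d[:-1]))
            rev = rev[(s[1:] * s[:-1]) < 0]
            span = max(t[-1] - t[0], 1e-9)
            win = (t > 60.0) & (t < duration - 30.0)
            rows.append({
                "scheme": scheme, "DT_ms": DT,
                "stable": strip.diverged_at is None,
                "first_failure_ms": strip.diverged_at,
                "reversal_per_ms": float(rev.sum() / span),
                "mean_T_act": float(df["T_act"].to_numpy()[win].mean()),
                "peak_R_B": float(df["R_B"].max()),
                "max_newton": int(df["newton_iters"].max()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SPOC

def detect_oscillations(lams: np.ndarray, min_amplitude: float = 0.04,
                        min_reversals: int = 3, discard_frac: float = 0.25):
    """Per-half-sarcomere oscillation detection on a (steps, N) stretch log.

    An element oscillates when, after discarding the initial transient, its
    peak-to-peak stretch excursion exceeds ``min_amplitude`` and its
    trajectory reverses direction at least ``min_reversals`` times with
    hysteresis of half the amplitude threshold (sawtooth counting).
    Returns (fraction_oscillating, per_element_table).
    """
    lams = np.asarray(lams, dtype=float)
    start = int(lams.shape[0] * discard_frac)
    win = lams[start:]
    rows = []
    hyst = 0.5 * min_amplitude
    for j in range(win.shape[1]):
        x = win[:, j]
        ptp = float(np.ptp(x))
        reversals = 0
        direction = 0
        ref = x[0]
        for v in x:
            if direction >= 0 and v < ref - hyst:
                reversals += 1 if direction != 0 else 0
                direction = -1
                ref = v
            elif direction <= 0 and v > ref + hyst:
                reversals += 1 if direction != 0 else 0
                direction = 1
                ref = v
            else:
                ref = max(ref, v) if direction >= 0 else min(ref, v)
        osc = ptp >= min_amplitude and reversals >= min_reversals
        rows.append({"element": j, "ptp": ptp, "reversals": reversals,
                     "oscillating": osc})
    table = pd.DataFrame(rows)
    return float(table["oscillating"].mean()), table


def run_spoc(kind: str = "DSE", ca: float = 0.3, duration: float = 4000.0,
             n_half_sarcomeres: int = 40, N_F: int = 4, gamma: float = 40.0,
             seed: int = 0, config: TestbedConfig | None = None):
    """Serial-chain run at constant Ca and its oscillation summary.

    Returns (df, fraction_oscillating, per_element_table, reverse_rate_peak)
    where ``reverse_rate_peak`` is the largest per-macro-step reverse-stroke
    event rate (1/s per molecule), the signature that distinguishes the BSE
    avalanche from the DSE behaviour during lengthening.
    """
    model = default_model(kind=kind, gamma=gamma, N_F=N_F)
    cfg = config if config is not None else TestbedConfig(
        n_half_sarcomeres=n_half_sarcomeres)
    df = run_myofibril_chain(model=model, config=cfg, ca=ca,
                             duration=duration, seed=seed)
    lams = np.stack(df["lams"].to_list())
    frac, table = detect_oscillations(lams)
    # reverse strokes are edges XB_PostR1->XB_PreR (5) and
    # XB_PostR2->XB_PostR1 (7)
    counts = np.stack(df["edge_counts"].to_list())  # (steps, B, NEDGE)
    n_mol_total = n_half_sarcomeres * model.geom.n_molecules
    rev = counts[:, :, [5, 7]].sum(axis=(1, 2))
    rev_rate = rev / (cfg.DT * 1e-3) / n_mol_total
    return df, frac, table, float(rev_rate.max())
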