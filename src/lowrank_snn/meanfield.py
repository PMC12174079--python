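"""Macroscopic (Lorentzian-ansatz) reduction and regime analysis.

For each population X in {E, I} the complex first-order moment
z_X = <exp(i*theta)> obeys a closed equation because the background currents
are Cauchy-distributed.  Writing the single-neuron phase velocity as
dtheta/dt = v + w cos(theta) + u sin(theta), with

    w = (c0*I + c1*g_XE + c2*g_XI - g_L)/C,
    v = (c0*I + c1*g_XE + c2*g_XI)/C,
    u = -(g_XE + g_XI)/C,

the moment equation is dz/dt = i [ f z^2 + h z + fbar ] with f = (w - i u)/2,
h = v and fbar = (w + i u)/2, evaluated at the complex current I = eta + i*delta
(analytic continuation over the Lorentzian).  Note fbar is NOT the complex
conjugate of f once delta > 0: conj(f) differs from the continued coefficient
by i*c0*delta/C.  The package integrates the continued form by default
("holomorphic"); the conjugate form is available for comparison
(closure="conjugate").  The population firing rate follows from the flux at
theta = pi:  A = g_L/(2 pi C) * [1 + 2 Re(-z/(1+z))]   (kHz).

Population conductances follow dg_XY/dt = -g_XY/tau_Y + g_peak_XY p_XY N_Y A_Y,
whose fixed point tau_Y * g_peak_XY * p_XY * N_Y * A_Y equals the time-averaged
summed conductance of the microscopic model (per-spike jump g_peak * J).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .params import BiophysicalParameters, derive_constants

__all__ = [
    "MacroParams", "MacroState", "MacroTrajectory", "RegimeResult",
    "firing_rate", "macro_rhs", "integrate_macro", "find_fixed_point",
    "classify_regime", "sweep_two_param", "FixedPointError",
]

#: amplitude threshold (relative peak-to-trough of A_I) separating oscillation
#: from stationarity
OSCILLATION_THRESHOLD = 0.01
#: boundary (Hz) between the low- and high-frequency oscillatory regimes
LOW_HIGH_SPLIT_HZ = 30.0


class FixedPointError(RuntimeError):
    pass


@dataclass
class MacroParams:
    """Parameters of the 8-dimensional macroscopic system."""

    params: BiophysicalParameters = field(default_factory=BiophysicalParameters)
    p_EE: float = 0.1
    p_EI: float = 0.1
    p_IE: float = 0.1
    p_II: float = 0.2
    closure: str = "holomorphic"       # or "conjugate" (literal printed form)
    drive_includes_tau: bool = False   # divide the rate drive by tau_Y

    def block_p(self) -> dict:
        return {"EE": self.p_EE, "EI": self.p_EI, "IE": self.p_IE, "II": self.p_II}

    def with_point(self, eta: float, p_II: float) -> "MacroParams":
        return MacroParams(params=self.params.with_overrides(eta=eta),
                           p_EE=self.p_EE, p_EI=self.p_EI, p_IE=self.p_IE,
                           p_II=p_II, closure=self.closure,
                           drive_includes_tau=self.drive_includes_tau)


@dataclass
class MacroState:
    z_E: complex
    z_I: complex
    g_EE: float = 0.0
    g_EI: float = 0.0
    g_IE: float = 0.0
    g_II: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([self.z_E.real, self.z_E.imag,
                         self.z_I.real, self.z_I.imag,
                         self.g_EE, self.g_EI, self.g_IE, self.g_II])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "MacroState":
        return cls(z_E=complex(y[0], y[1]), z_I=complex(y[2], y[3]),
                   g_EE=float(y[4]), g_EI=float(y[5]),
                   g_IE=float(y[6]), g_II=float(y[7]))


DEFAULT_INITIAL = MacroState(z_E=0.1 + 0.1j, z_I=0.1 + 0.1j)


def _rate_raw(z, g_L: float, C: float):
    """Rate expression without physicality checks (smooth off the manifold,
    as required inside root finders and ODE trial steps)."""
    z = np.asarray(z, dtype=complex)
    return g_L / (2.0 * np.pi * C) * (1.0 + 2.0 * np.real(-z / (1.0 + z)))


def firing_rate(z: complex, g_L: float, C: float, tol: float = 1e-9):
    """Population rate (kHz) from the first-order moment (flux at theta = pi)."""
    z = np.asarray(z, dtype=complex)
    denom = 1.0 + z
    if np.any(np.abs(denom) < 1e-12):
        raise ZeroDivisionError("firing_rate pole: z = -1")
    a = g_L / (2.0 * np.pi * C) * (1.0 + 2.0 * np.real(-z / denom))
    if np.any(a < -tol):
        raise FloatingPointError(f"negative firing rate {np.min(a):.3e}: "
                                 "state left the physical manifold")
    out = np.clip(a, 0.0, None)
    return float(out) if out.ndim == 0 else out


def macro_rhs(t: float, y: np.ndarray, mp: MacroParams) -> np.ndarray:
    """Time derivative of (Re z_E, Im z_E, Re z_I, Im z_I, g_EE, g_EI, g_IE, g_II)."""
    p = mp.params
    consts = derive_constants(p)
    zE = complex(y[0], y[1])
    zI = complex(y[2], y[3])
    gEE, gEI, gIE, gII = y[4:8]
    I_cplx = p.eta + 1j * p.delta

    def zdot(z, g_e, g_i, g_L):
        w = (consts.c0 * I_cplx + consts.c1 * g_e + consts.c2 * g_i - g_L) / p.C
        v = (consts.c0 * I_cplx + consts.c1 * g_e + consts.c2 * g_i) / p.C
        u = -(g_e + g_i) / p.C
        f = 0.5 * (w - 1j * u)
        if mp.closure == "holomorphic":
            fbar = 0.5 * (w + 1j * u)
        elif mp.closure == "conjugate":
            fbar = np.conj(f)
        else:
            raise ValueError(f"unknown closure {mp.closure!r}")
        return 1j * (f * z * z + v * z + fbar)

    dzE = zdot(zE, gEE, gEI, p.g_LE)
    dzI = zdot(zI, gIE, gII, p.g_LI)
    A_E = _rate_raw(zE, p.g_LE, p.C)
    A_I = _rate_raw(zI, p.g_LI, p.C)
    fE = 1.0 / p.tau_d_E if mp.drive_includes_tau else 1.0
    fI = 1.0 / p.tau_d_I if mp.drive_includes_tau else 1.0
    return np.array([
        dzE.real, dzE.imag, dzI.real, dzI.imag,
        -gEE / p.tau_d_E + p.g_peak_EE * mp.p_EE * p.N_E * A_E * fE,
        -gEI / p.tau_d_I + p.g_peak_EI * mp.p_EI * p.N_I * A_I * fI,
        -gIE / p.tau_d_E + p.g_peak_IE * mp.p_IE * p.N_E * A_E * fE,
        -gII / p.tau_d_I + p.g_peak_II * mp.p_II * p.N_I * A_I * fI,
    ])


@dataclass
class MacroTrajectory:
    t: np.ndarray
    y: np.ndarray       # (8, len(t))
    A_E: np.ndarray     # kHz
    A_I: np.ndarray     # kHz

    def state(self, idx: int = -1) -> MacroState:
        return MacroState.from_vector(self.y[:, idx])


def integrate_macro(mp: MacroParams, t_end: float,
                    initial: MacroState = DEFAULT_INITIAL,
                    dt_out: float = 0.1, t_start: float = 0.0,
                    rtol: float = 1e-8, atol: float = 1e-10) -> MacroTrajectory:
    """Adaptive integration sampled on a uniform grid."""
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    t_eval = np.arange(t_start, t_end, dt_out)
    sol = solve_ivp(macro_rhs, (t_start, t_end), initial.to_vector(),
                    args=(mp,), t_eval=t_eval, rtol=rtol, atol=atol,
                    max_step=1.0, method="RK45")
    if not sol.success:
        raise RuntimeError(f"macroscopic integration failed: {sol.message}")
    p = mp.params
    zE = sol.y[0] + 1j * sol.y[1]
    zI = sol.y[2] + 1j * sol.y[3]
    return MacroTrajectory(t=sol.t, y=sol.y,
                           A_E=np.maximum(_rate_raw(zE, p.g_LE, p.C), 0.0),
                           A_I=np.maximum(_rate_raw(zI, p.g_LI, p.C), 0.0))


def _numerical_jacobian(fun, y0: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    n = y0.shape[0]
    J = np.zeros((n, n))
    for k in range(n):
        up = y0.copy(); up[k] += eps
        dn = y0.copy(); dn[k] -= eps
        J[:, k] = (fun(up) - fun(dn)) / (2.0 * eps)
    return J


def find_fixed_point(mp: MacroParams, initial_guess: Optional[MacroState] = None,
                     settle_time: float = 3000.0, residual_tol: float = 1e-10):
    """Root of the macroscopic vector field plus its Jacobian eigenvalues.

    Seeded from the endpoint of a long integration unless a guess is given.
    Returns (MacroState, eigenvalues).  Raises FixedPointError when Newton
    does not converge (e.g. no stable or weakly unstable fixed point nearby).
    """
    if initial_guess is None:
        traj = integrate_macro(mp, settle_time)
        y0 = traj.y[:, -1]
    else:
        y0 = initial_guess.to_vector()
    fun = lambda y: macro_rhs(0.0, y, mp)
    sol = root(fun, y0, method="hybr", tol=1e-13)
    res = np.max(np.abs(fun(sol.x)))
    # hybr can report failure at a perfectly good root; trust the residual
    if res > residual_tol:
        raise FixedPointError(f"no fixed point found (residual {res:.2e})")
    eigvals = np.linalg.eigvals(_numerical_jacobian(fun, sol.x))
    return MacroState.from_vector(sol.x), eigvals


def dominant_frequency(t: np.ndarray, x: np.ndarray,
                       min_prominence_frac: float = 0.2) -> float:
    """Fundamental frequency (Hz) from mean inter-peak intervals.

    Robust to the strong harmonics of pulse-like relaxation waveforms that
    dominate a raw periodogram.  Returns 0 for signals without >= 2 prominent
    peaks.
    """
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span <= 0:
        return 0.0
    peaks, _ = find_peaks(x, prominence=min_prominence_frac * span)
    if len(peaks) < 2:
        return 0.0
    period_ms = float(np.mean(np.diff(t[peaks])))
    return 1000.0 / period_ms


@dataclass
class RegimeResult:
    label: str          # "stationary" | "low_freq_osc" | "high_freq_osc"
    frequency_hz: float
    amplitude: float    # peak-to-trough amplitude of A_I, kHz
    mean_rate_I_hz: float
    eigenvalue: Optional[complex] = None  # leading Jacobian eigenvalue, if available

    @property
    def oscillatory(self) -> bool:
        return self.label != "stationary"


def classify_regime(mp: MacroParams, t_end: float = 2000.0,
                    discard: float = 1000.0,
                    threshold: float = OSCILLATION_THRESHOLD,
                    split_hz: float = LOW_HIGH_SPLIT_HZ,
                    check_eigenvalues: bool = False) -> RegimeResult:
    """Simulation-based regime classification of the macroscopic model.

    Integrates, discards the transient, and calls the state oscillatory when
    the relative peak-to-trough amplitude of A_I exceeds ``threshold``; the
    oscillation frequency splits low vs high at ``split_hz``.  Optionally
    cross-checks against the fixed-point eigenvalue spectrum.
    """
    traj = integrate_macro(mp, t_end)
    sel = traj.t >= discard
    A = traj.A_I[sel] * 1000.0  # Hz
    amp = float(A.max() - A.min())
    mean = float(A.mean())
    rel = amp / mean if mean > 0 else 0.0
    lead = None
    if check_eigenvalues:
        try:
            _, eigvals = find_fixed_point(mp)
            lead = complex(eigvals[np.argmax(eigvals.real)])
        except FixedPointError:
            lead = None
    if rel < threshold:
        return RegimeResult("stationary", 0.0, amp / 1000.0, mean, lead)
    freq = dominant_frequency(traj.t[sel], A)
    label = "low_freq_osc" if freq < split_hz else "high_freq_osc"
    return RegimeResult(label, freq, amp / 1000.0, mean, lead)


def sweep_two_param(eta_grid, p_II_grid, base: Optional[MacroParams] = None,
                    **classify_kw):
    """Classify every (eta, p_II) node; returns a tidy pandas DataFrame."""
    import pandas as pd
    eta_grid = np.atleast_1d(np.asarray(eta_grid, dtype=float))
    p_II_grid = np.atleast_1d(np.asarray(p_II_grid, dtype=float))
    if eta_grid.size == 0 or p_II_grid.size == 0:
        raise ValueError("grids must be non-empty")
    base = base or MacroParams()
    rows = []
    for eta in eta_grid:
        for p_II in p_II_grid:
            mp = base.with_point(eta, p_II)
            try:
                r = classify_regime(mp, **classify_kw)
                rows.append(dict(eta=eta, p_II=p_II, label=r.label,
                                 frequency_hz=r.frequency_hz,
                                 amplitude=r.amplitude,
                                 mean_rate_I_hz=r.mean_rate_I_hz, error=""))
            except Exception as exc:  # per-node failures recorded, not fatal
                rows.append(dict(eta=eta, p_II=p_II, label="error",
                                 frequency_hz=np.nan, amplitude=np.nan,
                                 mean_rate_I_hz=np.nan, error=str(exc)))
    return pd.DataFrame(rows)
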