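"""Microscopic simulation of the voltage-dependent theta-neuron network.

Phases evolve by explicit Euler (default dt = 0.01 ms); a neuron spikes when
its phase crosses pi after the update, upon which the phase is reset by
theta -> theta - 2*pi and the spike is delivered to the postsynaptic
conductances at the next step boundary.  Synaptic conductances follow a
first-order exponential filter, dg/dt = -g/tau_d between spikes (integrated
exactly per step), and each presynaptic spike j adds g_peak * J_ij.

The integration core is a numba kernel; :func:`theta_rhs` is the reference
NumPy implementation of the phase velocity used by the kernel and by the
test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .params import (BiophysicalParameters, DerivedConstants, RngLike, as_rng,
                     derive_constants, sample_background_currents)
from .connectivity import ConnectivitySet, ablate_blocks  # re-export ablate_blocks

__all__ = [
    "SimulationConfig", "ReadoutConfig", "NetworkState", "SpikeTrain",
    "TraceRecord", "SimResult", "IntegrationError", "theta_rhs",
    "conductance_decay_factor", "voltage_from_phase", "run_simulation",
    "initial_state", "ablate_blocks",
]


class IntegrationError(RuntimeError):
    """Raised when the forward integration overflows or loses finiteness."""


@dataclass
class SimulationConfig:
    dt: float = 0.01            # integration step, ms
    duration: float = 1000.0    # simulated time, ms
    trace_stride: int = 10      # record traces every trace_stride steps
    record_isyn: bool = False   # record per-neuron E->E synaptic currents

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.trace_stride < 1:
            raise ValueError("trace_stride must be >= 1")


@dataclass
class ReadoutConfig:
    """How per-neuron E->E synaptic currents enter the tanh readout.

    The membrane potential recovered from the phase via the tangent map is
    clipped to ``[v_floor, v_ceil]`` before forming
    I_syn = -g_EE_i (V_i - V_E); the default floor/ceiling are the inhibitory
    and excitatory reversal potentials, bounding V to its physiological range
    and masking the divergence of tan(theta/2) during the instantaneous spike
    transit.  ``current_scale`` multiplies I_syn inside the tanh; ``None``
    selects c0 = 2/(V_T - V_R) (1/mV), the factor by which a current advances
    the phase, making the argument dimensionless.  ``printed`` selects the
    literal readout (cap +-500 mV, unscaled current).
    """

    v_floor: Optional[float] = None   # None -> V_I
    v_ceil: Optional[float] = None    # None -> V_E
    current_scale: Optional[float] = None  # None -> c0

    @classmethod
    def printed(cls) -> "ReadoutConfig":
        return cls(v_floor=-500.0, v_ceil=500.0, current_scale=1.0)

    def resolve(self, params: BiophysicalParameters) -> tuple:
        consts = derive_constants(params)
        lo = params.V_I if self.v_floor is None else self.v_floor
        hi = params.V_E if self.v_ceil is None else self.v_ceil
        sc = consts.c0 if self.current_scale is None else self.current_scale
        return float(lo), float(hi), float(sc)


@dataclass
class NetworkState:
    """Full microscopic state; sufficient to restart the integration."""

    t: float
    theta_E: np.ndarray
    theta_I: np.ndarray
    g_EE: np.ndarray   # summed E->E conductance per E neuron
    g_EI: np.ndarray   # summed I->E conductance per E neuron
    g_IE: np.ndarray   # summed E->I conductance per I neuron
    g_II: np.ndarray   # summed I->I conductance per I neuron
    I_bg_E: np.ndarray
    I_bg_I: np.ndarray

    def copy(self) -> "NetworkState":
        return NetworkState(self.t, *(a.copy() for a in (
            self.theta_E, self.theta_I, self.g_EE, self.g_EI,
            self.g_IE, self.g_II, self.I_bg_E, self.I_bg_I)))


@dataclass
class SpikeTrain:
    times: np.ndarray          # ms, non-decreasing
    neuron_ids: np.ndarray     # index within the population
    is_excitatory: np.ndarray  # bool

    def __len__(self) -> int:
        return self.times.shape[0]

    @property
    def population(self) -> np.ndarray:
        return np.where(self.is_excitatory, "E", "I")

    def count(self, population: Optional[str] = None) -> int:
        if population is None:
            return len(self)
        mask = self.is_excitatory if population == "E" else ~self.is_excitatory
        return int(mask.sum())

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "time_ms": self.times,
            "neuron_id": self.neuron_ids,
            "population": self.population,
        })


@dataclass
class TraceRecord:
    t: np.ndarray             # ms, uniform grid (dt * trace_stride)
    mean_g_EE: np.ndarray     # population-mean E->E conductance, mS/cm^2
    rate_E: np.ndarray        # binned population rate, kHz
    rate_I: np.ndarray
    Z: Optional[np.ndarray] = None      # tanh readout, if a readout vector was given
    isyn_EE: Optional[np.ndarray] = None  # (samples, N_E) per-neuron currents

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan


@dataclass
class SimResult:
    spikes: SpikeTrain
    trace: TraceRecord
    final_state: NetworkState


def voltage_from_phase(theta, params: BiophysicalParameters,
                       v_floor: float = -np.inf, v_ceil: float = np.inf):
    """Invert the phase transform: V = (V_R+V_T)/2 + (V_T-V_R)/2 * tan(theta/2)."""
    v = 0.5 * (params.V_R + params.V_T) + 0.5 * (params.V_T - params.V_R) * np.tan(
        np.asarray(theta) / 2.0)
    return np.clip(v, v_floor, v_ceil)


def theta_rhs(theta, g_e, g_i, I, params: BiophysicalParameters,
              consts: Optional[DerivedConstants] = None, population: str = "E"):
    """Phase velocity (rad/ms) of the voltage-dependent theta model.

    C dtheta/dt = -g_L cos(theta) + c0 (1 + cos(theta)) I
                  + g_e [c1 (1 + cos(theta)) - sin(theta)]
                  + g_i [c2 (1 + cos(theta)) - sin(theta)]
    """
    if consts is None:
        consts = derive_constants(params)
    g_L = params.g_LE if population == "E" else params.g_LI
    ct = np.cos(theta)
    st = np.sin(theta)
    return (-g_L * ct + consts.c0 * (1.0 + ct) * I
            + g_e * (consts.c1 * (1.0 + ct) - st)
            + g_i * (consts.c2 * (1.0 + ct) - st)) / params.C


def conductance_decay_factor(dt: float, tau_d: float) -> float:
    """Exact per-step decay of the exponential synaptic filter."""
    return float(np.exp(-dt / tau_d))


@njit(cache=True, fastmath=True)
def _integrate(thE, thI, gEE, gEI, gIE, gII, IbgE, IbgI,
               WEE_T, WEI_T, WIE_T, WII_T,
               stim, stim_on, stim_off,
               t0, dt, nsteps, stride,
               gLE, gLI, C, c0, c1, c2, decE, decI,
               wout, has_wout, v_lo, v_hi, cur_scale, VE,
               isyn_out, record_isyn,
               spk_t, spk_id, spk_exc,
               mg_out, z_out, cntE_out, cntI_out,
               half_sum, half_diff):
    """Euler integration core.  Mutates state arrays in place.

    Returns (status, n_spikes, bad_time): status 0 = ok, 1 = spike-buffer
    overflow, 2 = non-finite state encountered.
    """
    NE = thE.shape[0]
    NI = thI.shape[0]
    nrec = mg_out.shape[0]
    cap = spk_t.shape[0]
    ns = 0
    for s in range(nsteps):
        t = t0 + s * dt
        # -- record at the step start --------------------------------------
        if s % stride == 0:
            k = s // stride
            if k < nrec:
                acc = 0.0
                chk = 0.0
                zz = 0.0
                for i in range(NE):
                    acc += gEE[i]
                    chk += thE[i]
                    if has_wout or record_isyn:
                        V = half_sum + half_diff * np.tan(0.5 * thE[i])
                        if V > v_hi:
                            V = v_hi
                        elif V < v_lo:
                            V = v_lo
                        isyn = -gEE[i] * (V - VE)
                        if record_isyn:
                            isyn_out[k, i] = isyn
                        if has_wout:
                            zz += wout[i] * np.tanh(cur_scale * isyn)
                mg_out[k] = acc / NE
                if has_wout:
                    z_out[k] = zz
                if not np.isfinite(chk + acc):
                    return 2, ns, t
        stim_active = (t >= stim_on) and (t < stim_off)
        # -- phase update ---------------------------------------------------
        for i in range(NE):
            ct = np.cos(thE[i])
            st = np.sin(thE[i])
            I = IbgE[i]
            if stim_active:
                I += stim[i]
            thE[i] += dt * ((-gLE * ct + c0 * (1.0 + ct) * I
                             + gEE[i] * (c1 * (1.0 + ct) - st)
                             + gEI[i] * (c2 * (1.0 + ct) - st)) / C)
        for i in range(NI):
            ct = np.cos(thI[i])
            st = np.sin(thI[i])
            thI[i] += dt * ((-gLI * ct + c0 * (1.0 + ct) * IbgI[i]
                             + gIE[i] * (c1 * (1.0 + ct) - st)
                             + gII[i] * (c2 * (1.0 + ct) - st)) / C)
        # -- conductance decay over the step ---------------------------------
        for i in range(NE):
            gEE[i] *= decE
            gEI[i] *= decI
        for i in range(NI):
            gIE[i] *= decE
            gII[i] *= decI
        # -- spike detection, reset, delivery at the next step boundary ------
        kbin = s // stride
        for j in range(NE):
            if thE[j] >= np.pi:
                thE[j] -= 2.0 * np.pi
                if ns >= cap:
                    return 1, ns, t
                spk_t[ns] = t + dt
                spk_id[ns] = j
                spk_exc[ns] = True
                ns += 1
                if kbin < nrec:
                    cntE_out[kbin] += 1.0
                for i in range(NE):
                    gEE[i] += WEE_T[j, i]
                for i in range(NI):
                    gIE[i] += WIE_T[j, i]
            elif thE[j] < -np.pi:
                thE[j] += 2.0 * np.pi
        for j in range(NI):
            if thI[j] >= np.pi:
                thI[j] -= 2.0 * np.pi
                if ns >= cap:
                    return 1, ns, t
                spk_t[ns] = t + dt
                spk_id[ns] = j
                spk_exc[ns] = False
                ns += 1
                if kbin < nrec:
                    cntI_out[kbin] += 1.0
                for i in range(NE):
                    gEI[i] += WEI_T[j, i]
                for i in range(NI):
                    gII[i] += WII_T[j, i]
            elif thI[j] < -np.pi:
                thI[j] += 2.0 * np.pi
    return 0, ns, t0 + nsteps * dt


def initial_state(conn: ConnectivitySet, params: BiophysicalParameters,
                  rng: RngLike = None, t: float = 0.0) -> NetworkState:
    """Phases uniform on (-pi, pi), conductances zero, Cauchy background currents."""
    rng = as_rng(rng)
    N_E, N_I = conn.N_E, conn.N_I
    theta = rng.uniform(-np.pi, np.pi, size=N_E + N_I)
    currents = sample_background_currents(N_E + N_I, params.eta, params.delta, rng)
    return NetworkState(
        t=t,
        theta_E=theta[:N_E], theta_I=theta[N_E:],
        g_EE=np.zeros(N_E), g_EI=np.zeros(N_E),
        g_IE=np.zeros(N_I), g_II=np.zeros(N_I),
        I_bg_E=currents[:N_E], I_bg_I=currents[N_E:],
    )


def run_simulation(conn: ConnectivitySet, params: BiophysicalParameters,
                   sim_cfg: SimulationConfig,
                   stimulus=None,
                   rng: RngLike = None,
                   state: Optional[NetworkState] = None,
                   w_out: Optional[np.ndarray] = None,
                   readout: Optional[ReadoutConfig] = None,
                   spike_rate_headroom: float = 0.3) -> SimResult:
    """Forward-simulate the network.

    ``stimulus`` is any object with attributes ``vector`` (length N_E,
    uA/cm^2), ``onset`` and ``duration`` (ms, absolute times); it is added to
    the drive of the excitatory population only, inside its window.  If
    ``state`` is given the simulation continues from it (its ``t`` is the time
    origin); otherwise a fresh state is drawn from ``rng``.  ``w_out`` enables
    in-loop recording of the tanh readout Z(t).
    """
    params.validate()
    consts = derive_constants(params)
    if state is None:
        state = initial_state(conn, params, rng)
    else:
        state = state.copy()
    N_E, N_I = conn.N_E, conn.N_I
    if state.theta_E.shape[0] != N_E or state.theta_I.shape[0] != N_I:
        raise ValueError("state and connectivity dimensions disagree")

    nsteps = int(round(sim_cfg.duration / sim_cfg.dt))
    stride = sim_cfg.trace_stride
    nrec = (nsteps + stride - 1) // stride if nsteps > 0 else 1

    if stimulus is not None:
        stim = np.asarray(stimulus.vector, dtype=float)
        if stim.shape[0] != N_E:
            raise ValueError("stimulus vector must have length N_E")
        stim_on = float(stimulus.onset)
        stim_off = stim_on + float(stimulus.duration)
    else:
        stim = np.zeros(N_E)
        stim_on, stim_off = np.inf, np.inf

    has_wout = w_out is not None
    wout = np.asarray(w_out, dtype=float) if has_wout else np.zeros(N_E)
    v_lo, v_hi, cur_scale = (readout or ReadoutConfig()).resolve(params)

    # scaled, transposed weight matrices: row j = conductance jumps caused by
    # a spike of presynaptic neuron j (jump = g_peak * J_ij)
    WEE_T = np.ascontiguousarray(params.g_peak_EE * conn.J_EE.T)
    WEI_T = np.ascontiguousarray(params.g_peak_EI * conn.J_EI.T)
    WIE_T = np.ascontiguousarray(params.g_peak_IE * conn.J_IE.T)
    WII_T = np.ascontiguousarray(params.g_peak_II * conn.J_II.T)

    cap = max(1000, int((N_E + N_I) * sim_cfg.duration * spike_rate_headroom))
    spk_t = np.empty(cap)
    spk_id = np.empty(cap, dtype=np.int64)
    spk_exc = np.empty(cap, dtype=np.bool_)
    mg = np.zeros(nrec)
    z = np.zeros(nrec)
    cntE = np.zeros(nrec)
    cntI = np.zeros(nrec)
    isyn_out = np.zeros((nrec, N_E)) if sim_cfg.record_isyn else np.zeros((1, 1))

    status, ns, t_end = _integrate(
        state.theta_E, state.theta_I,
        state.g_EE, state.g_EI, state.g_IE, state.g_II,
        state.I_bg_E, state.I_bg_I,
        WEE_T, WEI_T, WIE_T, WII_T,
        stim, stim_on, stim_off,
        state.t, sim_cfg.dt, nsteps, stride,
        params.g_LE, params.g_LI, params.C,
        consts.c0, consts.c1, consts.c2,
        conductance_decay_factor(sim_cfg.dt, params.tau_d_E),
        conductance_decay_factor(sim_cfg.dt, params.tau_d_I),
        wout, has_wout, v_lo, v_hi, cur_scale, params.V_E,
        isyn_out, sim_cfg.record_isyn,
        spk_t, spk_id, spk_exc,
        mg, z, cntE, cntI,
        0.5 * (params.V_R + params.V_T), 0.5 * (params.V_T - params.V_R),
    )
    if status == 1:
        raise IntegrationError(
            f"spike buffer overflow at t={t_end:.3f} ms "
            f"(>{cap} spikes); raise spike_rate_headroom")
    if status == 2:
        raise IntegrationError(f"non-finite network state at t={t_end:.3f} ms")

    state.t = t_end
    if nsteps == 0:
        # degenerate run: report the initial state as a single-sample trace
        mg[0] = state.g_EE.mean()
        t_grid = np.array([state.t])
    else:
        t_grid = state.t - nsteps * sim_cfg.dt + np.arange(nrec) * stride * sim_cfg.dt
    bin_ms = stride * sim_cfg.dt
    trace = TraceRecord(
        t=t_grid,
        mean_g_EE=mg,
        rate_E=cntE / (N_E * bin_ms),
        rate_I=cntI / (N_I * bin_ms),
        Z=z if has_wout else None,
        isyn_EE=isyn_out if sim_cfg.record_isyn else None,
    )
    spikes = SpikeTrain(times=spk_t[:ns].copy(),
                        neuron_ids=spk_id[:ns].copy(),
                        is_excitatory=spk_exc[:ns].copy())
    return SimResult(spikes=spikes, trace=trace, final_state=state)
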