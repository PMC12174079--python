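"""Go-Nogo task: trials, tanh readout, output energy, and state comparisons.

The Go stimulus equals the left connectivity vector n; the Nogo stimulus is a
Gaussian vector orthogonal to n.  Both are injected into the excitatory
population for 10 ms.  The network output is the projection of the
tanh-squashed per-neuron E->E synaptic currents onto the readout vector
W_out = m, and the output energy is E(t) = Z(t)^2.  The peak energy inside a
post-onset analysis window (default 300 ms), the reaction time (onset to the
peak), and the multi-peak response duration quantify the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .params import BiophysicalParameters, RngLike, as_rng
from .connectivity import (ConnectivityConfig, ConnectivitySet,
                           assemble_connectivity, make_go_input,
                           make_nogo_input, readout_vector)
from .simulation import (ReadoutConfig, SimulationConfig, SimResult,
                         TraceRecord, run_simulation)

__all__ = [
    "TaskStimulus", "ReadoutResult", "STATE_POINTS", "readout_trace",
    "run_trial", "response_duration", "build_network", "compare_states",
]

#: Parameter points defining the three dynamical states used in experiments:
#: the gamma operating point and the stationary / low-frequency points of the
#: regime diagram.
STATE_POINTS: Dict[str, dict] = {
    "gamma": dict(eta=2.0, mean_II=0.2),
    "stationary": dict(eta=0.4, mean_II=0.1),
    "low_freq": dict(eta=0.1, mean_II=0.3),
}

DEFAULT_WINDOW_MS = 300.0
DEFAULT_ONSET_MS = 400.0
STIMULUS_DURATION_MS = 10.0


@dataclass
class TaskStimulus:
    vector: np.ndarray      # uA/cm^2, length N_E
    onset: float            # ms (absolute simulation time)
    duration: float = STIMULUS_DURATION_MS
    label: str = "go"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        self.vector = np.asarray(self.vector, dtype=float)


@dataclass
class ReadoutResult:
    t: np.ndarray
    Z: np.ndarray
    onset: float
    window: float
    peak_energy: float
    peak_time: float
    reaction_time: float
    baseline_energy: float    # median pre-onset energy
    label: str = ""
    trace: Optional[TraceRecord] = None

    @property
    def E(self) -> np.ndarray:
        return self.Z ** 2


def readout_trace(trace: TraceRecord, w_out: np.ndarray,
                  params: Optional[BiophysicalParameters] = None,
                  readout: Optional[ReadoutConfig] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Z(t) and E(t) from recorded per-neuron synaptic currents.

    Z(t) = sum_i W_out,i * tanh(s * I_syn,i(t)) with the configured current
    scale s.  Requires the simulation to have been run with record_isyn.
    """
    if trace.isyn_EE is None:
        raise ValueError("trace lacks per-neuron synaptic currents; "
                         "run the simulation with record_isyn=True")
    params = params or BiophysicalParameters()
    _, _, scale = (readout or ReadoutConfig()).resolve(params)
    Z = np.tanh(scale * trace.isyn_EE) @ np.asarray(w_out, dtype=float)
    return Z, Z ** 2


def _baseline_peak_level(t: np.ndarray, E: np.ndarray, onset: float) -> float:
    """Median height of pre-onset energy peaks (the baseline peak envelope).

    The ongoing gamma rhythm produces an energy peak every cycle; comparing
    response peaks against this envelope (rather than the near-zero inter-peak
    median) is what makes the multi-peak duration rule meaningful.  Falls back
    to the median energy when the pre-onset window has no clear peaks.
    """
    pre = (t >= max(t[0], onset - 150.0)) & (t < onset)
    if not np.any(pre):
        return 0.0
    Ep = E[pre]
    peaks, _ = find_peaks(Ep, prominence=0.1 * np.ptp(Ep)) if np.ptp(Ep) > 0 else ([], None)
    if len(peaks) >= 3:
        return float(np.median(Ep[peaks]))
    return float(np.median(Ep))


def _analyze(t: np.ndarray, Z: np.ndarray, onset: float, window: float,
             label: str, trace: Optional[TraceRecord]) -> ReadoutResult:
    E = Z ** 2
    in_win = (t >= onset) & (t <= onset + window)
    if not np.any(in_win):
        raise ValueError("analysis window lies outside the simulated range")
    idx = np.flatnonzero(in_win)
    k = idx[np.argmax(E[idx])]
    baseline = _baseline_peak_level(t, E, onset)
    return ReadoutResult(
        t=t, Z=Z, onset=onset, window=window,
        peak_energy=float(E[k]), peak_time=float(t[k]),
        reaction_time=float(t[k] - onset), baseline_energy=baseline,
        label=label, trace=trace,
    )


def run_trial(conn: ConnectivitySet, params: BiophysicalParameters,
              stimulus: TaskStimulus,
              sim_cfg: Optional[SimulationConfig] = None,
              rng: RngLike = None,
              state=None,
              window: float = DEFAULT_WINDOW_MS,
              readout: Optional[ReadoutConfig] = None,
              keep_trace: bool = False) -> ReadoutResult:
    """Simulate one trial and analyze the readout.

    The simulation covers [t0, onset + window + margin]; everything before the
    onset (transient plus baseline) is part of the run, so the network is
    equilibrated when the stimulus arrives.  A zero-amplitude stimulus gives
    the unstimulated twin of a trial (identical rng => identical background).
    """
    margin = 10.0
    t0 = state.t if state is not None else 0.0
    duration = stimulus.onset + stimulus.duration + window + margin - t0
    if duration <= 0:
        raise ValueError("stimulus onset precedes the start of the simulation")
    cfg = sim_cfg or SimulationConfig(duration=duration)
    if cfg.duration < duration:
        cfg = SimulationConfig(dt=cfg.dt, duration=duration,
                               trace_stride=cfg.trace_stride,
                               record_isyn=cfg.record_isyn)
    w_out = readout_vector(conn.lowrank)
    res = run_simulation(conn, params, cfg, stimulus=stimulus, rng=rng,
                         state=state, w_out=w_out, readout=readout)
    out = _analyze(res.trace.t, res.trace.Z, stimulus.onset, window,
                   stimulus.label, res.trace if keep_trace else None)
    return out


def response_duration(result: ReadoutResult,
                      baseline_E: Optional[float] = None,
                      threshold_frac: float = 0.1,
                      min_peak_separation_ms: float = 10.0) -> Tuple[float, int]:
    """Duration and cycle count of the multi-peak energy response.

    The energy-peak envelope (per-cycle maxima of E(t), separated by at least
    ``min_peak_separation_ms``) is compared against
    baseline + threshold_frac * (peak - baseline), where the baseline is the
    pre-onset peak-envelope level.  The duration runs from stimulus onset to
    the point where the envelope first falls below the threshold after the
    main peak (or to the last supra-threshold peak when it never does); the
    cycle count is the number of supra-threshold envelope peaks up to that
    point.  Returns (0.0, 0) when no peak clears the threshold.
    """
    E = result.E
    t = result.t
    base = result.baseline_energy if baseline_E is None else baseline_E
    sel = (t >= result.onset) & (t <= result.onset + result.window)
    Ew, tw = E[sel], t[sel]
    if Ew.size == 0 or Ew.max() <= 0:
        return 0.0, 0
    height = base + threshold_frac * (Ew.max() - base)
    if height <= 0:
        return 0.0, 0
    dt_trace = tw[1] - tw[0] if tw.size > 1 else 1.0
    distance = max(1, int(round(min_peak_separation_ms / dt_trace)))
    peaks, props = find_peaks(Ew, distance=distance)
    if len(peaks) == 0:
        return 0.0, 0
    heights = Ew[peaks]
    above = heights >= height
    if not above.any():
        return 0.0, 0
    k_main = int(np.argmax(heights))
    # the envelope crosses the threshold between the last supra-threshold
    # peak and the first sub-threshold peak after the main peak; interpolate
    # the crossing time linearly in peak height
    post = np.flatnonzero(~above[k_main:])
    if post.size:
        k_end = k_main + post[0]
        t_hi = tw[peaks[k_end - 1]] if k_end > 0 else tw[peaks[k_main]]
        t_lo = tw[peaks[k_end]]
        h_hi = heights[k_end - 1] if k_end > 0 else heights[k_main]
        h_lo = heights[k_end]
        frac = (h_hi - height) / (h_hi - h_lo) if h_hi > h_lo else 0.5
        end_time = t_hi + frac * (t_lo - t_hi)
        n_cycles = int(above[:k_end].sum())
    else:
        end_time = tw[peaks[-1]]
        n_cycles = int(above.sum())
    return float(end_time - result.onset), n_cycles


def build_network(params: BiophysicalParameters,
                  conn_cfg: Optional[ConnectivityConfig] = None,
                  rng: RngLike = None) -> ConnectivitySet:
    """Sample one low-rank network (connectivity + embedded m, n)."""
    cfg = conn_cfg or ConnectivityConfig()
    return assemble_connectivity(cfg, params.N_E, params.N_I, rng)


def _state_setup(state: str, base_params: BiophysicalParameters,
                 base_cfg: ConnectivityConfig):
    point = STATE_POINTS[state]
    params = base_params.with_overrides(eta=point["eta"])
    cfg = ConnectivityConfig(
        mean_EE=base_cfg.mean_EE, mean_EI=base_cfg.mean_EI,
        mean_IE=base_cfg.mean_IE, mean_II=point["mean_II"],
        chi_sd=base_cfg.chi_sd, lam=base_cfg.lam,
        sigma_lr=base_cfg.sigma_lr,
        calibrate_ee_mean=base_cfg.calibrate_ee_mean)
    return params, cfg


def compare_states(n_networks: int,
                   states: Sequence[str] = ("gamma", "stationary", "low_freq"),
                   rng_seed: RngLike = 0,
                   labels: Sequence[str] = ("go", "nogo"),
                   onset: float = DEFAULT_ONSET_MS,
                   window: float = DEFAULT_WINDOW_MS,
                   base_params: Optional[BiophysicalParameters] = None,
                   conn_cfg: Optional[ConnectivityConfig] = None,
                   readout: Optional[ReadoutConfig] = None):
    """Peak output energy per state and stimulus label across many networks.

    For every network seed a fresh low-rank structure is drawn; the same m, n
    pair (and the same trial randomness) is reused across states so the
    comparison isolates the dynamical regime.  Failed trials are recorded and
    excluded from the summary.

    Returns (trials DataFrame, summary dict state -> label -> mean/sd/n).
    """
    import pandas as pd
    base_params = base_params or BiophysicalParameters()
    base_cfg = conn_cfg or ConnectivityConfig()
    master = np.random.SeedSequence(rng_seed if isinstance(rng_seed, int) else None)
    net_seeds = master.spawn(n_networks)
    rows = []
    for k, ss in enumerate(net_seeds):
        ss_conn, ss_nogo, ss_trial = ss.spawn(3)
        for state in states:
            params, cfg = _state_setup(state, base_params, base_cfg)
            conn = assemble_connectivity(cfg, params.N_E, params.N_I,
                                         np.random.default_rng(ss_conn))
            go_vec = make_go_input(conn.lowrank)
            nogo_vec = make_nogo_input(conn.lowrank, np.random.default_rng(ss_nogo))
            for label in labels:
                vec = go_vec if label == "go" else nogo_vec
                stim = TaskStimulus(vector=vec, onset=onset, label=label)
                try:
                    r = run_trial(conn, params, stim,
                                  rng=np.random.default_rng(ss_trial),
                                  window=window, readout=readout)
                    dur, cyc = response_duration(r)
                    rows.append(dict(network=k, state=state, label=label,
                                     peak_energy=r.peak_energy,
                                     reaction_time=r.reaction_time,
                                     baseline_energy=r.baseline_energy,
                                     duration_ms=dur, n_cycles=cyc, error=""))
                except Exception as exc:
                    rows.append(dict(network=k, state=state, label=label,
                                     peak_energy=np.nan, reaction_time=np.nan,
                                     baseline_energy=np.nan, duration_ms=np.nan,
                                     n_cycles=0, error=str(exc)))
    df = pd.DataFrame(rows)
    summary: Dict[str, dict] = {}
    for state in states:
        summary[state] = {}
        for label in labels:
            sel = df[(df.state == state) & (df.label == label) & (df.error == "")]
            summary[state][label] = dict(
                mean_peak_energy=float(sel.peak_energy.mean()),
                sd_peak_energy=float(sel.peak_energy.std(ddof=0)),
                n=int(len(sel)),
                n_failed=int(((df.state == state) & (df.label == label)).sum() - len(sel)),
            )
    return df, summary
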