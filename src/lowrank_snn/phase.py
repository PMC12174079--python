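"""Gamma-phase extraction and phase-resolved stimulation experiments.

The population-mean E->E synaptic conductance serves as the proxy for network
activity; its instantaneous phase is the argument of the analytic signal
(Hilbert transform) of the mean-subtracted trace, so a conductance peak maps
to phase 0 and the trough to +-pi.  Stimuli are scheduled at target phases by
projecting the estimated period forward from a reference conductance peak of
a baseline (unstimulated) run; because the microscopic dynamics are
deterministic given the network state, the baseline run is the exact
unstimulated twin of every trial and the achieved phase is verified on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, hilbert

from .params import BiophysicalParameters, RngLike
from .connectivity import (ConnectivityConfig, assemble_connectivity,
                           make_go_input, make_nogo_input)
from .simulation import ReadoutConfig, SimulationConfig, run_simulation
from .task import (DEFAULT_WINDOW_MS, STIMULUS_DURATION_MS, TaskStimulus,
                   run_trial)

__all__ = [
    "PhaseTrace", "PhaseAnalysisError", "SchedulingError",
    "instantaneous_phase", "estimate_oscillation", "schedule_stimulus_at_phase",
    "bin_centers", "phase_sweep", "reaction_time_by_phase", "wrap_phase",
]

DEFAULT_N_BINS = 33


class PhaseAnalysisError(RuntimeError):
    pass


class SchedulingError(RuntimeError):
    pass


@dataclass
class PhaseTrace:
    t: np.ndarray
    phase: np.ndarray       # (-pi, pi]
    amplitude: np.ndarray   # analytic-signal envelope

    def at(self, time: float) -> float:
        """Phase at an arbitrary time (nearest-sample lookup)."""
        if time < self.t[0] or time > self.t[-1]:
            raise PhaseAnalysisError(
                f"t={time} outside the valid phase range [{self.t[0]}, {self.t[-1]}]")
        return float(self.phase[np.argmin(np.abs(self.t - time))])


def wrap_phase(phi):
    """Wrap angles to (-pi, pi]."""
    out = np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return float(out) if out.ndim == 0 else out


def instantaneous_phase(t: np.ndarray, signal: np.ndarray,
                        bandpass_hz: Optional[Tuple[float, float]] = None,
                        trim_cycles: float = 0.5) -> PhaseTrace:
    """Instantaneous phase of an oscillatory trace via the analytic signal.

    The signal is mean-subtracted (optionally band-passed) before the Hilbert
    transform; the first and last ``trim_cycles`` cycles are discarded where
    the analytic signal suffers edge effects.  The nearly monochromatic
    gamma-regime conductance needs no band-pass.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(signal, dtype=float)
    if t.shape != x.shape or t.size < 8:
        raise PhaseAnalysisError("signal too short for phase analysis")
    if np.ptp(x) == 0:
        raise PhaseAnalysisError("constant signal has no phase")
    dt = t[1] - t[0]
    y = x - x.mean()
    if bandpass_hz is not None:
        fs = 1000.0 / dt  # Hz
        lo, hi = bandpass_hz
        b, a = butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
        y = filtfilt(b, a, y)
    analytic = hilbert(y)
    phase = np.angle(analytic)
    amp = np.abs(analytic)
    # estimate the cycle length for trimming
    freq = _peak_frequency(t, y)
    if freq <= 0:
        raise PhaseAnalysisError("no oscillation detected (need >= 4 cycles)")
    period = 1000.0 / freq
    n_trim = int(round(trim_cycles * period / dt))
    if 2 * n_trim >= t.size:
        raise PhaseAnalysisError("signal shorter than the trim margin")
    sl = slice(n_trim, t.size - n_trim if n_trim else t.size)
    return PhaseTrace(t=t[sl], phase=phase[sl], amplitude=amp[sl])


def _peak_frequency(t, y, min_prominence_frac: float = 0.25):
    span = y.max() - y.min()
    if span <= 0:
        return 0.0
    peaks, _ = find_peaks(y, prominence=min_prominence_frac * span)
    if len(peaks) < 4:
        return 0.0
    return 1000.0 / float(np.mean(np.diff(t[peaks])))


@dataclass
class OscillationEstimate:
    period_ms: float
    frequency_hz: float
    peak_times: np.ndarray
    cv_period: float    # coefficient of variation of cycle lengths


def estimate_oscillation(t: np.ndarray, signal: np.ndarray,
                         min_peaks: int = 4,
                         max_cv: float = 0.25) -> OscillationEstimate:
    """Period and conductance-peak times of a stable oscillation.

    Raises SchedulingError when fewer than ``min_peaks`` prominent peaks are
    found or the cycle-length jitter exceeds ``max_cv`` (no stable rhythm to
    lock stimuli to).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(signal, dtype=float) - np.mean(signal)
    span = np.ptp(y)
    if span <= 0:
        raise SchedulingError("flat baseline trace: no oscillation")
    peaks, _ = find_peaks(y, prominence=0.25 * span)
    if len(peaks) < min_peaks:
        raise SchedulingError(f"only {len(peaks)} conductance peaks; "
                              f"need >= {min_peaks} for stable scheduling")
    intervals = np.diff(t[peaks])
    period = float(np.mean(intervals))
    cv = float(np.std(intervals) / period)
    if cv > max_cv:
        raise SchedulingError(f"unstable oscillation (period CV {cv:.2f} > {max_cv})")
    return OscillationEstimate(period_ms=period, frequency_hz=1000.0 / period,
                               peak_times=t[peaks], cv_period=cv)


def schedule_stimulus_at_phase(osc: OscillationEstimate, target_phase: float,
                               vector: np.ndarray, earliest: float,
                               duration: float = STIMULUS_DURATION_MS,
                               label: str = "go",
                               phase_trace: Optional[PhaseTrace] = None,
                               phase_reference: str = "midpoint") -> TaskStimulus:
    """Stimulus whose phase label equals a requested oscillation phase.

    Phase 0 is a conductance peak.  Because the 10 ms stimulus covers a large
    fraction of a gamma cycle, the phase assigned to a trial refers by default
    to the stimulus midpoint (onset + duration/2); ``phase_reference="onset"``
    labels trials by the onset instead.  The reference time is first
    extrapolated as t_ref + k*T + (phase/2pi)*T from the baseline conductance
    peak t_ref requiring the least forward extrapolation (k the first integer
    placing the onset at or after ``earliest``); when the measured
    ``phase_trace`` of the unstimulated twin is supplied, the time is refined
    to the sample within the following cycle whose measured phase is closest
    to the target, absorbing the cycle-to-cycle period jitter of the finite
    network.
    """
    if phase_reference not in ("midpoint", "onset"):
        raise ValueError("phase_reference must be 'midpoint' or 'onset'")
    lag = 0.5 * duration if phase_reference == "midpoint" else 0.0
    T = osc.period_ms
    frac = (wrap_phase(target_phase) / (2.0 * np.pi)) * T
    earliest_ref = earliest + lag
    # reference peak requiring the least forward extrapolation
    best = None
    for t_ref in osc.peak_times[::-1]:
        k = int(np.ceil((earliest_ref - t_ref - frac) / T))
        cand = t_ref + k * T + frac
        if best is None or (cand - t_ref) < (best[0] - best[1]):
            best = (cand, t_ref)
    ref_time = float(best[0])
    if phase_trace is not None:
        sel = (phase_trace.t >= earliest_ref) & (phase_trace.t <= earliest_ref + 1.2 * T)
        if not np.any(sel):
            raise SchedulingError("phase trace does not cover the scheduling window")
        tt = phase_trace.t[sel]
        err = np.abs(wrap_phase(phase_trace.phase[sel] - target_phase))
        ref_time = float(tt[np.argmin(err)])
    return TaskStimulus(vector=vector, onset=ref_time - lag, duration=duration,
                        label=label)


def bin_centers(n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equally spaced phase-bin centres covering one cycle: -pi + (j+1/2)*2pi/n."""
    j = np.arange(n_bins)
    return -np.pi + (j + 0.5) * 2.0 * np.pi / n_bins


def phase_sweep(n_networks: int,
                n_bins: int = DEFAULT_N_BINS,
                labels: Sequence[str] = ("go", "nogo"),
                rng_seed: RngLike = 0,
                base_params: Optional[BiophysicalParameters] = None,
                conn_cfg: Optional[ConnectivityConfig] = None,
                window: float = DEFAULT_WINDOW_MS,
                readout: Optional[ReadoutConfig] = None,
                transient: float = 500.0,
                dt: float = 0.01,
                trace_stride: int = 10,
                phase_reference: str = "midpoint"):
    """Phase-resolved stimulation across networks (gamma operating point).

    For each network one unstimulated baseline run provides (a) the restart
    checkpoint after the transient, (b) the period / reference-peak estimate,
    and (c) the seed-matched twin on which the achieved phase of every
    scheduled onset is verified (trials whose achieved phase misses the target
    by more than one bin width are rejected).  Each trial restarts from the
    checkpoint, so only onset-to-window-end time is re-simulated.

    Returns (trials DataFrame, summary dict label -> per-bin statistics).
    """
    import pandas as pd
    params = base_params or BiophysicalParameters()
    cfg = conn_cfg or ConnectivityConfig()
    centers = bin_centers(n_bins)
    bin_width = 2.0 * np.pi / n_bins
    master = np.random.SeedSequence(rng_seed if isinstance(rng_seed, int) else None)
    rows = []
    for k, ss in enumerate(master.spawn(n_networks)):
        ss_conn, ss_nogo, ss_state = ss.spawn(3)
        conn = assemble_connectivity(cfg, params.N_E, params.N_I,
                                     np.random.default_rng(ss_conn))
        vectors = {"go": make_go_input(conn.lowrank),
                   "nogo": make_nogo_input(conn.lowrank,
                                           np.random.default_rng(ss_nogo))}
        # baseline run: transient -> checkpoint, then an extension long enough
        # to cover every scheduled onset for phase verification
        base_cfg = SimulationConfig(dt=dt, duration=transient,
                                    trace_stride=trace_stride)
        base = run_simulation(conn, params, base_cfg,
                              rng=np.random.default_rng(ss_state))
        checkpoint = base.final_state
        ext_cfg = SimulationConfig(dt=dt, duration=200.0, trace_stride=trace_stride)
        ext = run_simulation(conn, params, ext_cfg, state=checkpoint)
        t_all = np.concatenate([base.trace.t, ext.trace.t])
        g_all = np.concatenate([base.trace.mean_g_EE, ext.trace.mean_g_EE])
        sel = t_all >= transient - 250.0
        try:
            osc = estimate_oscillation(t_all[sel], g_all[sel])
            ptrace = instantaneous_phase(t_all[sel], g_all[sel])
        except (SchedulingError, PhaseAnalysisError) as exc:
            rows.append(dict(network=k, label="", bin_center=np.nan,
                             target_phase=np.nan, achieved_phase=np.nan,
                             onset=np.nan, peak_energy=np.nan,
                             reaction_time=np.nan, accepted=False,
                             error=f"baseline: {exc}"))
            continue
        for label in labels:
            for phi in centers:
                stim = schedule_stimulus_at_phase(
                    osc, phi, vectors[label], earliest=transient + 2.0,
                    label=label, phase_trace=ptrace,
                    phase_reference=phase_reference)
                lag = 0.5 * stim.duration if phase_reference == "midpoint" else 0.0
                row = dict(network=k, label=label, bin_center=float(phi),
                           target_phase=float(phi), onset=stim.onset,
                           achieved_phase=np.nan, peak_energy=np.nan,
                           reaction_time=np.nan, accepted=False, error="")
                try:
                    achieved = ptrace.at(stim.onset + lag)
                    row["achieved_phase"] = achieved
                    if abs(wrap_phase(achieved - phi)) > bin_width:
                        row["error"] = "phase verification failed"
                        rows.append(row)
                        continue
                    r = run_trial(conn, params, stim, state=checkpoint,
                                  window=window, readout=readout,
                                  sim_cfg=SimulationConfig(
                                      dt=dt, duration=1.0,
                                      trace_stride=trace_stride))
                    row.update(peak_energy=r.peak_energy,
                               reaction_time=r.reaction_time, accepted=True)
                except Exception as exc:
                    row["error"] = str(exc)
                rows.append(row)
    df = pd.DataFrame(rows)
    summary = {}
    for label in labels:
        per_bin = []
        for phi in centers:
            sel = df[(df.label == label) & df.accepted
                     & np.isclose(df.bin_center, phi)]
            per_bin.append(dict(
                bin_center=float(phi),
                mean_peak_energy=float(sel.peak_energy.mean()) if len(sel) else np.nan,
                sd_peak_energy=float(sel.peak_energy.std(ddof=0)) if len(sel) else np.nan,
                mean_reaction_time=float(sel.reaction_time.mean()) if len(sel) else np.nan,
                sd_reaction_time=float(sel.reaction_time.std(ddof=0)) if len(sel) else np.nan,
                n=int(len(sel)),
            ))
        means = np.array([b["mean_peak_energy"] for b in per_bin])
        valid = np.isfinite(means)
        depth = (np.nanmax(means) - np.nanmin(means)) / np.nanmean(means) \
            if valid.any() and np.nanmean(means) > 0 else np.nan
        summary[label] = dict(
            bins=per_bin,
            modulation_depth=float(depth),
            argmax_phase=float(centers[np.nanargmax(means)]) if valid.any() else np.nan,
            # polar-plot coordinates (angle, radius)
            polar=[(b["bin_center"], b["mean_peak_energy"]) for b in per_bin],
        )
    return df, summary


def reaction_time_by_phase(trials, label: str = "go"):
    """Per-bin reaction-time statistics and their link to response strength.

    Returns a dict with per-bin mean/sd of the reaction time and the Spearman
    rank correlation between the per-bin reaction-time SD and the per-bin mean
    peak energy (the inverse-variability relation).  Empty bins are excluded.
    """
    from scipy.stats import spearmanr
    df = trials[(trials.label == label) & trials.accepted]
    stats = []
    for phi, grp in df.groupby("bin_center"):
        if len(grp) == 0:
            continue
        stats.append(dict(bin_center=float(phi),
                          mean_rt=float(grp.reaction_time.mean()),
                          sd_rt=float(grp.reaction_time.std(ddof=0)),
                          mean_peak_energy=float(grp.peak_energy.mean()),
                          n=int(len(grp))))
    if len(stats) < 3:
        return dict(bins=stats, spearman_rt_sd_vs_energy=np.nan, p_value=np.nan)
    sds = [s["sd_rt"] for s in stats]
    means = [s["mean_peak_energy"] for s in stats]
    rho, p = spearmanr(sds, means)
    return dict(bins=stats, spearman_rt_sd_vs_energy=float(rho), p_value=float(p))
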