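import numpy as np
import pytest

import lowrank_snn as ls
from lowrank_snn.simulation import ReadoutConfig, SimulationConfig, TraceRecord
from lowrank_snn.task import (TaskStimulus, _baseline_peak_level,
                              response_duration, run_trial)


def _trace_with_isyn(t, isyn):
    return TraceRecord(t=t, mean_g_EE=np.zeros_like(t),
                       rate_E=np.zeros_like(t), rate_I=np.zeros_like(t),
                       isyn_EE=isyn)


class TestReadoutTrace:
    def test_zero_currents_zero_output(self, params):
        t = np.arange(10.0)
        tr = _trace_with_isyn(t, np.zeros((10, 4)))
        Z, E = ls.readout_trace(tr, np.ones(4), params)
        assert np.all(Z == 0) and np.all(E == 0)

    def test_single_unit_projection(self, params):
        # W_out = e1 and I_syn,1 = 1 with the literal readout: Z = tanh(1)
        t = np.arange(3.0)
        isyn = np.zeros((3, 4))
        isyn[:, 0] = 1.0
        tr = _trace_with_isyn(t, isyn)
        Z, _ = ls.readout_trace(tr, np.eye(4)[0], params,
                                readout=ReadoutConfig.printed())
        assert Z == pytest.approx(np.tanh(1.0))

    def test_sign_flip_symmetry(self, params):
        rng = np.random.default_rng(0)
        tr = _trace_with_isyn(np.arange(5.0), rng.normal(size=(5, 6)))
        w = rng.normal(size=6)
        Z1, E1 = ls.readout_trace(tr, w, params)
        Z2, E2 = ls.readout_trace(tr, -w, params)
        assert np.allclose(Z1, -Z2) and np.allclose(E1, E2)

    def test_requires_recorded_currents(self, params):
        tr = TraceRecord(t=np.arange(3.0), mean_g_EE=np.zeros(3),
                         rate_E=np.zeros(3), rate_I=np.zeros(3))
        with pytest.raises(ValueError, match="record_isyn"):
            ls.readout_trace(tr, np.ones(4), params)

    def test_tanh_bound(self, params):
        rng = np.random.default_rng(1)
        w = rng.normal(size=8)
        tr = _trace_with_isyn(np.arange(4.0), rng.normal(scale=100, size=(4, 8)))
        Z, _ = ls.readout_trace(tr, w, params)
        assert np.all(np.abs(Z) <= np.abs(w).sum() + 1e-12)

    def test_inloop_readout_matches_posthoc(self, two_neuron):
        """The Z(t) recorded inside the integrator equals the readout computed
        from the recorded per-neuron currents."""
        conn, p0 = two_neuron
        p = p0.with_overrides(eta=2.0)
        w = np.array([0.5, -0.3])
        cfg = SimulationConfig(duration=50.0, record_isyn=True)
        res = ls.run_simulation(conn, p, cfg, rng=2, w_out=w)
        Z, _ = ls.readout_trace(res.trace, w, p)
        assert np.allclose(Z, res.trace.Z, atol=1e-12)


class TestStimulus:
    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            TaskStimulus(vector=np.ones(3), onset=0.0, duration=0.0)

    def test_wrong_length_rejected_at_run(self, two_neuron):
        conn, p = two_neuron
        stim = TaskStimulus(vector=np.ones(5), onset=10.0)
        with pytest.raises(ValueError, match="length"):
            ls.run_simulation(conn, p, SimulationConfig(duration=30.0),
                              stimulus=stim, rng=3)


class TestTrialAnalysis:
    def test_energy_nonnegative_and_rt_in_window(self, gamma_connectivity,
                                                 params):
        stim = TaskStimulus(
            vector=ls.make_go_input(gamma_connectivity.lowrank),
            onset=300.0, label="go")
        r = run_trial(gamma_connectivity, params, stim, rng=4, window=200.0)
        assert np.all(r.E >= 0)
        assert 0.0 <= r.reaction_time <= 200.0
        assert r.peak_energy == r.E.max() or r.peak_energy <= r.E.max()

    def test_go_differs_from_unstimulated_twin(self, gamma_connectivity,
                                               params):
        go = TaskStimulus(vector=ls.make_go_input(gamma_connectivity.lowrank),
                          onset=300.0, label="go")
        quiet = TaskStimulus(vector=np.zeros(params.N_E), onset=300.0,
                             label="none")
        r_go = run_trial(gamma_connectivity, params, go, rng=5, window=200.0)
        r_quiet = run_trial(gamma_connectivity, params, quiet, rng=5,
                            window=200.0)
        assert not np.allclose(r_go.Z, r_quiet.Z)

    def test_spiking_similar_but_readout_selective(self, gamma_connectivity,
                                                   params):
        """Go and Nogo trials barely differ in total spiking, yet the readout
        separates them (stimuli scheduled at the favourable phase)."""
        from lowrank_snn.phase import (estimate_oscillation,
                                       instantaneous_phase,
                                       schedule_stimulus_at_phase)
        base = ls.run_simulation(gamma_connectivity, params,
                                 SimulationConfig(duration=500.0), rng=6)
        sel = base.trace.t > 250
        osc = estimate_oscillation(base.trace.t[sel], base.trace.mean_g_EE[sel])
        ptr = instantaneous_phase(base.trace.t[sel], base.trace.mean_g_EE[sel])
        go_vec = ls.make_go_input(gamma_connectivity.lowrank)
        nogo_vec = ls.make_nogo_input(gamma_connectivity.lowrank, 7)
        peaks, counts = {}, {}
        for label, vec in [("go", go_vec), ("nogo", nogo_vec)]:
            stim = schedule_stimulus_at_phase(osc, np.pi, vec,
                                              earliest=300.0, label=label,
                                              phase_trace=ptr)
            r = run_trial(gamma_connectivity, params, stim, rng=6)
            cfgd = SimulationConfig(duration=stim.onset + 310.0)
            sim = ls.run_simulation(gamma_connectivity, params, cfgd,
                                    stimulus=stim, rng=6)
            counts[label] = len(sim.spikes)
            peaks[label] = r.peak_energy
        assert abs(counts["go"] - counts["nogo"]) / counts["nogo"] < 0.10
        assert peaks["go"] > peaks["nogo"]


class TestResponseDuration:
    def _result(self, t, E, onset=0.0, window=300.0, baseline=0.0):
        Z = np.sqrt(E)
        return ls.ReadoutResult(t=t, Z=Z, onset=onset, window=window,
                                peak_energy=float(E.max()),
                                peak_time=float(t[np.argmax(E)]),
                                reaction_time=float(t[np.argmax(E)] - onset),
                                baseline_energy=baseline)

    def test_all_zero_energy(self):
        t = np.arange(0, 300, 0.1)
        dur, cyc = response_duration(self._result(t, np.zeros_like(t)))
        assert dur == 0.0 and cyc == 0

    def test_decaying_peak_train(self):
        # peaks every 25 ms decaying exponentially: the envelope crosses 10%
        # of the maximum at the expected cycle
        t = np.arange(0, 300, 0.1)
        E = np.zeros_like(t)
        for k in range(12):
            E += np.exp(-((t - 10 - 25 * k) / 2) ** 2) * np.exp(-k / 2.5)
        dur, cyc = response_duration(self._result(t, E))
        # envelope exp(-k/2.5) crosses 0.1 between peak 5 (t=135, h=.135)
        # and peak 6 (t=160, h=.091): t = 135 + 25*(0.135-0.1)/(0.135-0.091)
        assert dur == pytest.approx(154.8, abs=5.0)
        assert cyc == 6

    def test_single_transient(self):
        t = np.arange(0, 300, 0.1)
        E = np.exp(-((t - 15) / 3) ** 2) * 100
        dur, cyc = response_duration(self._result(t, E))
        assert cyc == 1
        assert dur == pytest.approx(15.0, abs=1.0)

    def test_baseline_peak_level_uses_peak_envelope(self):
        t = np.arange(0, 400, 0.1)
        E = (1 + np.cos(2 * np.pi * t / 25)) ** 2 * 50  # peaks of height 200
        level = _baseline_peak_level(t, E, onset=350.0)
        assert level == pytest.approx(200.0, rel=0.02)


class TestCompareStates:
    def test_structure_and_selectivity(self, params):
        """Small smoke comparison: gamma-state go responses exceed nogo."""
        df, summary = ls.compare_states(2, states=("gamma",), rng_seed=11)
        assert set(df.state) == {"gamma"}
        assert summary["gamma"]["go"]["n"] == 2
        assert (summary["gamma"]["go"]["mean_peak_energy"]
                > summary["gamma"]["nogo"]["mean_peak_energy"])
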