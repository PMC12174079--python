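import numpy as np
import pytest
from scipy.integrate import solve_ivp

import lowrank_snn as ls
from lowrank_snn.simulation import conductance_decay_factor
from lowrank_snn.task import TaskStimulus


class TestThetaRhs:
    def test_at_pi_only_leak_acts(self, params, consts):
        # 1 + cos(pi) = 0 and sin(pi) = 0: dtheta/dt = g_L/C
        d = ls.theta_rhs(np.pi, 5.0, 3.0, 100.0, params, consts)
        assert d == pytest.approx(0.1)

    def test_quiescent_at_half_pi_without_drive(self, params, consts):
        assert ls.theta_rhs(np.pi / 2, 0.0, 0.0, 0.0, params, consts) == \
            pytest.approx(0.0, abs=1e-15)

    def test_at_zero_with_drive(self, params, consts):
        # -g_L + c0*2*I = -0.1 + (2/7)*2*2
        d = ls.theta_rhs(0.0, 0.0, 0.0, 2.0, params, consts)
        assert d == pytest.approx(-0.1 + 8.0 / 7.0)

    def test_vectorized(self, params, consts):
        th = np.linspace(-np.pi, np.pi, 7)
        d = ls.theta_rhs(th, 0.01, 0.02, 1.0, params, consts)
        assert d.shape == th.shape and np.all(np.isfinite(d))


class TestConductanceFilter:
    def test_exponential_decay(self, params):
        # g(tau_d) = g0 / e
        assert conductance_decay_factor(2.0, 2.0) == pytest.approx(1 / np.e)

    def test_single_spike_jump(self, two_neuron):
        # neuron 0 spikes; neuron 1 receives g_peak * J_10
        conn, p = two_neuron
        p = p.with_overrides(g_peak_EE=0.004, eta=2.0, delta=0.0)
        state = ls.initial_state(conn, p, rng=0)
        state.theta_E[:] = [np.pi - 1e-6, -2.0]  # neuron 0 about to fire
        res = ls.run_simulation(conn, p, ls.SimulationConfig(duration=0.05),
                                state=state)
        assert res.spikes.count() == 1
        # jump = g_peak * J = 0.004 * 0.5 = 0.002, then decays
        steps_since = round((res.final_state.t - res.spikes.times[0]) / 0.01)
        expected = 0.002 * conductance_decay_factor(0.01, p.tau_d_E) ** steps_since
        assert res.final_state.g_EE[1] == pytest.approx(expected, rel=1e-10)
        assert res.final_state.g_EE[0] == 0.0

    def test_steady_state_conductance(self, params):
        # a periodic spike train at rate r through weight J settles at a
        # time-averaged conductance tau_d * g_peak * J * r
        tau, g_peak, J, rate = 2.0, 0.004, 0.5, 0.05  # kHz
        dt = 0.01
        period = 1.0 / rate
        g = 0.0
        samples = []
        for step in range(int(3000 / dt)):
            g *= np.exp(-dt / tau)
            if step % int(period / dt) == 0:
                g += g_peak * J
            if step > 2000 / dt:
                samples.append(g)
        assert np.mean(samples) == pytest.approx(tau * g_peak * J * rate, rel=0.01)


class TestQifEquivalence:
    def test_phase_trajectory_maps_onto_qif_voltage(self, params):
        """Chain-rule oracle: between spikes the phase trajectory mapped
        through the tangent transform must solve the QIF equation
        C dV/dt = g_L (V-V_R)(V-V_T)/(V_T-V_R) + I."""
        conn, p0 = ls.make_fixture("two_neuron")
        p = p0.with_overrides(eta=2.0, delta=0.0)
        state = ls.initial_state(conn, p, rng=1)
        state.theta_E[:] = [-2.5, -2.5]
        cfg = ls.SimulationConfig(duration=8.0, dt=0.001)
        res = ls.run_simulation(conn, p, cfg, state=state)
        assert res.spikes.count() == 0  # stays subthreshold in this window

        def qif(t, v):
            return (p.g_LE * (v - p.V_R) * (v - p.V_T) / (p.V_T - p.V_R)
                    + 2.0) / p.C

        v0 = ls.voltage_from_phase(-2.5, p)
        sol = solve_ivp(qif, (0, 8.0), [v0], rtol=1e-10, atol=1e-10,
                        dense_output=True)
        # neuron 0 receives no synapses in this fixture: pure QIF in disguise
        v_theta = ls.voltage_from_phase(res.final_state.theta_E[0], p)
        v_qif = sol.sol(8.0)[0]
        assert v_theta == pytest.approx(v_qif, rel=2e-3)

    @pytest.mark.parametrize("I", [1.0, 2.0, 5.0])
    def test_tonic_rate_oracle(self, I):
        """With synapses silenced and no heterogeneity, every neuron fires at
        the closed-form QIF rate (2% at dt = 0.01 ms)."""
        conn, p0 = ls.make_fixture("two_neuron")
        p = p0.with_overrides(eta=I, delta=0.0, g_peak_EE=1e-12,
                              g_peak_EI=1e-12, g_peak_IE=1e-12, g_peak_II=1e-12)
        res = ls.run_simulation(conn, p, ls.SimulationConfig(duration=1000.0),
                                rng=2)
        expected_hz = 1000 * ls.tonic_rate(p, I)
        for nid in (0, 1):
            n_spk = int(((res.spikes.neuron_ids == nid)
                         & res.spikes.is_excitatory).sum())
            assert n_spk == pytest.approx(expected_hz, rel=0.02)


class TestRunSimulation:
    def test_deterministic(self, two_neuron):
        conn, p = two_neuron
        a = ls.run_simulation(conn, p, ls.SimulationConfig(duration=100.0), rng=3)
        b = ls.run_simulation(conn, p, ls.SimulationConfig(duration=100.0), rng=3)
        assert np.array_equal(a.spikes.times, b.spikes.times)
        assert np.array_equal(a.trace.mean_g_EE, b.trace.mean_g_EE)

    def test_zero_duration(self, two_neuron):
        conn, p = two_neuron
        res = ls.run_simulation(conn, p, ls.SimulationConfig(duration=0.0), rng=4)
        assert len(res.spikes) == 0
        assert res.trace.t.shape == (1,)

    def test_phases_stay_wrapped(self, gamma_run):
        th = np.concatenate([gamma_run.final_state.theta_E,
                             gamma_run.final_state.theta_I])
        assert np.all(th > -np.pi - 1e-12) and np.all(th <= np.pi + 1e-12)

    def test_conductances_nonnegative(self, gamma_run):
        for g in (gamma_run.final_state.g_EE, gamma_run.final_state.g_EI,
                  gamma_run.final_state.g_IE, gamma_run.final_state.g_II):
            assert np.all(g >= 0)
        assert np.all(gamma_run.trace.mean_g_EE >= 0)

    def test_spike_times_nondecreasing(self, gamma_run):
        assert np.all(np.diff(gamma_run.spikes.times) >= 0)

    def test_single_spike_and_reset(self, two_neuron):
        conn, p0 = two_neuron
        p = p0.with_overrides(eta=2.0, delta=0.0)
        state = ls.initial_state(conn, p, rng=5)
        state.theta_E[:] = [np.pi - 1e-9, 0.0]
        res = ls.run_simulation(conn, p, ls.SimulationConfig(duration=0.1),
                                state=state)
        mine = res.spikes.times[(res.spikes.neuron_ids == 0)
                                & res.spikes.is_excitatory]
        assert len(mine) == 1
        assert -np.pi < res.final_state.theta_E[0] <= np.pi

    def test_stimulus_confined_to_window(self, two_neuron):
        conn, p0 = two_neuron
        p = p0.with_overrides(eta=0.1, delta=0.0)  # subthreshold alone
        stim = TaskStimulus(vector=np.array([5.0, 5.0]), onset=10.0,
                            duration=10.0)
        res = ls.run_simulation(conn, p, ls.SimulationConfig(duration=100.0),
                                stimulus=stim, rng=6)
        quiet = ls.run_simulation(conn, p, ls.SimulationConfig(duration=100.0),
                                  rng=6)
        assert quiet.spikes.count() == 0
        assert res.spikes.count() > 0
        assert res.spikes.times.min() >= 10.0

    def test_spike_buffer_overflow_raises(self, gamma_connectivity, params):
        with pytest.raises(ls.IntegrationError, match="overflow"):
            ls.run_simulation(gamma_connectivity, params,
                              ls.SimulationConfig(duration=50.0), rng=7,
                              spike_rate_headroom=1e-6)

    def test_first_order_spike_time_convergence(self, two_neuron):
        """The first spike time converges to the exact QIF crossing as dt
        shrinks (first-order accuracy incl. threshold quantization)."""
        conn, p0 = two_neuron
        p = p0.with_overrides(eta=2.0, delta=0.0, g_peak_EE=1e-12)
        # exact time from theta=0 (V at the parabola minimum) to divergence:
        # quarter... half of the full limit cycle: (pi/2)/sqrt(a b)
        a, b = 0.1 / 7.0, 2.0 - 0.175
        t_exact = (np.pi / 2) / np.sqrt(a * b)
        err = {}
        for dt in (0.04, 0.01):
            state = ls.initial_state(conn, p, rng=8)
            state.theta_E[:] = 0.0
            res = ls.run_simulation(conn, p,
                                    ls.SimulationConfig(duration=30.0, dt=dt),
                                    state=state)
            err[dt] = abs(res.spikes.times.min() - t_exact)
        assert err[0.01] < err[0.04]
        assert err[0.01] < 0.05  # ms


class TestGammaOscillation:
    def test_spectral_peak_in_gamma_band(self, gamma_run):
        sel = gamma_run.trace.t > 200
        f = ls.dominant_frequency(gamma_run.trace.t[sel],
                                  gamma_run.trace.mean_g_EE[sel])
        assert 30.0 <= f <= 100.0

    def test_mean_conductance_trace_is_periodic(self, gamma_run):
        """Autocorrelation of the gamma-regime conductance has a strong
        secondary peak at one period lag."""
        sel = gamma_run.trace.t > 200
        x = gamma_run.trace.mean_g_EE[sel]
        x = x - x.mean()
        ac = np.correlate(x, x, mode="full")[x.size - 1:]
        ac /= ac[0]
        f = ls.dominant_frequency(gamma_run.trace.t[sel],
                                  gamma_run.trace.mean_g_EE[sel])
        lag = int(round(1000.0 / f / gamma_run.trace.dt))
        assert ac[lag - 20:lag + 20].max() > 0.5
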