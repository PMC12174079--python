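# Methods

## Model

### Microscopic network

Two populations (N_E = 800 excitatory, N_I = 200 inhibitory) of
quadratic-integrate-and-fire neurons in phase form. The tangent map
V = (V_R+V_T)/2 + (V_T−V_R)/2·tan(θ/2) turns the QIF's finite-time voltage
blow-up/reset into a smooth phase crossing of π, so the phase equation

    C dθ/dt = −g_L cos θ + c0 (1+cos θ)(I_bg + I_task)
              + g_E [c1 (1+cos θ) − sin θ] + g_I [c2 (1+cos θ) − sin θ]

is exactly equivalent to conductance-based QIF dynamics between spikes (this
equivalence is enforced by a chain-rule oracle in the test suite, and fixes
the sign and coefficient conventions: c0 = 2/(V_T−V_R),
c_X = (2V_X−V_T−V_R)/(V_T−V_R), giving c0 = 2/7, c1 = 117/7, c2 = −23/7 at the
default potentials). Excitation and inhibition act through reversal
potentials (V_E = 0, V_I = −70 mV), so all synaptic weights are non-negative
and Dale's principle is structural.

Synaptic conductances are first-order exponential filters,
dg/dt = −g/τ_d between spikes with τ_E = 2 ms, τ_I = 5 ms. **Per-spike
increment**: a spike of presynaptic neuron j adds g_peak·J_ij to the summed
conductance of each target. We deliberately use the peak-amplitude convention
(not g_peak·J/τ_d): it makes the time-averaged summed conductance equal to
τ_Y·g_peak·p·N_Y·A_Y, exactly the fixed point of the macroscopic conductance
equation below, and it places the network's gamma rhythm at ≈43–46 Hz at the
operating point (the alternative convention yields ≈58 Hz). Background
currents are Cauchy(η, Δ) (η = 2, Δ = 0.04 µA/cm² by default), sampled by
inverse CDF and not truncated — the heavy tails are what makes the mean-field
closure exact. An optional quantile-clipping switch exists for robustness
experiments (off by default).

Integration: explicit Euler on the phases (dt = 0.01 ms default), exact
exponential decay of conductances per step, spike detection by θ ≥ π after
the update with reset θ → θ−2π, delivery of conductance jumps at the next
step boundary, no axonal delays, phases wrapped to (−π, π] every step.
Initial conditions (not specified by the source model): phases uniform on
(−π, π), conductances zero; experiments discard a transient (200 ms or more)
before measuring. First-order convergence of spike times is verified against
the closed-form QIF crossing time.

### Connectivity

J = clip(λχ + P, 0, 1) on the E→E block with P = **m n**ᵀ;
the EI/IE/II blocks are Gamma-only. χ entries are Gamma-distributed with
standard deviation 0.1 and moment-matched shape/scale. **m, n** are i.i.d.
Gaussian with zero mean and variance 0.2 (σ ≈ 0.447). We read the source's
"N(0, 0.2)" as a variance: with σ = 0.2 the rank-1 structure is too weak to
produce any Go/Nogo selectivity in the spiking network (the stimulus-induced
reordering of burst spikes shifts spike times by only ~±1 ms against a ~3 ms
burst width), whereas the variance reading yields robust selectivity and the
published phase-π tuning.

Because P's entries are then comparable to χ's mean, truncation to [0, 1]
would inflate the realized E→E mean by ~0.04. The Gamma mean of χ is
therefore calibrated by bisection so that the realized post-truncation block
mean equals the target (0.1 at the gamma operating point). One number per
block — the realized mean — drives both the microscopic sampler and the
macroscopic connection probability p_XY. Stimuli: I_go = **n**;
I_nogo is a Gaussian draw with n's statistics, orthogonalized against **n**
(single Gram–Schmidt step) and rescaled to its pre-projection norm. The
readout vector is W_out = **m** exactly.

### Macroscopic reduction

For Cauchy-distributed drive the population's first-order moment
z = ⟨e^{iθ}⟩ obeys a closed ODE. Writing the phase velocity as
v + w·cos θ + u·sin θ, the moment equation is dz/dt = i[f z² + h z + f̃] with
f = (w−iu)/2, h = v, f̃ = (w+iu)/2, all evaluated at the complex current
η + iΔ. Note f̃ is the analytic continuation of the constant term and is
*not* conj(f) once Δ > 0; the two differ by i·c0·Δ/C. We validated the
continued form against an exact quadrature oracle (Lorentzian-weighted
closed-form QIF rates): it reproduces stationary population rates to four
digits, while the conjugate form errs by up to 35% at low drive. The
conjugate form remains available (`closure="conjugate"`) for comparison.

Population conductances follow dg_XY/dt = −g_XY/τ_Y + g_peak_XY·p_XY·N_Y·A_Y
with A the population rate from the flux at θ = π,
A = g_L/(2πC)·[1 + 2 Re(−z/(1+z))]. A `drive_includes_tau` switch divides the
drive by τ_Y for comparison with the alternative per-spike convention.

Regime classification integrates the 8-dimensional system for 2 s, discards
1 s, and calls the state oscillatory when the relative peak-to-trough
amplitude of A_I exceeds 1%. The oscillation frequency is estimated from mean
inter-peak intervals of prominent maxima rather than a periodogram argmax:
the relaxation-type waveforms carry strong harmonics that can dominate raw
spectral power (at the 43 Hz operating point the second harmonic wins a
periodogram). Low vs high frequency splits at 30 Hz. A damped-Newton fixed
point solver with finite-difference Jacobian provides an eigenvalue
cross-check (stable fixed point ↔ stationary classification), which agrees
with the amplitude-based label away from the Hopf boundary.

With these conventions the three sampled points of the two-parameter diagram
classify as published: (η, p_II) = (0.4, 0.1) stationary, (0.1, 0.3)
low-frequency oscillation, (1.5, 0.2) high-frequency oscillation, and the
operating point (2.0, 0.2) oscillates in the gamma band at the same
fundamental frequency (≈43 Hz) as the spiking network.

### Readout

Z(t) = Σᵢ W_out,i·tanh(s·I_syn,i(t)), I_syn,i = −g_EE,i(V_i−V_E), E = Z².
Two numerical choices matter here. (1) V_i is reconstructed from θ_i via the
tangent map, which diverges during the (instantaneous) spike transit; we clip
V to the physiological interval [V_I, V_E] = [−70, 0] mV. With a loose
±500 mV cap the transit excursions dominate Z with sign-flipping artifacts
(baseline peak energy ~3000 and no Go/Nogo contrast). (2) The tanh argument
is scaled by s = c0 = 2/(V_T−V_R) per mV⁻¹ — the current unit in which the
phase equation itself operates — which centres the baseline synaptic drive in
the sensitive range of tanh. Both choices are configuration options
(`ReadoutConfig`; `ReadoutConfig.printed()` selects the literal unscaled
form).

Trial analysis: peak energy is the raw maximum of E(t) within a 300 ms
post-onset window (a baseline-subtracted variant is available); reaction time
is onset → peak time. The multi-peak response duration compares the energy
peak envelope (peaks ≥ 10 ms apart) against
baseline + 0.1·(max − baseline), where the baseline level is the median
height of pre-onset energy peaks (E(t) is pulse-like, so its between-peak
median is ≈0 and would make the rule vacuous); the crossing time is
interpolated linearly between the last supra-threshold and the first
sub-threshold peak.

### Phase-resolved stimulation

The instantaneous gamma phase is the argument of the analytic signal
(Hilbert transform) of the mean-subtracted population-mean E→E conductance —
a conductance peak maps to phase 0 — with half a cycle trimmed at each edge;
the gamma-regime trace is close enough to monochromatic that no band-pass is
applied by default (a configurable band-pass exists for noisier regimes).
Because the dynamics are deterministic given the network state, one
unstimulated baseline run per network serves three purposes: the restart
checkpoint after the transient, the period/reference-peak estimate, and the
seed-matched twin on which the achieved phase of every scheduled onset is
verified (trials missing their target by more than one bin width are
rejected; onsets are refined against the measured twin phase trace, which
absorbs the cycle-to-cycle period jitter that defeats pure
period-extrapolation at 33-bin resolution). Each trial restarts from the
checkpoint, so only the onset-to-window-end segment is re-simulated.

A trial's phase label refers to the **stimulus midpoint** (onset + 5 ms): the
10 ms pulse covers almost half a gamma cycle, and the midpoint convention is
the one under which the optimal Go stimulus — delivered just after the
population burst — carries the label π, consistent with the published tuning.
The onset convention is available (`phase_reference="onset"`; the same
optimum then reads ≈0.6π).

## Synthetic data and what the tests show

All inputs are generated: connectivity, background currents, initial phases
and stimuli are seeded draws at the published parameter values (sample sizes
800E/200I, η = 2, Δ = 0.04, block means 0.1/0.1/0.1/0.2, σ² = 0.2, 10 ms
stimuli). A counter-based seed hierarchy (master seed → network → trial)
keeps earlier draws stable when more trials are added. The generator emulates
the study's idealized conditions — homogeneous capacitance, no synaptic
delays, no measurement noise, exact Lorentzian heterogeneity — so passing
tests certify the model implementation, not robustness to real-data features
(electrode noise, non-Lorentzian heterogeneity, conduction delays).

Problem sizes in the test suite are chosen to keep the full run in a few
minutes of one CPU: 10 networks for the state comparison (the published
comparison used 50; tolerances widened 25% accordingly), 6 networks × 33 bins
for the phase sweep, 3 seeds for spectral and consistency checks.

## Known limitations

* The published Go energy range (1500–2000) is reproduced, but our Nogo /
  baseline peak energies (~400–900) sit above the published 100–200: the
  literal tanh readout of a deeply synchronized gamma network carries an
  irreducible baseline fluctuation from common-mode conductance swings
  weighted by Σm_i. We did not find a printed convention that lowers it
  without destroying the other anchors.
* The Go-response ordering across states comes out
  stationary ≳ gamma > low-frequency rather than gamma > low-frequency >
  stationary: near rheobase the stationary network is more sensitive per unit
  current (dr/dI ≈ 40 vs 14 Hz per µA/cm²) and its low conductances leave the
  readout unsaturated.
* The multi-peak Go response decays with a ~65 ms envelope time constant
  (≈3 supra-threshold cycles, ~75 ms by the 10% rule) rather than the
  published ~150 ms / ~7 cycles; the stimulus-imprinted burst-order memory
  decorrelates faster in our network.
* Pseudo-arclength continuation of the Hopf boundary, rank-2+ structure,
  synaptic delays and plasticity are out of scope.
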