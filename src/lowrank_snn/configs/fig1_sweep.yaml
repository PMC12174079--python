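# Two-parameter regime sweep: background drive eta x inhibitory recurrence p_II
experiment:
  eta_min: 0.0
  eta_max: 2.0
  eta_steps: 9
  p_ii_min: 0.02
  p_ii_max: 0.5
  p_ii_steps: 9
connectivity:
  mean_EE: 0.1
  mean_EI: 0.1
  mean_IE: 0.1
seed: 0
outdir: results/sweep
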