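# Single-network Go-Nogo trials at the gamma operating point
params:
  eta: 2.0
connectivity:
  mean_EE: 0.1
  mean_EI: 0.1
  mean_IE: 0.1
  mean_II: 0.2
experiment:
  onset_ms: 400.0
  window_ms: 300.0
seed: 0
outdir: results/gonogo
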