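# Phase-resolved stimulation sweep (33 bins) at the gamma operating point
params:
  eta: 2.0
connectivity:
  mean_II: 0.2
experiment:
  n_networks: 50
  n_bins: 33
seed: 0
outdir: results/phase_sweep
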