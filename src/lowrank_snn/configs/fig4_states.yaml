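# Peak-energy comparison across gamma / stationary / low-frequency states
experiment:
  n_networks: 50
  states: [gamma, stationary, low_freq]
seed: 0
outdir: results/states
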