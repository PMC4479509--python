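# Coarse 6x6 equilibrium invasibility surface (theta descending, sigma
# ascending); the full default surface is 20x20.
parameters: {}
sweep:
  n_theta: 6
  n_sigma: 6
seed: 0
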