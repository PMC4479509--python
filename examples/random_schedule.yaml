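# Sporadic disturbances over 20 years: Poisson arrivals of 2-month
# immunosuppression windows (theta -> 0) and 10-day resource surges
# (sigma scaled by a factor drawn uniformly from [5, 100]).
parameters: {}
run:
  horizon: 20.0
schedule:
  generator:
    immune_rate: 0.5
    resource_rate: 2.0
    magnitude_ranges:
      immune: [0.0, 0.0]
      resource: [5.0, 100.0]
seed: 7
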