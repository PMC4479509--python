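# Worst-timing combined disturbance from the burned-in baseline:
# a 10-day resource surge (sigma x10) centered inside a 2-month
# full-immunosuppression window (theta -> 0).
parameters: {}          # published defaults
run:
  horizon: 4.0
schedule:
  pulses:
    - {target: immune, start: 0.5, duration: 0.16666666666666666, mode: replace, magnitude: 0.0}
    - {target: resource, start: 0.5698630136986301, duration: 0.0273972602739726, mode: scale, magnitude: 10.0}
seed: 0
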