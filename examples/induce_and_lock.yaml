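# Moderate forcing applied below the Turing point: a pulsating spot
# pattern appears and stays locked after the forcing stops.
a: 22.0
stages:
  - duration: 50.0            # settle the homogeneous state
  - {duration: 150.0, A: 6.0, T: 1.0}
  - duration: 150.0           # forcing off: the pattern persists
seed: 1
snapshot_interval: 50.0
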