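# Strong forcing applied inside the pattern window: the settled spot
# pattern is erased, then reforms once the forcing stops.
a: 24.0
stages:
  - duration: 150.0           # settle the spot pattern
  - {duration: 25.0, A: 15.0, T: 1.0}
  - duration: 225.0           # forcing off: the pattern regrows
seed: 1
snapshot_interval: 50.0
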