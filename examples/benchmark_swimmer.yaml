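# Benchmark swimmer: two-turn helix (b=1, pitch 8b, r=b/16) on a head R=2b.
geometry:
  amplitude: 1.0
  pitch: 8.0
  n_turns: 2.0
  filament_radius: 0.0625
  head_radius: 2.0
physics:
  viscosity: 1.0
  motor_rate: 1.0
task:
  kind: swim
  methods: [global, additive, rft-gh, rft-lighthill]
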