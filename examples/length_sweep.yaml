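# Tight-helix length sweep (pitch 2.42b) at fixed head size and motor rate.
geometry:
  amplitude: 1.0
  pitch: 2.42
  n_turns: 2.0          # overridden per grid point
  filament_radius: 0.0625
  head_radius: 2.0
physics:
  viscosity: 1.0
  motor_rate: 1.0
numerics:
  n_head_nodes: 300     # reduced resolution: qualitative shapes
  spacing_factor: 2.0
task:
  kind: sweep
  methods: [global, additive]
  n_turns_grid: [1, 2, 3, 5, 8, 12, 16, 20]
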