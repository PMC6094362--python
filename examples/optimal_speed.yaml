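# Flagellar length maximizing swimming speed (coupled solve).
geometry:
  amplitude: 1.0
  pitch: 2.42
  n_turns: 2.0
  filament_radius: 0.0625
  head_radius: 2.0
physics:
  viscosity: 1.0
  motor_rate: 1.0
numerics:
  n_head_nodes: 300
  spacing_factor: 2.0
task:
  kind: optimize
  methods: [global]
  measure: speed
  bracket: [2, 16]
  tolerance: 0.25
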