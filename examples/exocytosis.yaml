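# Ten docked synaptic vesicles fusing with the cell membrane at 5 /s.
mesh:
  generate: {shape: sphere, diameter: 0.5e-6, target_edge: 130.0e-9, seed: 1}
species: []
vesicle_types:
  - {name: sv, diameter: 4.0e-8, D: 0.0, count: 10, lumen_init: {glutamate: 1000}}
exocytosis:
  - {name: fuse, rate: 5.0, patch: surf, mode: full_collapse}
run:
  end_time: 0.4
  dt: 1.0e-2
  record: [vesicles]
  record_period: 0.1
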