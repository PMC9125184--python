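# Single-sink gradient diagnostics: one pathway, strong unloading zone.
name: single_sink
hydraulic_mode: phloem_only
source: {v0: 1.0e-9}
sinks:
  - {v_max: 25.0e-9, k_m: 75.0, pathway_length: 0.25}
scan:
  grid_pairs:  # (v_load, v_max_unloading) in mol/s
    - [1.0e-9, 25.0e-9]
    - [10.0e-9, 25.0e-9]
    - [10.0e-9, 15.0e-9]
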