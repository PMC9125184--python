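# Two root sinks, both coupled to soil at 0 MPa; source transpires 0.02 g/s.
name: root_root
hydraulic_mode: xylem_coupled
source: {v0: 12.5e-9, evaporation_mode: fixed}
sinks:
  - {v_max: 12.5e-9, k_m: 75.0, pathway_length: 0.25,
     water_boundary: {kind: soil_coupled, permeability_factor: 1.0, exchange_area: 1.6}}
  - {v_max: 12.5e-9, k_m: 75.0, pathway_length: 0.25,
     water_boundary: {kind: soil_coupled, permeability_factor: 1.0, exchange_area: 1.6}}
scan:
  loading_grid: {start: 0.025e-9, stop: 24.0e-9, num: 8, spacing: log}
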