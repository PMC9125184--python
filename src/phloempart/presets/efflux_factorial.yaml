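# Baseline of the length x xylem x efflux x SP6A factorial: initially equal
# sinks (v_max = 5 nmol/s, K_m = 75 mM, l = 0.25 m) representing a young leaf
# (sink 1) and roots/tubers (sink 2); the factorial driver switches on length
# differences (0.1 vs 0.3 m), xylem-flow differences (leaf evaporation 10%),
# radial efflux, SP6A (sweet v_max x 0.6) and a tuber sink-strength increase
# (5 -> 15 nmol/s with an equal source-strength increase).
name: efflux_factorial
hydraulic_mode: xylem_coupled
source: {v0: 2.5e-9, evaporation_mode: fixed}
sinks:
  - {v_max: 5.0e-9, k_m: 75.0, pathway_length: 0.25,
     water_boundary: {kind: soil_coupled, permeability_factor: 1.0, exchange_area: 1.6}}
  - {v_max: 5.0e-9, k_m: 75.0, pathway_length: 0.25,
     water_boundary: {kind: soil_coupled, permeability_factor: 1.0, exchange_area: 1.6}}
radial_sucrose:
  sweet_efflux: {v_max: 0.148, k_m: 70.0}
  sweet_retrieval: {v_max: 0.148, k_m: 10.0}
  sut_retrieval: {v_max: 0.117, k_m: 1.0}
  apoplast_volume_fraction: 0.05
  apoplast_removal_rate: 0.089
  zones: []          # exchange disabled at baseline; the driver enables it
scan:
  loading_grid: {start: 0.25e-9, stop: 9.0e-9, num: 6, spacing: log}
  tuber_v_max_increased: 15.0e-9
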