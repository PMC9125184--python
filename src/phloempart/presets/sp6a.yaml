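# Factorial baseline with undirected SP6A present in all long-distance
# phloem: SWEET v_max reduced by 40% in both pathways.
name: sp6a
hydraulic_mode: xylem_coupled
sp6a_factor: 0.6
source: {v0: 2.5e-9, evaporation_mode: fixed}
sinks:
  - {v_max: 5.0e-9, k_m: 75.0, pathway_length: 0.1,
     water_boundary: {kind: evaporating, fraction_of_source: 0.1}}
  - {v_max: 5.0e-9, k_m: 75.0, pathway_length: 0.3,
     water_boundary: {kind: soil_coupled, permeability_factor: 1.0, exchange_area: 1.6}}
radial_sucrose:
  sweet_efflux: {v_max: 0.148, k_m: 70.0}
  sweet_retrieval: {v_max: 0.148, k_m: 10.0}
  sut_retrieval: {v_max: 0.117, k_m: 1.0}
  apoplast_volume_fraction: 0.05
  apoplast_removal_rate: 0.089
  zones: [pathway_1, pathway_2]
scan:
  loading_grid: {start: 0.25e-9, stop: 9.0e-9, num: 6, spacing: log}
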