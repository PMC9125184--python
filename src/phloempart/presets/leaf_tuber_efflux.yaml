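# Leaf (0.1 m, evaporating) vs root/tuber (0.3 m, soil-coupled) with SWEET
# efflux and SWEET+SUT retrieval along both long-distance pathways; standard
# sink strength so the full 0.025-25 nmol/s loading scan stays below combined
# capacity. The apoplast removal rate is calibrated once so that the maximum
# net efflux over this scan is ~23% of the loading rate, then frozen here.
name: leaf_tuber_efflux
hydraulic_mode: xylem_coupled
source: {v0: 12.5e-9, evaporation_mode: fixed}
sinks:
  - {v_max: 12.5e-9, k_m: 75.0, pathway_length: 0.1,
     water_boundary: {kind: evaporating, fraction_of_source: 0.1}}
  - {v_max: 12.5e-9, k_m: 75.0, pathway_length: 0.3,
     water_boundary: {kind: soil_coupled, permeability_factor: 1.0, exchange_area: 1.6}}
radial_sucrose:
  sweet_efflux: {v_max: 0.148, k_m: 70.0}
  sweet_retrieval: {v_max: 0.148, k_m: 10.0}
  sut_retrieval: {v_max: 0.117, k_m: 1.0}
  apoplast_volume_fraction: 0.05
  apoplast_removal_rate: 0.089
  zones: [pathway_1, pathway_2]
scan:
  loading_grid: {start: 0.025e-9, stop: 25.0e-9, num: 8, spacing: log}
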