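# Sink-affinity scenario: equal v_max (12.5 nmol/s), K_m 75 vs 750 mM.
name: km
hydraulic_mode: phloem_only
vkr_r_refs: [7.5e+12, 7.5e+12]
source: {v0: 12.5e-9}
sinks:
  - {v_max: 12.5e-9, k_m: 75.0, pathway_length: 0.25}
  - {v_max: 12.5e-9, k_m: 750.0, pathway_length: 0.25}
scan:
  loading_grid: {start: 0.025e-9, stop: 25.0e-9, num: 40, spacing: log}
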