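# Sink-strength scenario: two sinks differing only in v_max (22.5 vs 2.5 nmol/s).
name: vmax
hydraulic_mode: phloem_only
vkr_r_refs: [7.5e+12, 7.5e+12]
source: {v0: 12.5e-9}
sinks:
  - {v_max: 22.5e-9, k_m: 75.0, pathway_length: 0.25}
  - {v_max: 2.5e-9, k_m: 75.0, pathway_length: 0.25}
scan:
  loading_grid: {start: 0.025e-9, stop: 25.0e-9, num: 40, spacing: log}
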