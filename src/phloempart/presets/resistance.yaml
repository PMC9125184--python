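# Pathway-resistance scenario: equal sinks, pathway lengths 0.25 vs 5 m
# (biophysical) and reference resistances 7.5e+12 vs 1.5e+14 mol s m^-6 (VKR).
name: resistance
hydraulic_mode: phloem_only
vkr_r_refs: [7.5e+12, 1.5e+14]
source: {v0: 12.5e-9}
sinks:
  - {v_max: 12.5e-9, k_m: 75.0, pathway_length: 0.25}
  - {v_max: 12.5e-9, k_m: 75.0, pathway_length: 5.0}
scan:
  loading_grid: {start: 0.025e-9, stop: 25.0e-9, num: 40, spacing: log}
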