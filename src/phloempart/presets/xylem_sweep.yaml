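# Xylem boundary sweep: sink 2 is a root with constant uptake 2e-8 m^3/s;
# sink 1 water flux is varied from evaporation (-1e-8) to equal uptake (2e-8).
# Source evaporation balances the net sink water flow.
name: xylem_sweep
hydraulic_mode: xylem_coupled
source: {v0: 12.5e-9, evaporation_mode: balance_sinks}
sinks:
  - {v_max: 12.5e-9, k_m: 75.0, pathway_length: 0.25,
     water_boundary: {kind: imposed_flux, q: 2.0e-8}}
  - {v_max: 12.5e-9, k_m: 75.0, pathway_length: 0.25,
     water_boundary: {kind: imposed_flux, q: 2.0e-8}}
scan:
  sink1_flux_grid: {start: -1.0e-8, stop: 2.0e-8, num: 7}
  loading_rates: [2.5e-9, 12.5e-9, 22.5e-9]
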