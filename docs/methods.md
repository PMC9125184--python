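# Methods

`phloempart` simulates steady-state sucrose distribution from one source
region to two competing sink organs in a potato plant, with three nested
model levels, and provides the scenario drivers used to study how sink
kinetics, pathway properties, xylem water flow, radial sucrose efflux and
the tuberigen SP6A shape resource partitioning.

The partitioning coefficient of sink *i* is PC_i = v_i / (v_1 + v_2), the
fraction of total unloading captured by that sink.

## Units

One internal unit system everywhere: gram, metre, second, MPa, mol.
Concentrations are mol/m^3, numerically equal to mM, so parameter values
quoted in mM are used unchanged.  The lumped model's resistance is in
mol s m^-6; hydraulic resistance is MPa s m^-3; the two are related by the
van 't Hoff factor RT (flow driven by osmotic pressure RT·Δc carrying
solute at the source concentration).

## Model 1 — VK (no resistance)

A perfectly conducting pathway equilibrates all concentrations
(c_0 = c_1 = c_2).  Sinks unload by Michaelis–Menten kinetics
v_i = v_max,i · c / (c + K_i), and the steady state solves
Σ v_i(c) = v_0.  With equal affinities the closed form is
c = K·v_0 / (Σ v_max − v_0); otherwise a bracketed scalar root.
Partitioning depends only on sink kinetics; for the sink-strength scenario
(v_max 22.5 vs 2.5 nmol/s) PC_1 = 90% identically in v_0.

## Model 2 — VKR (lumped sucrose-dependent resistance)

Each pathway carries flux c_0 (c_0 − c_i) / r_i, where the resistance
r_i = r_ref,i · p(S_1/2) depends on the mid-pathway concentration
S_1/2 = (c_0 + c_i)/2 (in mol/L) through the quartic viscosity polynomial

    p(S) = 0.685 S^4 − 1.0411 S^3 + 0.9512 S^2 + 0.1364 S + 0.3396,

stated valid for 0 ≤ S ≤ 1.5 M.  The steady state solves, for i = 1, 2,

    c_0 (c_0 − c_i) / r_i(S_1/2,i) = v_max,i c_i / (K_i + c_i),
    v_1 + v_2 = v_0,

for (c_0, c_1, c_2) by multi-start Newton iteration (≥ 15 starting points
spanning the low- and high-concentration regimes, residual threshold
1e-13 mol/s).  Only roots with all concentrations positive are accepted; if
several exist the smallest-c_0 root is reported and all roots are recorded
on the solution object.

Two numerical decisions matter here:

* **Polynomial clamping.**  Near sink saturation the concentrations exceed
  the polynomial's 1.5 M validity limit; extrapolating the quartic makes
  resistance grow like S^4, faster than the ~c_0^2 driving term, and
  steady states then cease to exist above ~23 nmol/s in the resistance
  scenario although the standard scan runs to 25 nmol/s.  `vkr_solve`
  therefore clamps S at 1.5 M by default (saturation of the viscosity law
  at its validity limit); the bare `vkr_resistance` operation keeps an
  evaluate-and-warn default so the printed polynomial remains available
  unmodified.
* **Low-loading limit.**  As v_0 → 0 the partitioning of the sink-strength
  scenario tends to exactly 50%, but the approach is slow (the deviation
  decays like √v_0): at the lowest scanned rate, 0.025 nmol/s, the model
  gives PC_1 = 51.46%, not 50.00%.  The package reports the computed value.

## Model 3 — spatially explicit biophysical model

### Geometry

A branched 1-D mesh: a loading zone (20 elements × 0.005 m), a zero-length
junction, and per sink a long-distance pathway (30 elements, length
pathway_length/30) ending in an unloading zone (20 elements × 0.005 m).
Each element represents N_Ph parallel sieve tubes of radius a_Ph = 8.4 µm
(phloem) and N_X parallel conduits of radius a_X = 30 µm (xylem); reference
volumes are N·π·a²·L.  The junction is a zero-storage node: the last
loading-zone element feeds both branch heads directly, with interface
lengths computed as if the junction had zero extent.

### State and derived fields

Per element: phloem water mass W_Ph (g) and sucrose S_Ph (mol); in
xylem-coupled mode also xylem water W_X; with radial sucrose exchange an
apoplast pool S_apo on the pathway elements.  Derived fields:

* concentration c = S / (W/ρ);
* turgor by linear elasticity, P = ε (V − V_ref)/V_ref, with ε_p = 30 MPa
  (phloem) and ε_x = 750 MPa (xylem, tension allowed) — the antecedent
  model's exact pressure–volume law is not restated anywhere, so linear
  elasticity about the reference volume is an explicit assumption;
* osmotic potential Π = −RT·c; water potential Ψ = P + Π (xylem carries no
  solute, Ψ_X = P_X);
* viscosity μ = μ_X exp(4.68 · 0.956 φ / (1 − 0.956 φ)) with the sucrose
  volume fraction φ = V_suc S / (V_suc S + V_water).  φ is capped at 0.8
  purely to keep the exponential finite during extreme transients.

### Fluxes

* Axial (phloem): Hagen–Poiseuille down the turgor gradient,
  Q = N_Ph π a_Ph² k_p / μ̄ · ΔP / L̄, with the interface viscosity and
  length taken as arithmetic means of the two elements (standard
  finite-volume choice).  Xylem analogously with permeability a_X²/8.
* Axial sucrose: advection at the upwind element's concentration
  (numerically stable; the discretisation is not otherwise specified).
* Radial water: J = L_r A_rad (Ψ_outside − Ψ_Ph), with
  A_rad = N_Ph · 2π a_Ph · L the sieve-tube lateral area (an assumption —
  only "the radial area between phloem and xylem" is stated).  In
  phloem-only mode the outside is a reservoir at Ψ = 0; in xylem-coupled
  mode it is the co-located xylem element, with the equal-and-opposite term
  applied there.
* Loading: v_0 spread uniformly over the loading-zone elements, constant in
  time.  Unloading: per-element Michaelis–Menten with the zone's v_max
  divided uniformly over its 20 elements (a tip-concentrated alternative is
  a configuration option).

### Water boundary conditions (xylem-coupled mode)

Per sink one of: imposed volumetric flux (uptake positive, evaporation
negative), soil-coupled uptake J = pf · L_r · A_soil · (ψ_soil − Ψ_X) with a
permeability factor pf (tubers: 0.1), or fixed evaporation as a fraction of
the source transpiration (young leaf: 0.1 × 0.02 g/s).  The source zone
extracts the transpiration rate J_trans, or, in balance mode, the net sum of
the sink water flows (used for the imposed-flux sweep, closing the water
budget exactly).

The soil exchange surface A_soil deserves a note: the sieve-tube lateral
area (~2.5 cm² per sink zone) would require soil–xylem potential drops of
order 10^3 MPa to pass transpiration-scale flows — roots absorb over a much
larger surface.  A_soil defaults to 1.6 m² per sink zone, which yields
root-zone potential drops of ~0.13 MPa at an uptake of 2e-8 m³/s and whole-
plant xylem potentials in the −0.1 to −0.5 MPa range, the magnitude the
organ scenarios display.  It is exposed per sink in the configuration.

### Parallel conduit number

N_Ph is not a printed parameter.  It is fixed by the calibration statement
that the standard 0.25 m pathway has, at zero sucrose, the same resistance
as the lumped model: μ_X L / (k_p N_Ph π a_Ph²) = RT · p(0) · 7.5e12,
giving N_Ph ≈ 47.6.  N_X defaults to N_Ph.  Note that this pins the product
N_Ph·a_Ph², hence the phloem volume per metre — the transport capacitance of
the model is therefore not a free parameter (see Limitations).

### Radial sucrose exchange and SP6A

On the pathway elements, bidirectional SWEET transporters efflux sucrose to
the apoplast (v_max 0.148 mol m^-3 s^-1 per phloem volume, K_m 70 mM) and,
together with SUT importers (0.117, 1 mM), retrieve it (SWEET retrieval:
0.148, 10 mM).  Rates are volumetric, so at uniform concentration the
efflux is constant per unit pathway length.  The apoplast pool loses
sucrose to the surrounding tissues by first-order removal in its
concentration, scaled by the phloem element volume
(removal = k_rem · c_apo · V_elem).  Removal in concentration rather than
amount makes the steady state independent of the assumed apoplast volume
fraction (default 5% of the phloem volume, which then only sets the pool's
transient inertia); this insensitivity is asserted in the tests.

k_rem is the one calibrated parameter: it was set once so that the maximum
net efflux fraction, (loading − total unloading)/loading, over the standard
8-point loading scan of the leaf (0.1 m, evaporating) / tuber-root (0.3 m,
soil-coupled) scenario is ≈ 23%, and frozen at 0.089 s^-1 in the preset.
The maximum is attained at the lowest loading rate and decreases
monotonically with loading.  The calibration scenario uses the standard
sink strength (12.5 nmol/s per sink) because the factorial baseline
(5 nmol/s per sink) cannot host loading rates up to 25 nmol/s.

SP6A reduces SWEET v_max by 40% (factor 0.6) in all long-distance phloem,
undirected.  Because SP6A binds the transporter itself, the default scales
both the efflux- and retrieval-side SWEET activity; an efflux-only variant
is a configuration flag (`sp6a_affects_retrieval=False`).

### Steady-state integration

The stiff ODE system (fast pressure equilibration, slow sucrose
redistribution; the stiffness ratio spans ~15 orders of magnitude because
of the xylem elastic modulus) is integrated with the implicit BDF method
and a sparse Jacobian pattern, on an internally scaled state (each
component divided by its reference magnitude).  Integration proceeds
through checkpoints (2e3 … 1e7 s); after each checkpoint the steady-state
criterion max_j |dy_j/dt| · τ / |y_j| is evaluated with τ = 1e4 s.

The default threshold is 1e-4, i.e. every component drifts by less than
1e-8 per second relative to its value.  Much tighter thresholds are not
meaningful in double precision: turgor-difference fluxes are computed by
catastrophic cancellation, and the resulting noise floor of the criterion
is ~2e-8 (phloem-only) to ~2.5e-5 (xylem-coupled, where ε_x = 750 MPa
amplifies state roundoff).  Near-steady states are refined by a damped
finite-difference Newton step (least-squares solve, which tolerates the
rank deficiency of water-conserving boundary modes); a Newton result is
accepted only if it stays within 50% of the integrated state, guarding
against jumps to a different root.  All runs are deterministic and
bit-reproducible; grid drivers warm-start each solve from the previous
steady state, with cold-start spot checks in the test suite.

The initial state is uniform: c = 300 mol/m³, volumes at reference, xylem
at the soil potential, empty apoplast.  Steady states are insensitive to
the initial concentration (tested at 100 vs 500 mol/m³).

## Diagnostics

* **Mean pathway summaries** (single-sink analysis): the *spatial* mode
  reports the length-weighted mean pathway concentration and the sum of
  local resistances (local viscosity); the *linear* mode reports the
  midpoint of a straight gradient between the source-zone and sink-zone
  concentrations and the resistance the pathway would have at that single
  concentration — the lumped-model view.  Both modes use the same
  (volume-fraction) viscosity law so they agree exactly for a uniform
  profile; the lumped view underestimates both quantities whenever a real
  gradient exists, increasingly so at higher loading and unloading rates.
* **Effective resistance** per branch: Σ μ_j L_j / (k_p N_Ph π a_Ph²),
  in MPa s m^-3 (divide by RT for the lumped unit).
* **Mass-balance audit**: |v_0 − v_1 − v_2 − removal|/v_0 < 1e-6 and, in
  coupled mode, net boundary water closure; non-converged runs fail.
* **Water-potential profiles** with the Ψ = P + Π decomposition per element.

## Scenario drivers and problem sizes

All drivers run at the full 20/30/20 mesh.  Default grids: 40 log-spaced
loading rates over 0.025–25 nmol/s for lumped scans; the spatial-model
scans in the shipped drivers and checks use 4–8 grid points per condition
(a full steady state takes ~0.3–1 s, so denser grids are a flag away).
The xylem sweep varies the sink-1 flux over [−1e-8, 2e-8] m³/s against a
constant 2e-8 m³/s root uptake at three loading rates (2.5/12.5/22.5
nmol/s — the sweep's loading rates are a package choice, labelled
low/mid/high, not printed values).

The step-response driver integrates the transient after an instantaneous
sink v_max change from a converged baseline and reports t_90, the time to
cover 90% of the partitioning shift measured from the immediate post-step
partitioning (the kinetic step moves PC discontinuously at t = 0+; the
quantity of interest is the slow transport-driven relaxation).  The default
experiment halves sink 1's v_max in the symmetric two-sink system at
1 nmol/s, a low, non-saturating rate — the regime where pathway effects
matter.

## What the scenarios do and do not emulate

The presets encode idealised organ physiology: a root is a soil-coupled
water absorber, a tuber the same with 90%-reduced uptake permeability, a
young sink leaf a weak evaporator.  All sinks unload actively
(Michaelis–Menten); the passive unloading mode of real maturing tubers is
deliberately out of scope.  Sieve-element architecture is uniform along the
plant, the geometry is static (no growth), and the xylem carries no solute.
Consequently, passing tests show that the transport physics produces the
documented partitioning phenomena under these idealisations — not that any
specific potato cultivar behaves quantitatively so.

## Known limitations

* **Adaptation timescale.**  The measured t_90 of partitioning adaptation
  after a sink v_max step is ~1–2 minutes (and the unaffected sink's import
  adjusts within ~15 minutes) across loading rates, much faster than the
  hour-scale adaptation reported for comparable models.  The timescale is
  set by the sucrose pool capacitance c·N_Ph·π·a_Ph²·L, and N_Ph·a_Ph² is
  already pinned by the resistance calibration, so this is an emergent,
  untunable property of the present parameterisation; organ-scale sink
  volumes (not representable in the sieve-element mesh) would lengthen it.
* **Relative pathway resistances.**  In the sink-strength scenario the
  spatial model's effective resistance ratio r_1/r_2 comes out a few
  percent above 1 (the strong-sink branch is less diluted by radial water
  inflow along its pathway), whereas the lumped model puts it slightly
  below 1.  The magnitude matches; the sign of this small quantity depends
  on discretisation details.  The robust ordering — the spatial model
  allocates to the strong sink no more than the lumped model at
  non-saturating loading — holds and is tested.
* **Unprinted constants.**  RT assumes 293.15 K; V_suc = 342.3 g/mol ÷
  1587 kg/m³ = 2.157e-4 m³/mol; both are flagged assumptions.  The lumped
  reference resistances are read as r_1 = 7.5e12 and r_2 = 1.5e14
  mol s m^-6 (1:20, consistent with the 0.25 m : 5 m length ratio).
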