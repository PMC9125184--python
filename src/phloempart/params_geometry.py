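"""Physical constants, scenario configuration, presets and the branched 1-D mesh.

Internal unit system (used everywhere, without exception): gram, metre,
second, MPa, mol.  Concentrations are mol/m^3, so a value printed as mM can
be used numerically unchanged (1 mM = 1 mol/m^3).  Resistances of the lumped
VKR model are mol s m^-6; hydraulic resistances are MPa s m^-3 and the two
are related by the van 't Hoff factor RT (MPa m^3 / mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .radial_sucrose import RadialSucroseConfig

__all__ = [
    "PlantParameters",
    "ImposedFlux",
    "SoilCoupled",
    "Evaporating",
    "SinkSpec",
    "SourceSpec",
    "MeshSpec",
    "SolverSettings",
    "ScenarioConfig",
    "Mesh",
    "Diagnostic",
    "build_mesh",
    "preset_scenario",
    "preset_names",
    "validate_config",
    "calibrated_n_ph",
    "config_to_dict",
    "config_from_dict",
]

#: Gas constant in MPa m^3 / (mol K).
R_GAS = 8.314462618e-6

#: VKR reference resistance of the standard 0.25 m pathway (mol s m^-6) and
#: the zero-sucrose value of the viscosity polynomial; together with RT they
#: anchor the number of parallel sieve tubes (see :func:`calibrated_n_ph`).
VKR_REFERENCE_RESISTANCE = 7.5e12
VKR_REFERENCE_LENGTH = 0.25
VISCOSITY_POLY_AT_ZERO = 0.3396


def calibrated_n_ph(
    mu_x: float,
    k_p: float,
    a_ph: float,
    rt: float,
    r_ref: float = VKR_REFERENCE_RESISTANCE,
    length: float = VKR_REFERENCE_LENGTH,
) -> float:
    """Number of parallel sieve tubes that equates pathway resistances.

    The biophysical pathway resistance at zero sucrose (viscosity of pure
    water) is ``mu_x * L / (k_p * N * pi * a_ph**2)`` (MPa s / m^3).  The VKR
    model's resistance at zero sucrose is ``r_ref * poly(0)`` (mol s / m^6),
    which converts to hydraulic units through RT.  Equating the two for the
    standard 0.25 m pathway fixes N.
    """
    r_single = mu_x * length / (k_p * math.pi * a_ph**2)
    return r_single / (rt * VISCOSITY_POLY_AT_ZERO * r_ref)


@dataclass
class PlantParameters:
    """Physical constants of the biophysically detailed model.

    Defaults are the potato parameterisation; ``rt`` corresponds to 293.15 K
    (an assumption: temperature is not part of the parameter table) and
    ``v_suc`` is the partial molar volume of sucrose, 342.3 g/mol divided by
    a density of 1587 kg/m^3 (likewise an assumption).
    """

    rho_water: float = 0.998e6      # g/m^3
    l_r: float = 5e-8               # m MPa^-1 s^-1, radial membrane permeability
    mu_x: float = 1.0019e-9         # MPa s, viscosity of water / xylem sap
    a_ph: float = 8.4e-6            # m, sieve element radius
    a_x: float = 30e-6              # m, xylem conduit radius
    k_p: float = 3.82e-12           # m^2, axial phloem permeability
    eps_p: float = 30.0             # MPa, phloem elastic modulus
    eps_x: float = 750.0            # MPa, xylem elastic modulus
    j_trans: float = 0.02           # g/s, source transpiration rate
    psi_soil: float = 0.0           # MPa
    rt: float = R_GAS * 293.15      # MPa m^3/mol
    v_suc: float = 342.3 / 1.587e6  # m^3/mol
    n_ph: Optional[float] = None    # parallel sieve tubes; None -> calibrated
    n_x: Optional[float] = None     # parallel xylem conduits; None -> n_ph

    def __post_init__(self) -> None:
        for name in ("rho_water", "l_r", "mu_x", "a_ph", "a_x", "k_p",
                     "eps_p", "eps_x", "j_trans", "rt", "v_suc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PlantParameters.{name} must be positive")
        if self.psi_soil > 0:
            raise ValueError("psi_soil must be <= 0 MPa")
        if self.n_ph is None:
            self.n_ph = calibrated_n_ph(self.mu_x, self.k_p, self.a_ph, self.rt)
        if self.n_x is None:
            self.n_x = self.n_ph
        if self.n_ph <= 0 or self.n_x <= 0:
            raise ValueError("conduit counts must be positive")

    # Convenience geometry (per single element of length L these are
    # multiplied by L; conduit counts included).
    @property
    def axial_area_ph(self) -> float:
        """Total phloem axial lumen area, N_Ph * pi * a_Ph^2 (m^2)."""
        return self.n_ph * math.pi * self.a_ph**2

    @property
    def axial_area_x(self) -> float:
        return self.n_x * math.pi * self.a_x**2

    @property
    def k_x(self) -> float:
        """Xylem axial permeability from Poiseuille flow in a tube, a^2/8 (m^2)."""
        return self.a_x**2 / 8.0


@dataclass
class ImposedFlux:
    """Fixed volumetric water exchange with the sink's xylem (m^3/s).

    Positive is uptake into the plant, negative is evaporation.
    """

    q: float
    kind: str = "imposed_flux"


@dataclass
class SoilCoupled:
    """Water uptake from soil, J = pf * L_r * A_soil * (psi_soil - Psi_X).

    ``permeability_factor`` scales the root's uptake permeability (tubers:
    0.1, i.e. 90% reduction).  ``exchange_area`` is the absorbing surface of
    the sink organ (m^2, whole sink zone); sieve-tube lateral area is far too
    small to pass transpiration-scale flows at realistic potential drops.
    """

    permeability_factor: float = 1.0
    exchange_area: float = 1.6
    kind: str = "soil_coupled"

    def __post_init__(self) -> None:
        if not 0 < self.permeability_factor <= 1:
            raise ValueError("permeability_factor must be in (0, 1]")
        if self.exchange_area <= 0:
            raise ValueError("exchange_area must be positive")


@dataclass
class Evaporating:
    """Fixed evaporation from the sink's xylem as a fraction of J_trans."""

    fraction_of_source: float = 0.1
    kind: str = "evaporating"

    def __post_init__(self) -> None:
        if not 0 < self.fraction_of_source <= 1:
            raise ValueError("evaporating fraction must be in (0, 1]")


WaterBoundary = Union[ImposedFlux, SoilCoupled, Evaporating]


@dataclass
class SinkSpec:
    """Per-sink unloading kinetics and water boundary condition."""

    v_max: float = 12.5e-9          # mol/s
    k_m: float = 75.0               # mol/m^3
    pathway_length: float = 0.25    # m
    water_boundary: WaterBoundary = field(default_factory=lambda: SoilCoupled())

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.k_m <= 0:
            raise ValueError("k_m must be positive")
        if self.pathway_length <= 0:
            raise ValueError("pathway_length must be positive")


@dataclass
class SourceSpec:
    """Sucrose loading rate and the source-zone water closure rule."""

    v0: float = 12.5e-9
    evaporation_mode: Literal["fixed", "balance_sinks"] = "fixed"

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError("loading rate must be >= 0")


@dataclass
class MeshSpec:
    """Per-zone element counts and lengths of the non-homogeneous mesh."""

    n_source: int = 20
    source_element_length: float = 0.005
    n_pathway: int = 30
    n_sink: int = 20
    sink_element_length: float = 0.005

    def __post_init__(self) -> None:
        for name in ("n_source", "n_pathway", "n_sink"):
            if getattr(self, name) < 1:
                raise ValueError(f"MeshSpec.{name} must be >= 1")
        if self.source_element_length <= 0 or self.sink_element_length <= 0:
            raise ValueError("element lengths must be positive")


@dataclass
class SolverSettings:
    """Numerical settings of the steady-state integrator."""

    rtol: float = 1e-6
    atol: float = 1e-9              # on the internally scaled state (~O(1))
    # Scaled-derivative steady-state threshold: max_j |dy_j/dt| * tau / |y_j|.
    # 1e-4 with tau = 1e4 s means every component drifts by less than 1e-8
    # per second relative to its value; thresholds much below ~1e-5 are not
    # attainable in double precision because turgor-difference fluxes are
    # computed by catastrophic cancellation (the xylem modulus of 750 MPa
    # amplifies state roundoff to ~1e-5 in criterion units).
    ss_tol: float = 1e-4
    ss_tau: float = 1e4             # s, reference horizon of the criterion
    t_max: float = 1e7              # s, hard integration horizon
    initial_concentration: float = 300.0  # mol/m^3
    newton_polish: bool = True      # refine near-steady states by Newton


@dataclass
class ScenarioConfig:
    """Complete description of one simulation scenario."""

    parameters: PlantParameters = field(default_factory=PlantParameters)
    source: SourceSpec = field(default_factory=SourceSpec)
    sinks: list[SinkSpec] = field(default_factory=lambda: [SinkSpec(), SinkSpec()])
    mesh_spec: MeshSpec = field(default_factory=MeshSpec)
    hydraulic_mode: Literal["phloem_only", "xylem_coupled"] = "phloem_only"
    radial_sucrose: Optional[RadialSucroseConfig] = None
    sp6a_factor: float = 1.0
    vkr_r_refs: tuple[float, float] = (7.5e12, 7.5e12)
    solver: SolverSettings = field(default_factory=SolverSettings)
    name: str = "custom"
    scan: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sinks) not in (1, 2):
            raise ValueError("a scenario has one or two sinks")
        if not 0 < self.sp6a_factor <= 1:
            raise ValueError("sp6a_factor must be in (0, 1]")

    @property
    def n_sinks(self) -> int:
        return len(self.sinks)

    def copy(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

ZONE_SOURCE = "source"
ZONE_PATHWAY = ("pathway_1", "pathway_2")
ZONE_SINK = ("sink_1", "sink_2")
ZONE_JUNCTION = "junction"


@dataclass
class Mesh:
    """Branched 1-D element mesh.

    State-carrying elements are stored in flat arrays; the junction is an
    explicit zero-length, zero-storage node kept only in the element table
    and in the connectivity (the last source element feeds both branch
    heads directly, with interface lengths computed as if the junction had
    zero extent).
    """

    zone: np.ndarray              # str per state element
    branch: np.ndarray            # 0 stem, 1 or 2
    length: np.ndarray            # m
    v_ref_ph: np.ndarray          # m^3
    v_ref_x: np.ndarray           # m^3
    a_rad: np.ndarray             # m^2, phloem lateral membrane area
    edges_parent: np.ndarray      # indices into state arrays
    edges_child: np.ndarray
    edge_length: np.ndarray       # m, interface length
    position: np.ndarray          # m, distance from the source tip
    n_sinks: int

    @property
    def n_state(self) -> int:
        return self.zone.size

    @property
    def n_elements(self) -> int:
        """Element count including the explicit junction node."""
        return self.n_state + (1 if self.n_sinks == 2 else 0)

    def zone_mask(self, name: str) -> np.ndarray:
        return self.zone == name

    def element_table(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "zone": self.zone,
                "branch": self.branch,
                "length": self.length,
                "position": self.position,
                "v_ref_ph": self.v_ref_ph,
                "v_ref_x": self.v_ref_x,
            }
        )
        if self.n_sinks == 2:
            junction_pos = float(
                self.position[self.zone == ZONE_SOURCE][-1]
                + self.length[self.zone == ZONE_SOURCE][-1] / 2
            )
            junction = pd.DataFrame(
                {
                    "zone": [ZONE_JUNCTION],
                    "branch": [0],
                    "length": [0.0],
                    "position": [junction_pos],
                    "v_ref_ph": [0.0],
                    "v_ref_x": [0.0],
                }
            )
            rows = pd.concat([rows, junction], ignore_index=True)
        return rows


def build_mesh(config: ScenarioConfig) -> Mesh:
    """Construct the branched mesh for a scenario.

    Source zone (n_source elements), then per sink a long-distance pathway
    (n_pathway elements of length pathway_length/n_pathway) ending in an
    unloading zone (n_sink elements).  With two sinks the branching point is
    a zero-length junction after the last source element.
    """
    ms = config.mesh_spec
    p = config.parameters
    zones, branches, lengths = [], [], []

    zones += [ZONE_SOURCE] * ms.n_source
    branches += [0] * ms.n_source
    lengths += [ms.source_element_length] * ms.n_source

    for i, sink in enumerate(config.sinks):
        if sink.pathway_length <= 0:
            raise ValueError("pathway_length must be positive")
        path_zone = ZONE_PATHWAY[i] if config.n_sinks == 2 else ZONE_PATHWAY[0]
        sink_zone = ZONE_SINK[i] if config.n_sinks == 2 else ZONE_SINK[0]
        zones += [path_zone] * ms.n_pathway
        branches += [i + 1] * ms.n_pathway
        lengths += [sink.pathway_length / ms.n_pathway] * ms.n_pathway
        zones += [sink_zone] * ms.n_sink
        branches += [i + 1] * ms.n_sink
        lengths += [ms.sink_element_length] * ms.n_sink

    zone = np.array(zones)
    branch = np.array(branches)
    length = np.array(lengths, dtype=float)

    # connectivity: chains within each branch, the last source element is
    # the parent of each branch head.
    parents, children = [], []
    n_src = ms.n_source
    per_branch = ms.n_pathway + ms.n_sink
    for i in range(n_src - 1):
        parents.append(i)
        children.append(i + 1)
    for b in range(config.n_sinks):
        start = n_src + b * per_branch
        parents.append(n_src - 1)
        children.append(start)
        for j in range(per_branch - 1):
            parents.append(start + j)
            children.append(start + j + 1)
    ep = np.array(parents, dtype=int)
    ec = np.array(children, dtype=int)
    edge_length = 0.5 * (length[ep] + length[ec])

    # distance from source tip, per element midpoint
    position = np.empty_like(length)
    cum = 0.0
    for i in range(n_src):
        position[i] = cum + length[i] / 2
        cum += length[i]
    source_end = cum
    for b in range(config.n_sinks):
        start = n_src + b * per_branch
        cum = source_end
        for j in range(per_branch):
            k = start + j
            position[k] = cum + length[k] / 2
            cum += length[k]

    v_ref_ph = p.axial_area_ph * length
    v_ref_x = p.axial_area_x * length
    a_rad = p.n_ph * 2 * math.pi * p.a_ph * length

    return Mesh(
        zone=zone,
        branch=branch,
        length=length,
        v_ref_ph=v_ref_ph,
        v_ref_x=v_ref_x,
        a_rad=a_rad,
        edges_parent=ep,
        edges_child=ec,
        edge_length=edge_length,
        position=position,
        n_sinks=config.n_sinks,
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_names() -> list[str]:
    files = resources.files("phloempart").joinpath("presets")
    return sorted(
        f.name.removesuffix(".yaml") for f in files.iterdir() if f.name.endswith(".yaml")
    )


def preset_scenario(name: str) -> ScenarioConfig:
    """Load a named preset scenario from the shipped catalogue."""
    path = resources.files("phloempart").joinpath("presets").joinpath(f"{name}.yaml")
    if not path.is_file():
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        )
    with path.open("r") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# Serialization (schema mirrors the dataclass field names)
# ---------------------------------------------------------------------------

def _boundary_to_dict(wb: WaterBoundary) -> dict:
    d = {"kind": wb.kind}
    if isinstance(wb, ImposedFlux):
        d["q"] = wb.q
    elif isinstance(wb, SoilCoupled):
        d["permeability_factor"] = wb.permeability_factor
        d["exchange_area"] = wb.exchange_area
    elif isinstance(wb, Evaporating):
        d["fraction_of_source"] = wb.fraction_of_source
    return d


def _boundary_from_dict(d: dict) -> WaterBoundary:
    kind = d.get("kind", "soil_coupled")
    rest = {k: v for k, v in d.items() if k != "kind"}
    if kind == "imposed_flux":
        return ImposedFlux(**rest)
    if kind == "soil_coupled":
        return SoilCoupled(**rest)
    if kind == "evaporating":
        return Evaporating(**rest)
    raise ValueError(f"unknown water boundary kind {kind!r}")


def config_to_dict(config: ScenarioConfig) -> dict:
    p = config.parameters
    return {
        "name": config.name,
        "hydraulic_mode": config.hydraulic_mode,
        "sp6a_factor": config.sp6a_factor,
        "vkr_r_refs": list(config.vkr_r_refs),
        "parameters": {
            "rho_water": p.rho_water, "l_r": p.l_r, "mu_x": p.mu_x,
            "a_ph": p.a_ph, "a_x": p.a_x, "k_p": p.k_p,
            "eps_p": p.eps_p, "eps_x": p.eps_x, "j_trans": p.j_trans,
            "psi_soil": p.psi_soil, "rt": p.rt, "v_suc": p.v_suc,
            "n_ph": p.n_ph, "n_x": p.n_x,
        },
        "source": {"v0": config.source.v0,
                   "evaporation_mode": config.source.evaporation_mode},
        "sinks": [
            {
                "v_max": s.v_max, "k_m": s.k_m,
                "pathway_length": s.pathway_length,
                "water_boundary": _boundary_to_dict(s.water_boundary),
            }
            for s in config.sinks
        ],
        "mesh_spec": {
            "n_source": config.mesh_spec.n_source,
            "source_element_length": config.mesh_spec.source_element_length,
            "n_pathway": config.mesh_spec.n_pathway,
            "n_sink": config.mesh_spec.n_sink,
            "sink_element_length": config.mesh_spec.sink_element_length,
        },
        "solver": vars(config.solver).copy(),
        "radial_sucrose": (None if config.radial_sucrose is None
                           else config.radial_sucrose.to_dict()),
        "scan": dict(config.scan),
    }


_TOP_KEYS = {"name", "hydraulic_mode", "sp6a_factor", "vkr_r_refs", "parameters",
             "source", "sinks", "mesh_spec", "solver", "radial_sucrose", "scan"}


def config_from_dict(data: dict) -> ScenarioConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    params = PlantParameters(**data.get("parameters", {}))
    source = SourceSpec(**data.get("source", {}))
    sinks = []
    for s in data.get("sinks", [{}, {}]):
        s = dict(s)
        wb = s.pop("water_boundary", None)
        sink = SinkSpec(**s) if wb is None else SinkSpec(
            **s, water_boundary=_boundary_from_dict(wb))
        sinks.append(sink)
    mesh_spec = MeshSpec(**data.get("mesh_spec", {}))
    solver = SolverSettings(**data.get("solver", {}))
    rs = data.get("radial_sucrose")
    radial = None if rs is None else RadialSucroseConfig.from_dict(rs)
    vkr = tuple(float(x) for x in data.get("vkr_r_refs", (7.5e12, 7.5e12)))
    return ScenarioConfig(
        parameters=params,
        source=source,
        sinks=sinks,
        mesh_spec=mesh_spec,
        hydraulic_mode=data.get("hydraulic_mode", "phloem_only"),
        radial_sucrose=radial,
        sp6a_factor=data.get("sp6a_factor", 1.0),
        vkr_r_refs=vkr,
        solver=solver,
        name=data.get("name", "custom"),
        scan=data.get("scan", {}) or {},
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Diagnostic:
    level: Literal["error", "warning"]
    message: str


def validate_config(config: ScenarioConfig) -> list[Diagnostic]:
    """Non-throwing sanity checks; presets produce an empty list."""
    out: list[Diagnostic] = []
    total_vmax = sum(s.v_max for s in config.sinks)
    if config.source.v0 >= total_vmax:
        out.append(Diagnostic(
            "warning",
            "loading rate >= combined sink capacity: no steady state exists "
            f"(v0={config.source.v0:g} mol/s, sum v_max={total_vmax:g} mol/s)",
        ))
    for i, s in enumerate(config.sinks):
        if s.k_m <= 0:
            out.append(Diagnostic("error", f"sink {i+1}: K_m must be positive"))
        if s.v_max <= 0:
            out.append(Diagnostic("error", f"sink {i+1}: v_max must be positive"))
    if config.hydraulic_mode == "xylem_coupled":
        has_supply = any(
            isinstance(s.water_boundary, SoilCoupled)
            or (isinstance(s.water_boundary, ImposedFlux) and s.water_boundary.q > 0)
            for s in config.sinks
        )
        if not has_supply and config.source.evaporation_mode == "fixed":
            out.append(Diagnostic(
                "error",
                "xylem-coupled run with fixed source transpiration but no "
                "water-supplying sink boundary: water balance cannot close",
            ))
    if config.radial_sucrose is not None:
        out.extend(
            Diagnostic(level, msg) for level, msg in config.radial_sucrose.check()
        )
    return out
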