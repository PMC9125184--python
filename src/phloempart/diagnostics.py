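"""Partitioning coefficients, conservation audits and pathway summaries.

All diagnostics are deterministic summaries of steady-state results; PC
values are reported as fractions (0-1) in data structures and files, and as
percent only in rendered text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .munch_core import SteadyStateResult

__all__ = [
    "PartitioningRecord",
    "partitioning_coefficient",
    "partitioning_record",
    "mean_pathway_summary",
    "effective_resistance",
    "mass_balance_audit",
    "water_potential_profile",
    "local_resistances",
]


@dataclass
class PartitioningRecord:
    v0: float
    v1: float
    v2: float
    pc1: float
    pc2: float
    c0_source: float
    physiological_flag: bool


def partitioning_coefficient(v1: float, v2: float) -> float:
    """PC of sink 1, ``v1 / (v1 + v2)``; NaN when both rates are zero."""
    if v1 < 0 or v2 < 0:
        raise ValueError("unloading rates must be non-negative")
    total = v1 + v2
    if total == 0:
        return float("nan")
    return v1 / total


def partitioning_record(result: SteadyStateResult) -> PartitioningRecord:
    v1, v2 = result.fluxes["v1"], result.fluxes["v2"]
    pc1 = partitioning_coefficient(v1, v2)
    c0 = float(result.fields.c_ph[result.mesh.zone == "source"].mean())
    return PartitioningRecord(
        v0=result.fluxes["v0"], v1=v1, v2=v2, pc1=pc1,
        pc2=1.0 - pc1 if not math.isnan(pc1) else float("nan"),
        c0_source=c0, physiological_flag=bool(100.0 < c0 < 2000.0))


def local_resistances(result: SteadyStateResult, branch: int = 1) -> np.ndarray:
    """Per-element axial hydraulic resistance mu*L/(k N pi a^2), MPa s/m^3."""
    m = result.mesh
    p = result.config.parameters
    idx = m.zone == f"pathway_{branch}"
    mu = result.fields.mu_ph[idx]
    return mu * m.length[idx] / (p.k_p * p.axial_area_ph)


def mean_pathway_summary(
    result: SteadyStateResult,
    mode: str = "spatial",
    branch: int = 1,
) -> dict:
    """Mean pathway concentration and resistance of one branch.

    ``spatial``: length-weighted mean of the local concentrations, and the
    sum of local resistances computed from local viscosity.  ``linear_vkr``:
    the mid-point of a linear gradient between the source-zone and
    sink-zone concentrations (the lumped model's c0 and c_sink), and the
    resistance the whole pathway would have at that single concentration.
    Because unloading drags the sink concentration well below the pathway
    values, the lumped view underestimates both mean concentration and
    resistance whenever a real spatial gradient exists.
    """
    if not result.converged:
        raise ValueError("mean_pathway_summary requires a converged result")
    m = result.mesh
    p = result.config.parameters
    idx = np.flatnonzero(m.zone == f"pathway_{branch}")
    if idx.size == 0:
        raise ValueError(f"no pathway elements for branch {branch}")
    c = result.fields.c_ph[idx]
    length = m.length[idx]
    total_l = length.sum()
    if mode == "spatial":
        mean_c = float((c * length).sum() / total_l)
        mean_r = float(local_resistances(result, branch).sum())
    elif mode == "linear_vkr":
        c_source = float(result.fields.c_ph[m.zone == "source"].mean())
        c_sink = float(result.fields.c_ph[m.zone == f"sink_{branch}"].mean())
        mean_c = (c_source + c_sink) / 2
        phi = p.v_suc * mean_c / (p.v_suc * mean_c + 1.0)
        mu = p.mu_x * math.exp(4.68 * 0.956 * phi / (1 - 0.956 * phi))
        mean_r = float(mu * total_l / (p.k_p * p.axial_area_ph))
    else:
        raise ValueError("mode must be 'spatial' or 'linear_vkr'")
    return {"mean_c": mean_c, "mean_r": mean_r}


def effective_resistance(result: SteadyStateResult, branch: int = 1) -> float:
    """Total pathway resistance of a branch with local viscosities (MPa s/m^3)."""
    return float(local_resistances(result, branch).sum())


def resistance_ratio(result: SteadyStateResult) -> float:
    """r1/r2 of the two long-distance pathways."""
    return effective_resistance(result, 1) / effective_resistance(result, 2)


def mass_balance_audit(result: SteadyStateResult, threshold: float = 1e-6) -> dict:
    """Sucrose and water closure of a steady state.

    Sucrose: |v0 - v1 - v2 - apoplast removal| / v0.  Water (xylem-coupled):
    |net boundary water| relative to the gross transpiration scale.
    """
    f = result.fluxes
    v0 = f["v0"]
    sucrose_residual = (abs(v0 - f["v1"] - f["v2"] - f["net_radial_efflux"])
                       / v0 if v0 > 0 else 0.0)
    report = {
        "sucrose_residual": sucrose_residual,
        "sucrose_pass": bool(sucrose_residual < threshold),
        "converged": bool(result.converged),
    }
    if result.config.hydraulic_mode == "xylem_coupled":
        w = result.water_fluxes
        # at steady state the phloem and xylem stores are constant, so the
        # boundary flows must cancel by themselves
        boundary_net = (sum(v for k, v in w.items() if k.startswith("sink_"))
                        - w["source_extraction"])
        scale = max(abs(w["source_extraction"]),
                    result.config.parameters.j_trans)
        water_residual = abs(boundary_net) / scale
        report["water_residual"] = water_residual
        report["water_pass"] = bool(water_residual < max(threshold, 1e-5))
    report["pass"] = bool(report["sucrose_pass"] and result.converged
                          and report.get("water_pass", True))
    return report


def water_potential_profile(result: SteadyStateResult) -> pd.DataFrame:
    """Per-element potentials with the turgor/osmotic decomposition."""
    f = result.fields
    df = pd.DataFrame({
        "position": result.mesh.position,
        "zone": result.mesh.zone,
        "branch": result.mesh.branch,
        "psi_ph": f.psi_ph,
        "p_ph": f.p_ph,
        "pi_ph": f.pi_ph,
    })
    if f.psi_x is not None:
        df["psi_x"] = f.psi_x
    return df
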