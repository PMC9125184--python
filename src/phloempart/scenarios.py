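"""Drivers for the in-silico partitioning experiments.

Each driver runs a family of steady states (or one transient), returns a
tidy :class:`pandas.DataFrame` and stamps it with provenance metadata
(preset name, configuration hash, solver tolerances) in ``DataFrame.attrs``.
Grids warm-start each solve from the previous steady state; correctness of
warm starts is guarded by cold-start spot checks in the test suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from . import lumped_models as lm
from .diagnostics import (
    effective_resistance,
    mean_pathway_summary,
    partitioning_record,
    water_potential_profile,
)
from .munch_core import MunchSystem, SteadyStateResult
from .params_geometry import (
    Evaporating,
    ScenarioConfig,
    SinkSpec,
    config_to_dict,
    preset_scenario,
)
from .radial_sucrose import net_efflux_fraction

__all__ = [
    "default_loading_grid",
    "run_single_sink_gradient",
    "run_model_comparison",
    "run_xylem_sweep",
    "run_organ_triad",
    "run_efflux_sp6a_factorial",
    "run_step_response",
    "zero_partitioning_boundary",
    "config_hash",
]


def default_loading_grid(num: int = 40) -> np.ndarray:
    """Log-spaced loading rates over the standard 0.025-25 nmol/s range."""
    return np.geomspace(0.025e-9, 25e-9, num)


def config_hash(config: ScenarioConfig) -> str:
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _stamp(df: pd.DataFrame, config: ScenarioConfig, extra: dict | None = None):
    df.attrs["preset"] = config.name
    df.attrs["config_hash"] = config_hash(config)
    df.attrs["rtol"] = config.solver.rtol
    df.attrs["ss_tol"] = config.solver.ss_tol
    if extra:
        df.attrs.update(extra)
    return df


def _grid_from_scan(config: ScenarioConfig, num: Optional[int] = None) -> np.ndarray:
    g = config.scan.get("loading_grid")
    if g is None:
        return default_loading_grid(num or 40)
    n = num or int(g.get("num", 40))
    if g.get("spacing", "log") == "log":
        return np.geomspace(float(g["start"]), float(g["stop"]), n)
    return np.linspace(float(g["start"]), float(g["stop"]), n)


# ---------------------------------------------------------------------------
# Fig.-2 style single-sink gradients
# ---------------------------------------------------------------------------

def run_single_sink_gradient(
    grid: Optional[Iterable[tuple[float, float]]] = None,
    config: Optional[ScenarioConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spatial gradients and mean-pathway summaries for a single sink.

    ``grid`` is an iterable of ``(v_load, v_max_unloading)`` pairs in mol/s;
    the default is the three standard pairs (1, 25), (10, 25), (10, 15)
    nmol/s.  Returns ``(profiles, summary)``.
    """
    config = preset_scenario("single_sink") if config is None else config
    if config.n_sinks != 1:
        raise ValueError("run_single_sink_gradient needs a single-sink config")
    if grid is None:
        pairs = config.scan.get("grid_pairs")
        grid = ([(float(a), float(b)) for a, b in pairs] if pairs
                else [(1e-9, 25e-9), (10e-9, 25e-9), (10e-9, 15e-9)])
    profiles, summaries = [], []
    state = None
    for v_load, v_max_un in grid:
        cfg = config.copy(
            source=replace(config.source, v0=v_load),
            sinks=[replace(config.sinks[0], v_max=v_max_un)])
        sys_ = MunchSystem(cfg)
        res = sys_.integrate_to_steady_state(state)
        state = res.state
        prof = res.per_element_table()
        prof["v_load"] = v_load
        prof["v_max_un"] = v_max_un
        profiles.append(prof)
        spatial = mean_pathway_summary(res, "spatial")
        linear = mean_pathway_summary(res, "linear_vkr")
        summaries.append({
            "v_load": v_load, "v_max_un": v_max_un,
            "mean_c_spatial": spatial["mean_c"],
            "mean_c_linear": linear["mean_c"],
            "mean_r_spatial": spatial["mean_r"],
            "mean_r_linear": linear["mean_r"],
            "converged": res.converged,
        })
    return (_stamp(pd.concat(profiles, ignore_index=True), config),
            _stamp(pd.DataFrame(summaries), config))


# ---------------------------------------------------------------------------
# Figs. 3-5: three-model comparison
# ---------------------------------------------------------------------------

def run_model_comparison(
    scenario: str,
    loading_grid: Optional[np.ndarray] = None,
    include_biophysical: bool = True,
) -> pd.DataFrame:
    """VK / VKR / biophysical partitioning over a loading-rate scan.

    ``scenario`` is one of the preset names ``vmax``, ``km``, ``resistance``.
    Rows with a failed model solve carry NaN for that model and continue.
    """
    config = preset_scenario(scenario)
    grid = (np.asarray(loading_grid, float) if loading_grid is not None
            else _grid_from_scan(config))
    sinks = [(s.v_max, s.k_m) for s in config.sinks]
    vk_tab = lm.lumped_scan("vk", grid[grid < sum(v for v, _ in sinks)],
                            sinks, config.vkr_r_refs)
    vkr_tab = lm.lumped_scan("vkr", grid[grid < sum(v for v, _ in sinks)],
                             sinks, config.vkr_r_refs)
    rows = []
    state = None
    for i, v0 in enumerate(grid):
        row = {"v0": v0}
        for tab, tag in ((vk_tab, "vk"), (vkr_tab, "vkr")):
            if i < len(tab) and tab.loc[i, "converged"]:
                row[f"pc1_{tag}"] = tab.loc[i, "pc1"]
                row[f"c0_{tag}"] = tab.loc[i, "c0"]
                row[f"c1_{tag}"] = tab.loc[i, "c1"]
                row[f"c2_{tag}"] = tab.loc[i, "c2"]
                row[f"physiological_{tag}"] = tab.loc[i, "physiological_flag"]
                if tag == "vkr":
                    row["r_ratio_vkr"] = tab.loc[i, "r1_eff"] / tab.loc[i, "r2_eff"]
            else:
                row[f"pc1_{tag}"] = np.nan
        if include_biophysical:
            try:
                cfg = config.copy(source=replace(config.source, v0=v0))
                sys_ = MunchSystem(cfg)
                res = sys_.integrate_to_steady_state(state)
                state = res.state
                rec = partitioning_record(res)
                row.update(
                    pc1_bio=rec.pc1, c0_bio=rec.c0_source,
                    c1_bio=float(res.fields.c_ph[res.mesh.zone == "sink_1"].mean()),
                    c2_bio=float(res.fields.c_ph[res.mesh.zone == "sink_2"].mean()),
                    physiological_bio=rec.physiological_flag,
                    r_ratio_bio=(effective_resistance(res, 1)
                                 / effective_resistance(res, 2)),
                    converged_bio=res.converged,
                )
            except Exception as exc:  # keep scanning on per-row failure
                row.update(pc1_bio=np.nan, converged_bio=False,
                           error=str(exc))
        rows.append(row)
    return _stamp(pd.DataFrame(rows), config, {"scenario": scenario})


# ---------------------------------------------------------------------------
# Fig. 6: xylem boundary sweep
# ---------------------------------------------------------------------------

def run_xylem_sweep(
    sink1_flux_grid: Optional[np.ndarray] = None,
    loading_rates: Optional[Iterable[float]] = None,
    with_profiles: bool = False,
):
    """PC1 as a function of imposed sink-1 water flux.

    Sink 2 keeps a constant uptake of 2e-8 m^3/s; the source evaporates the
    net sum.  Returns a tidy frame (and endpoint potential profiles when
    ``with_profiles``).
    """
    config = preset_scenario("xylem_sweep")
    scan = config.scan
    if sink1_flux_grid is None:
        g = scan.get("sink1_flux_grid", {})
        sink1_flux_grid = np.linspace(float(g.get("start", -1e-8)),
                                      float(g.get("stop", 2e-8)),
                                      int(g.get("num", 7)))
    else:
        sink1_flux_grid = np.asarray(sink1_flux_grid, float)
    if loading_rates is None:
        loading_rates = [float(x) for x in
                         scan.get("loading_rates", [2.5e-9, 12.5e-9, 22.5e-9])]
    rows, profiles = [], {}
    for v0 in loading_rates:
        state = None
        # sweep from the symmetric end toward evaporation for stable warm starts
        for q1 in sink1_flux_grid[::-1]:
            sink1 = replace(config.sinks[0],
                            water_boundary=replace(
                                config.sinks[0].water_boundary, q=float(q1)))
            cfg = config.copy(source=replace(config.source, v0=v0),
                              sinks=[sink1, config.sinks[1]])
            res = MunchSystem(cfg).integrate_to_steady_state(state)
            state = res.state
            rows.append({"v0": v0, "sink1_flux": q1, "pc1": res.pc1,
                         "converged": res.converged})
            if with_profiles and q1 in (sink1_flux_grid[0], sink1_flux_grid[-1]):
                profiles[(v0, float(q1))] = water_potential_profile(res)
    df = _stamp(pd.DataFrame(rows).sort_values(["v0", "sink1_flux"],
                                               ignore_index=True), config)
    return (df, profiles) if with_profiles else df


# ---------------------------------------------------------------------------
# Fig. 7: organ triad
# ---------------------------------------------------------------------------

ORGAN_CASES = ("root_root", "tuber_root", "leaf_root")


def run_organ_triad(
    loading_grid: Optional[np.ndarray] = None,
    with_profiles: bool = False,
):
    """PC1 per organ pairing (root-root, tuber-root, leaf-root) per loading."""
    rows, profiles = [], {}
    for case in ORGAN_CASES:
        config = preset_scenario(case)
        grid = (np.asarray(loading_grid, float) if loading_grid is not None
                else _grid_from_scan(config))
        state = None
        for v0 in grid:
            cfg = config.copy(source=replace(config.source, v0=v0))
            res = MunchSystem(cfg).integrate_to_steady_state(state)
            state = res.state
            rows.append({"case": case, "v0": v0, "pc1": res.pc1,
                         "converged": res.converged})
            if with_profiles:
                profiles[(case, float(v0))] = water_potential_profile(res)
    df = pd.DataFrame(rows)
    df.attrs["cases"] = list(ORGAN_CASES)
    return (df, profiles) if with_profiles else df


# ---------------------------------------------------------------------------
# Fig. 8: length x xylem x efflux x SP6A factorial
# ---------------------------------------------------------------------------

def _factorial_config(
    base: ScenarioConfig,
    length_diff: bool,
    xylem_diff: bool,
    efflux: bool,
    sp6a: bool,
    tuber_vmax_high: bool,
    v0: float,
) -> ScenarioConfig:
    sinks = [replace(s) for s in base.sinks]
    if length_diff:
        sinks[0] = replace(sinks[0], pathway_length=0.1)
        sinks[1] = replace(sinks[1], pathway_length=0.3)
    if xylem_diff:
        sinks[0] = replace(sinks[0], water_boundary=Evaporating(0.1))
    extra_v0 = 0.0
    if tuber_vmax_high:
        high = float(base.scan.get("tuber_v_max_increased", 15e-9))
        extra_v0 = high - sinks[1].v_max
        sinks[1] = replace(sinks[1], v_max=high)
    rs_cfg = base.radial_sucrose
    if rs_cfg is not None:
        rs_cfg = rs_cfg.copy(
            zones=("pathway_1", "pathway_2") if efflux else ())
    elif efflux:
        raise ValueError("factorial base config lacks a radial_sucrose section")
    return base.copy(
        sinks=sinks,
        source=replace(base.source, v0=v0 + extra_v0),
        radial_sucrose=rs_cfg,
        sp6a_factor=0.6 if sp6a else 1.0,
    )


def run_efflux_sp6a_factorial(
    loading_grid: Optional[np.ndarray] = None,
    conditions: Optional[Iterable[dict]] = None,
) -> pd.DataFrame:
    """Partitioning toward roots/tubers across the factorial conditions.

    Conditions are dicts with boolean keys ``length_diff``, ``xylem_diff``,
    ``efflux``, ``sp6a``, ``tuber_vmax_high``; the default set covers the
    individual and combined pathway effects, the efflux aggravation, and the
    two SP6A effects.  A tuber sink-strength increase is accompanied by an
    equal source-strength increase (sink-source feedback), so ``v0`` records
    the base loading rate and ``v0_effective`` the applied one.
    """
    base = preset_scenario("efflux_factorial")
    grid = (np.asarray(loading_grid, float) if loading_grid is not None
            else _grid_from_scan(base))
    if conditions is None:
        conditions = [
            dict(length_diff=True, xylem_diff=False, efflux=False, sp6a=False,
                 tuber_vmax_high=False),
            dict(length_diff=False, xylem_diff=True, efflux=False, sp6a=False,
                 tuber_vmax_high=False),
            dict(length_diff=True, xylem_diff=True, efflux=False, sp6a=False,
                 tuber_vmax_high=False),
            dict(length_diff=True, xylem_diff=True, efflux=True, sp6a=False,
                 tuber_vmax_high=False),
            dict(length_diff=True, xylem_diff=True, efflux=True, sp6a=True,
                 tuber_vmax_high=False),
            dict(length_diff=True, xylem_diff=True, efflux=True, sp6a=False,
                 tuber_vmax_high=True),
            dict(length_diff=True, xylem_diff=True, efflux=True, sp6a=True,
                 tuber_vmax_high=True),
        ]
    rows = []
    for cond in conditions:
        state = None
        for v0 in grid:
            cfg = _factorial_config(base, v0=float(v0), **cond)
            try:
                res = MunchSystem(cfg).integrate_to_steady_state(state)
                state = res.state
                rows.append({
                    **cond, "v0": v0, "v0_effective": cfg.source.v0,
                    "pc_tuber": res.pc2, "pc_leaf": res.pc1,
                    "net_efflux_fraction": net_efflux_fraction(res),
                    "converged": res.converged,
                })
            except Exception as exc:
                rows.append({**cond, "v0": v0, "pc_tuber": np.nan,
                             "converged": False, "error": str(exc)})
    return _stamp(pd.DataFrame(rows), base)


def zero_partitioning_boundary(
    table: pd.DataFrame, threshold: float = 0.01
) -> pd.DataFrame:
    """Lowest loading rate at which the tuber receives a visible share.

    Reported against both the total and the per-sink unloading capacity is a
    presentation concern; this returns the boundary in mol/s per condition.
    """
    keys = ["length_diff", "xylem_diff", "efflux", "sp6a", "tuber_vmax_high"]
    out = []
    for flags, grp in table.groupby(keys):
        grp = grp.sort_values("v0")
        above = grp[grp["pc_tuber"] > threshold]
        out.append(dict(zip(keys, flags)) | {
            "v0_boundary": float(above["v0"].iloc[0]) if len(above) else np.nan,
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Step response
# ---------------------------------------------------------------------------

def run_step_response(
    config: Optional[ScenarioConfig] = None,
    vmax_factor: float = 0.5,
    sink: int = 1,
    t_end: float = 6 * 3600.0,
    n_eval: int = 241,
):
    """Transient partitioning after an instantaneous sink v_max step.

    The pre-step configuration is integrated to steady state, the chosen
    sink's v_max is multiplied by ``vmax_factor`` and the transient PC1(t)
    is recorded.  Returns ``(series, info)`` where ``info`` carries ``t_90``
    (time to cover 90% of the PC1 shift) and the independently solved
    post-step steady state.

    The default scenario is the symmetric two-sink system at a low,
    non-saturating loading rate (1 nmol/s), the regime in which pathway
    effects are relevant and transport itself sets the adaptation timescale.
    """
    if config is None:
        config = ScenarioConfig(name="step_response_default")
        config = config.copy(source=replace(config.source, v0=1e-9))
    sys_pre = MunchSystem(config)
    res_pre = sys_pre.integrate_to_steady_state()
    if not res_pre.converged:
        raise RuntimeError("pre-step baseline did not converge")

    sinks = [replace(s) for s in config.sinks]
    sinks[sink - 1] = replace(sinks[sink - 1],
                              v_max=sinks[sink - 1].v_max * vmax_factor)
    post = config.copy(sinks=sinks)
    sys_post = MunchSystem(post)

    t_eval = np.linspace(0.0, t_end, n_eval)
    times, states = sys_post.integrate_transient(res_pre.state, t_eval)
    pc = []
    for st in states:
        f = sys_post.derived_fields(st)
        unload = sys_post.unloading_flux(f)
        v = [float(unload[idx].sum()) for idx in sys_post.sink_idx]
        pc.append(v[0] / (v[0] + v[1]))
    series = pd.DataFrame({"t": times, "pc1": pc})

    res_post = sys_post.integrate_to_steady_state()
    pc_pre, pc_post = res_pre.pc1, res_post.pc1
    # The v_max step changes the unloading rates instantaneously (PC1 jumps
    # at t = 0+); the adaptation of interest is the slow transport-driven
    # relaxation from that immediate post-step partitioning to the new
    # steady state.
    pc_jump = float(pc[0])
    target = pc_jump + 0.9 * (pc_post - pc_jump)
    shift = np.asarray(pc) - pc_jump
    covered = np.abs(shift) >= 0.9 * abs(pc_post - pc_jump)
    t_90 = float(times[np.argmax(covered)]) if covered.any() else float("nan")
    info = {
        "pc1_pre": pc_pre,
        "pc1_jump": pc_jump,
        "pc1_post_transient": float(pc[-1]),
        "pc1_post_steady": pc_post,
        "t_90": t_90,
        "target_pc1": target,
    }
    return _stamp(series, config), info
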