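"""Spatially explicit Münch pressure-flow model on the branched mesh.

Each element carries phloem water mass ``W_Ph`` (g) and sucrose ``S_Ph``
(mol); in xylem-coupled mode additionally xylem water ``W_X`` (g), and with
radial sucrose exchange an apoplast sucrose pool ``S_apo`` (mol) on the
long-distance pathway elements.

Turgor follows linear elasticity ``P = eps * (V - V_ref)/V_ref`` in both
conduit systems (the xylem is allowed negative pressure, i.e. tension, per
the cohesion-tension picture), osmotic potential is van 't Hoff
``Pi = -RT c``, sap viscosity depends on the sucrose volume fraction, and
axial flow is Hagen-Poiseuille down the turgor gradient.  Radial water
exchange is driven by the water-potential difference between phloem and
xylem (or a zero-potential reservoir in phloem-only mode).  Sucrose is
advected axially at the upwind element's concentration; sinks unload via
Michaelis-Menten kinetics distributed over their unloading zone.

Steady states are found by stiff implicit integration (BDF with a sparse
Jacobian pattern) until the scaled time-derivative norm falls below a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from . import radial_sucrose as rs
from .params_geometry import (
    Evaporating,
    ImposedFlux,
    Mesh,
    ScenarioConfig,
    SoilCoupled,
    build_mesh,
)

__all__ = [
    "StateVector",
    "DerivedFields",
    "SteadyStateResult",
    "MunchSystem",
    "initial_state",
    "derived_fields",
    "axial_water_flux",
    "radial_water_flux",
    "boundary_water_fluxes",
    "unloading_flux",
    "loading_flux",
    "time_derivatives",
    "integrate_to_steady_state",
    "StateCorruptionError",
]

#: Cap on the sucrose volume fraction entering the viscosity law; beyond it
#: the exponential is evaluated at the cap to keep the RHS finite during
#: transients (phi -> 1/0.956 would diverge).
PHI_CAP = 0.80


class StateCorruptionError(RuntimeError):
    """Nonpositive water volume or non-finite derivative during integration."""


@dataclass
class StateVector:
    """Per-element conserved quantities."""

    w_ph: np.ndarray                  # g
    s_ph: np.ndarray                  # mol
    w_x: Optional[np.ndarray] = None  # g, xylem-coupled mode
    s_apo: Optional[np.ndarray] = None  # mol, on exchanging elements only

    def copy(self) -> "StateVector":
        return StateVector(
            self.w_ph.copy(), self.s_ph.copy(),
            None if self.w_x is None else self.w_x.copy(),
            None if self.s_apo is None else self.s_apo.copy())


@dataclass
class DerivedFields:
    """Per-element fields derived from the state."""

    c_ph: np.ndarray       # mol/m^3
    p_ph: np.ndarray       # MPa
    pi_ph: np.ndarray      # MPa, <= 0
    mu_ph: np.ndarray      # MPa s
    psi_ph: np.ndarray     # MPa, = p_ph + pi_ph
    p_x: Optional[np.ndarray] = None
    psi_x: Optional[np.ndarray] = None
    c_apo: Optional[np.ndarray] = None  # mol/m^3 on exchanging elements


@dataclass
class SteadyStateResult:
    """Converged (or best-effort) steady state of one scenario."""

    config: ScenarioConfig
    mesh: Mesh
    state: StateVector
    fields: DerivedFields
    fluxes: dict                   # v0, v1, v2, net_radial_efflux (mol/s)
    water_fluxes: dict             # per-boundary g/s
    pc1: float
    converged: bool
    residual: float                # max scaled |dy/dt| (s^-1)
    t_final: float
    n_steps: int = 0

    @property
    def pc2(self) -> float:
        return 1.0 - self.pc1

    def per_element_table(self) -> pd.DataFrame:
        f = self.fields
        df = pd.DataFrame({
            "position": self.mesh.position,
            "zone": self.mesh.zone,
            "branch": self.mesh.branch,
            "c_ph": f.c_ph,
            "p_ph": f.p_ph,
            "pi_ph": f.pi_ph,
            "psi_ph": f.psi_ph,
            "mu_ph": f.mu_ph,
        })
        if f.psi_x is not None:
            df["psi_x"] = f.psi_x
            df["p_x"] = f.p_x
        return df

    def summary(self) -> dict:
        return {
            "name": self.config.name,
            "v0": self.fluxes["v0"],
            "v1": self.fluxes["v1"],
            "v2": self.fluxes.get("v2"),
            "net_radial_efflux": self.fluxes["net_radial_efflux"],
            "pc1": self.pc1,
            "converged": self.converged,
            "residual": self.residual,
            "t_final": self.t_final,
        }


class MunchSystem:
    """Assembled right-hand side and integrator for one scenario."""

    def __init__(self, config: ScenarioConfig, mesh: Optional[Mesh] = None):
        self.config = config
        self.mesh = build_mesh(config) if mesh is None else mesh
        self.params = config.parameters
        self.coupled = config.hydraulic_mode == "xylem_coupled"
        self.rs_config = config.radial_sucrose
        m, p = self.mesh, self.params

        self.n = m.n_state
        self.source_idx = np.flatnonzero(m.zone == "source")
        self.sink_idx = [
            np.flatnonzero(m.zone == f"sink_{i+1}") for i in range(m.n_sinks)
        ]
        self.pathway_idx = [
            np.flatnonzero(m.zone == f"pathway_{i+1}") for i in range(m.n_sinks)
        ]
        if self.rs_config is not None:
            masks = [m.zone == z for z in self.rs_config.zones]
            self.apo_idx = np.flatnonzero(np.logical_or.reduce(masks))
        else:
            self.apo_idx = np.array([], dtype=int)
        self.n_apo = self.apo_idx.size

        # geometry shortcuts
        self.a_ax_ph = p.axial_area_ph
        self.a_ax_x = p.axial_area_x
        self.g_edge_ph = self.a_ax_ph * p.k_p / m.edge_length  # / mu -> m^3/(MPa s)
        self.g_edge_x = self.a_ax_x * p.k_x / (p.mu_x * m.edge_length)
        self.v_apo = (None if self.rs_config is None else
                      self.rs_config.apoplast_volume_fraction
                      * m.v_ref_ph[self.apo_idx])

        # state layout and scaling (the concentration scale keeps a floor so
        # that a zero initial concentration still yields a finite scaling)
        c_init = max(config.solver.initial_concentration, 1.0)
        blocks = [("w_ph", self.n, p.rho_water * m.v_ref_ph),
                  ("s_ph", self.n, c_init * m.v_ref_ph)]
        if self.coupled:
            blocks.append(("w_x", self.n, p.rho_water * m.v_ref_x))
        if self.n_apo:
            blocks.append(("s_apo", self.n_apo, c_init * self.v_apo))
        self.block_names = [b[0] for b in blocks]
        self.block_slices = {}
        off = 0
        scales = []
        for name, size, scale in blocks:
            self.block_slices[name] = slice(off, off + size)
            scales.append(np.broadcast_to(np.asarray(scale, float), (size,)))
            off += size
        self.n_state_vars = off
        self.scale = np.concatenate(scales)

    # -- state packing ----------------------------------------------------

    def pack(self, state: StateVector) -> np.ndarray:
        y = np.empty(self.n_state_vars)
        y[self.block_slices["w_ph"]] = state.w_ph
        y[self.block_slices["s_ph"]] = state.s_ph
        if self.coupled:
            y[self.block_slices["w_x"]] = state.w_x
        if self.n_apo:
            y[self.block_slices["s_apo"]] = state.s_apo
        return y

    def unpack(self, y: np.ndarray) -> StateVector:
        return StateVector(
            w_ph=y[self.block_slices["w_ph"]],
            s_ph=y[self.block_slices["s_ph"]],
            w_x=y[self.block_slices["w_x"]] if self.coupled else None,
            s_apo=y[self.block_slices["s_apo"]] if self.n_apo else None)

    def initial_state(self) -> StateVector:
        """Uniform concentration, volumes at reference, xylem at psi_soil."""
        m, p = self.mesh, self.params
        c0 = self.config.solver.initial_concentration
        w_ph = p.rho_water * m.v_ref_ph
        s_ph = c0 * m.v_ref_ph
        w_x = None
        if self.coupled:
            w_x = p.rho_water * m.v_ref_x * (1.0 + p.psi_soil / p.eps_x)
        s_apo = np.zeros(self.n_apo) if self.n_apo else None
        return StateVector(w_ph=w_ph, s_ph=s_ph, w_x=w_x, s_apo=s_apo)

    # -- physics ----------------------------------------------------------

    def derived_fields(self, state: StateVector, check: bool = True) -> DerivedFields:
        m, p = self.mesh, self.params
        v_ph = state.w_ph / p.rho_water
        if check and np.any(v_ph <= 0):
            bad = int(np.argmin(v_ph))
            raise StateCorruptionError(
                f"nonpositive phloem water volume at element {bad}")
        c = state.s_ph / v_ph
        p_ph = p.eps_p * (v_ph - m.v_ref_ph) / m.v_ref_ph
        pi_ph = -p.rt * c
        vs = p.v_suc * state.s_ph
        phi = np.clip(vs / (vs + v_ph), 0.0, PHI_CAP)
        mu_ph = p.mu_x * np.exp(4.68 * 0.956 * phi / (1.0 - 0.956 * phi))
        psi_ph = p_ph + pi_ph
        p_x = psi_x = None
        if self.coupled:
            v_x = state.w_x / p.rho_water
            if check and np.any(v_x <= 0):
                bad = int(np.argmin(v_x))
                raise StateCorruptionError(
                    f"nonpositive xylem water volume at element {bad}")
            p_x = p.eps_x * (v_x - m.v_ref_x) / m.v_ref_x
            psi_x = p_x  # pure water: no osmotic term in the xylem
        c_apo = None
        if self.n_apo:
            c_apo = state.s_apo / self.v_apo
        return DerivedFields(c_ph=c, p_ph=p_ph, pi_ph=pi_ph, mu_ph=mu_ph,
                             psi_ph=psi_ph, p_x=p_x, psi_x=psi_x, c_apo=c_apo)

    def axial_water_flux(self, fields: DerivedFields):
        """Volumetric phloem flow per edge (m^3/s), positive away from source."""
        m = self.mesh
        mu_e = 0.5 * (fields.mu_ph[m.edges_parent] + fields.mu_ph[m.edges_child])
        dp = fields.p_ph[m.edges_parent] - fields.p_ph[m.edges_child]
        return self.g_edge_ph / mu_e * dp

    def axial_xylem_flux(self, fields: DerivedFields):
        m = self.mesh
        dp = fields.p_x[m.edges_parent] - fields.p_x[m.edges_child]
        return self.g_edge_x * dp

    def radial_water_flux(self, fields: DerivedFields):
        """Volumetric radial flow into the phloem per element (m^3/s)."""
        m, p = self.mesh, self.params
        outside = fields.psi_x if self.coupled else 0.0
        return p.l_r * m.a_rad * (outside - fields.psi_ph)

    def boundary_water_fluxes(self, fields: DerivedFields):
        """Xylem boundary water exchange, g/s per element (positive into plant).

        Returns ``(per_element, per_sink_totals, source_total)``.
        """
        m, p = self.mesh, self.params
        out = np.zeros(self.n)
        sink_totals = []
        for i, sink in enumerate(self.config.sinks):
            idx = self.sink_idx[i]
            wb = sink.water_boundary
            if isinstance(wb, ImposedFlux):
                j = np.full(idx.size, p.rho_water * wb.q / idx.size)
            elif isinstance(wb, SoilCoupled):
                area = wb.exchange_area / idx.size
                j = (p.rho_water * wb.permeability_factor * p.l_r * area
                     * (p.psi_soil - fields.psi_x[idx]))
            elif isinstance(wb, Evaporating):
                j = np.full(idx.size,
                            -wb.fraction_of_source * p.j_trans / idx.size)
            else:  # pragma: no cover
                raise TypeError(f"unknown water boundary {wb!r}")
            out[idx] += j
            sink_totals.append(float(j.sum()))
        if self.config.source.evaporation_mode == "balance_sinks":
            extraction = sum(sink_totals)
        else:
            extraction = p.j_trans
        out[self.source_idx] -= extraction / self.source_idx.size
        return out, sink_totals, extraction

    def unloading_flux(self, fields: DerivedFields):
        """Per-element unloading (mol/s); Michaelis-Menten on local c."""
        out = np.zeros(self.n)
        for i, sink in enumerate(self.config.sinks):
            idx = self.sink_idx[i]
            c = fields.c_ph[idx]
            out[idx] = (sink.v_max / idx.size) * c / (sink.k_m + c)
        return out

    def loading_flux(self):
        """Per-element loading (mol/s), uniform over the source zone."""
        out = np.zeros(self.n)
        out[self.source_idx] = self.config.source.v0 / self.source_idx.size
        return out

    # -- assembled RHS ----------------------------------------------------

    def time_derivatives(self, state: StateVector) -> StateVector:
        """Mass balances; returns d(state)/dt in g/s and mol/s."""
        m, p = self.mesh, self.params
        f = self.derived_fields(state)

        q_ph = self.axial_water_flux(f)          # m^3/s per edge
        c_up = np.where(q_ph >= 0,
                        f.c_ph[m.edges_parent], f.c_ph[m.edges_child])
        j_s_ax = q_ph * c_up                     # mol/s per edge
        j_w_ax = p.rho_water * q_ph              # g/s per edge

        dw = np.zeros(self.n)
        ds = np.zeros(self.n)
        np.add.at(dw, m.edges_child, j_w_ax)
        np.add.at(dw, m.edges_parent, -j_w_ax)
        np.add.at(ds, m.edges_child, j_s_ax)
        np.add.at(ds, m.edges_parent, -j_s_ax)

        q_rad = self.radial_water_flux(f)        # m^3/s, into phloem
        dw += p.rho_water * q_rad

        ds += self.loading_flux()
        ds -= self.unloading_flux(f)

        dwx = None
        if self.coupled:
            dwx = np.zeros(self.n)
            qx = self.axial_xylem_flux(f)
            jx = p.rho_water * qx
            np.add.at(dwx, m.edges_child, jx)
            np.add.at(dwx, m.edges_parent, -jx)
            dwx -= p.rho_water * q_rad
            boundary, _, _ = self.boundary_water_fluxes(f)
            dwx += boundary

        dsapo = None
        if self.n_apo:
            ds_apo, j_s_rad = rs.apoplast_derivative(
                f.c_ph[self.apo_idx], state.s_apo,
                self.mesh.v_ref_ph[self.apo_idx], self.rs_config,
                self.config.sp6a_factor)
            dsapo = ds_apo
            ds[self.apo_idx] += j_s_rad

        return StateVector(w_ph=dw, s_ph=ds, w_x=dwx, s_apo=dsapo)

    def rhs(self, t: float, y_scaled: np.ndarray) -> np.ndarray:
        state = self.unpack(y_scaled * self.scale)
        d = self.time_derivatives(state)
        dy = self.pack(d) / self.scale
        if not np.all(np.isfinite(dy)):
            bad = int(np.flatnonzero(~np.isfinite(dy))[0])
            raise StateCorruptionError(
                f"non-finite time derivative in state component {bad}")
        return dy

    # -- Jacobian sparsity ------------------------------------------------

    def jacobian_sparsity(self) -> sparse.csr_matrix:
        n, m = self.n, self.mesh
        adj = sparse.identity(n, format="lil")
        for a, b in zip(m.edges_parent, m.edges_child):
            adj[a, b] = 1
            adj[b, a] = 1
        adj = adj.tocsr()
        eye = sparse.identity(n, format="csr")
        names = self.block_names
        blocks = {}

        def put(r, c, mat):
            blocks[(names.index(r), names.index(c))] = mat

        put("w_ph", "w_ph", adj)
        put("w_ph", "s_ph", adj)
        put("s_ph", "w_ph", adj)
        put("s_ph", "s_ph", adj)
        if self.coupled:
            put("w_ph", "w_x", eye)
            put("w_x", "w_ph", eye)
            put("w_x", "s_ph", eye)
            put("w_x", "w_x", adj)
        if self.n_apo:
            sel = sparse.csr_matrix(
                (np.ones(self.n_apo), (np.arange(self.n_apo), self.apo_idx)),
                shape=(self.n_apo, n))
            put("s_ph", "s_apo", sel.T)
            put("s_apo", "w_ph", sel)
            put("s_apo", "s_ph", sel)
            put("s_apo", "s_apo", sparse.identity(self.n_apo, format="csr"))
        sizes = [self.block_slices[b].stop - self.block_slices[b].start
                 for b in names]
        grid = [[blocks.get((i, j), sparse.csr_matrix((sizes[i], sizes[j])))
                 for j in range(len(names))] for i in range(len(names))]
        return sparse.bmat(grid, format="csr")

    # -- steady state -----------------------------------------------------

    def steady_state_residual(self, y_scaled: np.ndarray) -> float:
        dy = self.rhs(0.0, y_scaled)
        tau = self.config.solver.ss_tau
        denom = np.maximum(np.abs(y_scaled), 1e-3)
        return float(np.max(np.abs(dy) * tau / denom))

    def _state_valid(self, y_scaled: np.ndarray) -> bool:
        if not np.all(np.isfinite(y_scaled)):
            return False
        state = self.unpack(y_scaled * self.scale)
        if np.any(state.w_ph <= 0):
            return False
        if self.coupled and np.any(state.w_x <= 0):
            return False
        if np.any(state.s_ph < -1e-9 * self.scale[self.block_slices["s_ph"]]):
            return False
        return True

    def _newton_polish(self, y: np.ndarray, max_iter: int = 12):
        """Damped finite-difference Newton refinement of a near-steady state.

        The Jacobian is formed densely by forward differences; ``lstsq``
        tolerates the rank deficiency that arises when a boundary mode
        conserves total water exactly (the residual then lies in the range
        of the Jacobian, so the minimum-norm step is still a Newton step).
        """
        tol = self.config.solver.ss_tol
        n = y.size
        y = y.copy()
        f = self.rhs(0.0, y)
        for _ in range(max_iter):
            res = self.steady_state_residual(y)
            if res < tol:
                return y, True
            jac = np.empty((n, n))
            h = 1e-8 * np.maximum(np.abs(y), 1e-4)
            for j in range(n):
                yj = y.copy()
                yj[j] += h[j]
                try:
                    jac[:, j] = (self.rhs(0.0, yj) - f) / h[j]
                except StateCorruptionError:
                    yj[j] = y[j] - h[j]
                    jac[:, j] = (f - self.rhs(0.0, yj)) / h[j]
            step = np.linalg.lstsq(jac, -f, rcond=None)[0]
            lam, improved = 1.0, False
            f_norm = np.max(np.abs(f))
            while lam > 1e-4:
                y_try = y + lam * step
                if self._state_valid(y_try):
                    try:
                        f_try = self.rhs(0.0, y_try)
                    except StateCorruptionError:
                        lam /= 2
                        continue
                    if np.max(np.abs(f_try)) < f_norm:
                        y, f = y_try, f_try
                        improved = True
                        break
                lam /= 2
            if not improved:
                return y, self.steady_state_residual(y) < tol
        return y, self.steady_state_residual(y) < tol

    def integrate_to_steady_state(
        self,
        state0: Optional[StateVector] = None,
        t_checkpoints: Optional[list[float]] = None,
    ) -> SteadyStateResult:
        solver = self.config.solver
        if state0 is None:
            state0 = self.initial_state()
        y = self.pack(state0) / self.scale
        if t_checkpoints is None:
            t_checkpoints = [2e3, 2e4, 2e5, 1e6, 3e6, 1e7]
        t_checkpoints = [t for t in t_checkpoints if t <= solver.t_max]
        if not t_checkpoints or t_checkpoints[-1] < solver.t_max:
            t_checkpoints = list(t_checkpoints) + [solver.t_max]

        sparsity = self.jacobian_sparsity()
        t_prev = 0.0
        converged = False
        n_steps = 0
        residual = np.inf
        for t_next in t_checkpoints:
            sol = solve_ivp(
                self.rhs, (t_prev, t_next), y, method="BDF",
                rtol=solver.rtol, atol=solver.atol,
                jac_sparsity=sparsity, dense_output=False)
            if not sol.success:
                raise StateCorruptionError(
                    f"stiff integration failed at t={sol.t[-1]:.3g} s: "
                    f"{sol.message}")
            y = sol.y[:, -1]
            n_steps += sol.t.size
            t_prev = t_next
            residual = self.steady_state_residual(y)
            if residual < solver.ss_tol:
                converged = True
                break
            if solver.newton_polish and residual < 1e-2:
                y_pol, ok = self._newton_polish(y)
                # accept only a refinement of the same steady state, not a
                # jump to a different root
                drift = np.max(np.abs(y_pol - y) / np.maximum(np.abs(y), 1.0))
                if ok and drift < 0.5:
                    y = y_pol
                    residual = self.steady_state_residual(y)
                    converged = True
                    break
        return self._build_result(y, converged, residual, t_prev, n_steps)

    def _build_result(self, y_scaled, converged, residual, t_final,
                      n_steps) -> SteadyStateResult:
        state = self.unpack(y_scaled * self.scale).copy()
        f = self.derived_fields(state)
        unload = self.unloading_flux(f)
        v_sinks = [float(unload[idx].sum()) for idx in self.sink_idx]
        v0 = self.config.source.v0
        removal = 0.0
        if self.n_apo:
            c_apo = state.s_apo / self.v_apo
            removal = float(
                (self.rs_config.apoplast_removal_rate * c_apo
                 * self.mesh.v_ref_ph[self.apo_idx]).sum())
        fluxes = {"v0": v0, "v1": v_sinks[0],
                  "v2": v_sinks[1] if len(v_sinks) > 1 else 0.0,
                  "net_radial_efflux": removal}
        water = {}
        if self.coupled:
            _, sink_totals, extraction = self.boundary_water_fluxes(f)
            water["source_extraction"] = extraction
            for i, tot in enumerate(sink_totals):
                water[f"sink_{i+1}_boundary"] = tot
        q_rad = self.radial_water_flux(f)
        water["radial_net_phloem"] = float(
            (self.params.rho_water * q_rad).sum())
        total_unload = sum(v_sinks)
        pc1 = v_sinks[0] / total_unload if total_unload > 0 else float("nan")
        return SteadyStateResult(
            config=self.config, mesh=self.mesh, state=state, fields=f,
            fluxes=fluxes, water_fluxes=water, pc1=pc1, converged=converged,
            residual=residual, t_final=t_final, n_steps=n_steps)

    def integrate_transient(
        self,
        state0: StateVector,
        t_eval: np.ndarray,
    ):
        """Integrate and return ``(t_eval, states)`` for transient analyses."""
        solver = self.config.solver
        y0 = self.pack(state0) / self.scale
        sol = solve_ivp(
            self.rhs, (0.0, float(t_eval[-1])), y0, method="BDF",
            rtol=solver.rtol, atol=solver.atol,
            jac_sparsity=self.jacobian_sparsity(), t_eval=t_eval)
        if not sol.success:
            raise StateCorruptionError(f"transient integration failed: {sol.message}")
        states = [self.unpack(sol.y[:, k] * self.scale).copy()
                  for k in range(sol.t.size)]
        return sol.t, states


# ---------------------------------------------------------------------------
# Module-level operations (thin wrappers over MunchSystem)
# ---------------------------------------------------------------------------

def initial_state(config: ScenarioConfig, mesh: Optional[Mesh] = None) -> StateVector:
    return MunchSystem(config, mesh).initial_state()


def derived_fields(state: StateVector, mesh: Mesh,
                   config: ScenarioConfig) -> DerivedFields:
    return MunchSystem(config, mesh).derived_fields(state)


def axial_water_flux(fields: DerivedFields, mesh: Mesh,
                     config: ScenarioConfig, which: str = "phloem") -> np.ndarray:
    """Axial water flow per edge in g/s (positive parent -> child)."""
    sys_ = MunchSystem(config, mesh)
    q = (sys_.axial_water_flux(fields) if which == "phloem"
         else sys_.axial_xylem_flux(fields))
    return config.parameters.rho_water * q


def radial_water_flux(fields: DerivedFields, mesh: Mesh,
                      config: ScenarioConfig) -> np.ndarray:
    """Radial water flow into the phloem per element, g/s."""
    sys_ = MunchSystem(config, mesh)
    return config.parameters.rho_water * sys_.radial_water_flux(fields)


def boundary_water_fluxes(fields: DerivedFields, mesh: Mesh,
                          config: ScenarioConfig) -> np.ndarray:
    return MunchSystem(config, mesh).boundary_water_fluxes(fields)[0]


def unloading_flux(fields: DerivedFields, mesh: Mesh,
                   config: ScenarioConfig) -> np.ndarray:
    return MunchSystem(config, mesh).unloading_flux(fields)


def loading_flux(config: ScenarioConfig, mesh: Optional[Mesh] = None) -> np.ndarray:
    return MunchSystem(config, mesh).loading_flux()


def time_derivatives(state: StateVector, mesh: Mesh,
                     config: ScenarioConfig) -> StateVector:
    return MunchSystem(config, mesh).time_derivatives(state)


def integrate_to_steady_state(
    config: ScenarioConfig,
    state0: Optional[StateVector] = None,
    mesh: Optional[Mesh] = None,
) -> SteadyStateResult:
    return MunchSystem(config, mesh).integrate_to_steady_state(state0)
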