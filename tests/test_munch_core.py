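"""Biophysical model: derived fields, fluxes, balances, steady states.

Unit tests run on a coarse mesh (4/6/4 elements) where the physics is
identical but integration takes milliseconds; full-resolution behaviour is
exercised by the scenario and acceptance tests.
"""

import math
from dataclasses import replace

import numpy as np
import pytest

from conftest import SMALL_MESH
from phloempart.munch_core import (
    MunchSystem,
    StateCorruptionError,
    StateVector,
)
from phloempart.params_geometry import (
    Evaporating,
    ImposedFlux,
    MeshSpec,
    ScenarioConfig,
    SinkSpec,
    SoilCoupled,
    SourceSpec,
)
from phloempart.radial_sucrose import RadialSucroseConfig


def uniform_state(sys_, c=300.0):
    st = sys_.initial_state()
    st.s_ph = c * sys_.mesh.v_ref_ph
    return st


class TestDerivedFields:
    def test_zero_sucrose_limit(self, small_config):
        sys_ = MunchSystem(small_config)
        st = uniform_state(sys_, c=0.0)
        f = sys_.derived_fields(st)
        np.testing.assert_allclose(f.mu_ph, 1.0019e-9)
        np.testing.assert_allclose(f.pi_ph, 0.0)
        np.testing.assert_allclose(f.p_ph, 0.0, atol=1e-15)

    def test_viscosity_volume_fraction_example(self, small_config):
        # scalar check of the exponential viscosity law
        p = small_config.parameters
        v_water, s = 1e-9, 1e-6
        phi = p.v_suc * s / (p.v_suc * s + v_water)
        assert phi == pytest.approx(0.17743, abs=2e-5)
        mu_ratio = math.exp(4.68 * 0.956 * phi / (1 - 0.956 * phi))
        assert mu_ratio == pytest.approx(2.60, abs=0.01)

    def test_reference_volume_gives_zero_turgor(self, small_config):
        sys_ = MunchSystem(small_config)
        f = sys_.derived_fields(uniform_state(sys_))
        np.testing.assert_allclose(f.p_ph, 0.0, atol=1e-15)
        np.testing.assert_allclose(f.psi_ph, f.p_ph + f.pi_ph)

    def test_nonpositive_water_volume_rejected(self, small_config):
        sys_ = MunchSystem(small_config)
        st = sys_.initial_state()
        st.w_ph[0] = -1.0
        with pytest.raises(StateCorruptionError):
            sys_.derived_fields(st)

    def test_concentration_definition(self, small_config):
        sys_ = MunchSystem(small_config)
        st = uniform_state(sys_, c=123.0)
        f = sys_.derived_fields(st)
        np.testing.assert_allclose(
            f.c_ph, st.s_ph / (st.w_ph / small_config.parameters.rho_water))


class TestAxialFlux:
    def test_zero_pressure_difference(self, small_config):
        sys_ = MunchSystem(small_config)
        f = sys_.derived_fields(uniform_state(sys_))
        np.testing.assert_allclose(sys_.axial_water_flux(f), 0.0, atol=1e-25)

    def test_single_edge_closed_form_and_antisymmetry(self):
        cfg = ScenarioConfig(
            mesh_spec=MeshSpec(n_source=1, source_element_length=0.0083,
                               n_pathway=1, n_sink=1,
                               sink_element_length=0.0083),
            sinks=[SinkSpec(pathway_length=0.0083)],
            parameters=replace(ScenarioConfig().parameters, n_ph=1.0),
        )
        sys_ = MunchSystem(cfg)
        p = cfg.parameters
        st = uniform_state(sys_, c=0.0)
        dp = 0.1
        st.w_ph[0] *= (1 + dp / p.eps_p)   # P[0] = 0.1 MPa, P[1] = P[2] = 0
        f = sys_.derived_fields(st)
        q = sys_.axial_water_flux(f)
        area = math.pi * p.a_ph**2
        # water volume also shifts concentration-free viscosity: mu = mu_x
        expected = area * p.k_p / p.mu_x * dp / 0.0083
        assert q[0] == pytest.approx(expected, rel=1e-6)
        # reversing the pressure assignment flips the sign exactly
        st2 = uniform_state(sys_, c=0.0)
        st2.w_ph[1] *= (1 + dp / p.eps_p)
        q2 = sys_.axial_water_flux(sys_.derived_fields(st2))
        assert q2[0] == pytest.approx(-q[0], rel=1e-9)


class TestRadialAndBoundary:
    def test_equilibrium_no_flow(self, small_config):
        sys_ = MunchSystem(small_config)
        f = sys_.derived_fields(uniform_state(sys_, c=0.0))  # psi = 0
        np.testing.assert_allclose(sys_.radial_water_flux(f), 0.0, atol=1e-20)

    def test_coupled_equal_potentials_no_flow(self):
        cfg = ScenarioConfig(mesh_spec=SMALL_MESH,
                             hydraulic_mode="xylem_coupled")
        sys_ = MunchSystem(cfg)
        st = uniform_state(sys_, c=0.0)
        f = sys_.derived_fields(st)  # both systems at reference: psi = 0
        np.testing.assert_allclose(sys_.radial_water_flux(f), 0.0, atol=1e-20)

    def test_potential_difference_drives_flow_toward_phloem(self):
        cfg = ScenarioConfig(mesh_spec=SMALL_MESH,
                             hydraulic_mode="xylem_coupled")
        sys_ = MunchSystem(cfg)
        p = cfg.parameters
        st = uniform_state(sys_, c=0.0)
        st.w_ph *= (1 - 0.5 / p.eps_p)   # P_ph = -0.5
        st.w_x *= (1 - 0.2 / p.eps_x)    # P_x = -0.2
        f = sys_.derived_fields(st)
        q = sys_.radial_water_flux(f)
        expected = p.l_r * sys_.mesh.a_rad * 0.3
        np.testing.assert_allclose(q, expected, rtol=1e-6)

    def test_soil_coupled_uptake_scales_with_permeability(self):
        def total_uptake(pf):
            cfg = ScenarioConfig(
                mesh_spec=SMALL_MESH, hydraulic_mode="xylem_coupled",
                sinks=[SinkSpec(water_boundary=SoilCoupled(pf)),
                       SinkSpec(water_boundary=SoilCoupled(1.0))])
            sys_ = MunchSystem(cfg)
            st = sys_.initial_state()
            st.w_x *= (1 - 0.3 / cfg.parameters.eps_x)  # Psi_X = -0.3 < soil
            f = sys_.derived_fields(st)
            _, sink_totals, _ = sys_.boundary_water_fluxes(f)
            return sink_totals

        full = total_uptake(1.0)
        tuber = total_uptake(0.1)
        assert tuber[0] == pytest.approx(0.1 * full[0], rel=1e-9)
        assert full[0] > 0  # uptake directed into the plant

    def test_evaporating_sink_extraction_rate(self):
        cfg = ScenarioConfig(
            mesh_spec=SMALL_MESH, hydraulic_mode="xylem_coupled",
            sinks=[SinkSpec(water_boundary=Evaporating(0.1)),
                   SinkSpec(water_boundary=SoilCoupled(1.0))])
        sys_ = MunchSystem(cfg)
        f = sys_.derived_fields(sys_.initial_state())
        _, sink_totals, _ = sys_.boundary_water_fluxes(f)
        assert sink_totals[0] == pytest.approx(-0.002)  # 10% of 0.02 g/s


class TestSourceSinkTerms:
    def test_unloading_half_saturation_and_saturation(self, small_config):
        sys_ = MunchSystem(small_config)
        f = sys_.derived_fields(uniform_state(sys_, c=75.0))
        u = sys_.unloading_flux(f)
        for i, sink in enumerate(small_config.sinks):
            assert u[sys_.sink_idx[i]].sum() == pytest.approx(
                sink.v_max / 2, rel=1e-12)
        f_hi = sys_.derived_fields(uniform_state(sys_, c=1e9))
        u_hi = sys_.unloading_flux(f_hi)
        assert u_hi[sys_.sink_idx[0]].sum() == pytest.approx(
            small_config.sinks[0].v_max, rel=1e-6)

    def test_loading_uniform_split(self, small_config):
        sys_ = MunchSystem(small_config)
        load = sys_.loading_flux()
        n_src = sys_.source_idx.size
        np.testing.assert_allclose(
            load[sys_.source_idx], small_config.source.v0 / n_src)
        assert load.sum() == pytest.approx(small_config.source.v0, rel=1e-12)

    def test_zero_loading(self, small_config):
        cfg = small_config.copy(source=SourceSpec(v0=0.0))
        assert MunchSystem(cfg).loading_flux().sum() == 0.0


class TestTimeDerivatives:
    def test_quiescent_fixed_point(self):
        cfg = ScenarioConfig(mesh_spec=SMALL_MESH, source=SourceSpec(v0=0.0))
        sys_ = MunchSystem(cfg)
        d = sys_.time_derivatives(uniform_state(sys_, c=0.0))
        np.testing.assert_allclose(d.w_ph, 0.0, atol=1e-25)
        np.testing.assert_allclose(d.s_ph, 0.0, atol=1e-25)

    def test_global_sucrose_balance_telescopes(self):
        cfg = ScenarioConfig(
            mesh_spec=SMALL_MESH, hydraulic_mode="xylem_coupled",
            sinks=[SinkSpec(water_boundary=SoilCoupled(1.0)),
                   SinkSpec(water_boundary=SoilCoupled(1.0))],
            radial_sucrose=RadialSucroseConfig(apoplast_removal_rate=0.5))
        sys_ = MunchSystem(cfg)
        rng = np.random.default_rng(7)
        st = sys_.initial_state()
        st.s_ph *= rng.uniform(0.3, 3.0, st.s_ph.size)
        st.w_ph *= rng.uniform(0.97, 1.03, st.w_ph.size)
        st.w_x *= rng.uniform(0.999, 1.001, st.w_x.size)
        st.s_apo = rng.uniform(0, 1, sys_.n_apo) * 1e-9
        d = sys_.time_derivatives(st)
        f = sys_.derived_fields(st)
        removal = (cfg.radial_sucrose.apoplast_removal_rate
                   / cfg.radial_sucrose.apoplast_volume_fraction
                   * st.s_apo.sum())
        expected = cfg.source.v0 - sys_.unloading_flux(f).sum() - removal
        got = d.s_ph.sum() + d.s_apo.sum()
        # axial advection telescopes exactly; only roundoff remains
        assert got == pytest.approx(expected, abs=1e-22)

    def test_water_conservation_in_balanced_imposed_mode(self):
        cfg = ScenarioConfig(
            mesh_spec=SMALL_MESH, hydraulic_mode="xylem_coupled",
            source=SourceSpec(v0=5e-9, evaporation_mode="balance_sinks"),
            sinks=[SinkSpec(water_boundary=ImposedFlux(2e-8)),
                   SinkSpec(water_boundary=ImposedFlux(1e-8))])
        sys_ = MunchSystem(cfg)
        rng = np.random.default_rng(11)
        st = sys_.initial_state()
        st.s_ph *= rng.uniform(0.5, 2.0, st.s_ph.size)
        st.w_ph *= rng.uniform(0.98, 1.02, st.w_ph.size)
        st.w_x *= rng.uniform(0.999, 1.001, st.w_x.size)
        d = sys_.time_derivatives(st)
        total = d.w_ph.sum() + d.w_x.sum()
        gross = np.abs(d.w_ph).sum() + np.abs(d.w_x).sum()
        assert abs(total) < 1e-10 * max(gross, 1e-30)

    def test_three_element_chain_matches_hand_assembly(self):
        # one element per zone; every flux evaluated by hand
        cfg = ScenarioConfig(
            mesh_spec=MeshSpec(n_source=1, source_element_length=0.01,
                               n_pathway=1, n_sink=1,
                               sink_element_length=0.01),
            sinks=[SinkSpec(v_max=10e-9, k_m=75.0, pathway_length=0.01)],
            source=SourceSpec(v0=2e-9))
        sys_ = MunchSystem(cfg)
        p = cfg.parameters
        st = sys_.initial_state()
        st.s_ph = np.array([400.0, 300.0, 200.0]) * sys_.mesh.v_ref_ph
        st.w_ph = st.w_ph * np.array([1.001, 1.0, 0.999])
        f = sys_.derived_fields(st)
        d = sys_.time_derivatives(st)

        area = p.n_ph * math.pi * p.a_ph**2
        q = []
        for a, b in ((0, 1), (1, 2)):
            mu = 0.5 * (f.mu_ph[a] + f.mu_ph[b])
            q.append(area * p.k_p / mu * (f.p_ph[a] - f.p_ph[b]) / 0.01)
        j_rad = p.l_r * sys_.mesh.a_rad * (0 - f.psi_ph)
        rho = p.rho_water
        dw_hand = rho * np.array([
            -q[0] + j_rad[0], q[0] - q[1] + j_rad[1], q[1] + j_rad[2]])
        unload = 10e-9 * f.c_ph[2] / (75.0 + f.c_ph[2])
        ds_hand = np.array([
            2e-9 - q[0] * f.c_ph[0],
            q[0] * f.c_ph[0] - q[1] * f.c_ph[1],
            q[1] * f.c_ph[1] - unload])
        np.testing.assert_allclose(d.w_ph, dw_hand, rtol=1e-12)
        np.testing.assert_allclose(d.s_ph, ds_hand, rtol=1e-12)

    def test_nan_state_raises_with_location(self, small_config):
        sys_ = MunchSystem(small_config)
        y = sys_.pack(sys_.initial_state()) / sys_.scale
        y[3] = np.nan
        with pytest.raises(StateCorruptionError):
            sys_.rhs(0.0, y)


class TestSteadyState:
    def test_symmetric_config_splits_evenly(self, small_config):
        res = MunchSystem(small_config).integrate_to_steady_state()
        assert res.converged
        assert res.pc1 == pytest.approx(0.5, abs=5e-3)
        f = res.fluxes
        assert abs(f["v0"] - f["v1"] - f["v2"]) / f["v0"] < 1e-6

    def test_munch_directionality(self, small_config):
        # water enters the phloem along source and pathway, leaves in sinks
        res = MunchSystem(small_config).integrate_to_steady_state()
        sys_ = MunchSystem(small_config, res.mesh)
        q_rad = sys_.radial_water_flux(res.fields)
        zone = res.mesh.zone
        assert np.all(q_rad[zone == "source"] > 0)
        assert np.all(q_rad[(zone == "pathway_1") | (zone == "pathway_2")] > 0)
        assert np.all(q_rad[(zone == "sink_1") | (zone == "sink_2")] < 0)

    def test_initial_concentration_basin(self, small_config):
        pcs = []
        for c0 in (100.0, 500.0):
            cfg = small_config.copy(
                solver=replace(small_config.solver, initial_concentration=c0))
            pcs.append(MunchSystem(cfg).integrate_to_steady_state().pc1)
        assert pcs[0] == pytest.approx(pcs[1], abs=1e-3)

    def test_single_sink_monotone_gradient(self, small_single_sink):
        res = MunchSystem(small_single_sink).integrate_to_steady_state()
        c = res.fields.c_ph
        zone = res.mesh.zone
        path = c[(zone == "source") | (zone == "pathway_1")]
        assert np.all(np.diff(path) < 1e-9)  # decreasing toward the sink

    def test_mean_concentration_increases_with_loading(self, small_single_sink):
        means = []
        for v0 in (1e-9, 5e-9, 10e-9):
            cfg = small_single_sink.copy(source=SourceSpec(v0=v0))
            res = MunchSystem(cfg).integrate_to_steady_state()
            zone = res.mesh.zone
            means.append(res.fields.c_ph[zone == "pathway_1"].mean())
        assert means[0] < means[1] < means[2]

    def test_transient_preserves_sucrose_budget(self, small_config):
        # cumulative loading minus unloading accounts for the pool change
        sys_ = MunchSystem(small_config)
        t, states = sys_.integrate_transient(
            sys_.initial_state(), np.linspace(0, 2000.0, 5))
        s0 = states[0].s_ph.sum()
        s1 = states[-1].s_ph.sum()
        v0 = small_config.source.v0
        # unloading <= v_max, so the pool change is bounded by the budget
        assert s1 - s0 <= v0 * t[-1] * (1 + 1e-9)
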