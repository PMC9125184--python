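"""Mesh construction, presets, validation and serialization."""

import math

import numpy as np
import pytest

from phloempart.params_geometry import (
    Evaporating,
    ImposedFlux,
    MeshSpec,
    PlantParameters,
    ScenarioConfig,
    SinkSpec,
    SoilCoupled,
    SourceSpec,
    build_mesh,
    calibrated_n_ph,
    config_from_dict,
    config_to_dict,
    preset_names,
    preset_scenario,
    validate_config,
)


class TestPlantParameters:
    def test_table_defaults(self):
        p = PlantParameters()
        assert p.rho_water == 0.998e6
        assert p.l_r == 5e-8
        assert p.mu_x == 1.0019e-9
        assert p.a_ph == 8.4e-6
        assert p.a_x == 30e-6
        assert p.k_p == 3.82e-12
        assert (p.eps_p, p.eps_x) == (30.0, 750.0)
        assert (p.j_trans, p.psi_soil) == (0.02, 0.0)

    def test_derived_conduit_count_anchors_pathway_resistance(self):
        # hydraulic resistance of the standard 0.25 m pathway at zero sucrose
        # equals the lumped reference resistance at zero sucrose, converted
        # through RT (van 't Hoff)
        p = PlantParameters()
        r_hydraulic = p.mu_x * 0.25 / (p.k_p * p.n_ph * math.pi * p.a_ph**2)
        r_lumped_zero = 0.3396 * 7.5e12 * p.rt
        assert r_hydraulic == pytest.approx(r_lumped_zero, rel=1e-12)
        assert p.n_x == p.n_ph

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PlantParameters(mu_x=-1)
        with pytest.raises(ValueError):
            PlantParameters(psi_soil=0.5)


class TestMesh:
    def test_default_two_sink_mesh(self):
        cfg = ScenarioConfig()
        mesh = build_mesh(cfg)
        # 20 source + 2*(30 pathway + 20 sink) state elements + junction
        assert mesh.n_state == 120
        assert mesh.n_elements == 121
        assert np.all(mesh.length[mesh.zone == "pathway_1"]
                      == pytest.approx(0.25 / 30))
        table = mesh.element_table()
        assert len(table) == 121
        assert (table.zone == "junction").sum() == 1

    @pytest.mark.parametrize("lengths, expected", [
        ((0.1, 0.3), (0.1 / 30, 0.3 / 30)),
        ((0.25, 5.0), (0.25 / 30, 5.0 / 30)),
    ])
    def test_per_branch_element_lengths(self, lengths, expected):
        cfg = ScenarioConfig(sinks=[
            SinkSpec(pathway_length=lengths[0]),
            SinkSpec(pathway_length=lengths[1])])
        mesh = build_mesh(cfg)
        for b, exp in enumerate(expected, start=1):
            got = mesh.length[mesh.zone == f"pathway_{b}"]
            assert got == pytest.approx(exp)
            # branch lengths sum to the configured pathway length
            assert got.sum() == pytest.approx(lengths[b - 1], rel=1e-12)

    def test_zero_pathway_length_rejected(self):
        with pytest.raises(ValueError):
            SinkSpec(pathway_length=0.0)

    def test_reference_volumes(self):
        cfg = ScenarioConfig()
        p = cfg.parameters
        mesh = build_mesh(cfg)
        np.testing.assert_allclose(
            mesh.v_ref_ph,
            p.n_ph * math.pi * p.a_ph**2 * mesh.length)
        np.testing.assert_allclose(
            mesh.v_ref_x,
            p.n_x * math.pi * p.a_x**2 * mesh.length)

    def test_deterministic(self):
        cfg = ScenarioConfig()
        m1, m2 = build_mesh(cfg), build_mesh(cfg)
        np.testing.assert_array_equal(m1.length, m2.length)
        np.testing.assert_array_equal(m1.edges_parent, m2.edges_parent)

    def test_connectivity_is_tree(self):
        mesh = build_mesh(ScenarioConfig())
        # every element except the root has exactly one parent edge
        children, counts = np.unique(mesh.edges_child, return_counts=True)
        assert np.all(counts == 1)
        assert mesh.edges_parent.size == mesh.n_state - 1


class TestPresets:
    def test_catalogue_complete(self):
        required = {"vmax", "km", "resistance", "xylem_sweep", "root_root",
                    "tuber_root", "leaf_root", "efflux_factorial", "sp6a",
                    "single_sink"}
        assert required <= set(preset_names())

    def test_vmax_preset_values(self):
        cfg = preset_scenario("vmax")
        assert [s.v_max for s in cfg.sinks] == [22.5e-9, 2.5e-9]
        assert all(s.k_m == 75.0 for s in cfg.sinks)

    def test_km_preset_values(self):
        cfg = preset_scenario("km")
        assert [s.k_m for s in cfg.sinks] == [75.0, 750.0]
        assert all(s.v_max == 12.5e-9 for s in cfg.sinks)

    def test_resistance_preset_values(self):
        cfg = preset_scenario("resistance")
        assert cfg.vkr_r_refs == (7.5e12, 1.5e14)
        assert [s.pathway_length for s in cfg.sinks] == [0.25, 5.0]

    def test_tuber_root_preset(self):
        cfg = preset_scenario("tuber_root")
        wb1, wb2 = (s.water_boundary for s in cfg.sinks)
        assert isinstance(wb1, SoilCoupled) and wb1.permeability_factor == 0.1
        assert isinstance(wb2, SoilCoupled) and wb2.permeability_factor == 1.0
        assert cfg.parameters.psi_soil == 0.0

    def test_xylem_sweep_preset(self):
        cfg = preset_scenario("xylem_sweep")
        assert cfg.sinks[1].water_boundary.q == 2e-8
        assert cfg.source.evaporation_mode == "balance_sinks"

    def test_sp6a_preset(self):
        assert preset_scenario("sp6a").sp6a_factor == 0.6
        assert preset_scenario("vmax").sp6a_factor == 1.0

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            preset_scenario("nope")

    @pytest.mark.parametrize("name", sorted(
        {"vmax", "km", "resistance", "xylem_sweep", "root_root", "tuber_root",
         "leaf_root", "efflux_factorial", "sp6a", "single_sink",
         "leaf_tuber_efflux"}))
    def test_presets_valid_and_round_trip(self, name):
        cfg = preset_scenario(name)
        assert validate_config(cfg) == []
        d1 = config_to_dict(cfg)
        d2 = config_to_dict(config_from_dict(d1))
        assert d1 == d2


class TestValidation:
    def test_overloaded_source_flagged(self):
        cfg = ScenarioConfig(source=SourceSpec(v0=30e-9))
        diags = validate_config(cfg)
        assert any("no steady state" in d.message for d in diags
                   if d.level == "warning")

    def test_zero_affinity_diagnostic(self):
        cfg = ScenarioConfig()
        cfg.sinks[0].k_m = 0.0  # corrupt after construction
        diags = validate_config(cfg)
        assert any(d.level == "error" and "K_m" in d.message for d in diags)

    def test_unclosable_water_balance(self):
        cfg = ScenarioConfig(
            hydraulic_mode="xylem_coupled",
            sinks=[SinkSpec(water_boundary=Evaporating(0.1)),
                   SinkSpec(water_boundary=Evaporating(0.1))])
        diags = validate_config(cfg)
        assert any(d.level == "error" for d in diags)

    def test_boundary_invariants(self):
        with pytest.raises(ValueError):
            SoilCoupled(permeability_factor=0.0)
        with pytest.raises(ValueError):
            Evaporating(fraction_of_source=1.5)

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown configuration keys"):
            config_from_dict({"sinks": [{}, {}], "bogus": 1})
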