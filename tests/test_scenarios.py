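"""Scenario construction, validation, perturbation and serialization."""

import dataclasses
import math

import pytest

import pyccm
from pyccm.scenarios import (
    ConfigurationError,
    ScenarioConfig,
    build_scenario,
    external_boundary_values,
    named_scenario,
    perturb,
    table_scenarios,
)


class TestBuildScenario:
    def test_land_plant_defaults(self):
        cfg = build_scenario("land_plant", ccm=False, bica_placement="none")
        p = cfg.parameters()
        assert p.wall_thickness == 0.32
        assert p.effective_porosity == 0.2
        assert cfg.rubisco_density == 7600.0

    def test_hornwort_wall_defaults(self):
        cfg = build_scenario("hornwort", ccm=True, bica_placement="none")
        p = cfg.parameters()
        assert p.wall_thickness == 1.6
        assert p.effective_porosity == pytest.approx(1e-4)
        geom = pyccm.build_geometry(cfg)
        assert not geom.has("substomatal_gas")

    def test_ccm_condenses_rubisco_capacity(self):
        cfg = build_scenario("land_plant", ccm=True, bica_placement="none")
        p = cfg.parameters()
        assert cfg.rubisco_density == pytest.approx(
            7600.0 * (p.r_chloroplast / p.r_pyrenoid) ** 3)

    def test_unknown_organism_or_placement(self):
        with pytest.raises(ConfigurationError):
            build_scenario("yeast", False, "none")
        with pytest.raises(ConfigurationError):
            build_scenario("alga", False, "everywhere")

    def test_apoplast_options_rejected_for_alga(self):
        with pytest.raises(ConfigurationError):
            build_scenario("alga", False, "none", {"apoplast_ca": True})

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigurationError):
            build_scenario("alga", False, "none",
                           {"parameter_overrides": {"bogus": 1.0}})

    def test_four_base_scenarios_differ_only_in_switches(self):
        scs = table_scenarios()
        assert set(scs) == {"land_plant_with_ccm", "land_plant_without_ccm",
                            "alga_with_ccm", "alga_without_ccm"}
        for name, cfg in scs.items():
            assert cfg.ccm == name.endswith("with_ccm")
            assert cfg.bica_placement == "none"
            assert not cfg.parameter_overrides


class TestPerturb:
    def test_scalar_parameter(self):
        cfg = named_scenario("land_plant_without_ccm")
        assert perturb(cfg, "Rub_Vmax_c", 1.1).parameters().Rub_Vmax_c \
            == pytest.approx(8360.0)

    def test_radius_scales_area_and_volume_only(self):
        cfg = named_scenario("alga_with_ccm")
        pert = perturb(cfg, "r_pyrenoid", 1.1)
        g0 = pyccm.build_geometry(cfg)
        g1 = pyccm.build_geometry(pert)
        pyr0, pyr1 = g0.compartment("pyrenoid"), g1.compartment("pyrenoid")
        assert pyr1.volume / pyr0.volume == pytest.approx(1.1**3)
        sheath0 = next(i for i in g0.interfaces if i.name == "starch_sheath")
        sheath1 = next(i for i in g1.interfaces if i.name == "starch_sheath")
        assert sheath1.area / sheath0.area == pytest.approx(1.1**2)
        # other radii and the frozen catalytic density stay fixed
        assert g1.compartment("stroma").r_outer == g0.compartment("stroma").r_outer
        assert pyr1.rubisco_density == pyr0.rubisco_density

    def test_unknown_symbol_and_bad_factor(self):
        cfg = named_scenario("land_plant_without_ccm")
        with pytest.raises(KeyError):
            perturb(cfg, "bogus", 1.1)
        with pytest.raises(ValueError):
            perturb(cfg, "Rub_Vmax_c", 0.0)


class TestSerialization:
    @pytest.mark.parametrize("name", ["land_plant_with_ccm", "alga_without_ccm"])
    def test_yaml_roundtrip_field_for_field(self, name):
        cfg = dataclasses.replace(
            named_scenario(name), permeability_fold=2.0,
            parameter_overrides={"g_s": 0.5})
        again = ScenarioConfig.from_yaml(cfg.to_yaml())
        assert again == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig.from_dict({"organism": "alga", "frobnicate": 1})


class TestExternalBoundary:
    def test_alga_bulk_is_bicarbonate_rich_at_ocean_pH(self):
        ext = external_boundary_values(named_scenario("alga_without_ccm"))
        # at pH 8 the bulk HCO3- pool is ~60x the dissolved CO2
        assert ext["HCO3"] / ext["CO2"] == pytest.approx(60.0, rel=1e-6)
        assert ext["O2"] == pytest.approx(8450.98 / 32.0, rel=1e-3)

    def test_land_boundary_is_gas_phase(self):
        ext = external_boundary_values(named_scenario("land_plant_without_ccm"))
        assert ext["CO2_gas"] == pytest.approx(16.62, abs=0.01)
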