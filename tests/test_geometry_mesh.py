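"""Compartment geometry, interface areas, and the radial mesh."""

import json
import math

import numpy as np
import pytest

import pyccm
from pyccm.geometry import build_geometry, series_conductance, sphere_area
from pyccm.mesh import MeshError, discretize
from pyccm.scenarios import named_scenario


class TestGeometry:
    def test_land_plant_compartment_sequence(self):
        geom = build_geometry(named_scenario("land_plant_without_ccm"))
        names = [c.name for c in geom.compartments]
        assert names == ["stroma", "cytosol", "apoplast", "substomatal_gas"]
        assert geom.exterior == "gas_node"

    def test_chloroplast_envelope_area(self):
        geom = build_geometry(named_scenario("land_plant_without_ccm"))
        env = next(i for i in geom.interfaces if i.name == "chloroplast_envelope")
        assert env.area == pytest.approx(4 * math.pi * 4.63**2, rel=1e-12)
        assert env.area == pytest.approx(269.4, abs=0.2)

    def test_thylakoid_pyrenoid_contact_is_six_end_caps(self):
        geom = build_geometry(named_scenario("land_plant_with_ccm"))
        caps = next(i for i in geom.interfaces if i.name == "thylakoid_pyrenoid")
        assert caps.area == pytest.approx(6 * math.pi * 0.25, rel=1e-12)
        assert caps.area == pytest.approx(4.712, abs=0.001)
        thyl = geom.compartment("thylakoid")
        assert thyl.volume == pytest.approx(6 * math.pi * 0.25 * 4.0, rel=1e-12)

    def test_starch_sheath_multiplies_bilayer_permeability(self):
        cfg = named_scenario("alga_with_ccm")
        geom = build_geometry(cfg)
        sheath = next(i for i in geom.interfaces if i.name == "starch_sheath")
        p = cfg.parameters()
        assert sheath.species_permeability["CO2"] == pytest.approx(0.1 * p.P_CO2)
        assert sheath.species_permeability["O2"] == pytest.approx(0.1 * p.P_O2)

    def test_alga_has_bulk_exterior_with_all_species(self):
        geom = build_geometry(named_scenario("alga_without_ccm"))
        assert geom.exterior == "bulk_dirichlet"
        series = next(i for i in geom.interfaces if i.kind == "series_bulk")
        assert set(series.conductance) == {"CO2", "H2CO3", "HCO3", "O2"}

    def test_geometry_dump_is_json(self):
        geom = build_geometry(named_scenario("land_plant_with_ccm"))
        data = json.loads(geom.to_json())
        assert {c["name"] for c in data["compartments"]} >= {"pyrenoid", "thylakoid"}


class TestSeriesConductance:
    def test_zero_porosity_seals_the_wall(self):
        assert series_conductance(1880.0, 100.0, 0.32, 0.0, 0.32) == 0.0

    def test_equal_resistances_halve_the_conductance(self):
        g_one = 1880.0 * 100.0 / 0.32
        g = series_conductance(1880.0, 100.0, 0.32, 1.0, 0.32)
        assert g == pytest.approx(0.5 * g_one, rel=1e-12)

    def test_wall_permeability_at_defaults(self):
        # per-area wall permeability D*porosity/thickness = 1880*0.2/0.32
        assert 1880.0 * 0.2 / 0.32 == pytest.approx(1175.0)
        g = pyccm.wall_series_conductance("CO2", named_scenario(
            "land_plant_without_ccm").parameters(), area=1.0)
        expected = 1.0 / (0.32 / 1880.0 + 0.32 / (1880.0 * 0.2))
        assert g == pytest.approx(expected, rel=1e-12)


class TestMesh:
    def test_mesh_volumes_match_analytic_shells(self):
        geom = build_geometry(named_scenario("alga_with_ccm"))
        mesh = discretize(geom, dr=0.1)
        for comp in geom.compartments:
            assert mesh.compartment_volume(comp.name) == pytest.approx(
                comp.volume, rel=5e-3)

    def test_interior_faces_are_conformal(self):
        geom = build_geometry(named_scenario("land_plant_without_ccm"))
        mesh = discretize(geom, dr=0.1)
        for (i, j, area, dist, ci) in mesh.faces:
            assert mesh.comp_idx[i] == mesh.comp_idx[j] == ci
            assert mesh.r_hi[i] == pytest.approx(mesh.r_lo[j])
            assert dist > 0 and area > 0

    def test_too_coarse_dr_errors(self):
        geom = build_geometry(named_scenario("land_plant_without_ccm"))
        with pytest.raises(MeshError):
            discretize(geom, dr=0.5)   # coarser than the apoplast layer
        with pytest.raises(MeshError):
            discretize(geom, dr=-0.1)

    def test_geometry_invariant_to_construction_order(self):
        # two independent builds produce identical radii and areas
        a = build_geometry(named_scenario("land_plant_with_ccm"))
        b = build_geometry(named_scenario("land_plant_with_ccm"))
        for ca, cb in zip(a.compartments, b.compartments):
            assert (ca.name, ca.r_inner, ca.r_outer, ca.volume) == \
                   (cb.name, cb.r_inner, cb.r_outer, cb.volume)
        for ia, ib in zip(a.interfaces, b.interfaces):
            assert ia.name == ib.name and ia.area == ib.area
            assert ia.species_permeability == ib.species_permeability


def test_thylakoid_conductance_robustness():
    """A 10x change of both tubule-interface conductances moves quantum
    yield by well under 15% (the tubule idealization is not load-bearing)."""
    phis = []
    for mult in (1.0, 10.0):
        cfg = named_scenario("land_plant_with_ccm", parameter_overrides={
            "thylakoid_interface_multiplier": mult})
        sol = pyccm.solve_scenario(cfg, dr=0.1)
        phis.append(pyccm.solution_budget(sol).quantum_yield)
    assert abs(phis[1] - phis[0]) / phis[0] < 0.15
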