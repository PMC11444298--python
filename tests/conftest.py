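"""Shared fixtures: the four base scenarios and their (cached) steady states."""

from __future__ import annotations

import pytest

import pyccm


@pytest.fixture(scope="session")
def base_scenarios():
    return pyccm.table_scenarios()


def _solve(name):
    return pyccm.solve_scenario(pyccm.named_scenario(name))


@pytest.fixture(scope="session")
def land_noccm_sol():
    return _solve("land_plant_without_ccm")


@pytest.fixture(scope="session")
def land_ccm_sol():
    return _solve("land_plant_with_ccm")


@pytest.fixture(scope="session")
def alga_noccm_sol():
    return _solve("alga_without_ccm")


@pytest.fixture(scope="session")
def alga_ccm_sol():
    return _solve("alga_with_ccm")


@pytest.fixture(scope="session")
def base_solutions(land_noccm_sol, land_ccm_sol, alga_noccm_sol, alga_ccm_sol):
    return {
        "land_plant_without_ccm": land_noccm_sol,
        "land_plant_with_ccm": land_ccm_sol,
        "alga_without_ccm": alga_noccm_sol,
        "alga_with_ccm": alga_ccm_sol,
    }
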