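"""Finite-volume assembly and steady-state solver behavior."""

import numpy as np
import pytest

import pyccm
from pyccm.geometry import build_geometry
from pyccm.mesh import discretize
from pyccm.scenarios import named_scenario
from pyccm.solver import (
    SteadyStateProblem,
    mass_balance_report,
    solve_scenario,
    solve_steady_state,
)


@pytest.fixture(scope="module")
def land_problem():
    sc = named_scenario("land_plant_without_ccm")
    return SteadyStateProblem(discretize(build_geometry(sc), dr=0.1), sc)


class TestAssembly:
    def test_system_size(self, land_problem):
        pr = land_problem
        assert pr.n == pr.n_aq * 4 + 2  # four species + gas-node CO2/O2

    def test_diffusion_rows_conserve_mass(self, land_problem):
        """Interior diffusion is conservative: summing the O2 rows of the
        transport operator over a sealed interior region cancels the
        interior exchanges (row sums of paired conductances vanish)."""
        pr = land_problem
        L = pr.L.toarray()
        # O2 has no reactions folded into L; total O2 rows must sum to the
        # boundary (stomatal + dissolution) terms only, which live on the
        # gas node and outermost aqueous node columns.
        o2_rows = [pr.idx(int(a), "O2") for a in pr.aq_nodes] + [pr.i_gas_o2]
        colsum = L[o2_rows, :].sum(axis=0)
        interior = np.ones(pr.n, bool)
        interior[pr.i_gas_o2] = False  # stomatal row couples to the exterior
        assert np.abs(colsum[interior]).max() < 1e-6 * np.abs(L).max()

    def test_stroma_diffusivity_uses_viscosity(self):
        sc = named_scenario("land_plant_without_ccm")
        p = sc.parameters()
        assert p.D_CO2 / p.visc_stroma == pytest.approx(188.0)

    def test_jacobian_matches_finite_differences(self, land_problem):
        pr = land_problem
        x = pr.initial_state() * 0.8 + 0.01
        F, _, _, J = pr.residual(x, want_jac=True)
        rng = np.random.default_rng(7)
        for k in rng.integers(0, pr.n, size=8):
            h = max(abs(x[k]), 1.0) * 1e-6
            xp = x.copy()
            xp[k] += h
            Fp, _, _, _ = pr.residual(xp)
            col = J[:, int(k)].toarray().ravel()
            scale = np.abs(col).max() + 1e-9
            assert np.abs((Fp - F) / h - col).max() / scale < 1e-4


class TestSolve:
    def test_pure_diffusion_relaxes_to_uniform(self):
        """With a sealed O2-like species (no reactions for O2 in a CA-free,
        rubisco-free variant) a nonuniform start relaxes to uniformity."""
        sc = named_scenario("alga_without_ccm", parameter_overrides={
            "CA_conc_stroma": 1e-12, "CA_conc_cytosol": 1e-12,
            "Rub_Vmax_c": 1e-12, "Rub_Vmax_o": 1e-12})
        pr = SteadyStateProblem(discretize(build_geometry(sc), dr=0.1), sc)
        x0 = pr.initial_state()
        rng = np.random.default_rng(0)
        for a in pr.aq_nodes:  # scramble O2
            x0[pr.idx(int(a), "O2")] *= rng.uniform(0.5, 1.5)
        sol = solve_steady_state(pr, x0=x0)
        o2 = [sol.x[pr.idx(int(a), "O2")] for a in pr.aq_nodes]
        assert np.ptp(o2) / np.mean(o2) < 1e-6

    def test_stroma_drawdown_sign(self, land_noccm_sol):
        sol = land_noccm_sol
        sub_aq = sol.x[sol.problem.i_gas_co2] / sol.problem.params.H_CO2
        assert sol.concentration("stroma", "CO2") < sub_aq

    def test_ccm_concentrates_co2_in_pyrenoid(self, alga_ccm_sol):
        assert alga_ccm_sol.concentration("pyrenoid", "CO2") > \
            2.0 * alga_ccm_sol.concentration("stroma", "CO2")

    def test_initial_condition_independence(self):
        sc = named_scenario("land_plant_without_ccm")
        pr = SteadyStateProblem(discretize(build_geometry(sc), dr=0.1), sc)
        a = solve_steady_state(pr)
        b = solve_steady_state(pr, x0=pr.initial_state(co2_scale=0.05))
        assert np.abs(a.x - b.x).max() / np.abs(a.x).max() < 1e-8

    def test_all_concentrations_nonnegative(self, base_solutions):
        for sol in base_solutions.values():
            assert (sol.x >= 0).all()

    def test_solution_frame_schema(self, land_noccm_sol):
        df = land_noccm_sol.to_frame()
        assert set(df.columns) >= {"radius_um", "compartment", "species",
                                   "concentration_uM"}
        assert (df["phase"] == "gas").sum() == 2


class TestMassBalance:
    def test_budget_rows_close(self, base_solutions):
        for sol in base_solutions.values():
            rep = mass_balance_report(sol)
            gross = max(sol.Vc_total, 1e-300)
            assert (rep["residual_mol_s"].abs() < 1e-5 * gross).all()
            # transport and reaction columns are equal and opposite
            assert np.allclose(rep["net_transport_mol_s"],
                               -rep["net_reaction_mol_s"], atol=1e-5 * gross)

    def test_global_dic_balance(self, base_solutions):
        for name, sol in base_solutions.items():
            assert sol.boundary_dic_influx() == pytest.approx(
                sol.net_fixation, abs=1e-6 * sol.Vc_total), name
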