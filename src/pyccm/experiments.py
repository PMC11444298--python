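"""Computational experiments: compensation points, scans, marginal CCM
cost, and local sensitivity analysis.

Everything here is a deterministic driver over the steady-state solver; no
randomness enters anywhere in the pipeline.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .energetics import EnergeticsConstants, net_fixation, solution_budget
from .parameters import micromolar_gas_to_ppm, ppm_to_micromolar_gas
from .scenarios import ScenarioConfig, perturb
from .solver import SolverError, solve_scenario


# ----------------------------------------------------------------------
# compensation point


def _net_fixation_at(scenario: ScenarioConfig, external: float, dr: float) -> float:
    sol = solve_scenario(scenario.with_external_co2(external), dr=dr)
    return sol.net_fixation


def compensation_point(scenario: ScenarioConfig,
                       bracket: tuple[float, float] | None = None,
                       dr: float = 0.05, xtol_ppm: float = 0.05) -> float:
    """External CO2 at which net fixation crosses zero.

    Returned in the scenario's own external units (ppm for land plant and
    hornwort, uM aqueous for the alga); the tolerance is 0.05 ppm or its
    aqueous equivalent.  The net-fixation curve is monotone in external
    CO2, so a coarse pre-scan brackets the root for Brent's method.
    """
    p = scenario.parameters()
    aquatic = scenario.organism == "alga"
    if bracket is None:
        hi = p.CO2_ext_ppm if not aquatic else ppm_to_micromolar_gas(p.CO2_ext_ppm) / p.H_CO2
        bracket = (hi * 1e-3, hi)
    lo, hi = bracket
    f_lo = _net_fixation_at(scenario, lo, dr)
    f_hi = _net_fixation_at(scenario, hi, dr)
    # pre-scan to tighten/locate a sign change
    if f_lo * f_hi > 0:
        grid = np.geomspace(lo, hi, 9)
        vals = [f_lo] + [_net_fixation_at(scenario, g, dr) for g in grid[1:-1]] + [f_hi]
        for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if fa * fb <= 0:
                lo, hi, f_lo, f_hi = a, b, fa, fb
                break
        else:
            raise ValueError(
                f"net fixation does not change sign over bracket {bracket}")
    xtol = xtol_ppm if not aquatic else xtol_ppm / (24.79 * p.H_CO2)
    root = brentq(lambda c: _net_fixation_at(scenario, c, dr), lo, hi,
                  xtol=xtol, rtol=1e-6)
    return float(root)


def well_mixed_compensation_ppm(scenario: ScenarioConfig, o2_aq: float | None = None) -> float:
    """Closed-form compensation point of the zero-gradient limit, gas ppm.

    With a single well-mixed aqueous pool, net fixation vanishes when
    CO2 = O2 * (Vmax_o * Km_CO2) / (2 * Vmax_c * Km_O2); the Michaelis
    denominators cancel exactly at that point, so the linear low-substrate
    formula is exact.
    """
    p = scenario.parameters()
    if o2_aq is None:
        o2_aq = p.o2_ext_gas_uM() / p.H_O2
    gamma_aq = 0.5 * o2_aq * (p.Rub_Vmax_o * p.km_co2) / (p.Rub_Vmax_c * p.km_o2)
    return micromolar_gas_to_ppm(gamma_aq * p.H_CO2)


# ----------------------------------------------------------------------
# grid scans


@dataclass
class ScanResult:
    scenario_label: str
    axes: dict
    table: pd.DataFrame  # one row per grid cell

    def pivot(self, value: str) -> pd.DataFrame:
        names = list(self.axes)
        return self.table.pivot(index=names[0], columns=names[1], values=value)


_AXIS_FIELDS = {"permeability_fold", "bica_vmax_fold", "porosity_override",
                "external_CO2", "apoplast_pH_override"}


def _with_axis(config: ScenarioConfig, name: str, value) -> ScenarioConfig:
    if name in _AXIS_FIELDS:
        return dataclasses.replace(config, **{name: value})
    overrides = dict(config.parameter_overrides)
    overrides[name] = value
    return dataclasses.replace(config, parameter_overrides=overrides)


def grid_scan(config: ScenarioConfig, axis1: tuple[str, list],
              axis2: tuple[str, list] | None = None, dr: float = 0.05,
              constants: EnergeticsConstants | None = None) -> ScanResult:
    """Solve every cell of a 1- or 2-axis parameter grid.

    Records rubisco saturation, quantum yield (CEF), net fixation and a few
    auxiliary outputs per cell; convergence failures are recorded as failed
    cells rather than aborting the scan.  Cells are solved in a fixed order
    from identical initial conditions, so results are order-independent.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2 if axis2 is not None else ("_", [None])
    rows = []
    for v1 in vals1:
        for v2 in vals2:
            cfg = _with_axis(config, name1, v1)
            if name2 != "_":
                cfg = _with_axis(cfg, name2, v2)
            row = {name1: v1}
            if name2 != "_":
                row[name2] = v2
            try:
                sol = solve_scenario(cfg, dr=dr)
                budget = solution_budget(sol, constants, "CEF")
                row.update(
                    converged=True,
                    rubisco_saturation=sol.rubisco_saturation(),
                    quantum_yield=budget.quantum_yield,
                    net_fixation_mol_s=sol.net_fixation,
                    photons_mol_s=budget.photons_total,
                )
                if sol.problem.has_gas:
                    row["substomatal_co2_ppm"] = sol.substomatal_co2_ppm()
                surf = "boundary_water" if cfg.organism == "alga" else "apoplast"
                row["external_hco3_uM"] = sol.concentration(surf, "HCO3")
            except SolverError:
                row.update(converged=False)
            rows.append(row)
    axes = {name1: list(vals1)}
    if name2 != "_":
        axes[name2] = list(vals2)
    return ScanResult(config.label, axes, pd.DataFrame(rows))


# ----------------------------------------------------------------------
# marginal CCM cost


def marginal_ccm_cost(photons_with: float, netfix_with: float,
                      photons_without: float, netfix_without: float) -> float:
    """Marginal photon cost of CCM-driven fixation over the no-CCM average.

    ratio = [(P_w - P_wo) / (N_w - N_wo)] / [P_wo / N_wo]; below 1 the CCM
    is marginally light-efficient.  Undefined (ValueError) when the CCM
    does not increase net fixation.
    """
    if netfix_with <= netfix_without:
        raise ValueError("marginal cost undefined: CCM does not increase net fixation")
    if netfix_without <= 0 or photons_without <= 0:
        raise ValueError("no-CCM baseline must have positive fixation and photon use")
    marginal = (photons_with - photons_without) / (netfix_with - netfix_without)
    average = photons_without / netfix_without
    return marginal / average


@dataclass
class MarginalCostPoint:
    external_co2: float
    ratio: float
    substomatal_co2_ppm_without: float | None
    substomatal_co2_ppm_with: float | None


def marginal_cost_curve(scenario_with: ScenarioConfig, scenario_without: ScenarioConfig,
                        external_values: list[float], dr: float = 0.05,
                        constants: EnergeticsConstants | None = None
                        ) -> list[MarginalCostPoint]:
    points = []
    for ext in external_values:
        s_w = solve_scenario(scenario_with.with_external_co2(ext), dr=dr)
        s_wo = solve_scenario(scenario_without.with_external_co2(ext), dr=dr)
        b_w = solution_budget(s_w, constants, "CEF")
        b_wo = solution_budget(s_wo, constants, "CEF")
        try:
            ratio = marginal_ccm_cost(b_w.photons_total, s_w.net_fixation,
                                      b_wo.photons_total, s_wo.net_fixation)
        except ValueError:
            ratio = math.nan
        points.append(MarginalCostPoint(
            ext, ratio,
            s_wo.substomatal_co2_ppm() if s_wo.problem.has_gas else None,
            s_w.substomatal_co2_ppm() if s_w.problem.has_gas else None))
    return points


def marginal_cost_crossover(scenario_with: ScenarioConfig,
                            scenario_without: ScenarioConfig,
                            bracket: tuple[float, float], n_scan: int = 9,
                            dr: float = 0.05,
                            constants: EnergeticsConstants | None = None) -> dict:
    """External CO2 at which the marginal-cost ratio crosses 1.

    Scans the bracket, locates a sign change of (ratio - 1), refines with
    Brent's method, and reports the crossover in external units plus (for
    land plants) the substomatal CO2 of the no-CCM model there.
    """
    def ratio_minus_one(ext: float) -> float:
        pt = marginal_cost_curve(scenario_with, scenario_without, [ext],
                                 dr=dr, constants=constants)[0]
        return pt.ratio - 1.0

    grid = np.geomspace(bracket[0], bracket[1], n_scan)
    vals = [ratio_minus_one(g) for g in grid]
    lo = hi = None
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if np.isfinite(fa) and np.isfinite(fb) and fa * fb <= 0:
            lo, hi = a, b
            break
    if lo is None:
        raise ValueError(
            f"marginal-cost ratio does not cross 1 over {bracket}: {vals}")
    root = brentq(ratio_minus_one, lo, hi, xtol=max(1e-3 * hi, 1e-4), rtol=1e-4)
    pt = marginal_cost_curve(scenario_with, scenario_without, [root],
                             dr=dr, constants=constants)[0]
    return {
        "external_co2": float(root),
        "substomatal_co2_ppm": pt.substomatal_co2_ppm_without,
        "ratio": pt.ratio,
    }


# ----------------------------------------------------------------------
# sensitivity analysis


@dataclass
class SensitivityRow:
    parameter: str
    pct_change_saturation: float  # avg |%| over +/-10%
    pct_change_quantum_yield: float
    flagged: bool = False
    note: str = ""


DEFAULT_SENSITIVITY_PARAMETERS = (
    "Rub_Vmax_c", "Rub_Km_CO2", "Rub_Km_O2", "P_CO2", "P_HCO3",
    "D_CO2", "kf_hyd", "CA_kcat", "CA_conc_stroma", "g_s",
    "effective_porosity", "r_chloroplast", "r_cytosol",
)


def local_sensitivity(scenario: ScenarioConfig,
                      parameter_list: tuple[str, ...] = DEFAULT_SENSITIVITY_PARAMETERS,
                      rel_change: float = 0.10, dr: float = 0.05,
                      constants: EnergeticsConstants | None = None
                      ) -> list[SensitivityRow]:
    """Average |%| change of rubisco saturation and quantum yield for a
    +/-10% perturbation of each parameter.

    Radius perturbations recompute areas and volumes while holding protein
    densities constant.  If a 10% geometric perturbation breaks the solve,
    a 1% perturbation scaled by 10 is used instead (flagged in the row).
    """
    base = solve_scenario(scenario, dr=dr)
    sat0 = base.rubisco_saturation()
    phi0 = solution_budget(base, constants, "CEF").quantum_yield
    rows = []
    for name in parameter_list:
        deltas_sat, deltas_phi, flagged, note = [], [], False, ""
        for sign in (+1.0, -1.0):
            factor = 1.0 + sign * rel_change
            scale = 1.0
            try:
                sol = solve_scenario(perturb(scenario, name, factor), dr=dr)
            except (SolverError, ValueError):
                # fall back to a 1% perturbation scaled linearly by 10
                try:
                    small = 1.0 + sign * rel_change / 10.0
                    sol = solve_scenario(perturb(scenario, name, small), dr=dr)
                    scale = 10.0
                    flagged, note = True, "1% perturbation x10"
                except (SolverError, ValueError):
                    flagged, note = True, "solve failed"
                    continue
            sat = sol.rubisco_saturation()
            phi = solution_budget(sol, constants, "CEF").quantum_yield
            deltas_sat.append(abs(sat - sat0) / sat0 * 100.0 * scale if sat0 else 0.0)
            deltas_phi.append(abs(phi - phi0) / phi0 * 100.0 * scale if phi0 else 0.0)
        rows.append(SensitivityRow(
            name,
            float(np.mean(deltas_sat)) if deltas_sat else math.nan,
            float(np.mean(deltas_phi)) if deltas_phi else math.nan,
            flagged, note))
    return rows


def sensitivity_frame(rows: list[SensitivityRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


# ----------------------------------------------------------------------
# substomatal-CO2 targeting (C4-like intercellular CO2 regime)

#: C4 plants regulate their intercellular CO2 to roughly 0.3-0.4 of
#: ambient; the band midpoint defines the "C4-like C_i" operating point
#: used when scanning external CO2 downward.
C4_CI_CA_RATIO = 0.35


def c4_ci_target_ppm(ambient_ppm: float = 412.0) -> float:
    """C4-typical substomatal CO2 (ppm) for a given ambient level."""
    return C4_CI_CA_RATIO * ambient_ppm


def external_co2_for_ci(scenario: ScenarioConfig, ci_target_ppm: float,
                        bracket: tuple[float, float] | None = None,
                        dr: float = 0.05) -> float:
    """External CO2 (ppm) at which the steady-state substomatal CO2 equals
    ``ci_target_ppm``; land-plant scenarios only."""
    if scenario.organism != "land_plant":
        raise ValueError("substomatal CO2 exists only in land-plant scenarios")

    def ci_err(ext: float) -> float:
        sol = solve_scenario(scenario.with_external_co2(ext), dr=dr)
        return sol.substomatal_co2_ppm() - ci_target_ppm

    if bracket is None:
        bracket = (ci_target_ppm, scenario.parameters().CO2_ext_ppm * 2.0)
    return float(brentq(ci_err, bracket[0], bracket[1], xtol=0.05, rtol=1e-6))
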