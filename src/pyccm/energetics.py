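"""ATP/NADPH/photon accounting and quantum yield.

Demand side: each carboxylation costs 3 ATP + 2 NADPH, each oxygenation
3.5 ATP + 2 NADPH (Calvin-Benson cycle plus photorespiratory recovery).
Running a lumenal carbonic anhydrase drains the proton-motive force: each
HCO3- dehydrated in the lumen removes one pumped proton, which costs
3/14 ATP at the 14:3 H+:ATP stoichiometry of the chloroplast ATP synthase.

Active bicarbonate pumping (BicA) is costed the same way as the lumenal
CA: one cation-equivalent translocation per HCO3- moved, i.e. 3/14 ATP per
transport event, so futile pump-and-leak cycles show up as a photon cost.

Supply side: linear electron flow (LEF) delivers, per 2 NADPH, 8 photons
and 12 pumped H+ = 18/7 ATP.  Any ATP demand beyond that is met either by
cyclic electron flow (CEF, 0.43 ATP per extra photon) or by the malate
valve (5.45 ATP per 2 NADPH-equivalent exported, at 4 photons per NADPH).
The quantum yield is net CO2 fixed per photon absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Mode = Literal["CEF", "malate"]


@dataclass(frozen=True)
class EnergeticsConstants:
    atp_per_carbox: float = 3.0
    atp_per_oxy: float = 3.5
    nadph_per_rxn: float = 2.0      # per carboxylation and per oxygenation
    h_per_atp: float = 14.0 / 3.0   # ATP synthase c-ring stoichiometry
    photons_base: float = 8.0       # photons per 2 NADPH by linear flow
    nadph_base: float = 2.0
    atp_base: float = 12.0 * 3.0 / 14.0  # ATP per 2 NADPH from LEF (= 18/7)
    atp_per_hco3_pumped: float = 3.0 / 14.0  # active HCO3- transport cost
    cef_atp_per_photon: float = 0.43
    malate_atp_per_2nadph: float = 5.45
    photons_per_nadph_malate: float = 4.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EnergyBudget:
    """ATP/NADPH/photon demand for a converged flux state (all mol/s)."""

    Vc: float
    Vo: float
    atp_total: float
    nadph_total: float
    atp_nadph_ratio: float
    lumen_ca_atp: float
    bica_atp: float = 0.0
    mode: Mode = "CEF"
    photons_total: float = 0.0
    quantum_yield: float = 0.0


def net_fixation(vc_total: float, vo_total: float) -> float:
    """Net CO2 fixation Vc - Vo/2 (compensation when Vc = Vo/2)."""
    if vc_total < 0 or vo_total < 0:
        raise ValueError("rubisco totals must be nonnegative")
    return vc_total - 0.5 * vo_total


def lumen_ca_atp_cost(j_lumen_ca: float, constants: EnergeticsConstants | None = None) -> float:
    """Indirect ATP cost of net lumenal CA dehydration flux: J * 3/14."""
    c = constants or EnergeticsConstants()
    return max(j_lumen_ca, 0.0) / c.h_per_atp


def demand_budget(vc: float, vo: float, j_lumen_ca: float = 0.0,
                  j_bica: float = 0.0,
                  constants: EnergeticsConstants | None = None) -> EnergyBudget:
    """ATP and NADPH demand before photon conversion.

    atp = 3*Vc + 3.5*Vo + lumen-CA cost + pump cost; nadph = 2*(Vc+Vo).
    """
    c = constants or EnergeticsConstants()
    if vc < 0 or vo < 0:
        raise ValueError("rubisco totals must be nonnegative")
    lumen_atp = lumen_ca_atp_cost(j_lumen_ca, c)
    bica_atp = max(j_bica, 0.0) * c.atp_per_hco3_pumped
    atp = c.atp_per_carbox * vc + c.atp_per_oxy * vo + lumen_atp + bica_atp
    nadph = c.nadph_per_rxn * (vc + vo)
    if nadph == 0:
        raise ValueError("Vc + Vo = 0: ATP:NADPH ratio undefined")
    return EnergyBudget(Vc=vc, Vo=vo, atp_total=atp, nadph_total=nadph,
                        atp_nadph_ratio=atp / nadph, lumen_ca_atp=lumen_atp,
                        bica_atp=bica_atp)


def photons_per_reaction(ratio: float, constants: EnergeticsConstants | None = None,
                         mode: Mode = "CEF") -> float:
    """Photons needed per rubisco reaction (carboxylation or oxygenation).

    LEF supplies ``photons_base`` photons and ``atp_base`` ATP per 2 NADPH;
    the ATP shortfall (floored at zero: excess ATP earns no photon credit)
    is covered by CEF at 0.43 ATP/photon or by the malate valve at
    5.45 ATP per 2 NADPH-equivalent with 4 photons per NADPH.
    """
    c = constants or EnergeticsConstants()
    shortfall = max(ratio * c.nadph_base - c.atp_base, 0.0)
    if mode == "CEF":
        return c.photons_base + shortfall / c.cef_atp_per_photon
    if mode == "malate":
        return c.photons_base + (shortfall / c.malate_atp_per_2nadph) \
            * c.nadph_base * c.photons_per_nadph_malate
    raise ValueError(f"unknown mode {mode!r}")


def quantum_yield(budget: EnergyBudget, constants: EnergeticsConstants | None = None,
                  mode: Mode = "CEF") -> EnergyBudget:
    """Fill in photon totals and the quantum yield phi for a budget.

    phi = [(Vc - Vo/2) / (Vc + Vo)] / photons-per-reaction; bounded above
    by 1/photons_base.
    """
    c = constants or EnergeticsConstants()
    vc, vo = budget.Vc, budget.Vo
    if vc + vo <= 0:
        raise ValueError("Vc + Vo = 0: quantum yield undefined")
    p_rxn = photons_per_reaction(budget.atp_nadph_ratio, c, mode)
    photons = p_rxn * (vc + vo)
    phi = net_fixation(vc, vo) / photons
    budget.mode = mode
    budget.photons_total = photons
    budget.quantum_yield = phi
    return budget


def solution_budget(solution, constants: EnergeticsConstants | None = None,
                    mode: Mode = "CEF") -> EnergyBudget:
    """Energy budget of a converged steady-state solution (mol/s basis)."""
    return quantum_yield(
        demand_budget(solution.Vc_total, solution.Vo_total,
                      solution.J_lumenCA, solution.J_BicA, constants),
        constants, mode)


def energy_report(solution, constants: EnergeticsConstants | None = None) -> dict:
    """JSON-serializable energy summary with both rebalancing modes."""
    b_cef = solution_budget(solution, constants, "CEF")
    b_mal = solution_budget(solution, constants, "malate")
    return {
        "Vc_mol_s": b_cef.Vc,
        "Vo_mol_s": b_cef.Vo,
        "net_fixation_mol_s": net_fixation(b_cef.Vc, b_cef.Vo),
        "atp_mol_s": b_cef.atp_total,
        "nadph_mol_s": b_cef.nadph_total,
        "atp_nadph_ratio": b_cef.atp_nadph_ratio,
        "lumen_ca_atp_mol_s": b_cef.lumen_ca_atp,
        "bica_atp_mol_s": b_cef.bica_atp,
        "photons_mol_s_cef": b_cef.photons_total,
        "quantum_yield_cef": b_cef.quantum_yield,
        "photons_mol_s_malate": b_mal.photons_total,
        "quantum_yield_malate": b_mal.quantum_yield,
        "rubisco_saturation": solution.rubisco_saturation(),
    }
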