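"""Local reaction rates and interface flux laws.

All rate functions work in internal units (uM, um, s) and return both the
rate and, where the solver needs them, analytic partial derivatives.
Rubisco follows competitive-inhibition Michaelis--Menten kinetics for
carboxylation and oxygenation; carbonic anhydrase (CA) is a reversible
ping-pong-style form driven by displacement from the CO2/HCO3- equilibrium
at the compartment pH; the spontaneous hydration and (de)protonation steps
use mass-action kinetics with H+ pinned by compartment pH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet, proton_concentration


# ----------------------------------------------------------------------
# rubisco


def rubisco_rates(co2, o2, params: ParameterSet):
    """Carboxylation and oxygenation rates (uM/s per unit Vmax_c density).

    Returns (Vc, Vo) at the tabulated densities: Vc saturates at Rub_Vmax_c
    and Vo at Rub_Vmax_o = kcat_ratio_oc * Rub_Vmax_c.  CO2 and O2 inhibit
    each other competitively.
    """
    co2 = np.asarray(co2, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    if np.any(co2 < 0) or np.any(o2 < 0):
        raise ValueError("concentrations must be nonnegative")
    kc, ko = params.km_co2, params.km_o2
    vc = params.Rub_Vmax_c * co2 / (co2 + kc * (1.0 + o2 / ko))
    vo = params.Rub_Vmax_o * o2 / (o2 + ko * (1.0 + co2 / kc))
    return vc, vo


def rubisco_rates_jac(co2: float, o2: float, params: ParameterSet):
    """(Vc, Vo, dVc/dCO2, dVc/dO2, dVo/dO2, dVo/dCO2) at one point."""
    kc, ko = params.km_co2, params.km_o2
    dc = co2 + kc * (1.0 + o2 / ko)
    do = o2 + ko * (1.0 + co2 / kc)
    vc = params.Rub_Vmax_c * co2 / dc
    vo = params.Rub_Vmax_o * o2 / do
    dvc_dc = params.Rub_Vmax_c * (dc - co2) / dc**2
    dvc_do = -params.Rub_Vmax_c * co2 * (kc / ko) / dc**2
    dvo_do = params.Rub_Vmax_o * (do - o2) / do**2
    dvo_dc = -params.Rub_Vmax_o * o2 * (ko / kc) / do**2
    return vc, vo, dvc_dc, dvc_do, dvo_do, dvo_dc


# ----------------------------------------------------------------------
# carbonic anhydrase


def ca_rate(co2, hco3, pH: float, conc_ca: float, params: ParameterSet):
    """Net CA-catalyzed hydration rate (uM/s), positive = CO2 -> HCO3-.

    Vanishes exactly at [HCO3-][H+] = Keq [CO2]; at low substrate the
    forward arm reduces to conc * kcat * [CO2] / Km_CO2.
    """
    if params.CA_Keq <= 0:
        raise ValueError("CA_Keq must be positive")
    co2 = np.asarray(co2, dtype=float)
    hco3 = np.asarray(hco3, dtype=float)
    h = proton_concentration(pH)
    num = conc_ca * params.CA_kcat * (co2 - hco3 * h / params.CA_Keq)
    den = params.CA_Km_CO2 + hco3 * (params.CA_Km_CO2 / params.CA_Km_HCO3) + co2
    return num / den


def ca_rate_jac(co2: float, hco3: float, pH: float, conc_ca: float,
                params: ParameterSet):
    """(rate, d/dCO2, d/dHCO3) of :func:`ca_rate` at one point."""
    h = proton_concentration(pH)
    k = conc_ca * params.CA_kcat
    keq = params.CA_Keq
    kmr = params.CA_Km_CO2 / params.CA_Km_HCO3
    num = k * (co2 - hco3 * h / keq)
    den = params.CA_Km_CO2 + hco3 * kmr + co2
    rate = num / den
    d_co2 = (k * den - num) / den**2
    d_hco3 = (-k * h / keq * den - num * kmr) / den**2
    return rate, d_co2, d_hco3


# ----------------------------------------------------------------------
# spontaneous DIC chemistry


def spontaneous_dic_rates(co2, h2co3, hco3, pH: float, params: ParameterSet):
    """Mass-action rates of the two spontaneous DIC steps (uM/s).

    Returns (hydration, deprotonation): hydration = kf_hyd*[CO2] -
    kr_dehyd*[H2CO3] (CO2 -> H2CO3 positive); deprotonation =
    kf_deprot*[H2CO3] - kr_prot*[H+]*[HCO3-] (H2CO3 -> HCO3- positive).
    [H+] is fixed by the compartment pH.
    """
    co2 = np.asarray(co2, dtype=float)
    h2co3 = np.asarray(h2co3, dtype=float)
    hco3 = np.asarray(hco3, dtype=float)
    h = proton_concentration(pH)
    hyd = params.kf_hyd * co2 - params.kr_dehyd * h2co3
    deprot = params.kf_deprot * h2co3 - params.kr_prot * h * hco3
    return hyd, deprot


# ----------------------------------------------------------------------
# interface flux laws


def membrane_flux(P: float, outside, inside):
    """Passive flux density P*(outside - inside), uM*um/s (antisymmetric)."""
    if P < 0:
        raise ValueError("permeability must be nonnegative")
    return P * (np.asarray(outside, dtype=float) - np.asarray(inside, dtype=float))


def bica_flux(hco3_source, vmax: float, km: float):
    """Unidirectional pump flux density, Michaelis--Menten in the source
    bicarbonate: vmax*S/(km+S), same units as vmax (mol/(m^2 s))."""
    s = np.asarray(hco3_source, dtype=float)
    return vmax * s / (km + s)


#: mol/(m^2 s) over um^2 -> uM um^3/s
BICA_AREA_FLUX_TO_INTERNAL = 1e9


def wall_series_conductance(species: str, params: ParameterSet, area: float,
                            delta_w: float | None = None) -> float:
    """Series film+wall conductance for one species over ``area`` (um^3/s)."""
    from .geometry import series_conductance  # local import avoids a cycle
    d = {"CO2": params.D_CO2, "H2CO3": params.D_H2CO3,
         "HCO3": params.D_HCO3, "O2": params.D_O2}[species]
    dw = params.apoplast_thickness if delta_w is None else delta_w
    return series_conductance(d, area, dw, params.effective_porosity,
                              params.wall_thickness)


def stomatal_flux(co2_ext_gas: float, co2_sub_gas: float, g_s: float,
                  leaf_area: float) -> float:
    """Stomatal gas flux, uM um^3/s, for gas-phase concentrations in uM.

    ``leaf_area`` is the per-cell share of leaf surface in um^2 (exchanging
    cell surface divided by the mesophyll:leaf area ratio).
    """
    return g_s * leaf_area * 24.79e3 * (co2_ext_gas - co2_sub_gas)


# ----------------------------------------------------------------------
# photorespiration / O2-evolution coupling


@dataclass(frozen=True)
class O2Stoichiometry:
    """Coupling of rubisco turnover to O2 sources and sinks.

    The oxygenation reaction itself always consumes 1 O2 at rubisco (it is
    part of the Vo rate law).  On top of that, ``evolved_per_carbox`` and
    ``evolved_per_oxy`` O2 are released in the stroma by the light
    reactions, and ``photoresp_o2_per_oxy`` O2 are consumed in the cytosol
    by the photorespiratory pathway.  The default gives a net cellular O2
    balance of Vc - 1.5*Vo; the "farquhar" preset (evolution tracking total
    electron demand) gives Vc - 0.5*Vo.
    """

    evolved_per_carbox: float = 1.0
    evolved_per_oxy: float = 0.0
    photoresp_o2_per_oxy: float = 0.5

    @classmethod
    def preset(cls, name: str) -> "O2Stoichiometry":
        if name == "default":
            return cls()
        if name == "farquhar":
            return cls(evolved_per_carbox=1.0, evolved_per_oxy=1.0,
                       photoresp_o2_per_oxy=0.5)
        raise ValueError(f"unknown O2 stoichiometry preset {name!r}")


def coupled_sources(vc_total: float, vo_total: float,
                    stoich: O2Stoichiometry | None = None) -> dict[str, float]:
    """Well-mixed source totals (uM um^3/s) driven by global rubisco fluxes.

    Photorespiration releases half a CO2 per oxygenation in the cytosol
    (the mitochondria are not resolved); O2 couplings follow ``stoich``.
    """
    if vc_total < 0 or vo_total < 0:
        raise ValueError("rubisco totals must be nonnegative")
    s = stoich or O2Stoichiometry()
    return {
        "co2_cytosol": 0.5 * vo_total,
        "o2_stroma": s.evolved_per_carbox * vc_total + s.evolved_per_oxy * vo_total,
        "o2_cytosol": -s.photoresp_o2_per_oxy * vo_total,
    }
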