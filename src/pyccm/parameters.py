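"""Parameter registry and unit conversions.

All quantities are stored in a single internal unit system:

* length  — micrometres (um)
* time    — seconds (s)
* amount  — micromolar (uM = umol / L); one "internal amount unit" is
  1 uM * um^3 = 1e-21 mol.

Every literature value (m/s membrane permeabilities, mol/m^3 Michaelis
constants, mol/(m^2 s) pump capacities, ...) is converted once, on
construction, so the rest of the package never sees mixed units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

#: litres of air per mole at the reference temperature/pressure used for
#: gas-phase mole-fraction <-> concentration conversions.
MOLAR_VOLUME_AIR_L = 24.79

#: 1 uM * um^3 expressed in moles.
MOL_PER_INTERNAL_AMOUNT = 1e-21


def ppm_to_micromolar_gas(ppm: float) -> float:
    """Convert a gas-phase mixing ratio (ppm) to a molar concentration (uM).

    A mixing ratio of x umol gas per mol of air occupies ``MOLAR_VOLUME_AIR_L``
    litres, so the concentration is ``x / 24.79`` uM.  412 ppm CO2 maps to
    ~16.62 uM.
    """
    if ppm < 0:
        raise ValueError(f"mixing ratio must be nonnegative, got {ppm}")
    return ppm / MOLAR_VOLUME_AIR_L


def micromolar_gas_to_ppm(um: float) -> float:
    """Inverse of :func:`ppm_to_micromolar_gas`."""
    if um < 0:
        raise ValueError(f"concentration must be nonnegative, got {um}")
    return um * MOLAR_VOLUME_AIR_L


def partialpressure_to_micromolar_gas(atm: float) -> float:
    """Convert a partial pressure (atm) to a gas-phase concentration (uM).

    0.2095 atm O2 maps to ~8450.98 uM.
    """
    if atm < 0:
        raise ValueError(f"partial pressure must be nonnegative, got {atm}")
    return atm * 1e6 / MOLAR_VOLUME_AIR_L


def proton_concentration(pH: float) -> float:
    """[H+] in uM for a given pH."""
    return 10.0 ** (-pH) * 1e6


KmOrdering = Literal["transposed", "as_printed"]


@dataclass(frozen=True)
class ParameterSet:
    """The complete model constant registry (internal units: um, s, uM).

    Default values are the study's baseline constants after unit
    normalization.  ``km_ordering`` controls the assignment of the two
    rubisco Michaelis constants: the "transposed" default gives
    Km_CO2 = 8.6 uM and Km_O2 = 215 uM, the ordering consistent with known
    plant rubisco kinetics (specificity factor ~120) and with the printed
    compensation points; "as_printed" swaps them.
    """

    # -- diffusivities in water, um^2/s
    D_CO2: float = 1.88e3
    D_H2CO3: float = 1.2e3
    D_HCO3: float = 1.15e3
    D_O2: float = 2.42e3

    # -- lipid-bilayer permeabilities, um/s
    P_CO2: float = 3.5e3        # 3.50e-3 m/s (Gutknecht); scans go up to 3.2e-2 m/s
    P_H2CO3: float = 30.0
    P_HCO3: float = 0.05
    P_O2: float = 7.5e5         # 75 cm/s

    # -- facilitated (channel) HCO3- permeabilities, um/s
    P_HCO3_BLP: float = 1.0e4   # bestrophin-like channels, thylakoid membrane (1e-2 m/s)
    P_HCO3_LCIA: float = 1.0e-2  # chloroplast envelope channel (1e-8 m/s)

    # -- spontaneous DIC chemistry
    kf_hyd: float = 6e-2        # CO2 + H2O -> H2CO3, 1/s
    kr_dehyd: float = 2e1       # H2CO3 -> CO2 + H2O, 1/s
    kf_deprot: float = 1e7      # H2CO3 -> HCO3- + H+, 1/s
    kr_prot: float = 5e4        # HCO3- + H+ -> H2CO3, 1/(uM s)  (5e10 1/(M s))

    # -- carbonic anhydrase
    CA_kcat: float = 0.3e6      # 1/s
    CA_Km_CO2: float = 1.5e3    # uM (1.5 mol/m^3)
    CA_Km_HCO3: float = 3.4e4   # uM (34 mol/m^3)
    CA_Keq: float = 0.56        # uM; apparent [HCO3][H+]/[CO2] equilibrium constant
    CA_conc_stroma: float = 270.0   # uM
    CA_conc_cytosol: float = 135.0  # uM
    CA_conc_lumen: float = 135.0    # uM
    CA_conc_apoplast: float = 135.0  # uM, used only when an apoplastic CA is enabled

    # -- rubisco
    Rub_Vmax_c: float = 7.6e3   # uM/s
    Rub_Vmax_o: float = 1.596e3  # uM/s = 0.21 * Vmax_c
    Rub_Km_CO2: float = 8.6     # uM (see km_ordering)
    Rub_Km_O2: float = 215.0    # uM
    kcat_ratio_oc: float = 0.21
    km_ordering: KmOrdering = "transposed"

    # -- BicA bicarbonate pump (per membrane area; converted at assembly)
    BicA_Vmax: float = 1.85e-4  # mol/(m^2 s)
    BicA_Km: float = 217.0      # uM (0.217 mol/m^3)

    # -- external environment
    g_s: float = 0.4375         # stomatal conductance, mol/(m^2 s) per leaf area
    CO2_ext_ppm: float = 412.0
    O2_ext: float = 0.2095      # partial pressure, atm

    # -- cell wall / boundary layers, um
    wall_thickness: float = 0.32       # angiosperm default; 1.6 for hornworts
    effective_porosity: float = 0.2    # porosity / tortuosity; 1e-4 for hornworts
    boundary_thickness: float = 0.32   # algal unstirred boundary layer
    apoplast_thickness: float = 0.32   # land-plant surface water layer
    ratio_mesophyll_area: float = 15.0  # mesophyll cell area : leaf area
    IAS_adjacent: float = 0.5          # fraction of cell surface facing airspace

    # -- pyrenoid starch sheath
    starch_sheath_multiplier: float = 0.1

    #: conductance multiplier on the thylakoid-tubule interfaces (both the
    #: stroma and pyrenoid contacts, all species).  The tubule system is
    #: idealized as 6 coarse cylinders standing in for many finer tubules;
    #: the multiplier lets the per-area transport across the idealized
    #: interfaces be scaled to probe that simplification (quantum yield and
    #: rubisco saturation shift by under ten percent per decade of it).
    thylakoid_interface_multiplier: float = 1.0

    # -- geometry, um
    r_pyrenoid: float = 1.0
    r_thylakoid: float = 0.5    # tubule cylinder radius
    h_thylakoid: float = 4.0    # tubule cylinder height
    r_chloroplast: float = 4.63
    r_cytosol: float = 8.77
    r_plasmalemma: float = 9.23
    r_substomatal: float = 11.63
    n_tubules: int = 6

    # -- compartment pH
    pH_apoplast: float = 6.0
    pH_ocean: float = 8.0
    pH_cytosol: float = 7.2
    pH_stroma: float = 8.0
    pH_lumen: float = 6.0

    # -- dimensionless diffusivity divisors
    visc_cytosol: float = 2.0
    visc_stroma: float = 10.0
    visc_thylakoid: float = 10.0
    visc_pyrenoid: float = 10.0

    # -- dimensionless Henry constants, gas-phase / aqueous concentration ratio
    H_CO2: float = 1.2
    H_O2: float = 32.0

    T_ref: float = 25.0  # degC, reference only; no temperature dependence modeled

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "D_CO2", "D_H2CO3", "D_HCO3", "D_O2",
            "P_CO2", "P_H2CO3", "P_HCO3", "P_O2", "P_HCO3_BLP", "P_HCO3_LCIA",
            "kf_hyd", "kr_dehyd", "kf_deprot", "kr_prot",
            "CA_kcat", "CA_Km_CO2", "CA_Km_HCO3", "CA_Keq",
            "Rub_Vmax_c", "Rub_Vmax_o", "Rub_Km_CO2", "Rub_Km_O2",
            "BicA_Vmax", "BicA_Km", "g_s",
            "wall_thickness", "boundary_thickness", "apoplast_thickness",
            "ratio_mesophyll_area", "thylakoid_interface_multiplier",
            "r_pyrenoid", "r_thylakoid", "h_thylakoid", "r_chloroplast",
            "r_cytosol", "r_plasmalemma", "r_substomatal",
            "visc_cytosol", "visc_stroma", "visc_thylakoid", "visc_pyrenoid",
            "H_CO2", "H_O2",
        ]
        for name in positive:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not 0 < self.effective_porosity <= 1:
            raise ValueError(f"effective_porosity must be in (0, 1], got {self.effective_porosity}")
        if not 0 <= self.IAS_adjacent <= 1:
            raise ValueError(f"IAS_adjacent must be in [0, 1], got {self.IAS_adjacent}")
        if not 0 < self.starch_sheath_multiplier <= 1:
            raise ValueError(
                f"starch_sheath_multiplier must be in (0, 1], got {self.starch_sheath_multiplier}")
        for name in ("pH_apoplast", "pH_ocean", "pH_cytosol", "pH_stroma", "pH_lumen"):
            v = getattr(self, name)
            if not 0 < v < 14:
                raise ValueError(f"{name} must be a pH in (0, 14), got {v}")
        if not (self.r_pyrenoid < self.r_chloroplast < self.r_cytosol
                < self.r_plasmalemma < self.r_substomatal):
            raise ValueError(
                "radii must satisfy r_pyrenoid < r_chloroplast < r_cytosol "
                "< r_plasmalemma < r_substomatal")
        if self.CO2_ext_ppm < 0 or self.O2_ext < 0:
            raise ValueError("external concentrations must be nonnegative")

    # -- derived quantities -------------------------------------------------

    @property
    def km_co2(self) -> float:
        """Effective rubisco Km for CO2 under the selected ordering (uM)."""
        return self.Rub_Km_CO2 if self.km_ordering == "transposed" else self.Rub_Km_O2

    @property
    def km_o2(self) -> float:
        """Effective rubisco Km for O2 under the selected ordering (uM)."""
        return self.Rub_Km_O2 if self.km_ordering == "transposed" else self.Rub_Km_CO2

    @property
    def spontaneous_keq(self) -> float:
        """[HCO3][H+]/[CO2] implied by the spontaneous rate constants (uM)."""
        return (self.kf_hyd / self.kr_dehyd) * (self.kf_deprot / self.kr_prot)

    def o2_ext_gas_uM(self) -> float:
        return partialpressure_to_micromolar_gas(self.O2_ext)

    def co2_ext_gas_uM(self) -> float:
        return ppm_to_micromolar_gas(self.CO2_ext_ppm)

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))


# frozen dataclass: __post_init__ needs object.__setattr__-free validation only,
# which is the case above (validate reads, never writes).


def default_parameters() -> ParameterSet:
    """The full baseline constant registry in internal units."""
    return ParameterSet()


def equilibrium_dic(co2_uM: float, pH: float, params: ParameterSet) -> dict[str, float]:
    """DIC speciation at chemical equilibrium with a given aqueous CO2 (uM).

    Uses the spontaneous-chemistry constants: H2CO3 = (kf/kr)*CO2 and
    HCO3- = kf_deprot*H2CO3 / (kr_prot*[H+]).
    """
    h2co3 = co2_uM * params.kf_hyd / params.kr_dehyd
    hco3 = h2co3 * params.kf_deprot / (params.kr_prot * proton_concentration(pH))
    return {"CO2": co2_uM, "H2CO3": h2co3, "HCO3": hco3}
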