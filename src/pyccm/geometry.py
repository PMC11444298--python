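"""Concentric-compartment geometry for each scenario.

The cell is spherically symmetric: pyrenoid (optional), stroma, cytosol and
a surface-water layer are concentric shells; the thylakoid-tubule system is
a single well-mixed aqueous compartment whose contact areas with the stroma
(cylinder walls) and the pyrenoid (cylinder end caps) come from the
6-cylinder tubule idealization.  Outside the cell sit, depending on the
organism, a substomatal gas space (land plant), the open atmosphere
(hornwort) or bulk sea water (alga); the cell wall and the unstirred film
are not meshed but enter as a series conductance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .parameters import ParameterSet
from .scenarios import ConfigurationError, ScenarioConfig

SPECIES = ("CO2", "H2CO3", "HCO3", "O2")


def sphere_area(r: float) -> float:
    return 4.0 * math.pi * r * r


def shell_volume(r_in: float, r_out: float) -> float:
    return 4.0 * math.pi / 3.0 * (r_out**3 - r_in**3)


@dataclass
class Compartment:
    """A model compartment: a radial shell or a well-mixed pocket."""

    name: str
    r_inner: float
    r_outer: float
    pH: float
    viscosity: float
    phase: str = "aqueous"  # "aqueous" | "gas"
    well_mixed: bool = False
    volume: float | None = None  # explicit for well-mixed pockets
    rubisco_density: float = 0.0  # uM/s catalytic density (Vmax_c basis)
    ca_entries: tuple[tuple[float, float], ...] = ()  # (concentration uM, pH used)

    def __post_init__(self) -> None:
        if not self.well_mixed and not self.r_inner < self.r_outer:
            raise ConfigurationError(
                f"compartment {self.name}: r_inner must be < r_outer "
                f"({self.r_inner} vs {self.r_outer})")
        if self.volume is None:
            self.volume = shell_volume(self.r_inner, self.r_outer)

    @property
    def thickness(self) -> float:
        return self.r_outer - self.r_inner


@dataclass
class Transporter:
    name: str
    vmax: float  # mol/(m^2 s)
    km: float    # uM
    species: str
    source: str  # compartment name on the substrate side
    dest: str    # compartment name receiving the flux


@dataclass
class Interface:
    """A labelled connection between two compartments (or to the exterior).

    ``kind`` selects the flux law used at assembly:

    * ``membrane``   — P * (outside - inside) per species
    * ``series_gas`` — wall + unstirred-film series conductance with Henry
      partitioning, gas phase on the outer side (CO2/O2 only)
    * ``series_bulk``— the same series law between bulk medium and the
      surface water layer, aqueous on both sides (all species)
    * ``stomata``    — stomatal gas exchange with the external atmosphere
    * ``distributed``— membrane law with the contact area spread over the
      nodes of a radial compartment (thylakoid contacts)
    """

    name: str
    kind: str
    area: float
    inner: str  # compartment name (or "external")
    outer: str
    species_permeability: dict = field(default_factory=dict)  # um/s per species
    conductance: dict = field(default_factory=dict)  # um^3/s per species (series/stomata)
    transporters: list = field(default_factory=list)
    geometry_source: str = "sphere"

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ConfigurationError(f"interface {self.name}: area must be positive")
        for sp, p in self.species_permeability.items():
            if p < 0:
                raise ConfigurationError(
                    f"interface {self.name}: negative permeability for {sp}")


@dataclass
class GeometryModel:
    scenario: ScenarioConfig
    params: ParameterSet
    compartments: list
    interfaces: list
    exterior: str  # "gas_node" | "gas_dirichlet" | "bulk_dirichlet"

    def compartment(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def has(self, name: str) -> bool:
        return any(c.name == name for c in self.compartments)

    def to_json(self) -> str:
        """Inspection/regression dump of compartments and interfaces."""
        return json.dumps({
            "exterior": self.exterior,
            "compartments": [
                {"name": c.name, "r_inner": c.r_inner, "r_outer": c.r_outer,
                 "volume": c.volume, "pH": c.pH, "viscosity": c.viscosity,
                 "phase": c.phase, "well_mixed": c.well_mixed,
                 "rubisco_density": c.rubisco_density,
                 "ca_entries": list(map(list, c.ca_entries))}
                for c in self.compartments],
            "interfaces": [
                {"name": i.name, "kind": i.kind, "area": i.area,
                 "inner": i.inner, "outer": i.outer,
                 "species_permeability": i.species_permeability,
                 "conductance": i.conductance,
                 "transporters": [t.name for t in i.transporters]}
                for i in self.interfaces],
        }, indent=2)


# ----------------------------------------------------------------------


def series_conductance(d_w: float, area: float, delta_w: float,
                       porosity: float, delta_wall: float) -> float:
    """Series combination of unstirred-film and cell-wall conductances.

    Each layer has per-area permeability D/delta (film) and
    D*porosity/delta (wall); multiplied by area these are conductances in
    um^3/s, combined as resistances in series.  A vanishing porosity gives
    conductance 0 (fully sealed wall), not an error.
    """
    if porosity < 0:
        raise ConfigurationError("porosity must be nonnegative")
    if porosity == 0:
        return 0.0
    g_film = d_w * area / delta_w
    g_wall = d_w * porosity * area / delta_wall
    return 1.0 / (1.0 / g_film + 1.0 / g_wall)


def bilayer_permeabilities(p: ParameterSet, fold: float) -> dict[str, float]:
    return {"CO2": p.P_CO2 * fold, "H2CO3": p.P_H2CO3,
            "HCO3": p.P_HCO3, "O2": p.P_O2}


def build_geometry(scenario: ScenarioConfig) -> GeometryModel:
    """Resolve a scenario into compartments and labelled interfaces."""
    p = scenario.parameters()
    fold = scenario.permeability_fold
    ccm = scenario.ccm
    organism = scenario.organism

    rub_density = scenario.rubisco_density
    if rub_density is None:
        rub_density = p.Rub_Vmax_c * ((p.r_chloroplast / p.r_pyrenoid) ** 3 if ccm else 1.0)

    compartments: list[Compartment] = []
    interfaces: list[Interface] = []

    # --- intracellular shells -----------------------------------------
    if ccm:
        compartments.append(Compartment(
            "pyrenoid", 0.0, p.r_pyrenoid, pH=p.pH_stroma, viscosity=p.visc_pyrenoid,
            rubisco_density=rub_density,
            # the lumenal CA is localized to the pyrenoid but runs at the
            # thylakoid-lumen pH; DIC in pyrenoid and thylakoid stay separate
            ca_entries=((p.CA_conc_lumen, p.pH_lumen),)))
        stroma_inner = p.r_pyrenoid
        stroma_density = 0.0
    else:
        stroma_inner = 0.0
        stroma_density = rub_density
    compartments.append(Compartment(
        "stroma", stroma_inner, p.r_chloroplast, pH=p.pH_stroma, viscosity=p.visc_stroma,
        rubisco_density=stroma_density,
        ca_entries=((p.CA_conc_stroma, p.pH_stroma),)))
    compartments.append(Compartment(
        "cytosol", p.r_chloroplast, p.r_cytosol, pH=p.pH_cytosol, viscosity=p.visc_cytosol,
        ca_entries=((p.CA_conc_cytosol, p.pH_cytosol),)))

    # --- surface water layer ------------------------------------------
    if organism == "alga":
        surf_name, surf_pH = "boundary_water", p.pH_ocean
        surf_thick = p.boundary_thickness
        surf_ca: tuple = ()
    else:
        surf_name, surf_pH = "apoplast", p.pH_apoplast
        surf_thick = p.apoplast_thickness
        surf_ca = ((p.CA_conc_apoplast, surf_pH),) if scenario.apoplast_ca else ()
    r_surf_out = p.r_cytosol + surf_thick
    compartments.append(Compartment(
        surf_name, p.r_cytosol, r_surf_out, pH=surf_pH, viscosity=1.0,
        ca_entries=surf_ca))

    r_wall_out = r_surf_out + p.wall_thickness

    # --- thylakoid pocket ---------------------------------------------
    if ccm:
        v_thyl = p.n_tubules * math.pi * p.r_thylakoid**2 * p.h_thylakoid
        compartments.append(Compartment(
            "thylakoid", 0.0, 0.0, pH=p.pH_lumen, viscosity=p.visc_thylakoid,
            well_mixed=True, volume=v_thyl))

    # --- exterior ------------------------------------------------------
    if organism == "land_plant":
        if not r_wall_out < p.r_substomatal:
            raise ConfigurationError(
                "substomatal radius must exceed the wall outer radius "
                f"({p.r_substomatal} vs {r_wall_out})")
        compartments.append(Compartment(
            "substomatal_gas", r_wall_out, p.r_substomatal, pH=7.0, viscosity=1.0,
            phase="gas", well_mixed=True))
        exterior = "gas_node"
    elif organism == "hornwort":
        exterior = "gas_dirichlet"
    else:
        exterior = "bulk_dirichlet"

    # --- interfaces ----------------------------------------------------
    bilayer = bilayer_permeabilities(p, fold)

    if ccm:
        sheath = {sp: p.starch_sheath_multiplier * perm for sp, perm in bilayer.items()}
        interfaces.append(Interface(
            "starch_sheath", "membrane", sphere_area(p.r_pyrenoid),
            inner="pyrenoid", outer="stroma", species_permeability=sheath))

        # bestrophin-like channels carry HCO3-; all per-area permeabilities
        # are scaled by the tubule surface:volume correction
        m10 = p.thylakoid_interface_multiplier
        thyl_perm = {sp: m10 * perm for sp, perm in
                     dict(bilayer, HCO3=p.P_HCO3 + p.P_HCO3_BLP).items()}
        a_lateral = p.n_tubules * 2 * math.pi * p.r_thylakoid * p.h_thylakoid
        a_caps = p.n_tubules * math.pi * p.r_thylakoid**2
        interfaces.append(Interface(
            "thylakoid_stroma", "distributed", a_lateral,
            inner="thylakoid", outer="stroma", species_permeability=thyl_perm,
            geometry_source="cylinder_set"))
        interfaces.append(Interface(
            "thylakoid_pyrenoid", "distributed", a_caps,
            inner="thylakoid", outer="pyrenoid", species_permeability=thyl_perm,
            geometry_source="cylinder_set"))

    env_perm = dict(bilayer)
    if ccm:
        env_perm["HCO3"] = p.P_HCO3 + p.P_HCO3_LCIA
    env_transporters = []
    if scenario.bica_placement == "chloroplast_envelope":
        env_transporters.append(Transporter(
            "BicA", scenario.bica_vmax(p), p.BicA_Km, "HCO3",
            source="cytosol", dest="stroma"))
    interfaces.append(Interface(
        "chloroplast_envelope", "membrane", sphere_area(p.r_chloroplast),
        inner="stroma", outer="cytosol", species_permeability=env_perm,
        transporters=env_transporters))

    pl_transporters = []
    if scenario.bica_placement == "plasmalemma":
        pl_transporters.append(Transporter(
            "BicA", scenario.bica_vmax(p), p.BicA_Km, "HCO3",
            source=surf_name, dest="cytosol"))
    interfaces.append(Interface(
        "plasmalemma", "membrane", sphere_area(p.r_cytosol),
        inner="cytosol", outer=surf_name, species_permeability=dict(bilayer),
        transporters=pl_transporters))

    # wall + film series conductance to the exterior
    diffusivity = {"CO2": p.D_CO2, "H2CO3": p.D_H2CO3, "HCO3": p.D_HCO3, "O2": p.D_O2}
    if organism == "alga":
        a_exch = sphere_area(r_surf_out)
        cond = {sp: series_conductance(d, a_exch, p.boundary_thickness,
                                       p.effective_porosity, p.wall_thickness)
                for sp, d in diffusivity.items()}
        interfaces.append(Interface(
            "wall_water_series", "series_bulk", a_exch,
            inner=surf_name, outer="external", conductance=cond))
    else:
        a_exch = sphere_area(r_surf_out) * p.IAS_adjacent
        if a_exch <= 0:
            raise ConfigurationError("IAS_adjacent must be positive for gas exchange")
        cond = {sp: series_conductance(diffusivity[sp], a_exch, p.apoplast_thickness,
                                       p.effective_porosity, p.wall_thickness)
                for sp in ("CO2", "O2")}
        outer = "substomatal_gas" if organism == "land_plant" else "external"
        interfaces.append(Interface(
            "wall_water_series", "series_gas", a_exch,
            inner=surf_name, outer=outer, conductance=cond))

    if organism == "land_plant":
        # stomatal exchange, scaled from leaf area to the per-cell gas space
        a_cell_exch = sphere_area(r_wall_out) * p.IAS_adjacent
        a_leaf = a_cell_exch / p.ratio_mesophyll_area
        # mol/(m^2 s) per mole-fraction -> um^3/s on gas-phase uM:
        # flux[mol/s] = g_s * A[m^2] * dX, dX = dC[uM] * 24.79e-6 / 1e6 * 1e6...
        g_stom = p.g_s * a_leaf * 24.79e3
        interfaces.append(Interface(
            "stomata", "stomata", a_leaf,
            inner="substomatal_gas", outer="external",
            conductance={"CO2": g_stom, "O2": g_stom},
            geometry_source="leaf_scaling"))

    return GeometryModel(scenario, p, compartments, interfaces, exterior)
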