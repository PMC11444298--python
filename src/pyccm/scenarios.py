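"""Scenario configuration: every model variant the pipeline can run.

A :class:`ScenarioConfig` bundles the organism, the CCM on/off switch, the
bicarbonate-pump placement and a handful of overrides; it is the single
"synthetic input" the rest of the pipeline consumes.  The four headline
scenarios (land plant and alga, each with and without a pyrenoid CCM) are
constructible by name via :func:`named_scenario`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import yaml

from .parameters import (
    MOLAR_VOLUME_AIR_L,
    ParameterSet,
    default_parameters,
    equilibrium_dic,
    partialpressure_to_micromolar_gas,
    ppm_to_micromolar_gas,
)

Organism = Literal["land_plant", "alga", "hornwort"]
BicaPlacement = Literal["none", "chloroplast_envelope", "plasmalemma"]

_ORGANISMS = ("land_plant", "alga", "hornwort")
_PLACEMENTS = ("none", "chloroplast_envelope", "plasmalemma")

#: organism-specific cell-wall defaults (thickness um, effective porosity)
_WALL_DEFAULTS = {
    "land_plant": (0.32, 0.2),
    "alga": (0.32, 0.2),
    "hornwort": (1.6, 1e-4),
}


class ConfigurationError(ValueError):
    """Raised for invalid or conflicting scenario options."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One runnable model variant.

    ``external_CO2`` is in ppm for land_plant/hornwort and in uM aqueous for
    alga (the alga sits in sea water, not air).  ``permeability_fold``
    multiplies the CO2 permeability of every lipid bilayer;
    ``bica_vmax_fold`` scales the pump capacity (0 disables it even when a
    placement is set).
    """

    organism: Organism = "land_plant"
    ccm: bool = False
    bica_placement: BicaPlacement = "none"
    apoplast_ca: bool = False
    apoplast_pH_override: float | None = None
    external_CO2: float | None = None  # ppm (land/hornwort) or uM aqueous (alga)
    permeability_fold: float = 1.0
    porosity_override: float | None = None
    bica_vmax_fold: float = 1.0
    parameter_overrides: dict = field(default_factory=dict)
    label: str = ""
    # rubisco catalytic density in its compartment, uM/s; derived once at
    # build time so radius perturbations keep protein densities constant
    rubisco_density: float | None = None

    def __post_init__(self) -> None:
        if self.organism not in _ORGANISMS:
            raise ConfigurationError(f"unknown organism {self.organism!r}")
        if self.bica_placement not in _PLACEMENTS:
            raise ConfigurationError(f"unknown BicA placement {self.bica_placement!r}")
        if self.permeability_fold <= 0:
            raise ConfigurationError("permeability_fold must be positive")
        if self.bica_vmax_fold < 0:
            raise ConfigurationError("bica_vmax_fold must be nonnegative")
        if self.organism == "alga" and (self.apoplast_ca or self.apoplast_pH_override is not None):
            raise ConfigurationError(
                "apoplast_ca / apoplast_pH_override apply only to land_plant or hornwort")
        unknown = set(self.parameter_overrides) - set(ParameterSet.field_names())
        if unknown:
            raise ConfigurationError(f"unknown parameter override(s): {sorted(unknown)}")

    # ------------------------------------------------------------------

    def parameters(self) -> ParameterSet:
        """The fully resolved :class:`ParameterSet` for this scenario."""
        wall, porosity = _WALL_DEFAULTS[self.organism]
        changes: dict = {"wall_thickness": wall, "effective_porosity": porosity}
        changes.update(self.parameter_overrides)
        if self.porosity_override is not None:
            changes["effective_porosity"] = self.porosity_override
        if self.apoplast_pH_override is not None:
            changes["pH_apoplast"] = self.apoplast_pH_override
        if self.external_CO2 is not None and self.organism != "alga":
            changes["CO2_ext_ppm"] = self.external_CO2
        return default_parameters().replace(**changes)

    def bilayer_P_CO2(self, params: ParameterSet | None = None) -> float:
        p = params or self.parameters()
        return p.P_CO2 * self.permeability_fold

    def bica_vmax(self, params: ParameterSet | None = None) -> float:
        """Effective pump Vmax, mol/(m^2 s); 0 when no placement selected."""
        if self.bica_placement == "none":
            return 0.0
        p = params or self.parameters()
        return p.BicA_Vmax * self.bica_vmax_fold

    def external_co2_gas_uM(self) -> float:
        """External CO2 as a gas-phase concentration in uM.

        For the alga the stated aqueous concentration is converted to its
        gas-phase equivalent through the Henry constant (used only for
        reporting compensation points in ppm).
        """
        p = self.parameters()
        if self.organism == "alga":
            aq = self.external_CO2 if self.external_CO2 is not None else (
                ppm_to_micromolar_gas(p.CO2_ext_ppm) / p.H_CO2)
            return aq * p.H_CO2
        return ppm_to_micromolar_gas(p.CO2_ext_ppm)

    def with_external_co2(self, value: float) -> "ScenarioConfig":
        """Copy of this scenario at a different external CO2 (same units)."""
        return dataclasses.replace(self, external_CO2=value)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["parameters"] = dict(d.pop("parameter_overrides"))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        overrides = d.pop("parameters", d.pop("parameter_overrides", {})) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(parameter_overrides=dict(overrides), **d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(data)


# ----------------------------------------------------------------------


def build_scenario(
    organism: str,
    ccm: bool,
    bica_placement: str = "none",
    options: dict | None = None,
) -> ScenarioConfig:
    """Build and validate a scenario, deriving the rubisco density.

    In no-CCM models rubisco fills the chloroplast at the tabulated Vmax
    density; in with-CCM models the same total catalytic capacity is
    condensed into the pyrenoid, so the pyrenoid density is the tabulated
    value scaled by the chloroplast:pyrenoid volume ratio.  The density is
    frozen here so later radius perturbations keep it constant.
    """
    options = dict(options or {})
    label = options.pop("label", "")
    cfg = ScenarioConfig(
        organism=organism,  # type: ignore[arg-type]
        ccm=ccm,
        bica_placement=bica_placement,  # type: ignore[arg-type]
        label=label,
        **options,
    )
    p = cfg.parameters()
    if ccm:
        density = p.Rub_Vmax_c * (p.r_chloroplast / p.r_pyrenoid) ** 3
    else:
        density = p.Rub_Vmax_c
    return dataclasses.replace(cfg, rubisco_density=density)


_NAMED = {
    "land_plant_with_ccm": ("land_plant", True),
    "land_plant_without_ccm": ("land_plant", False),
    "alga_with_ccm": ("alga", True),
    "alga_without_ccm": ("alga", False),
    "hornwort_with_ccm": ("hornwort", True),
    "hornwort_without_ccm": ("hornwort", False),
}


def named_scenario(name: str, **options) -> ScenarioConfig:
    """Construct one of the documented base scenarios by name."""
    if name not in _NAMED:
        raise ConfigurationError(
            f"unknown scenario {name!r}; choose from {sorted(_NAMED)}")
    organism, ccm = _NAMED[name]
    options.setdefault("label", name)
    return build_scenario(organism, ccm, "none", options)


def table_scenarios() -> dict[str, ScenarioConfig]:
    """The four base model variants used for compensation-point work."""
    return {name: named_scenario(name) for name in (
        "land_plant_with_ccm", "land_plant_without_ccm",
        "alga_with_ccm", "alga_without_ccm")}


# ----------------------------------------------------------------------

_RADIUS_FIELDS = {"r_pyrenoid", "r_thylakoid", "h_thylakoid", "r_chloroplast",
                  "r_cytosol", "r_plasmalemma", "r_substomatal"}


def perturb(config: ScenarioConfig, symbol: str, factor: float) -> ScenarioConfig:
    """Scenario with one parameter (or radius) multiplied by ``factor``.

    Radius perturbations recompute the dependent areas and volumes through
    the geometry builder while every other radius stays fixed; per-area and
    per-volume protein densities are held constant (the frozen
    ``rubisco_density`` is carried over unchanged).
    """
    if factor <= 0:
        raise ValueError(f"perturbation factor must be positive, got {factor}")
    if symbol not in ParameterSet.field_names():
        raise KeyError(f"unknown parameter symbol {symbol!r}")
    base = getattr(config.parameters(), symbol)
    if not isinstance(base, (int, float)) or isinstance(base, bool):
        raise KeyError(f"parameter {symbol!r} is not numeric")
    overrides = dict(config.parameter_overrides)
    overrides[symbol] = base * factor
    return dataclasses.replace(config, parameter_overrides=overrides)


# ----------------------------------------------------------------------


def external_boundary_values(config: ScenarioConfig) -> dict[str, float]:
    """Concentrations at the outer boundary of the model, internal units.

    Land plant / hornwort: gas-phase CO2 and O2 in uM.  Alga: bulk aqueous
    concentrations of all four species, with DIC speciated at the ocean pH
    (the bulk medium is held at chemical equilibrium outside the unstirred
    boundary layer, so bicarbonate is abundant externally).
    """
    p = config.parameters()
    if config.organism == "alga":
        co2_aq = config.external_CO2 if config.external_CO2 is not None else (
            ppm_to_micromolar_gas(p.CO2_ext_ppm) / p.H_CO2)
        dic = equilibrium_dic(co2_aq, p.pH_ocean, p)
        return {
            "CO2": dic["CO2"],
            "H2CO3": dic["H2CO3"],
            "HCO3": dic["HCO3"],
            "O2": partialpressure_to_micromolar_gas(p.O2_ext) / p.H_O2,
        }
    return {
        "CO2_gas": ppm_to_micromolar_gas(p.CO2_ext_ppm),
        "O2_gas": partialpressure_to_micromolar_gas(p.O2_ext),
    }
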