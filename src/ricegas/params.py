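"""Central registry of emission factors, physical constants and conversions.

All pathway calculations draw their constants from :class:`EmissionParams`.
Every field carries a unit in its description and a provenance string in
:data:`PROVENANCE`, so reports can emit a fully cited parameter table.
Masses are handled per hectare per year; the functional unit is the yield
from one hectare of rice land.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "EmissionParams",
    "HerdModel",
    "StrawBiomass",
    "PROVENANCE",
    "load_params",
    "weighted_ym",
    "straw_yield",
    "to_dry_matter",
]

C_TO_CO2 = 44.0 / 12.0
N2ON_TO_N2O = 44.0 / 28.0


class EmissionParams(BaseModel):
    """All constants of the farm-scale GHG accounting, with defaults.

    Defaults describe the Eastern-India rice-wheat study system: current
    mean rice grain yield, IPCC Tier-2 livestock coefficients for the
    Indian subcontinent, country-specific open-burning emission factors,
    medium-temperature pyrolysis biochar, and AR6 100-year GWPs.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    grain_yield_t_ha: float = Field(3.77, ge=0, description="rice grain yield, t/ha fresh")
    straw_ratio_R: float = Field(1.5, ge=0, description="grain-to-straw production ratio, -")
    dm_fraction_D: float = Field(0.86, ge=0, le=1, description="dry-matter fraction of fresh straw, -")
    burn_efficiency_B: float = Field(0.89, ge=0, le=1, description="open-burning combustion completeness, -")
    straw_energy_Es: float = Field(14.08, ge=0, description="HHV energy density of rice straw, MJ/kg DM")
    methane_energy_ECH4: float = Field(55.65, ge=0, description="energy density of methane, MJ/kg")
    ym_fraction: float = Field(0.0474, ge=0, le=1, description="enteric CH4 conversion, fraction of gross energy")
    digestible_energy_DE: float = Field(0.55, ge=0, le=1, description="digestible energy fraction of feed, -")
    urinary_energy_UE: float = Field(0.04, ge=0, le=1, description="urinary energy as fraction of GE, -")
    ash_fraction_ASH: float = Field(0.08, ge=0, le=1, description="ash content of manure, fraction of DM intake")
    vs_energy_divisor: float = Field(18.45, gt=0, description="GE density of dry feed, MJ/kg")
    bo_m3_per_kgVS: float = Field(0.13, ge=0, description="max CH4 producing capacity of manure, m3/kg VS")
    ch4_density_kg_m3: float = Field(0.67, ge=0, description="density of CH4, kg/m3")
    mcf: float = Field(0.05, ge=0, le=1, description="methane conversion factor, solid storage, warm climate")
    nf_fraction: float = Field(0.022, ge=0, le=1, description="N fraction of VS, dry ash-free basis")
    efn_kgN2ON_per_kgN: float = Field(0.01, ge=0, description="manure-storage direct N2O EF, kg N2O-N/kg N")
    cookstove_ef_ch4_kg_TJ: float = Field(281.0, ge=0, description="cookstove CH4 EF, kg/TJ")
    cookstove_ef_n2o_kg_TJ: float = Field(27.0, ge=0, description="cookstove N2O EF, kg/TJ")
    dung_ncv_MJ_kg: float = Field(17.8, ge=0, description="net caloric value of dry cattle dung, MJ/kg")
    fperm: float = Field(0.71, ge=0, le=1, description="biochar C fraction persisting after 100 yr, -")
    lignin_Lf: float = Field(0.179, ge=0, le=1, description="lignin mass fraction of rice straw, dry basis")
    pyrolysis_T_K: float = Field(798.15, gt=0, description="pyrolysis temperature, K (525 C, medium range)")
    pyc_fraction_Pf: float = Field(0.11, ge=0, le=1, description="pyrogenic C fraction surviving open burn, -")
    pyc_retained_Pr: float = Field(0.9895, ge=0, le=1, description="fraction of PyC remaining on site, -")
    burn_ef_ch4_g_kg: float = Field(9.59, ge=0, description="open-burning CH4 EF, g/kg residue")
    burn_ef_n2o_g_kg: float = Field(0.48, ge=0, description="open-burning N2O EF, g/kg residue")
    gwp_ch4: float = Field(27.9, gt=1, description="100-yr GWP of CH4, -")
    gwp_n2o: float = Field(273.0, gt=1, description="100-yr GWP of N2O, -")
    c_to_co2: float = Field(C_TO_CO2, description="stoichiometric C -> CO2, 44/12")
    n2on_to_n2o: float = Field(N2ON_TO_N2O, description="stoichiometric N2O-N -> N2O, 44/28")
    manure_field_split: float = Field(0.5, ge=0, le=1, description="fraction of VS returned to field (rest to cookstove)")
    rice_season_start_day: int = Field(183, ge=1, le=365, description="Julian day rice season starts")

    @field_validator("c_to_co2")
    @classmethod
    def _exact_c_to_co2(cls, v: float) -> float:
        if v != C_TO_CO2:
            raise ValueError("c_to_co2 must be exactly 44/12")
        return v

    @field_validator("n2on_to_n2o")
    @classmethod
    def _exact_n2on(cls, v: float) -> float:
        if v != N2ON_TO_N2O:
            raise ValueError("n2on_to_n2o must be exactly 44/28")
        return v

    def provenance(self, field: str) -> str:
        """Citation string for one parameter."""
        return PROVENANCE[field]


#: Source citation for every parameter, kept verbatim-adjacent to the study's
#: reference list so reports can print a cited parameter table.
PROVENANCE: dict[str, str] = {
    "grain_yield_t_ha": "mean observed yield of rice cv. Sarju52, West Champaran 2021 crop-cut data (n=210)",
    "straw_ratio_R": "crop production to straw ratio for rice (regional residue inventory)",
    "dm_fraction_D": "dry matter fraction of fresh rice straw (regional residue inventory)",
    "burn_efficiency_B": "burn efficiency fraction for open field burning of rice straw (Turn et al.)",
    "straw_energy_Es": "HHV of rice straw, MJ/kg DM (biomass energy handbook)",
    "methane_energy_ECH4": "energy content of methane (IPCC 2006 guidelines)",
    "ym_fraction": "herd-weighted enteric CH4 conversion factor, 4.74% of GE (20th Livestock Census herd model x IPCC Tier 2 category factors)",
    "digestible_energy_DE": "digestible energy coefficient for the Indian subcontinent (IPCC 2006)",
    "urinary_energy_UE": "urinary energy fraction for most ruminants (IPCC 2006)",
    "ash_fraction_ASH": "ash content of cattle manure (IPCC 2006)",
    "vs_energy_divisor": "gross-energy density of dry feed, 18.45 MJ/kg (IPCC 2006 VS equation)",
    "bo_m3_per_kgVS": "Bo for dairy cattle, Indian subcontinent (IPCC 2006)",
    "ch4_density_kg_m3": "CH4 density at reference conditions, 0.67 kg/m3 (IPCC 2006)",
    "mcf": "MCF for solid manure storage, warm annual average temperature (IPCC 2019 refinement)",
    "nf_fraction": "N in manure volatile solids, 2.2% dry ash-free, conservative for low-intensity systems",
    "efn_kgN2ON_per_kgN": "direct N2O EF for solid manure storage, IPCC default (source citation ambiguous in study; config-overridable)",
    "cookstove_ef_ch4_kg_TJ": "Tier 1 CH4 EF for dung-fuelled cookstoves (IPCC 2006)",
    "cookstove_ef_n2o_kg_TJ": "Tier 1 N2O EF for dung-fuelled cookstoves (IPCC 2006)",
    "dung_ncv_MJ_kg": "net caloric value of dry cattle dung, 17.8 MJ/kg",
    "fperm": "biochar permanence fraction over 100 yr at 14.9 C cropland MAT, medium-T pyrolysis (SE 0.03, recorded as metadata only)",
    "lignin_Lf": "lignin mass fraction of rice residues, dry basis (Phyllis2 database)",
    "pyrolysis_T_K": "assumed medium pyrolysis temperature 525 C (450-600 C range)",
    "pyc_fraction_Pf": "1 - burn efficiency: pyrogenic carbon fraction after open burn",
    "pyc_retained_Pr": "fraction of PyC remaining on site, excluding atmospheric black carbon",
    "burn_ef_ch4_g_kg": "country-specific Tier 2 CH4 EF for rice residue burning",
    "burn_ef_n2o_g_kg": "country-specific Tier 2 N2O EF for rice residue burning",
    "gwp_ch4": "AR6 100-yr GWP for CH4",
    "gwp_n2o": "AR6 100-yr GWP for N2O",
    "c_to_co2": "molar mass ratio CO2/C",
    "n2on_to_n2o": "molar mass ratio N2O/N2",
    "manure_field_split": "half of stored manure returned to field, half burned in cookstoves (farmer interviews)",
    "rice_season_start_day": "rice season Julian day 183 (field water-tube monitoring window start)",
}


@dataclass(frozen=True)
class HerdModel:
    """Representative herd composition with per-category CH4 conversion factors.

    ``categories`` holds ``(label, herd_fraction, ym_percent)`` tuples; herd
    fractions must sum to 1 and ym is expressed in percent of gross energy.
    """

    categories: Sequence[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("herd model needs at least one category")
        total = sum(f for _, f, _ in self.categories)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"herd fractions sum to {total!r}, expected 1")
        for label, frac, ym in self.categories:
            if frac < 0 or ym < 0:
                raise ValueError(f"negative fraction or ym in category {label!r}")


@dataclass(frozen=True)
class StrawBiomass:
    """Fresh straw yield and its dry-matter equivalent for one hectare-year."""

    fresh_t_ha: float
    dm_kg_ha: float

    def __post_init__(self) -> None:
        if self.fresh_t_ha < 0 or self.dm_kg_ha < 0:
            raise ValueError("straw masses must be non-negative")


class ConfigError(ValueError):
    """Raised for unknown keys or malformed parameter configuration."""


def load_params(config_source: str | Path | Mapping[str, Any] | None = None) -> EmissionParams:
    """Build an :class:`EmissionParams`, overlaying overrides on the defaults.

    Parameters
    ----------
    config_source
        ``None`` for pure defaults, a mapping of field overrides, or a path
        to a YAML/JSON file containing such a mapping.

    Raises
    ------
    ConfigError
        If the config contains a key that is not an ``EmissionParams`` field.
    pydantic.ValidationError
        If any override violates a field bound (e.g. a fraction > 1).
    """
    if config_source is None:
        overrides: Mapping[str, Any] = {}
    elif isinstance(config_source, Mapping):
        overrides = config_source
    else:
        text = Path(config_source).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"parameter file must hold a mapping, got {type(loaded).__name__}")
        overrides = loaded

    unknown = set(overrides) - set(EmissionParams.model_fields)
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
    return EmissionParams(**overrides)


def weighted_ym(herd: HerdModel) -> float:
    """Herd-composition-weighted enteric CH4 conversion factor, as a fraction.

    Each livestock category contributes its CH4 conversion factor (percent
    of gross feed energy) weighted by its share of the herd; the result is
    returned as a fraction (percent / 100).
    """
    pct = sum(frac * ym for _, frac, ym in herd.categories)
    return pct / 100.0


def straw_yield(grain_yield: float, ratio_R: float) -> float:
    """Fresh straw yield (t/ha) from grain yield and the straw ratio."""
    if grain_yield < 0 or ratio_R < 0:
        raise ValueError("grain yield and straw ratio must be non-negative")
    return grain_yield * ratio_R


def to_dry_matter(fresh_t_ha: float, dm_fraction: float) -> float:
    """Convert fresh straw (t/ha) to dry matter (kg/ha)."""
    if fresh_t_ha < 0 or dm_fraction < 0:
        raise ValueError("inputs must be non-negative")
    if dm_fraction > 1:
        raise ValueError(f"dry-matter fraction {dm_fraction} exceeds 1")
    return fresh_t_ha * 1000.0 * dm_fraction


def straw_biomass(params: EmissionParams) -> StrawBiomass:
    """Fresh and dry straw mass for one hectare under the given parameters."""
    fresh = straw_yield(params.grain_yield_t_ha, params.straw_ratio_R)
    return StrawBiomass(fresh_t_ha=fresh, dm_kg_ha=to_dry_matter(fresh, params.dm_fraction_D))
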