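"""Non-soil emissions of the livestock-fodder pathway.

All rice straw from one hectare is fed to a representative herd. Enteric
CH4 is a Tier-2 fraction (Ym) of the straw's gross energy. The excreted
manure (volatile solids, VS) is stored daily — storage CH4 and direct N2O
apply to the full VS — and then split: half returned to the field five
days before the rice season (the soil model handles its consequences) and
half burned in cookstoves with Tier-1 fuel-combustion emission factors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import EmissionParams, straw_biomass
from .reporting import GasInventory

__all__ = [
    "ManureBudget",
    "AmendmentSchedule",
    "gross_energy",
    "enteric_ch4",
    "volatile_solids",
    "manure_storage_ch4",
    "manure_storage_n2o",
    "cookstove_emissions",
    "field_amendment",
    "livestock_pathway",
    "manure_budget",
]


@dataclass(frozen=True)
class ManureBudget:
    """Energy and volatile-solids budget for one hectare-year of straw feed."""

    gross_energy_MJ: float
    vs_total_kg: float
    vs_to_field_kg: float
    vs_to_cookstove_kg: float
    field_n_kg: float

    def __post_init__(self) -> None:
        if min(self.gross_energy_MJ, self.vs_total_kg, self.vs_to_field_kg,
               self.vs_to_cookstove_kg, self.field_n_kg) < 0:
            raise ValueError("manure budget terms must be non-negative")
        if abs(self.vs_to_field_kg + self.vs_to_cookstove_kg - self.vs_total_kg) > 1e-9:
            raise ValueError("field + cookstove VS must equal total VS")


@dataclass(frozen=True)
class AmendmentSchedule:
    """Field manure application: timing, dry mass and nitrogen content."""

    application_julian_day: int
    manure_dm_kg_ha: float
    n_fraction: float
    n_kg_ha: float


def gross_energy(straw_dm_kg: float, es: float) -> float:
    """Gross energy (MJ) of the straw consumed: mass x energy density."""
    if straw_dm_kg < 0 or es < 0:
        raise ValueError("inputs must be non-negative")
    return straw_dm_kg * es


def enteric_ch4(straw_dm_kg: float, es: float, ym: float, e_ch4: float) -> float:
    """Enteric CH4 (kg): Ym fraction of gross feed energy, divided by CH4 energy density."""
    if not 0 <= ym <= 1:
        raise ValueError("ym must be a fraction in [0, 1]")
    if straw_dm_kg < 0 or es < 0:
        raise ValueError("inputs must be non-negative")
    if e_ch4 <= 0:
        raise ValueError("methane energy density must be positive")
    return ym * straw_dm_kg * es / e_ch4


def volatile_solids(ge_MJ: float, de: float, ue: float, ash: float, divisor: float = 18.45) -> float:
    """Volatile solids excreted (kg, dry organic matter).

    VS = [GE(1 - DE) + UE*GE] * (1 - ASH) / 18.45 — indigestible plus urinary
    energy, converted to dry mass with the feed gross-energy density and
    corrected for ash.
    """
    for name, f in (("de", de), ("ue", ue), ("ash", ash)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must be a fraction in [0, 1]")
    if divisor <= 0:
        raise ValueError("energy divisor must be positive")
    if ge_MJ < 0:
        raise ValueError("gross energy must be non-negative")
    return (ge_MJ * (1.0 - de) + ue * ge_MJ) * (1.0 - ash) / divisor


def manure_storage_ch4(vs_kg: float, bo: float, density: float, mcf: float) -> float:
    """CH4 (kg) from manure storage: VS x Bo x CH4 density x MCF."""
    if min(vs_kg, bo, density, mcf) < 0:
        raise ValueError("inputs must be non-negative")
    return vs_kg * bo * density * mcf


def manure_storage_n2o(vs_kg: float, nf: float, efn: float, n2on_to_n2o: float = 44.0 / 28.0) -> float:
    """Direct N2O (kg) from manure storage: N in VS x EF x N2O-N -> N2O."""
    if min(vs_kg, nf, efn, n2on_to_n2o) < 0:
        raise ValueError("inputs must be non-negative")
    return nf * vs_kg * efn * n2on_to_n2o


def cookstove_emissions(
    manure_dm_kg: float, ncv_MJ_kg: float, ef_ch4: float, ef_n2o: float
) -> tuple[float, float]:
    """CH4 and N2O (kg) from burning dung in cookstoves.

    Fuel combusted FC (TJ) = dry dung mass x NCV x 1e-6; each gas is
    FC x its Tier-1 emission factor (kg/TJ).
    """
    if min(manure_dm_kg, ncv_MJ_kg, ef_ch4, ef_n2o) < 0:
        raise ValueError("inputs must be non-negative")
    fc_TJ = manure_dm_kg * ncv_MJ_kg * 1e-6
    return fc_TJ * ef_ch4, fc_TJ * ef_n2o


def field_amendment(
    vs_total_kg: float, field_split: float, n_fraction: float, rice_start_day: int
) -> AmendmentSchedule:
    """Schedule the field manure return: five days before the rice season."""
    if not 0 <= field_split <= 1:
        raise ValueError("field split must be a fraction in [0, 1]")
    if rice_start_day <= 5:
        raise ValueError("rice season start day must exceed 5 for pre-season application")
    dm = vs_total_kg * field_split
    return AmendmentSchedule(
        application_julian_day=rice_start_day - 5,
        manure_dm_kg_ha=dm,
        n_fraction=n_fraction,
        n_kg_ha=dm * n_fraction,
    )


def manure_budget(params: EmissionParams) -> ManureBudget:
    """Gross energy and VS budget for one hectare's straw under ``params``."""
    straw = straw_biomass(params)
    ge = gross_energy(straw.dm_kg_ha, params.straw_energy_Es)
    vs = volatile_solids(
        ge,
        params.digestible_energy_DE,
        params.urinary_energy_UE,
        params.ash_fraction_ASH,
        params.vs_energy_divisor,
    )
    to_field = vs * params.manure_field_split
    return ManureBudget(
        gross_energy_MJ=ge,
        vs_total_kg=vs,
        vs_to_field_kg=to_field,
        vs_to_cookstove_kg=vs - to_field,
        field_n_kg=to_field * params.nf_fraction,
    )


def livestock_pathway(params: EmissionParams) -> GasInventory:
    """All non-soil livestock emissions, by component, for one hectare-year.

    Components: enteric fermentation, manure-storage CH4 and N2O (on the
    full VS, stored daily before either use), and cookstove CH4 and N2O on
    the non-field half of the manure.
    """
    straw = straw_biomass(params)
    budget = manure_budget(params)
    ent = enteric_ch4(
        straw.dm_kg_ha, params.straw_energy_Es, params.ym_fraction, params.methane_energy_ECH4
    )
    st_ch4 = manure_storage_ch4(
        budget.vs_total_kg, params.bo_m3_per_kgVS, params.ch4_density_kg_m3, params.mcf
    )
    st_n2o = manure_storage_n2o(
        budget.vs_total_kg, params.nf_fraction, params.efn_kgN2ON_per_kgN, params.n2on_to_n2o
    )
    ck_ch4, ck_n2o = cookstove_emissions(
        budget.vs_to_cookstove_kg,
        params.dung_ncv_MJ_kg,
        params.cookstove_ef_ch4_kg_TJ,
        params.cookstove_ef_n2o_kg_TJ,
    )
    return GasInventory.from_components(
        [
            ("enteric_ch4", ent, 0.0),
            ("storage_ch4", st_ch4, 0.0),
            ("storage_n2o", 0.0, st_n2o),
            ("cookstove_ch4", ck_ch4, 0.0),
            ("cookstove_n2o", 0.0, ck_n2o),
        ],
        params,
    )


def livestock_amendment(params: EmissionParams) -> AmendmentSchedule:
    """Field manure amendment implied by the livestock pathway defaults."""
    budget = manure_budget(params)
    return field_amendment(
        budget.vs_total_kg,
        params.manure_field_split,
        params.nf_fraction,
        params.rice_season_start_day,
    )
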