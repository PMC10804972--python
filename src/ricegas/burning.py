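"""Open-burning pathway: combustion CH4/N2O and the on-site pyrogenic-carbon credit.

All available straw is assumed burned in the field. Combustion CO2 is
biogenic-neutral, so only CH4 and N2O are counted, with country-specific
emission factors. The uncombusted fraction (1 - burn efficiency) forms
pyrogenic carbon; the share remaining on site earns the same 100-year
permanence credit as biochar. Atmospheric black carbon is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .biochar import biochar_yield_fraction, net_avoided_ghg
from .params import EmissionParams

__all__ = [
    "BurningResult",
    "residue_burned_mass",
    "burning_emissions",
    "pyc_credit",
    "burning_pathway",
]


@dataclass(frozen=True)
class BurningResult:
    """Combustion emissions and pyrogenic-carbon credit for one hectare-year."""

    mass_burned_kg: float
    ch4_kg: float
    n2o_kg: float
    pyc_credit_MgCO2e: float  # positive credit
    net_nonsoil_MgCO2e: float  # combustion CO2-e minus credit


def residue_burned_mass(grain_kg: float, ratio_R: float, dm_fraction: float, burn_eff: float) -> float:
    """Dry residue mass combusted (kg): grain x straw ratio x DM x burn efficiency."""
    if min(grain_kg, ratio_R, dm_fraction, burn_eff) < 0:
        raise ValueError("inputs must be non-negative")
    if dm_fraction > 1 or burn_eff > 1:
        raise ValueError("fractions must not exceed 1")
    return grain_kg * ratio_R * dm_fraction * burn_eff


def burning_emissions(mass_burned_kg: float, ef_ch4_g_kg: float, ef_n2o_g_kg: float) -> tuple[float, float]:
    """CH4 and N2O (kg) from open burning, per-kg emission factors in g/kg."""
    if min(mass_burned_kg, ef_ch4_g_kg, ef_n2o_g_kg) < 0:
        raise ValueError("inputs must be non-negative")
    return mass_burned_kg * ef_ch4_g_kg / 1000.0, mass_burned_kg * ef_n2o_g_kg / 1000.0


def pyc_credit(
    fby: float, straw_fresh_kg: float, dm_fraction: float, pf: float, pr: float, fperm: float
) -> float:
    """Avoided GHG (Mg CO2-e) from pyrogenic C remaining on site after the burn.

    Mbc = Fby x fresh straw x DM x Pf x Pr, then the 100-year permanence
    credit (x Fperm x 44/12).
    """
    for name, f in (("fby", fby), ("dm_fraction", dm_fraction), ("pf", pf),
                    ("pr", pr), ("fperm", fperm)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must be a fraction in [0, 1]")
    if straw_fresh_kg < 0:
        raise ValueError("straw mass must be non-negative")
    mbc = fby * straw_fresh_kg * dm_fraction * pf * pr
    return net_avoided_ghg(mbc, fperm)


def burning_pathway(params: EmissionParams) -> BurningResult:
    """Full burning chain for one hectare's straw under ``params``."""
    grain_kg = params.grain_yield_t_ha * 1000.0
    burned = residue_burned_mass(
        grain_kg, params.straw_ratio_R, params.dm_fraction_D, params.burn_efficiency_B
    )
    ch4, n2o = burning_emissions(burned, params.burn_ef_ch4_g_kg, params.burn_ef_n2o_g_kg)
    fby = biochar_yield_fraction(params.lignin_Lf, params.pyrolysis_T_K)
    straw_fresh_kg = grain_kg * params.straw_ratio_R
    credit = pyc_credit(
        fby, straw_fresh_kg, params.dm_fraction_D,
        params.pyc_fraction_Pf, params.pyc_retained_Pr, params.fperm,
    )
    combustion = (ch4 * params.gwp_ch4 + n2o * params.gwp_n2o) / 1000.0
    return BurningResult(
        mass_burned_kg=burned,
        ch4_kg=ch4,
        n2o_kg=n2o,
        pyc_credit_MgCO2e=credit,
        net_nonsoil_MgCO2e=combustion - credit,
    )
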