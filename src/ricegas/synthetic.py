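"""Synthetic field hydrographs and soil-flux series for pipeline testing.

Real inputs are (a) daily field water-tube observations and (b) annual soil
fluxes from a process-based model; neither is deposited publicly. This
module generates stand-ins with the statistical structure the analysis
assumes: a cohort of fields spanning drained-dominant to flooded-dominant
rice seasons, and lognormal interannual flux series whose category means
match the study system (no-residue CH4 means of 0.08 / 0.22 / 0.31
Mg/ha/yr for dry / median / wet, residue return adding 0.03 / 0.10 /
0.14 Mg). It makes no claim of biogeochemical realism beyond these summary
statistics; it is not a process-model emulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hydrology import RICE_SEASON_END, RICE_SEASON_START, WaterLevelSeries
from .soilflux import SoilFluxSeries

__all__ = [
    "HydroGenConfig",
    "FluxGenConfig",
    "gen_water_levels",
    "gen_soil_flux_series",
    "NO_RESIDUE_CH4_MEANS_MG",
    "RESIDUE_CH4_INCREMENT_MG",
    "N2O_MEANS_KG",
    "SOC_DELTA_KGC",
]

#: No-residue-return mean annual CH4 (Mg/ha/yr) by hydrology category.
NO_RESIDUE_CH4_MEANS_MG = {"dry": 0.08, "median": 0.22, "wet": 0.31}
#: Additional mean annual CH4 (Mg/ha/yr) when residues are returned.
RESIDUE_CH4_INCREMENT_MG = {"dry": 0.03, "median": 0.10, "wet": 0.14}
#: Mean annual N2O (kg/ha/yr) by category (fixture values within the
#: simulated 0.010-0.020 range; drier sites emit more N2O).
N2O_MEANS_KG = {"dry": 0.020, "median": 0.015, "wet": 0.010}
#: Mean annual SOC change (kg C/ha/yr): none without residue return, a
#: small accrual with it (fixture value; long-run stock gains are small).
SOC_DELTA_KGC = {False: 0.0, True: 30.0}

#: Day-to-day water-level spread (cm) of the latent AR(1) process.
SIGMA_DAY_CM = 10.0


@dataclass(frozen=True)
class HydroGenConfig:
    """Cohort-level controls for the synthetic hydrograph generator.

    ``climate_wetness`` is the year-level propensity of a day being flooded
    at an average field; ``field_sd`` (cm) spreads field mean levels so the
    cohort spans near-always-drained to near-always-flooded; ``persistence``
    is the lag-1 autocorrelation of the daily level.
    """

    n_fields: int = 35
    climate_wetness: float = 0.5
    field_sd: float = 8.0
    persistence: float = 0.85
    seed: int = 0
    climate_year: int = 0
    initial_level: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_fields < 3:
            raise ValueError("need at least 3 fields")
        if not 0 <= self.climate_wetness <= 1:
            raise ValueError("climate_wetness must be in [0, 1]")
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must be in [0, 1]")
        if self.field_sd < 0:
            raise ValueError("field_sd must be non-negative")


@dataclass(frozen=True)
class FluxGenConfig:
    """Controls for one synthetic annual soil-flux series."""

    category: str = "median"
    residue_returned: bool = False
    mean_ch4_Mg: Optional[float] = None  # default: category mean (+ increment if residue)
    cv_interannual: float = 0.3
    mean_n2o_kg: Optional[float] = None
    mean_soc_delta_kgC: Optional[float] = None
    n_years: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in NO_RESIDUE_CH4_MEANS_MG:
            raise ValueError(f"unknown category {self.category!r}")
        if self.cv_interannual < 0:
            raise ValueError("cv must be non-negative")
        if self.n_years < 1:
            raise ValueError("n_years must be positive")
        for name in ("mean_ch4_Mg", "mean_n2o_kg"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def resolved_means(self) -> tuple[float, float, float]:
        ch4 = self.mean_ch4_Mg
        if ch4 is None:
            ch4 = NO_RESIDUE_CH4_MEANS_MG[self.category]
            if self.residue_returned:
                ch4 += RESIDUE_CH4_INCREMENT_MG[self.category]
        n2o = self.mean_n2o_kg if self.mean_n2o_kg is not None else N2O_MEANS_KG[self.category]
        soc = (
            self.mean_soc_delta_kgC
            if self.mean_soc_delta_kgC is not None
            else SOC_DELTA_KGC[self.residue_returned]
        )
        return ch4, n2o, soc


def _wetness_to_mean_level(wetness: float) -> float:
    """Field mean level (cm) at which a Normal(mu, SIGMA_DAY) day floods
    with probability ``wetness`` (probit link, clipped to avoid infinities)."""
    from scipy.stats import norm  # local import keeps module import light

    w = min(max(wetness, 1e-6), 1 - 1e-6)
    return SIGMA_DAY_CM * float(norm.ppf(w))


def gen_water_levels(config: HydroGenConfig) -> list[WaterLevelSeries]:
    """Generate one rice season of daily water levels for a field cohort.

    Each field gets a mean-level offset drawn Normal(0, field_sd) around
    the climate-year level implied by ``climate_wetness``; daily levels
    follow a stationary AR(1) around that mean and are clipped to
    [-100, +30] cm. Seeded and fully reproducible.
    """
    rng = np.random.default_rng(config.seed)
    n_days = RICE_SEASON_END - RICE_SEASON_START + 1
    days = tuple(range(RICE_SEASON_START, RICE_SEASON_END + 1))
    mu_year = _wetness_to_mean_level(config.climate_wetness)
    p = config.persistence
    innov_sd = SIGMA_DAY_CM * math.sqrt(max(0.0, 1.0 - p * p))

    out = []
    for i in range(config.n_fields):
        mu = mu_year + rng.normal(0.0, config.field_sd)
        if config.initial_level is not None:
            x = config.initial_level
        elif p == 1.0:
            x = mu
        else:
            x = rng.normal(mu, SIGMA_DAY_CM)
        levels = np.empty(n_days)
        levels[0] = x
        eps = rng.normal(0.0, 1.0, size=n_days - 1)
        for t in range(1, n_days):
            x = mu + p * (x - mu) + innov_sd * eps[t - 1]
            levels[t] = x
        levels = np.clip(levels, -100.0, 30.0)
        out.append(
            WaterLevelSeries(
                field_id=f"F{i:03d}",
                climate_year=config.climate_year,
                julian_days=days,
                levels_cm=tuple(float(v) for v in levels),
            )
        )
    return out


def _lognormal_draws(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal sample with the given arithmetic mean and coefficient of variation."""
    if mean == 0.0 or cv == 0.0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def gen_soil_flux_series(config: FluxGenConfig) -> SoilFluxSeries:
    """Generate a synthetic annual soil-flux series.

    CH4 and N2O are independent lognormal draws with the configured means
    and interannual CV (sample means converge to the configured means as
    the horizon grows); the SOC change is Normal with SD = CV x |mean|
    (it may legitimately be negative).
    """
    rng = np.random.default_rng(config.seed)
    mean_ch4_Mg, mean_n2o, mean_soc = config.resolved_means()
    ch4_kg = _lognormal_draws(rng, mean_ch4_Mg * 1000.0, config.cv_interannual, config.n_years)
    n2o_kg = _lognormal_draws(rng, mean_n2o, config.cv_interannual, config.n_years)
    if mean_soc == 0.0 or config.cv_interannual == 0.0:
        soc = np.full(config.n_years, mean_soc)
    else:
        soc = rng.normal(mean_soc, config.cv_interannual * abs(mean_soc), size=config.n_years)
    return SoilFluxSeries(
        pathway_label="synthetic",
        hydrology_category=config.category,
        residue_returned=config.residue_returned,
        years=tuple(range(1, config.n_years + 1)),
        ch4_kg_ha=tuple(float(v) for v in ch4_kg),
        n2o_kg_ha=tuple(float(v) for v in n2o_kg),
        soc_delta_kgC_ha=tuple(float(v) for v in soc),
    )
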