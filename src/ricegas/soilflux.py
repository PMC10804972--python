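"""Aggregation of annual soil-flux series into season-average net CO2-e.

Annual CH4, N2O and SOC-change trajectories come from a process-based
soil biogeochemistry model (or the synthetic generator); this module turns
them into the horizon-mean net soil flux (gases converted with 100-year
GWPs, SOC gain entering as a negative CO2 term) and computes the
residue-return effect statistics (absolute and percent CH4 difference,
with/without-residue ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .params import EmissionParams

__all__ = [
    "SoilFluxSeries",
    "SoilFluxSummary",
    "read_soil_flux_series",
    "season_average_soil_co2e",
    "residue_effect_stats",
]

REQUIRED_COLUMNS = ("year", "ch4_kg_ha", "n2o_kg_ha")


@dataclass(frozen=True)
class SoilFluxSeries:
    """Annual CH4 / N2O / delta-SOC trajectory for one pathway x category."""

    pathway_label: str
    hydrology_category: str
    residue_returned: bool
    years: tuple[int, ...]
    ch4_kg_ha: tuple[float, ...]
    n2o_kg_ha: tuple[float, ...]
    soc_delta_kgC_ha: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.years)
        if n < 1:
            raise ValueError("soil flux series must have at least one year")
        if not (len(self.ch4_kg_ha) == len(self.n2o_kg_ha) == len(self.soc_delta_kgC_ha) == n):
            raise ValueError("column lengths differ")
        if list(self.years) != list(range(self.years[0], self.years[0] + n)):
            raise ValueError("year indices must be contiguous")
        if min(self.ch4_kg_ha) < 0 or min(self.n2o_kg_ha) < 0:
            raise ValueError("gas fluxes must be non-negative")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "ch4_kg_ha": self.ch4_kg_ha,
                "n2o_kg_ha": self.n2o_kg_ha,
                "soc_delta_kgC_ha": self.soc_delta_kgC_ha,
            }
        )


@dataclass(frozen=True)
class SoilFluxSummary:
    """Horizon means and the net soil CO2-e per ha-year."""

    mean_ch4_Mg_ha: float
    mean_n2o_kg_ha: float
    mean_soc_delta_MgC_ha: float
    net_soil_MgCO2e: float


def read_soil_flux_series(
    path,
    pathway_label: str = "",
    hydrology_category: str = "",
    residue_returned: bool = False,
) -> SoilFluxSeries:
    """Read an annual soil-flux CSV into a validated :class:`SoilFluxSeries`.

    Expects columns ``year, ch4_kg_ha, n2o_kg_ha`` plus either
    ``soc_delta_kgC_ha`` (direct annual SOC change) or ``soc_stock_kgC_ha``
    (stock trajectory, first-differenced; the first year's delta is 0 since
    no pre-series stock is available). Metadata columns ``pathway``,
    ``category`` and ``residue_returned``, if present, override the
    keyword arguments.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"soil flux CSV missing columns: {missing}")
    if "soc_delta_kgC_ha" in df.columns:
        soc_delta = df["soc_delta_kgC_ha"].to_numpy(dtype=float)
    elif "soc_stock_kgC_ha" in df.columns:
        stock = df["soc_stock_kgC_ha"].to_numpy(dtype=float)
        soc_delta = np.diff(stock, prepend=stock[:1])
    else:
        raise ValueError("soil flux CSV missing columns: ['soc_delta_kgC_ha' or 'soc_stock_kgC_ha']")

    if "pathway" in df.columns:
        pathway_label = str(df["pathway"].iloc[0])
    if "category" in df.columns:
        hydrology_category = str(df["category"].iloc[0])
    if "residue_returned" in df.columns:
        residue_returned = bool(df["residue_returned"].iloc[0])

    return SoilFluxSeries(
        pathway_label=pathway_label,
        hydrology_category=hydrology_category,
        residue_returned=residue_returned,
        years=tuple(int(y) for y in df["year"]),
        ch4_kg_ha=tuple(float(v) for v in df["ch4_kg_ha"]),
        n2o_kg_ha=tuple(float(v) for v in df["n2o_kg_ha"]),
        soc_delta_kgC_ha=tuple(float(v) for v in soc_delta),
    )


def season_average_soil_co2e(
    series: SoilFluxSeries, params: EmissionParams, include_soc: bool = True
) -> SoilFluxSummary:
    """Horizon-mean net soil CO2-e (Mg/ha/yr) for one flux series.

    net = mean CH4 x GWP_CH4 + mean N2O x GWP_N2O - mean annual delta-SOC
    x 44/12. Setting ``include_soc=False`` drops the SOC term (sensitivity
    mode).
    """
    if series.n_years == 0:
        raise ValueError("empty series")
    mean_ch4_kg = float(np.mean(series.ch4_kg_ha))
    mean_n2o_kg = float(np.mean(series.n2o_kg_ha))
    mean_soc_kgC = float(np.mean(series.soc_delta_kgC_ha))
    net = (mean_ch4_kg * params.gwp_ch4 + mean_n2o_kg * params.gwp_n2o) / 1000.0
    if include_soc:
        net -= mean_soc_kgC / 1000.0 * params.c_to_co2
    return SoilFluxSummary(
        mean_ch4_Mg_ha=mean_ch4_kg / 1000.0,
        mean_n2o_kg_ha=mean_n2o_kg,
        mean_soc_delta_MgC_ha=mean_soc_kgC / 1000.0,
        net_soil_MgCO2e=net,
    )


def residue_effect_stats(
    no_residue: SoilFluxSeries, with_residue: SoilFluxSeries
) -> dict[str, Optional[float]]:
    """Residue-return effect on mean annual CH4 flux.

    Returns ``abs_diff_Mg`` (mean with-residue minus mean no-residue, Mg
    CH4/ha/yr), ``pct_diff`` (percent of the no-residue mean) and ``ratio``
    (with / no). When the no-residue mean is zero, ``pct_diff`` and
    ``ratio`` are ``None`` (undefined), not an exception.
    """
    if no_residue.hydrology_category != with_residue.hydrology_category:
        raise ValueError("series must share a hydrology category")
    if no_residue.n_years != with_residue.n_years:
        raise ValueError("series must cover the same number of years")
    mean_no = float(np.mean(no_residue.ch4_kg_ha)) / 1000.0
    mean_with = float(np.mean(with_residue.ch4_kg_ha)) / 1000.0
    diff = mean_with - mean_no
    if mean_no == 0.0:
        return {"abs_diff_Mg": diff, "pct_diff": None, "ratio": None}
    return {"abs_diff_Mg": diff, "pct_diff": diff / mean_no * 100.0, "ratio": mean_with / mean_no}
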