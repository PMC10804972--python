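"""CO2-equivalent conversion, scenario-table assembly and pathway comparisons.

Gas masses are converted to CO2-e with 100-year GWPs (CH4 27.9, N2O 273 by
default). The scenario table mirrors the study layout: four residue
pathways x three hydrology categories, with season-average soil fluxes,
a per-pathway non-soil flux, and cell-wise totals. Credits (biochar,
pyrogenic carbon) enter the non-soil column as negative values so that
total = soil + non-soil holds uniformly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .params import EmissionParams

__all__ = [
    "PATHWAYS",
    "CATEGORIES",
    "GasInventory",
    "ScenarioTable",
    "co2e",
    "build_scenario_table",
    "compare_to_reference",
    "round_half_away",
]

PATHWAYS = ("burning", "incorporation", "livestock", "biochar")
CATEGORIES = ("dry", "median", "wet")


def co2e(ch4_kg: float, n2o_kg: float, params: EmissionParams) -> float:
    """Convert CH4 and N2O masses (kg) to Mg CO2-equivalent."""
    if ch4_kg < 0 or n2o_kg < 0:
        raise ValueError("gas masses must be non-negative; handle credits as signed terms upstream")
    return (ch4_kg * params.gwp_ch4 + n2o_kg * params.gwp_n2o) / 1000.0


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention; machine outputs stay unrounded)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class GasInventory:
    """Component-labelled CH4/N2O masses with CO2-e totals for one pathway.

    ``components`` holds ``(label, ch4_kg, n2o_kg)``; totals are the
    component sums and the CO2-e total uses the GWPs captured at build time.
    """

    components: tuple[tuple[str, float, float], ...]
    gwp_ch4: float
    gwp_n2o: float

    @classmethod
    def from_components(
        cls, components: Sequence[tuple[str, float, float]], params: EmissionParams
    ) -> "GasInventory":
        return cls(tuple(components), params.gwp_ch4, params.gwp_n2o)

    @property
    def ch4_kg(self) -> float:
        return sum(c for _, c, _ in self.components)

    @property
    def n2o_kg(self) -> float:
        return sum(n for _, _, n in self.components)

    @property
    def co2e_Mg(self) -> float:
        return (self.ch4_kg * self.gwp_ch4 + self.n2o_kg * self.gwp_n2o) / 1000.0

    def component_co2e(self) -> dict[str, float]:
        """Per-component CO2-e (Mg), in component order."""
        return {
            label: (c * self.gwp_ch4 + n * self.gwp_n2o) / 1000.0
            for label, c, n in self.components
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": label, "ch4_kg": c, "n2o_kg": n,
             "co2e_Mg": (c * self.gwp_ch4 + n * self.gwp_n2o) / 1000.0}
            for label, c, n in self.components
        ]
        rows.append({"component": "total", "ch4_kg": self.ch4_kg,
                     "n2o_kg": self.n2o_kg, "co2e_Mg": self.co2e_Mg})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioTable:
    """Pathway x hydrology-category matrix of soil, non-soil and total fluxes.

    All values in Mg CO2-e per ha-year, unrounded; ``to_display`` applies
    the 1-decimal half-away-from-zero convention.
    """

    soil: Mapping[str, Mapping[str, float]]  # pathway -> category -> Mg CO2-e
    nonsoil: Mapping[str, float]  # pathway -> Mg CO2-e (signed; credits negative)

    def total(self, pathway: str, category: str) -> float:
        return self.soil[pathway][category] + self.nonsoil[pathway]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.soil:
            row = {"pathway": p}
            for c in CATEGORIES:
                row[f"soil_{c}"] = self.soil[p][c]
            row["nonsoil"] = self.nonsoil[p]
            for c in CATEGORIES:
                row[f"total_{c}"] = self.total(p, c)
            rows.append(row)
        return pd.DataFrame(rows).set_index("pathway")

    def to_display(self, decimals: int = 1) -> pd.DataFrame:
        return self.to_frame().map(lambda v: round_half_away(v, decimals))


def build_scenario_table(
    soil_summaries: Mapping[str, Mapping[str, float]],
    nonsoil: Mapping[str, float],
    pathways: Sequence[str] = PATHWAYS,
) -> ScenarioTable:
    """Assemble the scenario table from soil and non-soil fluxes (Mg CO2-e).

    Every pathway needs all three category soil values; the incorporation
    pathway has no non-soil term and is forced to zero.
    """
    soil: dict[str, dict[str, float]] = {}
    ns: dict[str, float] = {}
    for p in pathways:
        if p not in soil_summaries:
            raise ValueError(f"missing soil fluxes for pathway {p!r}")
        soil[p] = {}
        for c in CATEGORIES:
            if c not in soil_summaries[p]:
                raise ValueError(f"missing soil flux for pathway {p!r}, category {c!r}")
            soil[p][c] = float(soil_summaries[p][c])
        ns[p] = 0.0 if p == "incorporation" else float(nonsoil.get(p, 0.0))
    return ScenarioTable(soil=soil, nonsoil=ns)


def compare_to_reference(table: ScenarioTable, reference_pathway: str) -> pd.DataFrame:
    """Per-pathway, per-category total-flux deltas against a reference pathway.

    Positive values indicate an emissions increase relative to the
    reference. Computed on unrounded totals.
    """
    if reference_pathway not in table.soil:
        raise ValueError(f"unknown reference pathway {reference_pathway!r}")
    rows = []
    for p in table.soil:
        rows.append(
            {"pathway": p, **{c: table.total(p, c) - table.total(reference_pathway, c)
                              for c in CATEGORIES}}
        )
    return pd.DataFrame(rows).set_index("pathway")
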