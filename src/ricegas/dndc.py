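"""File-level interface to the external soil process model, plus the
generic calibrate-to-within-tolerance search harness.

The process model itself is never invoked: this module writes its
water-table-mode daily input files and manure amendment schedules, parses
its annual output summaries into :class:`~ricegas.soilflux.SoilFluxSeries`,
and provides the iterative parameter search used during manual model
calibration (step a parameter until a simulated observable lands within a
fractional tolerance of its target). Because water-table file grammars vary
between model versions, the delimiter and level unit are configurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .hydrology import DAYS_PER_YEAR, WaterInputSchedule
from .livestock import AmendmentSchedule
from .soilflux import SoilFluxSeries

__all__ = [
    "SiteSheet",
    "CalibrationSpec",
    "CalibrationError",
    "CalibrationResult",
    "write_water_table_files",
    "read_water_table_file",
    "write_amendment_schedule",
    "parse_model_output",
    "calibration_search",
]


@dataclass(frozen=True)
class SiteSheet:
    """Measured initial site parameters for the simulated rice-wheat field."""

    soc_0_10cm_gC_kg: float = 5.2
    ph: float = 8.12
    bulk_density_Mg_m3: float = 1.46
    texture_label: str = "sandy clay"
    clay_fraction: float = 0.42
    rice_nursery_day: str = "Jun 9"
    wheat_plant_day: str = "Nov 23"
    rice_harvest_day: str = "Oct 29"
    wheat_harvest_day: str = "Apr 10"
    tillage: str = "two passes, 20 cm (rice) and 10 cm (wheat)"

    def __post_init__(self) -> None:
        if not 0 <= self.clay_fraction <= 1:
            raise ValueError("clay fraction must be in [0, 1]")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


@dataclass(frozen=True)
class CalibrationSpec:
    """One calibration loop: step a parameter until the observable is close to target."""

    parameter_name: str
    initial_value: float
    target_value: float
    tolerance_fraction: float = 0.10
    step_rule: str = "multiplicative"  # or "additive"
    step_size: float = 1.1  # factor for multiplicative, increment for additive
    max_iterations: int = 100
    direction_hint: Optional[int] = None  # +1 increase, -1 decrease, None = infer

    def __post_init__(self) -> None:
        if self.tolerance_fraction <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.step_rule not in ("multiplicative", "additive"):
            raise ValueError("step_rule must be multiplicative or additive")
        if self.step_rule == "multiplicative" and self.step_size <= 1:
            raise ValueError("multiplicative step factor must exceed 1")
        if self.step_rule == "additive" and self.step_size <= 0:
            raise ValueError("additive step must be positive")


class CalibrationError(RuntimeError):
    """Search exhausted without reaching tolerance; carries the trace."""

    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class CalibrationResult:
    value: float
    observable: float
    iterations: int
    trace: tuple[dict, ...]
    warnings: tuple[str, ...] = ()


def write_water_table_files(
    schedule: WaterInputSchedule,
    directory,
    unit: str = "cm",
    delimiter: str = " ",
) -> list[Path]:
    """Write one two-column daily water-table file per simulation year.

    Each file has 365 ``julian_day level`` lines (1-based days); a
    ``manifest.json`` sidecar records the seed, unit and per-year source
    climate years. Levels are written in cm by default or converted to m.
    File content is deterministic (no timestamps).
    """
    if unit not in ("cm", "m"):
        raise ValueError("unit must be 'cm' or 'm'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scale = 1.0 if unit == "cm" else 0.01
    paths = []
    for i, levels in enumerate(schedule.levels_cm, start=1):
        lines = [
            f"{day}{delimiter}{level * scale:g}"
            for day, level in zip(range(1, DAYS_PER_YEAR + 1), levels)
        ]
        p = directory / f"water_year_{i:03d}.txt"
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    manifest = {
        "seed": schedule.seed,
        "n_years": schedule.n_years,
        "unit": unit,
        "source_years": list(schedule.source_years),
    }
    mp = directory / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2) + "\n")
    return paths + [mp]


def read_water_table_file(path, unit: str = "cm", delimiter: Optional[str] = None) -> np.ndarray:
    """Read a two-column daily water-table file back into a 365-vector (cm)."""
    days, levels = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        day_s, level_s = line.split(delimiter) if delimiter else line.split()
        days.append(int(day_s))
        levels.append(float(level_s))
    if days != list(range(1, DAYS_PER_YEAR + 1)):
        raise ValueError(f"{path}: expected days 1..{DAYS_PER_YEAR} in order")
    arr = np.array(levels)
    return arr * (100.0 if unit == "m" else 1.0)


def write_amendment_schedule(schedule: AmendmentSchedule, path) -> Path:
    """Serialize a field manure amendment as CSV (day, DM mass, N fraction, N mass).

    A zero-mass amendment produces a header-only file.
    """
    path = Path(path)
    header = "application_julian_day,manure_dm_kg_ha,n_fraction,n_kg_ha"
    if schedule.manure_dm_kg_ha == 0:
        path.write_text(header + "\n")
    else:
        path.write_text(
            header + "\n"
            f"{schedule.application_julian_day},{schedule.manure_dm_kg_ha!r},"
            f"{schedule.n_fraction!r},{schedule.n_kg_ha!r}\n"
        )
    return path


#: Recognized unit tokens for model-output columns and their conversion to
#: the canonical units (kg CH4, kg N2O, kg C).
_UNIT_FACTORS = {
    "ch4": {"CH4": 1.0, "CH4-C": 16.0 / 12.0},
    "n2o": {"N2O": 1.0, "N2O-N": 44.0 / 28.0},
}


def parse_model_output(
    path,
    mapping: Mapping[str, str],
    pathway_label: str = "",
    hydrology_category: str = "",
    residue_returned: bool = False,
) -> SoilFluxSeries:
    """Parse a delimited annual model summary into a :class:`SoilFluxSeries`.

    ``mapping`` names the source columns and species units, e.g.::

        {"year": "Year", "ch4": "CH4-C flux", "ch4_unit": "CH4-C",
         "n2o": "N2O flux", "n2o_unit": "N2O", "soc_delta": "dSOC"}

    ``ch4_unit`` may be ``CH4`` or ``CH4-C`` (converted x16/12);
    ``n2o_unit`` may be ``N2O`` or ``N2O-N`` (converted x44/28). Either
    ``soc_delta`` or ``soc_stock`` (first-differenced) must be mapped.
    """
    df = pd.read_csv(path)
    for key in ("year", "ch4", "n2o"):
        col = mapping.get(key)
        if col is None or col not in df.columns:
            raise ValueError(f"mapping for {key!r} missing or column {col!r} not in file")

    ch4_unit = mapping.get("ch4_unit", "CH4")
    n2o_unit = mapping.get("n2o_unit", "N2O")
    if ch4_unit not in _UNIT_FACTORS["ch4"]:
        raise ValueError(f"unknown CH4 unit token {ch4_unit!r}")
    if n2o_unit not in _UNIT_FACTORS["n2o"]:
        raise ValueError(f"unknown N2O unit token {n2o_unit!r}")

    ch4 = df[mapping["ch4"]].to_numpy(dtype=float) * _UNIT_FACTORS["ch4"][ch4_unit]
    n2o = df[mapping["n2o"]].to_numpy(dtype=float) * _UNIT_FACTORS["n2o"][n2o_unit]

    if "soc_delta" in mapping and mapping["soc_delta"] in df.columns:
        soc = df[mapping["soc_delta"]].to_numpy(dtype=float)
    elif "soc_stock" in mapping and mapping["soc_stock"] in df.columns:
        stock = df[mapping["soc_stock"]].to_numpy(dtype=float)
        soc = np.diff(stock, prepend=stock[:1])
    else:
        raise ValueError("mapping must provide soc_delta or soc_stock")

    return SoilFluxSeries(
        pathway_label=pathway_label,
        hydrology_category=hydrology_category,
        residue_returned=residue_returned,
        years=tuple(int(y) for y in df[mapping["year"]]),
        ch4_kg_ha=tuple(float(v) for v in ch4),
        n2o_kg_ha=tuple(float(v) for v in n2o),
        soc_delta_kgC_ha=tuple(float(v) for v in soc),
    )


def _step(value: float, spec: CalibrationSpec, direction: int) -> float:
    if spec.step_rule == "multiplicative":
        return value * spec.step_size if direction > 0 else value / spec.step_size
    return value + direction * spec.step_size


def calibration_search(
    simulate: Callable[[float], float], spec: CalibrationSpec
) -> CalibrationResult:
    """Incrementally step a parameter until ``simulate`` lands within tolerance.

    The first parameter value whose observable falls within
    ``tolerance_fraction`` of the target (relative) is returned with the
    full iteration trace. The stepping direction is taken from
    ``direction_hint`` or inferred from the first two evaluations. If a
    step overshoots the target without entering the tolerance band, the
    search bisects between the bracketing values. A doubly reversing error
    trend (non-monotone response) adds a warning to the trace.
    """
    target = spec.target_value
    if target == 0:
        raise ValueError("target_value must be nonzero for relative tolerance")

    trace: list[dict] = []
    warns: list[str] = []

    def rel_err(obs: float) -> float:
        return abs(obs - target) / abs(target)

    def evaluate(value: float) -> float:
        obs = simulate(value)
        trace.append(
            {"iteration": len(trace), "value": value, "observable": obs, "rel_err": rel_err(obs)}
        )
        return obs

    value = spec.initial_value
    obs = evaluate(value)
    if rel_err(obs) <= spec.tolerance_fraction:
        return CalibrationResult(value, obs, 0, tuple(trace))

    if spec.direction_hint in (1, -1):
        direction = spec.direction_hint
    else:
        probe = _step(value, spec, +1)
        obs_probe = evaluate(probe)
        if rel_err(obs_probe) <= spec.tolerance_fraction:
            return CalibrationResult(probe, obs_probe, len(trace) - 1, tuple(trace))
        direction = 1 if rel_err(obs_probe) < rel_err(obs) else -1
        if direction == 1:
            value, obs = probe, obs_probe

    prev_err = rel_err(obs)
    reversals = 0
    improving = True
    for _ in range(spec.max_iterations):
        new_value = _step(value, spec, direction)
        new_obs = evaluate(new_value)
        err = rel_err(new_obs)
        if err <= spec.tolerance_fraction:
            return CalibrationResult(
                new_value, new_obs, len(trace) - 1, tuple(trace), tuple(warns)
            )
        # overshoot: observable crossed the target without entering the band
        if (obs - target) * (new_obs - target) < 0:
            lo, hi = sorted((value, new_value))
            for _ in range(spec.max_iterations):
                if len(trace) - 1 >= spec.max_iterations:
                    break
                mid = 0.5 * (lo + hi)
                mid_obs = evaluate(mid)
                if rel_err(mid_obs) <= spec.tolerance_fraction:
                    return CalibrationResult(
                        mid, mid_obs, len(trace) - 1, tuple(trace), tuple(warns)
                    )
                if (simulate(lo) - target) * (mid_obs - target) < 0:
                    hi = mid
                else:
                    lo = mid
            break
        now_improving = err < prev_err
        if now_improving != improving:
            reversals += 1
            if reversals >= 2 and "non-monotone response detected" not in warns:
                warns.append("non-monotone response detected")
                warnings.warn("calibration_search: non-monotone response detected")
        improving = now_improving
        prev_err = err
        value, obs = new_value, new_obs

    raise CalibrationError(
        f"calibration of {spec.parameter_name!r} did not reach "
        f"{spec.tolerance_fraction:.0%} of target {target} within "
        f"{spec.max_iterations} iterations",
        trace,
    )
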