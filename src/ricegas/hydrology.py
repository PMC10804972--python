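"""Field water-level classification, representative-site selection and
construction of long-run water-table input schedules.

Daily water levels are measured in perforated field tubes as cm relative to
the soil surface (positive = ponded water). The rice season spans Julian
days 183-302 (120 days). Each field-year is summarized by its flooded /
saturated / drained day counts; one representative field per hydrology
category (dry, median, wet) is selected per climate year, and 100-year
process-model inputs are assembled by resampling climate years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RICE_SEASON_START",
    "RICE_SEASON_END",
    "WaterLevelSeries",
    "FieldWaterSummary",
    "CategoryAssignment",
    "WaterInputSchedule",
    "classify_day",
    "summarize_field",
    "assign_categories",
    "build_water_input",
    "read_water_levels_csv",
]

RICE_SEASON_START = 183
RICE_SEASON_END = 302  # inclusive
RICE_SEASON_DAYS = range(RICE_SEASON_START, RICE_SEASON_END + 1)
SATURATION_DEPTH_CM = -15.0
WHEAT_FILL_CM = -100.0
IRRIGATION_DAYS = (22, 340, 352)  # wheat-season irrigation events, level 0 cm
DAYS_PER_YEAR = 365  # fixed calendar; leap days dropped on ingest


@dataclass(frozen=True)
class WaterLevelSeries:
    """Daily water levels for one field-year, cm relative to soil surface."""

    field_id: str
    climate_year: int
    julian_days: tuple[int, ...]
    levels_cm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.julian_days) != len(self.levels_cm):
            raise ValueError("julian_days and levels_cm differ in length")
        if any(b <= a for a, b in zip(self.julian_days, self.julian_days[1:])):
            raise ValueError(f"julian days not strictly increasing for field {self.field_id!r}")
        if not all(math.isfinite(v) for v in self.levels_cm):
            raise ValueError(f"non-finite water level in field {self.field_id!r}")

    def rice_season_levels(self) -> np.ndarray:
        """Levels for Julian days 183-302; raises if any season day is missing."""
        by_day = dict(zip(self.julian_days, self.levels_cm))
        missing = [d for d in RICE_SEASON_DAYS if d not in by_day]
        if missing:
            raise ValueError(
                f"field {self.field_id!r} year {self.climate_year} missing rice-season days {missing}"
            )
        return np.array([by_day[d] for d in RICE_SEASON_DAYS], dtype=float)


@dataclass(frozen=True)
class FieldWaterSummary:
    """Flooded / saturated / drained day counts for one field's rice season."""

    field_id: str
    flooded_days: int
    saturated_days: int
    drained_days: int

    @property
    def total_days(self) -> int:
        return self.flooded_days + self.saturated_days + self.drained_days


@dataclass(frozen=True)
class CategoryAssignment:
    """Representative field per hydrology category for one climate year."""

    climate_year: int
    dry_field: str
    median_field: str
    wet_field: str
    seed: int
    mean_flooded: float
    sd_flooded: float
    dry_candidates: tuple[str, ...]
    wet_candidates: tuple[str, ...]


@dataclass(frozen=True)
class WaterInputSchedule:
    """Multi-year daily water-table schedule for the process model.

    Each simulation year carries a full 365-day level vector: the rice
    season copied verbatim from one source climate year, every other day at
    -100 cm except the wheat irrigation days (22, 340, 352) at 0 cm.
    """

    seed: int
    source_years: tuple[int, ...]
    levels_cm: tuple[tuple[float, ...], ...]  # one 365-vector per simulation year

    @property
    def n_years(self) -> int:
        return len(self.source_years)


def classify_day(level_cm: float) -> str:
    """Classify one day's water level as ``flooded``, ``saturated`` or ``drained``.

    Flooded means ponded water above the soil surface (level > 0); saturated
    means a free water surface within the top 15 cm (-15 <= level <= 0);
    drained means the water surface is below 15 cm depth.
    """
    if not math.isfinite(level_cm):
        raise ValueError(f"non-finite water level: {level_cm!r}")
    if level_cm > 0:
        return "flooded"
    if level_cm >= SATURATION_DEPTH_CM:
        return "saturated"
    return "drained"


def summarize_field(series: WaterLevelSeries) -> FieldWaterSummary:
    """Count flooded/saturated/drained days over the rice season."""
    levels = series.rice_season_levels()
    flooded = int(np.sum(levels > 0))
    saturated = int(np.sum((levels <= 0) & (levels >= SATURATION_DEPTH_CM)))
    drained = int(np.sum(levels < SATURATION_DEPTH_CM))
    return FieldWaterSummary(series.field_id, flooded, saturated, drained)


def assign_categories(
    summaries: Sequence[FieldWaterSummary],
    seed: int,
    climate_year: int = 0,
    sd_multiplier: float = 1.0,
) -> CategoryAssignment:
    """Pick dry / median / wet representative fields from a cohort.

    The median field is the one whose flooded-day count is closest to the
    sample median (ties broken by lexicographic field id). Dry and wet
    representatives are drawn uniformly at random (seeded) from the fields
    at least ``sd_multiplier`` sample standard deviations below / above the
    mean flooded-day count; the median field is excluded from both pools so
    the three representatives are distinct.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 fields to assign hydrology categories")
    counts = np.array([s.flooded_days for s in summaries], dtype=float)
    ids = [s.field_id for s in summaries]
    if np.all(counts == counts[0]):
        raise ValueError("all flooded-day counts identical; categories are undefined")

    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1))
    med = float(np.median(counts))

    # closest to median, ties by lexicographic field id
    order = sorted(range(len(ids)), key=lambda i: (abs(counts[i] - med), ids[i]))
    median_idx = order[0]

    dry_pool = sorted(
        ids[i] for i in range(len(ids))
        if counts[i] <= mean - sd_multiplier * sd and i != median_idx
    )
    wet_pool = sorted(
        ids[i] for i in range(len(ids))
        if counts[i] >= mean + sd_multiplier * sd and i != median_idx
    )
    if not dry_pool or not wet_pool:
        raise ValueError(
            "empty dry or wet candidate set at "
            f"{sd_multiplier} SD from the mean; relax sd_multiplier "
            f"(mean={mean:.2f}, sd={sd:.2f})"
        )

    rng = np.random.default_rng(seed)
    dry = dry_pool[int(rng.integers(len(dry_pool)))]
    wet = wet_pool[int(rng.integers(len(wet_pool)))]
    return CategoryAssignment(
        climate_year=climate_year,
        dry_field=dry,
        median_field=ids[median_idx],
        wet_field=wet,
        seed=seed,
        mean_flooded=mean,
        sd_flooded=sd,
        dry_candidates=tuple(dry_pool),
        wet_candidates=tuple(wet_pool),
    )


def build_water_input(
    category_series: Mapping[int, WaterLevelSeries],
    n_years: int,
    seed: int,
) -> WaterInputSchedule:
    """Assemble an ``n_years`` daily water-table schedule for one category.

    For every simulation year one source climate year is drawn uniformly
    (seeded); its rice-season levels (days 183-302) are copied verbatim.
    All other days are set to -100 cm, except Julian days 22, 340 and 352
    which are set to 0 cm to represent typical wheat-season irrigation.
    """
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    if not category_series:
        raise ValueError("need at least one source climate year")

    years = sorted(category_series)
    season = {y: category_series[y].rice_season_levels() for y in years}

    template = np.full(DAYS_PER_YEAR, WHEAT_FILL_CM)
    for d in IRRIGATION_DAYS:
        template[d - 1] = 0.0

    rng = np.random.default_rng(seed)
    choices = [years[int(i)] for i in rng.integers(len(years), size=n_years)]

    all_levels = []
    for y in choices:
        vec = template.copy()
        vec[RICE_SEASON_START - 1 : RICE_SEASON_END] = season[y]
        all_levels.append(tuple(vec))
    return WaterInputSchedule(seed=seed, source_years=tuple(choices), levels_cm=tuple(all_levels))


def read_water_levels_csv(path) -> list[WaterLevelSeries]:
    """Read long-format daily water observations into per-field series.

    Accepts either ``field_id,date,level_cm`` (ISO dates; Julian day and
    climate year derived from the date, Feb 29 dropped) or
    ``field_id,julian_day,level_cm`` with an optional ``climate_year``
    column (1-based Julian days).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if not {"field_id", "level_cm"} <= cols:
        raise ValueError(f"water-level CSV needs field_id and level_cm columns, got {sorted(cols)}")
    if "date" in cols:
        dates = pd.to_datetime(df["date"])
        leap = (dates.dt.month == 2) & (dates.dt.day == 29)
        df = df.loc[~leap].copy()
        dates = dates[~leap]
        # fixed 365-day calendar: renumber days after Feb 28 in leap years
        doy = dates.dt.dayofyear - (dates.dt.is_leap_year & (dates.dt.dayofyear > 59)).astype(int)
        df["julian_day"] = doy
        df["climate_year"] = dates.dt.year
    elif "julian_day" not in cols:
        raise ValueError("water-level CSV needs either a date or a julian_day column")
    if "climate_year" not in df.columns:
        df["climate_year"] = 0

    out = []
    for (fid, year), grp in df.groupby(["field_id", "climate_year"], sort=True):
        grp = grp.sort_values("julian_day")
        out.append(
            WaterLevelSeries(
                field_id=str(fid),
                climate_year=int(year),
                julian_days=tuple(int(d) for d in grp["julian_day"]),
                levels_cm=tuple(float(v) for v in grp["level_cm"]),
            )
        )
    return out
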