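# Methods

## Scope and model structure

The package accounts for the direct greenhouse-gas consequences of four
fates of rice straw in a rice–wheat rotation: open burning, in-situ
incorporation, feeding to livestock with partial manure return, and
conversion to biochar. The functional unit is the residue produced by one
hectare of rice in one year. Soil-derived fluxes (CH4, N2O, SOC change)
come from an external daily-time-step process model of soil
biogeochemistry run over a 100-year horizon; this package prepares that
model's water-table inputs, aggregates its annual outputs, computes the
Tier-1/2 non-soil emissions, and assembles everything into a pathway ×
hydrology-category table of net CO2-equivalents. The process model itself
is never invoked — the interface is file-level only, so the whole pipeline
runs against the synthetic generator in environments where the model
executable is unavailable.

## Parameters

All constants live in `EmissionParams` with units, bounds and a provenance
string per field (`ricegas.params.PROVENANCE`). The defaults describe the
study system: mean rice yield 3.77 t/ha, straw ratio 1.5, dry-matter
fraction 0.86; IPCC Tier-2 livestock coefficients for the Indian
subcontinent (DE 0.55, UE 0.04, ASH 0.08, Bo 0.13 m³/kg VS, MCF 0.05,
herd-weighted Ym 4.74 % of gross energy); dung cookstove EFs 281 and
27 kg/TJ with NCV 17.8 MJ/kg; country-specific burning EFs 9.59 and
0.48 g/kg with burn efficiency 0.89; medium-temperature pyrolysis
(798.15 K) with straw lignin fraction 0.179 and 100-year permanence 0.71
(its reported SE of 0.03 is metadata only — no uncertainty propagation);
AR6 100-year GWPs 27.9 (CH4) and 273 (N2O). Every value is overridable via
a YAML mapping or `--set key=value` on the CLI; fractions are validated to
[0, 1] and the stoichiometric ratios 44/12 and 44/28 are pinned exactly.

Two printed-source issues are resolved inside the package as deliberate
readings, both config-insensitive:

- The CO2-e formula is implemented as CH4 × 27.9 + N2O × 273; the stated
  GWP values leave no ambiguity about which factor belongs to which gas.
- The volatile-solids equation is implemented in its standard IPCC form
  [GE(1−DE) + UE·GE]·(1−ASH)/18.45, consistent with the variable
  definitions accompanying it.

The manure-storage N2O emission factor is nowhere stated numerically in
the source material; the IPCC solid-storage default of 0.01 kg N2O-N/kg N
is adopted (it reproduces the published livestock non-soil total of
2.2 Mg CO2-e/ha/yr) and is config-overridable. Likewise the source is
ambiguous about whether urinary energy enters VS with a positive sign
across IPCC editions; the printed "+ UE·GE" is implemented.

Manure storage emissions apply to the *full* VS because manure is stored
daily before either use; the 50/50 field/cookstove split is itself a
parameter (`manure_field_split`). The field half is scheduled five days
before the rice season (day 178 by default) at 2.2 % N, emitted as an
`AmendmentSchedule` for the soil-model interface — its soil consequences
belong to the process model, not to this package.

## Hydrologic classification

A day is **flooded** when the water level is strictly above the soil
surface, **saturated** when a free water surface sits within the top 15 cm
(−15 ≤ level ≤ 0), and **drained** below that. Level exactly 0 is assigned
to "saturated"; the boundary is not stated in the source and the strict
inequality is the package's choice. Fields are summarized by flooded-day
counts over the 120-day rice season (Julian days 183–302; series with
missing season days are rejected rather than imputed). Per climate year,
the **median** representative is the field whose count is closest to the
sample median (ties by lexicographic field id), and the **dry**/**wet**
representatives are seeded uniform picks among fields at least one sample
(n−1) standard deviation below/above the mean count (multiplier
configurable; the median field is excluded from both pools so the three
representatives are distinct). Degenerate cohorts — all-identical counts,
or an empty candidate pool — raise errors that advise relaxing the SD
multiplier.

Long-run water-table schedules resample one source climate year per
simulation year with equal probability (single seeded generator per run,
seed logged in the output manifest). Rice-season days are copied verbatim
from the source; all other days are −100 cm except Julian days 22, 340 and
352 at 0 cm, representing typical wheat-season irrigation. The calendar is
a fixed 365 days; Feb 29 observations are dropped on ingest and subsequent
days renumbered. Written water-table files are two-column
`julian_day level` text (1-based days, cm by default, m optional) with a
JSON manifest; the dialect (delimiter, unit) is configurable because
process-model versions differ in their expected grammar.

## Soil-flux aggregation

The "soil" column of the scenario table is the horizon-mean
CH4 × GWP_CH4 + N2O × GWP_N2O − mean annual ΔSOC × 44/12 (Mg CO2-e/ha/yr).
The SOC annualization — mean annual stock change over the horizon — is the
package's construction; a switch (`include_soc=False`) drops the term for
sensitivity checks. ΔSOC may be supplied directly or derived by
first-differencing a stock column (auto-detected by header); with stock
input the first year's delta is set to 0, since no pre-series stock
exists. The horizon is whatever the series length is — 100 years in the
default study conditions, 10 for the interannual-variability view.
Residue-effect statistics compare the mean annual CH4 of paired
no-residue / with-residue series: absolute difference (Mg), percent of the
no-residue mean, and their ratio; a zero baseline flags percent and ratio
as undefined rather than raising.

## Synthetic data generator

The generator exists so that every pipeline stage is testable without
field data or the process model; it reproduces summary statistics, not
biogeochemistry.

**Hydrographs.** Daily levels follow a stationary AR(1) around a field
mean, with day-to-day spread σ_day = 10 cm, default persistence 0.85, and
levels clipped to [−100, +30] cm. The climate-year wetness *w* (propensity
of a day being flooded at an average field) maps to the year-level mean
via the probit link μ = σ_day·Φ⁻¹(w); field offsets are Normal(0, 8 cm) by
default so a default cohort spans drained-dominant to flooded-dominant
regimes, matching the extreme between-field variability the field
water-tube data show. The AR(1) family was chosen as the simplest process
producing multi-day flooded/drained runs; it does not emulate monsoon
timing, drainage events or irrigation pulses, so passing tests demonstrate
the classification and selection machinery, not hydrological realism.

**Soil fluxes.** Annual CH4 and N2O are independent lognormal draws with
configured arithmetic means and interannual CV; ΔSOC is Normal (it may be
negative). Default no-residue CH4 means are 0.08 / 0.22 / 0.31 Mg/ha/yr
for dry / median / wet, with residue return adding 0.03 / 0.10 / 0.14 Mg —
the study-system values. N2O means (0.020 / 0.015 / 0.010 kg/ha/yr) sit in
the simulated 0.010–0.020 range with drier sites higher; ΔSOC defaults to
0 without residue return and +30 kg C/ha/yr with it (long-run stock gains
are small). The interannual CV default of 0.3 is a fixture parameter — the
source gives no numeric CV — and the absence of CH4–N2O correlation is a
simplification. Tests recover configured means within 3 standard errors
over 100-year series across 20 seeds.

## Calibration harness

`calibration_search` generalizes the manual model-calibration procedure:
step a parameter incrementally (default ×1.1 per iteration; the source
says only "incrementally") until a black-box simulator's observable lands
within a fractional tolerance (default 10 %) of its target. Direction
comes from a hint or is inferred from the first two evaluations; if a step
crosses the target without entering the tolerance band the search bisects
the bracketing pair; a doubly-reversing error trend records a
non-monotone-response warning in the trace. Exhausting the iteration
budget raises an error carrying the full trace.

## Numerical conventions

- Display rounding is half-away-from-zero to one decimal, matching the
  published table's apparent convention; machine outputs are never rounded.
- Credits (biochar, pyrogenic carbon) are stored as positive magnitudes
  and enter the non-soil column negated, so total = soil + non-soil holds
  cell-wise to 1e-12.
- Combustion CO2 is biogenic-neutral in the burning pathway: only CH4 and
  N2O are counted, plus the PyC credit.
- All random draws use a single `numpy` Generator seeded per run; file
  writers embed no timestamps, so outputs are byte-reproducible.

## Known limitations and discrepancies

- The published table's burning non-soil value (0.4 Mg CO2-e/ha/yr) is not
  reproducible from the printed equations and emission factors, which give
  ≈ 1.45 Mg (1.73 combustion − 0.27 PyC credit). The package follows the
  equations; comparisons against burning therefore use the published
  totals where the published convention is wanted.
- In the published table the livestock dry-category total (4.5) exceeds
  the sum of its rounded soil and non-soil cells (2.2 + 2.2 = 4.4),
  presumably because the original sum used unrounded values; the package
  reproduces the median and wet cells exactly and treats the dry cell as a
  rounding artifact of the published inputs.
- Whether flooded-day counting uses level > 0 or ≥ 0 is undocumented in
  the source; the strict boundary is configurable in spirit (classify by
  your own threshold before summarizing) and documented here.
- No gap-filling of missing daily water observations, no spatial drainage
  modeling, no herd dynamics or feed substitution, no pyrolysis process
  energy or transport, no PM2.5/black-carbon impacts, no uncertainty
  propagation on parameters.

## Problem sizes used in the self-checks

The test suite and `scripts/acceptance.py` run the study conditions at
their native sizes where cheap (100-year flux series, 100-year water-input
schedules, 20-seed recovery checks, 200 random cohorts for the selection
procedure) — all complete in seconds on one CPU.
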