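"""Construction of "no-shock" counterfactual rate schedules.

A pandemic-style shock perturbs mortality, fertility and migration for a
few years, after which the published forecasts assume a return to the
pre-shock trajectory. The counterfactual schedules bridge the shock window
from its unperturbed anchor years:

* mortality — linear interpolation of log rates between the anchors
  (default 2019 and 2025), per age and sex, then the antilogarithm;
* fertility — only the shock year (default 2020) is replaced: its TFR is
  the mean of the anchor-year TFRs (default 2019 and 2021) and its age
  pattern is the pattern of the later anchor;
* migration — linear interpolation of the total net migration counts
  between the anchors (default 2019 and 2022).

All years outside the windows are copied from the baseline unchanged, and
the sex ratio at birth is never counterfactualized.
"""
from __future__ import annotations

from typing import Iterable, Set

import numpy as np

from .schedules_io import (
    CoverageError,
    FertilityTable,
    MigrationSeries,
    MortalityTable,
    RateSchedules,
    TableValidationError,
)

COMPONENTS = ("mortality", "fertility", "migration")


def geometric_interpolate(lo_vals, hi_vals, year: int, anchor_lo: int, anchor_hi: int):
    """Value at ``year`` of the log-linear path between the two anchors."""
    w = (year - anchor_lo) / (anchor_hi - anchor_lo)
    lo_vals = np.asarray(lo_vals, dtype=np.float64)
    hi_vals = np.asarray(hi_vals, dtype=np.float64)
    return np.exp(np.log(lo_vals) + w * (np.log(hi_vals) - np.log(lo_vals)))


def linear_interpolate(lo_val, hi_val, year: int, anchor_lo: int, anchor_hi: int):
    """Value at ``year`` of the straight line between the two anchors."""
    w = (year - anchor_lo) / (anchor_hi - anchor_lo)
    return lo_val + w * (hi_val - lo_val)


def counterfactual_mortality(
    baseline: MortalityTable, anchor_lo: int = 2019, anchor_hi: int = 2025
) -> MortalityTable:
    """Replace rates strictly between the anchors by log-linear interpolation.

    Interpolation is done independently per (age, sex) cell; anchor rates
    must be strictly positive for the logarithm to be defined.
    """
    lo = baseline.rates_for(anchor_lo)  # raises CoverageError if absent
    hi = baseline.rates_for(anchor_hi)
    if (lo <= 0).any() or (hi <= 0).any():
        raise TableValidationError(
            f"anchor mortality rates must be > 0 for log interpolation "
            f"(anchors {anchor_lo}, {anchor_hi})"
        )
    out = baseline.copy()
    for year in range(anchor_lo + 1, anchor_hi):
        if out.years[0] <= year <= out.years[-1]:
            out.rates[year - out.years[0]] = geometric_interpolate(
                lo, hi, year, anchor_lo, anchor_hi
            )
    return out


def counterfactual_fertility(
    baseline: FertilityTable,
    shock_year: int = 2020,
    anchor_lo: int = 2019,
    pattern_year: int = 2021,
) -> FertilityTable:
    """Replace the shock year's rates: anchor-mean TFR on the pattern year's shape."""
    tfr_pattern = baseline.tfr(pattern_year)
    if tfr_pattern <= 0:
        raise TableValidationError(f"TFR({pattern_year}) must be > 0")
    tfr_target = (baseline.tfr(anchor_lo) + baseline.tfr(pattern_year)) / 2.0
    out = baseline.copy()
    out.rates[shock_year - out.years[0]] = baseline.rates_for(pattern_year) * (
        tfr_target / tfr_pattern
    )
    return out


def counterfactual_migration(
    baseline: MigrationSeries, anchor_lo: int = 2019, anchor_hi: int = 2022
) -> MigrationSeries:
    """Replace totals strictly between the anchors by linear interpolation."""
    lo = baseline.total_for(anchor_lo)
    hi = baseline.total_for(anchor_hi)
    out = baseline.copy()
    for year in range(anchor_lo + 1, anchor_hi):
        if out.years[0] <= year <= out.years[-1]:
            out.totals[year - out.years[0]] = linear_interpolate(
                lo, hi, year, anchor_lo, anchor_hi
            )
    return out


def build_counterfactual(
    baseline: RateSchedules,
    components: Iterable[str] = COMPONENTS,
    *,
    mortality_anchors: tuple[int, int] = (2019, 2025),
    fertility_anchors: tuple[int, int, int] = (2020, 2019, 2021),
    migration_anchors: tuple[int, int] = (2019, 2022),
) -> RateSchedules:
    """Scenario with the named components replaced by their counterfactuals.

    ``components`` is a non-empty subset of {"mortality", "fertility",
    "migration"}; the full set gives the all-counterfactual scenario,
    singleton sets give the one-component-at-a-time decomposition
    scenarios. The sex ratio at birth is always copied from baseline.
    ``fertility_anchors`` is (shock_year, anchor_lo, pattern_year).
    """
    comps: Set[str] = set(components)
    if not comps:
        raise ValueError("components must be non-empty; use the baseline directly")
    unknown = comps - set(COMPONENTS)
    if unknown:
        raise ValueError(f"unknown components {sorted(unknown)}; expected {COMPONENTS}")

    mortality = (
        counterfactual_mortality(baseline.mortality, *mortality_anchors)
        if "mortality" in comps
        else baseline.mortality.copy()
    )
    fertility = (
        counterfactual_fertility(baseline.fertility, *fertility_anchors)
        if "fertility" in comps
        else baseline.fertility.copy()
    )
    migration = (
        counterfactual_migration(baseline.migration, *migration_anchors)
        if "migration" in comps
        else baseline.migration.copy()
    )
    label = f"{baseline.label}|cf[{'+'.join(sorted(comps))}]"
    return RateSchedules(mortality, fertility, migration, baseline.srb.copy(), label)
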