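"""Synthetic demographic input bundles with known ground truth.

Generates rate schedules and starting populations shaped like a national
medium-variant projection extract — smooth Gompertz-Makeham mortality with
a gentle secular decline, a unimodal fertility schedule over ages 15-49
scaled to a slowly drifting TFR, a linear-trend net migration series, a
constant sex ratio at birth, and a quasi-stationary population pyramid —
plus an injectable pandemic-style shock (old-age- and male-skewed excess
mortality in 2020-2021, a fertility dip in 2020, roughly halved net
migration in 2020-2021).

The unshocked ("truth") schedules are finished by passing the raw drafts
through the counterfactual construction itself, so within the shock
windows they satisfy the interpolation forms exactly: log-linear mortality
over 2019-2025, linear migration over 2019-2022, and a 2020 TFR equal to
the 2019/2021 mean on the 2021 age pattern. Because a default shock leaves
the anchor years untouched, rebuilding the counterfactual from the shocked
bundle recovers the unshocked truth cell-exactly — which is what makes the
whole pipeline testable as a parameter-recovery problem.
"""
from __future__ import annotations

import dataclasses
from typing import Dict, Optional

import numpy as np

from .counterfactual import COMPONENTS, build_counterfactual
from .projection_engine import mx_to_sx
from .migration_schedule import largest_remainder_round
from .schedules_io import (
    AGE_MAX,
    AGES,
    FEMALE,
    MALE,
    FertilityTable,
    MigrationSeries,
    MortalityTable,
    PopulationState,
    RateSchedules,
    SRBSeries,
)

#: Approximate population sizes emulated by each fixture scale. "full" is
#: a large national population; "tiny" keeps tests fast.
SCALE_SIZES = {"tiny": 10_000, "small": 1_000_000, "full": 330_000_000}

#: Net migration at full scale in the first year, persons/year, with a
#: gentle linear rise thereafter.
_FULL_MIGRATION_2019 = 900_000.0
_FULL_MIGRATION_TREND = 5_000.0


@dataclasses.dataclass(frozen=True)
class GompertzMakehamParams:
    """m(x) = A + B * exp(theta * x): background plus senescent mortality."""

    A: float
    B: float
    theta: float

    def validate(self) -> "GompertzMakehamParams":
        if self.A < 0 or self.B <= 0 or self.theta <= 0:
            raise ValueError("require A >= 0, B > 0, theta > 0")
        return self


DEFAULT_GM_FEMALE = GompertzMakehamParams(A=2.0e-4, B=2.6e-5, theta=0.098)
DEFAULT_GM_MALE = GompertzMakehamParams(A=3.5e-4, B=4.2e-5, theta=0.098)


@dataclasses.dataclass
class ShockSpec:
    """A pandemic-style perturbation of the rate schedules.

    ``mortality_mult`` maps shock years to (101, 2) cell-wise multipliers;
    ``fertility_mult`` and ``migration_mult`` map years to scalar
    multipliers of the TFR (preserving the age pattern) and of the net
    migration total.
    """

    mortality_mult: Dict[int, np.ndarray] = dataclasses.field(default_factory=dict)
    fertility_mult: Dict[int, float] = dataclasses.field(default_factory=dict)
    migration_mult: Dict[int, float] = dataclasses.field(default_factory=dict)

    def validate(self) -> "ShockSpec":
        for year, mult in self.mortality_mult.items():
            mult = np.asarray(mult)
            if mult.shape != (AGE_MAX + 1, 2) or (mult < 0).any():
                raise ValueError(f"mortality multiplier for {year} must be (101, 2) and >= 0")
        for mapping in (self.fertility_mult, self.migration_mult):
            if any(v < 0 for v in mapping.values()):
                raise ValueError("multipliers must be >= 0")
        return self

    @staticmethod
    def identity() -> "ShockSpec":
        return ShockSpec()

    @staticmethod
    def default_pandemic() -> "ShockSpec":
        """Two shock years: excess mortality rising with age and higher for
        males, a 4% fertility dip in the first year, and halved migration."""
        age_frac = (AGES / AGE_MAX) ** 2
        excess = np.empty((AGE_MAX + 1, 2))
        excess[:, MALE] = 0.10 + 0.50 * age_frac
        excess[:, FEMALE] = 0.75 * excess[:, MALE]
        return ShockSpec(
            mortality_mult={2020: 1.0 + excess, 2021: 1.0 + 0.8 * excess},
            fertility_mult={2020: 0.96},
            migration_mult={2020: 0.5, 2021: 0.5},
        ).validate()

    @staticmethod
    def mild(epsilon: float = 0.05) -> "ShockSpec":
        """Uniform small perturbation (for near-additivity checks)."""
        ones = np.ones((AGE_MAX + 1, 2))
        return ShockSpec(
            mortality_mult={2020: (1 + epsilon) * ones, 2021: (1 + epsilon / 2) * ones},
            fertility_mult={2020: 1 - epsilon / 2},
            migration_mult={2020: 1 - epsilon, 2021: 1 - epsilon},
        ).validate()


def make_mortality(
    years,
    params_f: GompertzMakehamParams = DEFAULT_GM_FEMALE,
    params_m: GompertzMakehamParams = DEFAULT_GM_MALE,
    improvement: float = 0.995,
) -> MortalityTable:
    """Gompertz-Makeham schedule with a multiplicative annual improvement.

    m(x, t) = (A + B*exp(theta*x)) * improvement^(t - t0), so log m is
    exactly linear in calendar time for every (age, sex) cell.
    """
    years = np.asarray(years, dtype=np.int64)
    rates = np.empty((years.size, AGE_MAX + 1, 2))
    for sex_i, p in ((FEMALE, params_f), (MALE, params_m)):
        p.validate()
        base = p.A + p.B * np.exp(p.theta * AGES.astype(np.float64))
        for yi, year in enumerate(years):
            rates[yi, :, sex_i] = base * improvement ** (year - years[0])
    return MortalityTable(years, rates).validate()


def make_fertility(
    years,
    tfr_start: float = 1.70,
    tfr_trend: float = -0.002,
    peak_age: int = 28,
    spread: float = 5.5,
    age_min: int = 15,
    age_max: int = 49,
) -> FertilityTable:
    """Unimodal (Gaussian-kernel) fertility over the reproductive ages.

    The age pattern is constant across years and each year's rates are
    scaled so they sum exactly to TFR(t) = tfr_start + tfr_trend*(t - t0).
    """
    years = np.asarray(years, dtype=np.int64)
    ages = np.arange(age_min, age_max + 1)
    kernel = np.exp(-((ages - peak_age) ** 2) / (2.0 * spread**2))
    kernel = kernel / kernel.sum()
    tfr_path = tfr_start + tfr_trend * (years - years[0])
    if (tfr_path <= 0).any():
        raise ValueError("TFR path must stay positive over the year range")
    rates = tfr_path[:, np.newaxis] * kernel[np.newaxis, :]
    return FertilityTable(years, ages, rates).validate()


def make_migration(years, start: float, trend: float) -> MigrationSeries:
    years = np.asarray(years, dtype=np.int64)
    return MigrationSeries(years, start + trend * (years - years[0])).validate()


def make_population(
    total_size: float,
    mortality: MortalityTable,
    year: int = 2020,
    growth_discount: float = 1.008,
    integerize: bool = True,
) -> PopulationState:
    """Quasi-stationary pyramid from survivorship under the given mortality.

    Cell weights are l(x, sex) / growth_discount^x with l(x) the
    survivorship column implied by the table's first-year rates, split
    evenly between the sexes. With ``integerize`` (the default) counts are
    rounded by largest remainder so they sum exactly to
    round(total_size); without it the pyramid scales exactly
    proportionally with ``total_size``.
    """
    if total_size <= 0:
        raise ValueError("total_size must be positive")
    m = mortality.rates_for(int(mortality.years[0]))
    s = mx_to_sx(m, AGES[:, np.newaxis])
    l = np.cumprod(np.vstack([np.ones((1, 2)), s[:-1]]), axis=0)
    weights = l / growth_discount ** AGES[:, np.newaxis].astype(np.float64)
    weights /= weights.sum()
    counts = total_size * weights
    if integerize:
        counts = largest_remainder_round(counts)
    return PopulationState(year, counts).validate()


def apply_shock(unshocked: RateSchedules, spec: ShockSpec) -> RateSchedules:
    """The shocked ("with pandemic", i.e. baseline) world.

    Mortality is multiplied cell-wise, fertility is scaled per year
    preserving its age pattern, migration totals are multiplied; all
    non-shock years and the sex ratio at birth are untouched.
    """
    spec.validate()
    out = unshocked.copy()
    out.label = "baseline"
    for year, mult in spec.mortality_mult.items():
        out.mortality.rates[year - out.mortality.years[0]] *= np.asarray(mult)
    for year, mult in spec.fertility_mult.items():
        out.fertility.rates[year - out.fertility.years[0]] *= mult
    for year, mult in spec.migration_mult.items():
        out.migration.totals[year - out.migration.years[0]] *= mult
    return out.validate()


@dataclasses.dataclass
class SyntheticTruth:
    """A complete study fixture: truth, shocked world, and provenance."""

    unshocked: RateSchedules
    shocked: RateSchedules
    shock: ShockSpec
    pop0: PopulationState
    seed: int
    scale: str


def make_study_fixture(
    seed: int = 0,
    scale: str = "tiny",
    shock: Optional[ShockSpec] = None,
    year_lo: int = 2019,
    year_hi: int = 2060,
) -> SyntheticTruth:
    """A validated bundle spanning ``year_lo``..``year_hi`` with known truth.

    The unshocked schedules satisfy the counterfactual interpolation forms
    exactly within the shock windows (see module docstring), so
    reconstructing the counterfactual from the shocked bundle recovers the
    unshocked truth cell-exactly. ``seed`` deterministically jitters the
    mortality and fertility levels a little, so distinct seeds give
    distinct but equally valid worlds.
    """
    if scale not in SCALE_SIZES:
        raise ValueError(f"scale must be one of {sorted(SCALE_SIZES)}")
    total = SCALE_SIZES[scale]
    rng = np.random.default_rng(seed)
    jitter = np.exp(0.01 * rng.standard_normal(3))
    years = np.arange(year_lo, year_hi + 1)

    draft = RateSchedules(
        mortality=make_mortality(
            years,
            GompertzMakehamParams(
                DEFAULT_GM_FEMALE.A, DEFAULT_GM_FEMALE.B * jitter[0], DEFAULT_GM_FEMALE.theta
            ),
            GompertzMakehamParams(
                DEFAULT_GM_MALE.A, DEFAULT_GM_MALE.B * jitter[1], DEFAULT_GM_MALE.theta
            ),
        ),
        fertility=make_fertility(years, tfr_start=1.70 * jitter[2]),
        migration=make_migration(
            years,
            start=_FULL_MIGRATION_2019 * total / SCALE_SIZES["full"],
            trend=_FULL_MIGRATION_TREND * total / SCALE_SIZES["full"],
        ),
        srb=SRBSeries(years, np.full(years.size, 1.05)),
        label="draft",
    ).validate()

    # Finish the truth through the counterfactual construction itself so the
    # interpolation forms hold exactly within the shock windows.
    unshocked = build_counterfactual(draft, COMPONENTS)
    unshocked.label = "counterfactual-truth"
    unshocked.validate()

    spec = shock if shock is not None else ShockSpec.default_pandemic()
    shocked = apply_shock(unshocked, spec)
    pop0 = make_population(total, unshocked.mortality, year=2020)
    return SyntheticTruth(
        unshocked=unshocked, shocked=shocked, shock=spec, pop0=pop0, seed=seed, scale=scale
    )
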