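"""Two-sex, single-year cohort-component projection engine.

Advances a 1-January population one calendar year at a time under a
scenario's rate schedules. Within each projected year the event order is:

1. survival — every (age, sex) cohort survives to the next 1 January with
   probability s(age, sex, year); survivors move up one year of age, with
   survivors of age 99 and of the open 100+ interval pooling at 100+;
2. births — the expected number of live births applies the age-specific
   fertility rates to the start-of-year female population; newborns are
   split by the sex ratio at birth and survive to 1 January with one
   application of the age-0 survival probability;
3. migration — the year's net migration total, spread over age and sex by
   the model schedule, is added at year end (migrant ages as of the next
   1 January, with no mortality or fertility exposure in the arrival year).

Deterministic mode propagates expectations; stochastic mode draws
survivors from per-cell binomials, total births from a Poisson with the
deterministic mean, the newborn sex split from a binomial, and keeps
migration deterministic up to an unbiased integer rounding. Randomness is
organized in named substreams keyed by (seed, replicate, year, stage) so
replicates are order-independent and reproducible.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Callable, List, Optional, Sequence, Union

import numpy as np

from .migration_schedule import (
    MigrationProfile,
    distribute_migration,
    largest_remainder_round,
    stochastic_round,
)
from .schedules_io import (
    AGE_MAX,
    AGES,
    FEMALE,
    MALE,
    CoverageError,
    FertilityTable,
    PopulationState,
    RateSchedules,
)

logger = logging.getLogger(__name__)

DETERMINISTIC = "deterministic"
STOCHASTIC = "stochastic"

_STAGE_IDS = {"survival": 0, "births": 1, "migration": 2}

#: Average fraction of the year lived by those dying at each age: infant
#: deaths cluster early in the interval, all other ages use the midpoint.
_A0, _AX = 0.1, 0.5


def substream(seed: int, replicate: int, year: int, stage: str) -> np.random.Generator:
    """Independent, reproducible RNG substream for one (replicate, year, stage)."""
    key = (replicate, year, _STAGE_IDS[stage])
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def mx_to_sx(m, age) -> np.ndarray:
    """Survival probability s = 1 - q from central death rate m.

    Uses the standard life-table conversion q = m / (1 + (1-a)*m) with
    a = 0.1 at age 0 and a = 0.5 at ages 1+.
    """
    m = np.asarray(m, dtype=np.float64)
    if (m < 0).any():
        raise ValueError("central death rates must be non-negative")
    a = np.where(np.asarray(age) == 0, _A0, _AX)
    q = m / (1.0 + (1.0 - a) * m)
    return 1.0 - q


def expected_births(pop: PopulationState, fertility: FertilityTable, year: int) -> float:
    """Mean live births from applying ASFRs to start-of-year female counts."""
    f = fertility.rates_for(year)
    exposure = pop.counts[fertility.ages, FEMALE]
    return float(f @ exposure)


@dataclasses.dataclass
class ProjectionResult:
    """A trajectory of 1-January population states, one per year."""

    states: List[PopulationState]
    mode: str = DETERMINISTIC
    replicate_id: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        years = [s.year for s in self.states]
        if years != list(range(years[0], years[0] + len(years))):
            raise ValueError("states must be consecutive years")

    @property
    def years(self) -> np.ndarray:
        return np.array([s.year for s in self.states])

    def state_for(self, year: int) -> PopulationState:
        y0 = self.states[0].year
        if not y0 <= year <= self.states[-1].year:
            raise CoverageError(f"year {year} outside projection {y0}..{self.states[-1].year}")
        return self.states[year - y0]

    def counts_array(self) -> np.ndarray:
        """(n_years, 101, 2) array of counts."""
        return np.stack([s.counts for s in self.states])

    def totals(self) -> np.ndarray:
        return np.array([s.total() for s in self.states])


def _stream_factory(
    mode: str, seed: Optional[int], replicate: int
) -> Callable[[int, str], Optional[np.random.Generator]]:
    if mode == DETERMINISTIC:
        return lambda year, stage: None
    if seed is None:
        raise ValueError("stochastic mode requires a seed")
    return lambda year, stage: substream(seed, replicate, year, stage)


def project_one_year(
    pop: PopulationState,
    scenario: RateSchedules,
    profile: MigrationProfile,
    mode: str = DETERMINISTIC,
    rng_for_stage: Optional[Callable[[str], Optional[np.random.Generator]]] = None,
) -> PopulationState:
    """Advance the population from 1 January of its year to the next.

    ``rng_for_stage`` maps a stage name ("survival", "births",
    "migration") to a seeded generator; required in stochastic mode.
    """
    year = pop.year
    if not scenario.covers(year):
        raise CoverageError(f"scenario '{scenario.label}' does not cover year {year}")
    if mode not in (DETERMINISTIC, STOCHASTIC):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == STOCHASTIC and not pop.is_integer():
        raise ValueError("stochastic mode requires integer population counts")

    s = mx_to_sx(scenario.mortality.rates_for(year), AGES[:, np.newaxis])
    counts = pop.counts

    # --- stage 1: survival and aging -------------------------------------
    if mode == DETERMINISTIC:
        survivors = counts * s
    else:
        rng = rng_for_stage("survival")
        survivors = rng.binomial(np.rint(counts).astype(np.int64), s).astype(np.float64)
    aged = np.zeros_like(counts)
    aged[1:AGE_MAX + 1] = survivors[0:AGE_MAX]
    aged[AGE_MAX] += survivors[AGE_MAX]  # 100+ pool keeps its own survivors

    # --- stage 2: births ---------------------------------------------------
    mean_births = expected_births(pop, scenario.fertility, year)
    srb = scenario.srb.srb_for(year)
    p_female = 1.0 / (1.0 + srb)
    if mode == DETERMINISTIC:
        births_f = mean_births * p_female
        births_m = mean_births - births_f
        newborn = np.array([births_f * s[0, FEMALE], births_m * s[0, MALE]])
    else:
        rng = rng_for_stage("births")
        total_births = rng.poisson(mean_births)
        births_f = rng.binomial(total_births, p_female)
        births_m = total_births - births_f
        newborn = np.array(
            [rng.binomial(births_f, s[0, FEMALE]), rng.binomial(births_m, s[0, MALE])],
            dtype=np.float64,
        )
    aged[0] += newborn

    # --- stage 3: migration ------------------------------------------------
    net_total = scenario.migration.total_for(year)
    migrants = distribute_migration(net_total, profile)
    if mode == STOCHASTIC:
        migrants = stochastic_round(migrants, rng_for_stage("migration"))
    new_counts = aged + migrants

    # Bookkeeping identity before any flooring of negative cells.
    expected_total = survivors.sum() + newborn.sum() + migrants.sum()
    got_total = new_counts.sum()
    if abs(got_total - expected_total) > 1e-9 * max(1.0, abs(expected_total)):
        raise AssertionError(
            f"bookkeeping identity violated in year {year}: "
            f"{got_total} != {expected_total}"
        )

    negative = new_counts < 0
    if negative.any():
        deficit = -new_counts[negative].sum()
        logger.warning(
            "year %d: floored %d negative cells (deficit %.3f persons) after net out-migration",
            year,
            int(negative.sum()),
            deficit,
        )
        new_counts = np.where(negative, 0.0, new_counts)

    return PopulationState(year + 1, new_counts)


def run_projection(
    pop0: PopulationState,
    scenario: RateSchedules,
    profile: MigrationProfile,
    end_year: int,
    mode: str = DETERMINISTIC,
    n_reps: int = 1,
    seed: Optional[int] = None,
) -> Union[ProjectionResult, List[ProjectionResult]]:
    """Project from pop0's 1 January to 1 January of ``end_year``.

    Deterministic mode returns a single :class:`ProjectionResult`;
    stochastic mode returns ``n_reps`` results whose randomness comes
    from independent substreams derived from ``(seed, replicate_id)``,
    making runs with identical inputs and seed bit-identical.
    """
    if end_year < pop0.year:
        raise ValueError("end_year precedes the initial population year")
    for year in range(pop0.year, end_year):
        if not scenario.covers(year):
            raise CoverageError(
                f"scenario '{scenario.label}' does not cover projection year {year}"
            )
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    if mode == DETERMINISTIC:
        states = [pop0.copy()]
        for year in range(pop0.year, end_year):
            states.append(project_one_year(states[-1], scenario, profile, mode))
        return ProjectionResult(states, mode=mode)

    if seed is None:
        raise ValueError("stochastic mode requires a seed")
    start = pop0.copy()
    if not start.is_integer():
        start = PopulationState(start.year, largest_remainder_round(start.counts))
    results = []
    for rep in range(n_reps):
        states = [start.copy()]
        for year in range(pop0.year, end_year):
            rng_for_stage = lambda stage, _y=year, _r=rep: substream(seed, _r, _y, stage)
            states.append(
                project_one_year(states[-1], scenario, profile, STOCHASTIC, rng_for_stage)
            )
        results.append(ProjectionResult(states, mode=STOCHASTIC, replicate_id=rep, seed=seed))
    return results
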