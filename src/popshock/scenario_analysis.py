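"""Comparison of baseline and counterfactual projections.

Computes the "missing population" (baseline minus counterfactual counts,
absolute and as a percentage of baseline), dependency ratios and their
baseline-minus-counterfactual differences, changes in age-group population
shares, the one-component-at-a-time decomposition runs, and empirical
median / 95% interval summaries across stochastic replicates.

Sign convention: a harmful shock depresses the baseline, so "missing
population" is negative; report tables also carry the negated "additional
people without the shock" column.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .counterfactual import COMPONENTS, build_counterfactual
from .migration_schedule import MigrationProfile
from .projection_engine import DETERMINISTIC, ProjectionResult, run_projection
from .schedules_io import AGE_MAX, FEMALE, MALE, SEXES, PopulationState, RateSchedules

#: Default reporting age bands (inclusive bounds; 100 = open interval 100+).
DEFAULT_AGE_GROUPS: Dict[str, Tuple[int, int]] = {
    "0-14": (0, 14),
    "15-49": (15, 49),
    "50-64": (50, 64),
    "65-84": (65, 84),
    "85+": (85, AGE_MAX),
}

Runs = Union[ProjectionResult, List[ProjectionResult]]


def _check_groups(age_groups: Mapping[str, Tuple[int, int]]) -> None:
    covered = sorted(a for lo, hi in age_groups.values() for a in range(lo, hi + 1))
    if covered != list(range(AGE_MAX + 1)):
        raise ValueError("age_groups must partition ages 0..100")


def _group_counts(
    counts: np.ndarray, age_groups: Mapping[str, Tuple[int, int]]
) -> np.ndarray:
    """(n_groups, 2) sums of an (101, 2) count array."""
    return np.stack([counts[lo:hi + 1].sum(axis=0) for lo, hi in age_groups.values()])


def _align(baseline: ProjectionResult, counterfactual: ProjectionResult) -> np.ndarray:
    if not np.array_equal(baseline.years, counterfactual.years):
        raise ValueError("projections cover different year ranges")
    return baseline.years


def missing_population(
    baseline: ProjectionResult,
    counterfactual: ProjectionResult,
    age_groups: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Baseline-minus-counterfactual population by year, age group and sex.

    Rows cover each age group plus a "total" group, for each sex plus the
    sex "total". ``absolute`` is the count difference; ``relative`` is
    absolute / baseline x 100 (NaN where baseline is zero);
    ``additional_without_shock`` is the negated absolute difference.
    """
    age_groups = dict(age_groups or DEFAULT_AGE_GROUPS)
    _check_groups(age_groups)
    years = _align(baseline, counterfactual)
    rows = []
    for yi, year in enumerate(years):
        gb = _group_counts(baseline.states[yi].counts, age_groups)
        gc = _group_counts(counterfactual.states[yi].counts, age_groups)
        gb = np.vstack([gb, gb.sum(axis=0)])  # append "total" group
        gc = np.vstack([gc, gc.sum(axis=0)])
        names = list(age_groups) + ["total"]
        for gi, group in enumerate(names):
            for si, sex in enumerate(list(SEXES) + ["total"]):
                b = gb[gi].sum() if sex == "total" else gb[gi, si]
                c = gc[gi].sum() if sex == "total" else gc[gi, si]
                absolute = b - c
                rows.append(
                    {
                        "year": int(year),
                        "age_group": group,
                        "sex": sex,
                        "baseline": b,
                        "counterfactual": c,
                        "absolute": absolute,
                        "relative": 100.0 * absolute / b if b > 0 else np.nan,
                        "additional_without_shock": -absolute,
                    }
                )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class DependencyRatios:
    """Young-age, old-age and total dependency ratios, in percent.

    young = 100 * N(<15) / N(15-64); old = 100 * N(>=65) / N(15-64);
    total = young + old (shared denominator).
    """

    young: float
    old: float
    total: float


def dependency_ratios(pop: PopulationState) -> DependencyRatios:
    working = pop.counts[15:65].sum()
    if working <= 0:
        raise ValueError(f"zero working-age population in year {pop.year}")
    young = 100.0 * pop.counts[:15].sum() / working
    old = 100.0 * pop.counts[65:].sum() / working
    return DependencyRatios(young=young, old=old, total=young + old)


def dependency_ratio_series(result: ProjectionResult) -> pd.DataFrame:
    rows = [
        {"year": int(s.year), **dataclasses.asdict(dependency_ratios(s))}
        for s in result.states
    ]
    return pd.DataFrame(rows)


def decompose_components(
    baseline_rates: RateSchedules,
    pop0: PopulationState,
    profile: MigrationProfile,
    end_year: int,
    mode: str = DETERMINISTIC,
    n_reps: int = 1,
    seed: Optional[int] = None,
    components: Sequence[str] = COMPONENTS,
) -> Dict[str, Runs]:
    """Run baseline plus all-/single-component counterfactual projections.

    Returns a dict with keys "baseline", one key per requested component,
    and "all" when more than one component is requested (with a single
    component the all-counterfactual run would duplicate it). All runs
    share pop0, the migration profile and the seed policy, so stochastic
    replicates are paired by common random numbers.
    """
    scenarios: Dict[str, RateSchedules] = {"baseline": baseline_rates}
    if len(components) > 1:
        scenarios["all"] = build_counterfactual(baseline_rates, components)
    for comp in components:
        scenarios[comp] = build_counterfactual(baseline_rates, {comp})
    return {
        name: run_projection(pop0, rates, profile, end_year, mode, n_reps, seed)
        for name, rates in scenarios.items()
    }


def _as_replicates(runs: Runs) -> List[ProjectionResult]:
    return runs if isinstance(runs, list) else [runs]


def _paired_apply(
    baseline: Runs, counterfactual: Runs, fn: Callable[[ProjectionResult, ProjectionResult], np.ndarray]
) -> np.ndarray:
    """Apply a pairwise statistic per replicate; (n_reps, ...) stack."""
    b_reps, c_reps = _as_replicates(baseline), _as_replicates(counterfactual)
    if len(b_reps) != len(c_reps):
        raise ValueError("replicate counts differ between scenarios")
    return np.stack([fn(b, c) for b, c in zip(b_reps, c_reps)])


def dependency_ratio_difference(
    baseline: Runs, counterfactuals: Mapping[str, Runs]
) -> pd.DataFrame:
    """Baseline-minus-counterfactual dependency ratios, percentage points.

    ``counterfactuals`` maps component labels (e.g. "all", "mortality")
    to their runs. With stochastic runs, differences are formed per paired
    replicate and summarized (median and 95% interval); deterministic runs
    yield the plain differences with degenerate intervals.
    """
    years = _as_replicates(baseline)[0].years
    frames = []
    for component, runs in counterfactuals.items():
        def diff(b: ProjectionResult, c: ProjectionResult) -> np.ndarray:
            _align(b, c)
            out = np.empty((len(b.states), 3))
            for i, (sb, sc) in enumerate(zip(b.states, c.states)):
                rb, rc = dependency_ratios(sb), dependency_ratios(sc)
                out[i] = (rb.young - rc.young, rb.old - rc.old, rb.total - rc.total)
            return out

        stack = _paired_apply(baseline, runs, diff)
        summary = summarize_reps(stack) if stack.shape[0] > 1 else None
        for i, year in enumerate(years):
            row = {"year": int(year), "component": component}
            for j, measure in enumerate(("young", "old", "total")):
                if summary is None:
                    row[measure] = stack[0, i, j]
                    row[f"{measure}_ci_low"] = stack[0, i, j]
                    row[f"{measure}_ci_high"] = stack[0, i, j]
                else:
                    row[measure] = summary.median[i, j]
                    row[f"{measure}_ci_low"] = summary.ci_low[i, j]
                    row[f"{measure}_ci_high"] = summary.ci_high[i, j]
            frames.append(row)
    return pd.DataFrame(frames)


def age_share_change(
    baseline: Runs,
    counterfactual: Runs,
    age_groups: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Change in each age group's share of total population, percentage points.

    share_baseline(group) - share_counterfactual(group), with shares
    computed within each run; the changes sum to zero across groups each
    year. Stochastic runs are paired per replicate and summarized.
    """
    age_groups = dict(age_groups or DEFAULT_AGE_GROUPS)
    _check_groups(age_groups)
    years = _as_replicates(baseline)[0].years

    def diff(b: ProjectionResult, c: ProjectionResult) -> np.ndarray:
        _align(b, c)
        out = np.empty((len(b.states), len(age_groups)))
        for i, (sb, sc) in enumerate(zip(b.states, c.states)):
            shares_b = _group_counts(sb.counts, age_groups).sum(axis=1) / sb.total()
            shares_c = _group_counts(sc.counts, age_groups).sum(axis=1) / sc.total()
            out[i] = 100.0 * (shares_b - shares_c)
        return out

    stack = _paired_apply(baseline, counterfactual, diff)
    summary = summarize_reps(stack) if stack.shape[0] > 1 else None
    rows = []
    for i, year in enumerate(years):
        for gi, group in enumerate(age_groups):
            rows.append(
                {
                    "year": int(year),
                    "age_group": group,
                    "change_pp": stack[0, i, gi] if summary is None else summary.median[i, gi],
                    "ci_low": stack[0, i, gi] if summary is None else summary.ci_low[i, gi],
                    "ci_high": stack[0, i, gi] if summary is None else summary.ci_high[i, gi],
                }
            )
    return pd.DataFrame(rows)


def missing_population_summary(
    baseline: Runs,
    counterfactual: Runs,
    age_groups: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Missing population with replicate medians and 95% intervals.

    Deterministic runs give degenerate intervals equal to the point
    values; stochastic runs are paired per replicate (common random
    numbers) before summarizing.
    """
    age_groups = dict(age_groups or DEFAULT_AGE_GROUPS)
    _check_groups(age_groups)
    years = _as_replicates(baseline)[0].years
    names = list(age_groups) + ["total"]
    sexes = list(SEXES) + ["total"]

    def cells(b: ProjectionResult, c: ProjectionResult) -> np.ndarray:
        _align(b, c)
        out = np.empty((len(b.states), len(names), len(sexes), 2))
        for i, (sb, sc) in enumerate(zip(b.states, c.states)):
            gb = _group_counts(sb.counts, age_groups)
            gc = _group_counts(sc.counts, age_groups)
            gb = np.vstack([gb, gb.sum(axis=0)])
            gc = np.vstack([gc, gc.sum(axis=0)])
            gb = np.hstack([gb, gb.sum(axis=1, keepdims=True)])
            gc = np.hstack([gc, gc.sum(axis=1, keepdims=True)])
            absolute = gb - gc
            with np.errstate(divide="ignore", invalid="ignore"):
                relative = np.where(gb > 0, 100.0 * absolute / gb, np.nan)
            out[i] = np.stack([absolute, relative], axis=-1)
        return out

    stack = _paired_apply(baseline, counterfactual, cells)
    summary = summarize_reps(stack) if stack.shape[0] > 1 else None
    med = stack[0] if summary is None else summary.median
    lo = stack[0] if summary is None else summary.ci_low
    hi = stack[0] if summary is None else summary.ci_high
    rows = []
    for i, year in enumerate(years):
        for gi, group in enumerate(names):
            for si, sex in enumerate(sexes):
                rows.append(
                    {
                        "year": int(year),
                        "age_group": group,
                        "sex": sex,
                        "absolute": med[i, gi, si, 0],
                        "absolute_ci_low": lo[i, gi, si, 0],
                        "absolute_ci_high": hi[i, gi, si, 0],
                        "relative": med[i, gi, si, 1],
                        "relative_ci_low": lo[i, gi, si, 1],
                        "relative_ci_high": hi[i, gi, si, 1],
                    }
                )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class StochasticSummary:
    """Per-cell median and central 95% interval across replicates."""

    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def summarize_reps(
    values: np.ndarray, quantiles: Tuple[float, float, float] = (0.025, 0.5, 0.975)
) -> StochasticSummary:
    """Empirical quantile summary over the replicate (first) axis.

    Quantiles use linear interpolation between order statistics. Requires
    at least two replicates; permutation-invariant over the replicate
    axis by construction.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim < 1 or values.shape[0] < 2:
        raise ValueError("summarize_reps requires at least two replicates")
    lo, med, hi = (np.quantile(values, q, axis=0) for q in quantiles)
    return StochasticSummary(median=med, ci_low=lo, ci_high=hi)
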