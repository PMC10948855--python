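"""Missing population, dependency ratios, shares, replicate summaries."""
import numpy as np
import pandas as pd
import pytest

import popshock as ps
from popshock.projection_engine import ProjectionResult
from popshock.schedules_io import FEMALE, MALE, PopulationState


def _single_state_result(counts, year=2025):
    return ProjectionResult([PopulationState(year, counts)])


def test_missing_population_arithmetic():
    b = np.zeros((101, 2))
    c = np.zeros((101, 2))
    b[30, FEMALE], c[30, FEMALE] = 990.0, 1000.0
    df = ps.missing_population(_single_state_result(b), _single_state_result(c))
    row = df[(df.age_group == "15-49") & (df.sex == "female")].iloc[0]
    assert row.absolute == pytest.approx(-10.0)
    assert row.relative == pytest.approx(-10.0 / 990.0 * 100.0, rel=1e-12)
    assert row.additional_without_shock == pytest.approx(10.0)
    # relative undefined where baseline is zero
    assert np.isnan(df[(df.age_group == "85+") & (df.sex == "male")].iloc[0].relative)


def test_missing_population_identical_runs_zero(det_runs):
    b, _ = det_runs
    df = ps.missing_population(b, b)
    assert (df.absolute == 0).all()
    assert (df.relative.dropna() == 0).all()


def test_group_sums_match_single_age_differences(det_runs):
    b, c = det_runs
    df = ps.missing_population(b, c)
    for year in (2025, 2060):
        sub = df[(df.year == year) & (df.sex == "total")]
        total = sub[sub.age_group == "total"].absolute.iloc[0]
        parts = sub[sub.age_group != "total"].absolute.sum()
        assert total == pytest.approx(parts, rel=1e-12)
        direct = b.state_for(year).total() - c.state_for(year).total()
        assert total == pytest.approx(direct, rel=1e-12)


def test_mismatched_horizons_rejected(det_runs):
    b, c = det_runs
    truncated = ProjectionResult(c.states[:-5])
    with pytest.raises(ValueError, match="year range"):
        ps.missing_population(b, truncated)


def test_dependency_ratio_hand_example():
    counts = np.zeros((101, 2))
    counts[5, FEMALE] = 20.0
    counts[30, FEMALE] = 100.0
    counts[70, FEMALE] = 30.0
    r = ps.dependency_ratios(PopulationState(2025, counts))
    assert (r.young, r.old, r.total) == pytest.approx((20.0, 30.0, 50.0))


def test_dependency_ratio_uniform_population():
    r = ps.dependency_ratios(PopulationState(2025, np.ones((101, 2))))
    assert r.young == pytest.approx(15 / 50 * 100)
    assert r.old == pytest.approx(36 / 50 * 100)
    assert r.total - r.young - r.old == 0.0


def test_dependency_ratio_zero_working_age_rejected():
    counts = np.zeros((101, 2))
    counts[70, MALE] = 5.0
    with pytest.raises(ValueError, match="working-age"):
        ps.dependency_ratios(PopulationState(2025, counts))


def test_dependency_difference_sign_convention():
    b = np.ones((101, 2))
    c = np.ones((101, 2))
    c[70] += 1.0  # counterfactual has more old people
    df = ps.dependency_ratio_difference(
        _single_state_result(b), {"all": _single_state_result(c)}
    )
    assert df.old.iloc[0] < 0
    df_same = ps.dependency_ratio_difference(
        _single_state_result(b), {"all": _single_state_result(b)}
    )
    assert (df_same[["young", "old", "total"]] == 0).all().all()


def test_age_share_change_identities(det_runs):
    b, c = det_runs
    df = ps.age_share_change(b, c)
    sums = df.groupby("year").change_pp.sum()
    assert np.abs(sums).max() < 1e-12
    zeros = ps.age_share_change(b, b)
    assert (zeros.change_pp == 0).all()
    # uniform scaling of both runs leaves shares unchanged
    scaled_b = ProjectionResult([PopulationState(s.year, 2.0 * s.counts) for s in b.states])
    scaled_c = ProjectionResult([PopulationState(s.year, 2.0 * s.counts) for s in c.states])
    assert np.allclose(
        ps.age_share_change(scaled_b, scaled_c).change_pp, df.change_pp, rtol=0, atol=1e-12
    )


def test_fertility_only_counterfactual_touches_only_new_cohorts(tiny_truth, profile):
    """Cohorts alive before the shock are identical under a fertility-only
    counterfactual; only cohorts born from 2020 onward can differ."""
    cf = ps.build_counterfactual(tiny_truth.shocked, {"fertility"})
    rb = ps.run_projection(tiny_truth.pop0, tiny_truth.shocked, profile, 2035)
    rc = ps.run_projection(tiny_truth.pop0, cf, profile, 2035)
    for sb, sc in zip(rb.states, rc.states):
        born_before_2020 = np.arange(101) > (sb.year - 2020 - 1)
        assert np.array_equal(sb.counts[born_before_2020], sc.counts[born_before_2020])
    assert not np.array_equal(rb.state_for(2021).counts[0], rc.state_for(2021).counts[0])


def test_summarize_reps_quantiles():
    const = np.full((5, 3), 7.0)
    s = ps.summarize_reps(const)
    assert (s.median == 7.0).all() and (s.ci_low == 7.0).all() and (s.ci_high == 7.0).all()

    s = ps.summarize_reps(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
    assert s.median == 3.0

    draws = np.random.default_rng(2024).standard_normal(1000)
    s = ps.summarize_reps(draws)
    assert abs(s.median) < 0.1
    assert s.ci_low == pytest.approx(-1.96, abs=0.15)
    assert s.ci_high == pytest.approx(1.96, abs=0.15)
    assert s.ci_low <= s.median <= s.ci_high

    with pytest.raises(ValueError, match="two replicates"):
        ps.summarize_reps(np.array([1.0]))


def test_summaries_permutation_invariant():
    rng = np.random.default_rng(5)
    values = rng.normal(size=(40, 6))
    a = ps.summarize_reps(values)
    b = ps.summarize_reps(values[rng.permutation(40)])
    assert np.array_equal(a.median, b.median)
    assert np.array_equal(a.ci_low, b.ci_low)


def test_decompose_components_scenario_set(tiny_truth, profile):
    runs = ps.decompose_components(tiny_truth.shocked, tiny_truth.pop0, profile, 2025)
    assert set(runs) == {"baseline", "all", "mortality", "fertility", "migration"}
    only = ps.decompose_components(
        tiny_truth.shocked, tiny_truth.pop0, profile, 2025, components=["mortality"]
    )
    assert set(only) == {"baseline", "mortality"}


def test_stochastic_missing_population_summary_brackets_deterministic(tiny_truth, profile):
    cf_rates = ps.build_counterfactual(tiny_truth.shocked)
    kw = dict(end_year=2025, mode="stochastic", n_reps=60, seed=9)
    rb = ps.run_projection(tiny_truth.pop0, tiny_truth.shocked, profile, **kw)
    rc = ps.run_projection(tiny_truth.pop0, cf_rates, profile, **kw)
    df = ps.missing_population_summary(rb, rc)
    total = df[(df.age_group == "total") & (df.sex == "total") & (df.year == 2025)].iloc[0]
    assert total.absolute_ci_low <= total.absolute <= total.absolute_ci_high
    det_b = ps.run_projection(tiny_truth.pop0, tiny_truth.shocked, profile, 2025)
    det_c = ps.run_projection(tiny_truth.pop0, cf_rates, profile, 2025)
    det = det_b.state_for(2025).total() - det_c.state_for(2025).total()
    assert total.absolute_ci_low - 5 <= det <= total.absolute_ci_high + 5
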