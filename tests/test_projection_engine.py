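"""Cohort-component engine: survival conversion, bookkeeping, stochastics."""
import numpy as np
import pytest

import popshock as ps
from popshock.projection_engine import STOCHASTIC, substream
from popshock.schedules_io import CoverageError, FEMALE, MALE


def toy_scenario(y0, y1, m=0.0, f=0.0, mig=0.0, srb=1.05):
    """Flat-rate scenario over calendar years y0..y1."""
    years = np.arange(y0, y1 + 1)
    n = years.size
    return ps.RateSchedules(
        ps.MortalityTable(years, np.full((n, 101, 2), float(m))),
        ps.FertilityTable(years, np.arange(15, 50), np.full((n, 35), float(f))),
        ps.MigrationSeries(years, np.full(n, float(mig))),
        ps.SRBSeries(years, np.full(n, float(srb))),
        "toy",
    )


class TestSurvivalConversion:
    def test_zero_rate_gives_certain_survival(self):
        assert ps.mx_to_sx(0.0, 30) == 1.0

    def test_adult_closed_form(self):
        # q = m / (1 + 0.5 m) at ages 1+
        assert ps.mx_to_sx(0.02, 30) == pytest.approx(1 - 0.02 / 1.01, rel=1e-14)

    def test_infant_separation_fraction(self):
        # a(0) = 0.1 gives q = m / (1 + 0.9 m), below the adult midpoint value
        assert ps.mx_to_sx(0.02, 0) == pytest.approx(1 - 0.02 / (1 + 0.9 * 0.02), rel=1e-14)
        assert ps.mx_to_sx(0.02, 0) > ps.mx_to_sx(0.02, 1)

    def test_strictly_decreasing_in_m(self):
        m = np.linspace(0, 1, 50)
        s = ps.mx_to_sx(m, 30)
        assert (np.diff(s) < 0).all()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ps.mx_to_sx(-0.01, 30)


def test_expected_births_arithmetic():
    counts = np.zeros((101, 2))
    counts[15:50, FEMALE] = 1000.0
    pop = ps.PopulationState(2020, counts)
    scen = toy_scenario(2020, 2021, f=0.05)
    assert ps.expected_births(pop, scen.fertility, 2020) == pytest.approx(1750.0)
    empty = ps.PopulationState(2020, np.zeros((101, 2)))
    assert ps.expected_births(empty, scen.fertility, 2020) == 0.0


def test_one_cohort_deterministic_bookkeeping(profile):
    # s(30) = 0.99 corresponds to m = q / (1 - 0.5 q) with q = 0.01
    m = 0.01 / (1 - 0.5 * 0.01)
    scen = toy_scenario(2020, 2021, m=m)
    counts = np.zeros((101, 2))
    counts[30, FEMALE] = 100.0
    nxt = ps.project_one_year(ps.PopulationState(2020, counts), scen, profile)
    assert nxt.year == 2021
    assert nxt.counts[31, FEMALE] == pytest.approx(99.0, rel=1e-12)
    other = nxt.counts.copy()
    other[31, FEMALE] = 0.0
    assert np.all(other == 0.0)


def test_pure_aging_limit_deterministic(tiny_truth, profile):
    """s=1, f=0, M=0 permutes counts upward with a 100+ pool."""
    scen = toy_scenario(2020, 2021)
    pop = tiny_truth.pop0
    nxt = ps.project_one_year(pop, scen, profile)
    assert np.array_equal(nxt.counts[1:100], pop.counts[0:99])
    assert nxt.counts[100].sum() == pytest.approx(pop.counts[99:].sum(), rel=1e-12)
    assert nxt.counts[0].sum() == 0.0
    assert nxt.total() == pytest.approx(pop.total(), rel=1e-12)


def test_pure_aging_limit_stochastic_is_exact(tiny_truth, profile):
    scen = toy_scenario(2020, 2021)
    rng_for_stage = lambda stage: substream(123, 0, 2020, stage)
    nxt = ps.project_one_year(
        tiny_truth.pop0, scen, profile, STOCHASTIC, rng_for_stage
    )
    assert np.array_equal(nxt.counts[1:100], tiny_truth.pop0.counts[0:99])
    assert nxt.counts[100].sum() == tiny_truth.pop0.counts[99:].sum()


def test_stochastic_requires_integer_counts(profile):
    scen = toy_scenario(2020, 2021)
    frac = ps.PopulationState(2020, np.full((101, 2), 0.5))
    with pytest.raises(ValueError, match="integer"):
        ps.project_one_year(frac, scen, profile, STOCHASTIC, lambda s: substream(1, 0, 2020, s))


def test_newborns_split_by_srb_and_survive(profile):
    scen = toy_scenario(2020, 2021, f=0.05, srb=1.05)
    counts = np.zeros((101, 2))
    counts[25, FEMALE] = 1000.0
    nxt = ps.project_one_year(ps.PopulationState(2020, counts), scen, profile)
    births = 50.0
    assert nxt.counts[0, FEMALE] == pytest.approx(births / 2.05, rel=1e-12)
    assert nxt.counts[0, MALE] == pytest.approx(births * 1.05 / 2.05, rel=1e-12)


def test_trivial_horizon_returns_initial_state(tiny_truth, profile):
    res = ps.run_projection(tiny_truth.pop0, tiny_truth.shocked, profile, 2020)
    assert len(res.states) == 1
    assert np.array_equal(res.states[0].counts, tiny_truth.pop0.counts)


def test_horizon_beyond_coverage_rejected(tiny_truth, profile):
    with pytest.raises(CoverageError):
        ps.run_projection(tiny_truth.pop0, tiny_truth.shocked, profile, 2062)


def test_stochastic_runs_reproducible_and_seed_sensitive(tiny_truth, profile):
    args = (tiny_truth.pop0, tiny_truth.shocked, profile, 2024, "stochastic", 3)
    runs_a = ps.run_projection(*args, seed=42)
    runs_b = ps.run_projection(*args, seed=42)
    runs_c = ps.run_projection(*args, seed=43)
    for a, b in zip(runs_a, runs_b):
        assert np.array_equal(a.counts_array(), b.counts_array())
    assert not np.array_equal(runs_a[0].counts_array(), runs_c[0].counts_array())
    # replicates are independent substreams, not copies
    assert not np.array_equal(runs_a[0].counts_array(), runs_a[1].counts_array())


def test_lower_mortality_never_decreases_any_count(tiny_truth, profile):
    base = tiny_truth.shocked
    better = base.copy()
    better.mortality.rates *= 0.9
    r_base = ps.run_projection(tiny_truth.pop0, base, profile, 2035)
    r_better = ps.run_projection(tiny_truth.pop0, better, profile, 2035)
    assert (r_better.counts_array() >= r_base.counts_array() - 1e-12).all()


def test_deterministic_total_matches_component_sum(tiny_truth, profile):
    """total(t+1) = survivors + surviving newborns + net migrants."""
    from popshock.schedules_io import AGES

    scen = tiny_truth.shocked
    pop = tiny_truth.pop0
    for _ in range(5):
        s = ps.mx_to_sx(scen.mortality.rates_for(pop.year), AGES[:, None])
        survivors = (pop.counts * s).sum()
        births = ps.expected_births(pop, scen.fertility, pop.year)
        srb = scen.srb.srb_for(pop.year)
        newborns = births / (1 + srb) * s[0, FEMALE] + births * srb / (1 + srb) * s[0, MALE]
        migrants = scen.migration.total_for(pop.year)
        nxt = ps.project_one_year(pop, scen, profile)
        assert nxt.total() == pytest.approx(survivors + newborns + migrants, rel=1e-9)
        pop = nxt
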