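import pytest
from hypothesis import settings

import popshock as ps

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_truth() -> ps.SyntheticTruth:
    """Shocked/unshocked study fixture at the ~10^4-person scale."""
    return ps.make_study_fixture(seed=7, scale="tiny")


@pytest.fixture(scope="session")
def profile() -> ps.MigrationProfile:
    return ps.build_profile()


@pytest.fixture(scope="session")
def det_runs(tiny_truth, profile):
    """Deterministic baseline and all-counterfactual runs to 2060."""
    cf_rates = ps.build_counterfactual(tiny_truth.shocked)
    baseline = ps.run_projection(tiny_truth.pop0, tiny_truth.shocked, profile, 2060)
    counterfactual = ps.run_projection(tiny_truth.pop0, cf_rates, profile, 2060)
    return baseline, counterfactual
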