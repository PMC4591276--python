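import pytest
from hypothesis import HealthCheck, settings

from clonsel.synthetic_data import CloneModel, simulate_pair
from clonsel.variants import Thresholds, build_merged_table

settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture(scope="session")
def small_pair():
    """One modest simulated pair shared by read-only tests."""
    model = CloneModel(n_ancestral_variants=300, n_selected_variants=60,
                       n_depleted_variants=40, n_neutral_variants=300)
    return simulate_pair(model, seed=11)


@pytest.fixture(scope="session")
def small_merged(small_pair):
    return build_merged_table(small_pair.counts_sensitive,
                              small_pair.counts_resistant)
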