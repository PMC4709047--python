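import numpy as np
import pytest

from founderscan.simulate import CohortSpec, simulate_cohort, truth_table


@pytest.fixture(scope="session")
def small_spec():
    """A small but non-trivial cohort: founder span present, some missingness."""
    return CohortSpec(
        n_stage4=60,
        n_stage12=120,
        n_controls=30,
        n_snps=30,
        region_snps=21,
        index_maf=0.15,
        allelic_or=2.5,
        founder_span=10,
        background_maf_range=(0.08, 0.40),
        missing_rate=0.01,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return truth_table(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160111)
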