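import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across read-only tests."""
    from mnvkit.simulate import CohortConfig, simulate_cohort

    cfg = CohortConfig(n_trios=300, coding_bp=150_000, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    """The same cohort written to disk (VCF, pedigree, truth tables)."""
    from mnvkit.simulate import write_cohort

    out = tmp_path_factory.mktemp("cohort")
    return write_cohort(small_cohort.config, str(out))


@pytest.fixture(scope="session")
def discovered_calls(cohort_dir):
    from mnvkit import discovery

    return discovery.discover(cohort_dir["vcf"], cohort_dir["pedigree"])


@pytest.fixture(scope="session")
def aa_matrix():
    from mnvkit.codons import aa_distance_matrix

    return aa_distance_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
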