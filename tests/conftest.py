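import pytest

from tumorchrono.synthetic_cohort import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact mixed cohort (WGD and diploid samples) reused across tests."""
    config = SimConfig(n_samples=4, seed=7, n_snvs=800)
    cohort, truth = simulate_cohort(config)
    return config, cohort, truth
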