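import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small planted cohort shared by pipeline-level tests."""
    from srnapipe.synthetic_data import (make_genome,
                                         make_targets_and_degradome)

    genome, truth = make_genome(8, 8, seed=11)
    transcripts, deg = make_targets_and_degradome(
        truth, transcripts_n=12, n_compliant=8, n_violating=8,
        signal_reads=50, noise_rate=0.1, seed=12)
    return genome, truth, transcripts, deg


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
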