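import numpy as np
import pytest

from ftcooc.formats_io import GenomicInterval, Pwm
from ftcooc.synthetic_cortex import SyntheticConfig, design_truth, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_pwm():
    return Pwm(tf_name="UNIF", probs=np.full((6, 4), 0.25))


@pytest.fixture
def sharp_pwm():
    # strong consensus ACGTAC with small off-consensus mass
    probs = np.full((6, 4), 0.02)
    for i, b in enumerate([0, 1, 2, 3, 0, 1]):
        probs[i, b] = 0.94
    return Pwm(tf_name="SHARP", probs=probs)


@pytest.fixture(scope="session")
def small_config():
    # desk-scale config used by several integration tests
    return SyntheticConfig(
        n_genes=120,
        n_enhancers=20,
        chrom_length=2_500_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return design_truth(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


def random_interval(rng, chrom="chr1", max_start=10_000, max_len=500):
    start = int(rng.integers(0, max_start))
    end = start + 1 + int(rng.integers(0, max_len))
    strand = rng.choice(["+", "-", "."])
    return GenomicInterval(chrom, start, end, str(strand), "iv")
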