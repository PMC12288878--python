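import numpy as np
import pytest

from ssmut import Genome, SimConfig, simulate_genome


@pytest.fixture
def toy_genome() -> Genome:
    # small explicit sequences used for hand-checkable cases
    return Genome(
        sequences={
            "c1": "AACGGTACCGATTTCCCCGA",
            "c2": "TTGCGGCCAATGCATGCATG",
        }
    )


@pytest.fixture(scope="session")
def sim_genome() -> Genome:
    """A 4 x 80 kb random genome shared across statistical tests."""
    cfg = SimConfig(seed=11, n_chrom=4, chrom_length=80_000)
    return simulate_genome(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
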