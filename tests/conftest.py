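import numpy as np
import pytest

from incseq.benchmarks import consensus_benchmark
from incseq.simulate import make_reference_set

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def two_refs():
    """Two 700 bp references at ~10% per-branch divergence."""
    return make_reference_set(2, 700, 0.1, seed=7)


@pytest.fixture(scope="session")
def high_copy_benchmark():
    """200 reads of 18 copies each at the nanopore-like error model."""
    root = np.random.SeedSequence(ACCEPTANCE_SEED)
    seed = int(root.spawn(2)[0].generate_state(1)[0] % (2**31))
    return consensus_benchmark(seed, n_reads=200, copy_range=(18, 18))


@pytest.fixture(scope="session")
def mixed_copy_benchmark():
    """200 reads with 6-20 copies each at the nanopore-like error model."""
    root = np.random.SeedSequence(ACCEPTANCE_SEED)
    seed = int(root.spawn(2)[1].generate_state(1)[0] % (2**31))
    return consensus_benchmark(seed, n_reads=200, copy_range=(6, 20))
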