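import numpy as np
import pytest

from ssrpop.genotypes import MISSING, GenotypeDataset


def random_dataset(rng, n_samples=8, n_loci=3, n_localities=2,
                   alleles=(101, 103, 105, 107), missing_rate=0.0):
    """Small random dataset for round-trip and oracle tests."""
    calls = rng.choice(alleles, size=(n_samples, n_loci, 2)).astype(np.int32)
    if missing_rate:
        drop = rng.random((n_samples, n_loci)) < missing_rate
        calls[drop] = MISSING
    locs = [f"loc{1 + i % n_localities}" for i in range(n_samples)]
    locs.sort()
    return GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        locus_names=[f"L{j}" for j in range(n_loci)],
        calls=calls,
        localities=locs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240711)


@pytest.fixture(scope="session")
def preset():
    """The 192 x 24 study-emulation dataset + truth (one per session)."""
    from ssrpop.simulate import study_preset

    return study_preset(7)
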