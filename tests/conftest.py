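import numpy as np
import pytest

from superbsa import sim


@pytest.fixture(scope="session")
def toy_genome() -> sim.ReferenceGenome:
    """Small annotated genome shared by annotation/overlap tests."""
    return sim.make_genome(
        n_scaffolds=2, scaffold_len=50_000, gene_density=100, repeat_fraction=0.1, seed=11
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
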