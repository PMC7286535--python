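import numpy as np
import pytest

from genopca.genotypes import GenotypeMatrix, drop_monomorphic
from genopca.simulate import SimulationSpec, simulate_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """A modest structured panel: 2000 SNPs x 300 samples, 3 populations."""
    spec = SimulationSpec(m=2000, n=300, q=3, fst=0.05, seed=7)
    geno, labels, freqs = simulate_genotypes(spec)
    geno, _ = drop_monomorphic(geno)
    return geno, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genotypes(rng, m, n, missing_rate=0.0) -> GenotypeMatrix:
    """Random unstructured genotype matrix, optionally with missing calls."""
    values = rng.integers(0, 3, size=(m, n)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((m, n)) < missing_rate
        # keep at least one called genotype per row
        full = mask.all(axis=1)
        mask[full, 0] = False
        rows, cols = np.nonzero(mask)
        values[rows, cols] = 0
        return GenotypeMatrix(values, rows, cols)
    return GenotypeMatrix(values)
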