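import numpy as np
import pytest

from fragdrift.genotypes import GenotypeMatrix
from fragdrift.synthetic import study_spectra


@pytest.fixture(scope="session")
def spectra10():
    """Ten moderately diverse locus spectra (He 0.65, six alleles each)."""
    return study_spectra(10, 6.0, 0.65, seed=42)


@pytest.fixture(scope="session")
def spectra5():
    return study_spectra(5, 5.0, 0.60, seed=42)


@pytest.fixture
def toy_matrix():
    """4 individuals, 2 populations, 2 loci, one missing call."""
    calls = np.array(
        [
            [[150, 152], [200, 200]],
            [[150, 150], [200, 204]],
            [[152, 152], [-1, -1]],
            [[150, 152], [204, 204]],
        ]
    )
    return GenotypeMatrix(
        ["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"], ["L1", "L2"], calls
    )


def random_matrix(rng, n=20, n_loci=5, n_pops=2, missing_rate=0.0):
    """Random genotype matrix for round-trip and tally oracles."""
    alleles = 100 + 2 * np.arange(8)
    calls = rng.choice(alleles, size=(n, n_loci, 2))
    if missing_rate:
        miss = rng.uniform(size=(n, n_loci)) < missing_rate
        calls[miss] = -1
    pops = [f"P{1 + (i * n_pops) // n}" for i in range(n)]
    return GenotypeMatrix([f"i{i}" for i in range(n)], pops, [f"L{j}" for j in range(n_loci)], calls)
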