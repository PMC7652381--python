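import numpy as np
import pytest

from popdiv import GenotypeMatrix


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """4 diploids (2 basalt + 2 chalk), 6 sites, no missing data."""
    genotypes = np.array(
        [
            [0, 1, 2, 0, 1, 2],
            [0, 2, 2, 1, 0, 2],
            [1, 0, 0, 2, 1, 2],
            [2, 0, 1, 2, 2, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        sample_ids=["b1", "b2", "c1", "c2"],
        pop_labels=["basalt", "basalt", "chalk", "chalk"],
        chrom=np.array(["chr1"] * 6, dtype=object),
        pos=np.array([10, 25, 40, 55, 70, 85]),
        genotypes=genotypes,
    )


@pytest.fixture
def missing_matrix() -> GenotypeMatrix:
    """4 samples, 5 sites, with missing calls sprinkled in."""
    genotypes = np.array(
        [
            [0, 1, -1, 0, 2],
            [1, -1, 2, 0, 2],
            [2, 1, 1, -1, 0],
            [-1, 0, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        pop_labels=["p1", "p1", "p2", "p2"],
        chrom=np.array(["chr1"] * 5, dtype=object),
        pos=np.array([100, 200, 300, 400, 500]),
        genotypes=genotypes,
    )


def brute_force_pi_per_site(genotypes: np.ndarray) -> float:
    """Mean pairwise allele-copy difference summed over sites (oracle).

    Expands each diploid dosage into explicit allele copies and averages
    differences over every pair of called copies at each site.
    """
    total = 0.0
    for col in genotypes.T:
        copies = []
        for g in col:
            if g == -1:
                continue
            copies += [1, 1] if g == 2 else ([0, 1] if g == 1 else [0, 0])
        n = len(copies)
        if n < 2:
            continue
        diffs = sum(
            copies[a] != copies[b] for a in range(n) for b in range(a + 1, n)
        )
        total += diffs / (n * (n - 1) / 2)
    return total
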