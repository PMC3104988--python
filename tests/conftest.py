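import numpy as np
import pytest

from clonepop.genotypes_io import GenotypeDataset


def make_dataset(rows, loci=None, pop="p1"):
    """Build a single-population dataset from a list of call rows.

    Each row is a list of 2-tuples (or None); individuals are auto-named.
    """
    n_loci = len(rows[0])
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    individuals = [f"i{k + 1:03d}" for k in range(len(rows))]
    return GenotypeDataset(
        individuals=individuals,
        populations={ind: pop for ind in individuals},
        loci=list(loci),
        calls=[list(r) for r in rows],
    )


def random_dataset(rng, n_ind=4, n_loci=3, n_alleles=4, n_pops=1,
                   missing_rate=0.0):
    """Small random dataset with 3-digit allele labels (GenePop-safe)."""
    alleles = [f"{a + 101:03d}" for a in range(n_alleles)]
    individuals = [f"ind{k + 1:03d}" for k in range(n_ind)]
    pops = {ind: f"pop{(k % n_pops) + 1}"
            for k, ind in enumerate(individuals)}
    # keep individuals of one population contiguous (GenePop requirement)
    individuals.sort(key=lambda i: pops[i])
    calls = []
    for _ in individuals:
        row = []
        for _j in range(n_loci):
            if rng.random() < missing_rate:
                row.append(None)
            else:
                row.append(tuple(sorted(rng.choice(alleles, 2))))
        calls.append(row)
    return GenotypeDataset(
        individuals=individuals, populations=pops,
        loci=[f"L{j + 1}" for j in range(n_loci)], calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
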