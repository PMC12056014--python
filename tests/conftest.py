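import numpy as np
import pytest

from sweepscan.hapio import HaplotypeMatrix


def make_matrix(alleles, positions=None, pops=None, chrom="chr1"):
    """HaplotypeMatrix from a (sites x haplotypes) list/array."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites, n_hap = alleles.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    if pops is None:
        pops = ["POP1"] * n_hap
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        hap_pop=np.asarray(pops),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_panel(rng, n_sites, n_hap, pops=None):
    """Random binary panel with strictly increasing positions."""
    alleles = rng.integers(0, 2, size=(n_sites, n_hap), dtype=np.int8)
    positions = np.sort(rng.choice(np.arange(1, 100 * n_sites), n_sites, replace=False))
    return make_matrix(alleles, positions=positions, pops=pops)


def ehh_pair_oracle(hm, carriers, lo, hi):
    """Brute-force EHH: enumerate all carrier pairs, count identical strings."""
    carriers = list(carriers)
    n = len(carriers)
    ident = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            a = hm.alleles[lo : hi + 1, carriers[i]]
            b = hm.alleles[lo : hi + 1, carriers[j]]
            ident += int((a == b).all())
    return ident / total
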