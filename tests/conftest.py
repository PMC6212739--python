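import numpy as np
import pytest

from antebayes.data_model import GenotypeData, PhenotypeData


def make_geno(markers, chrom=None, pos=None, animal_ids=None):
    """Build a GenotypeData from a raw 0/1/2 matrix with an auto map."""
    markers = np.asarray(markers)
    n, m = markers.shape
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    chrom = np.asarray(chrom, dtype=object)
    if pos is None:
        pos = np.empty(m, dtype=np.int64)
        counter = {}
        for j in range(m):
            counter[chrom[j]] = counter.get(chrom[j], 0) + 1
            pos[j] = counter[chrom[j]] * 1000
    if animal_ids is None:
        animal_ids = [f"A{i+1}" for i in range(n)]
    return GenotypeData(
        markers=markers,
        marker_ids=np.array([f"SNP{j+1}" for j in range(m)], dtype=object),
        chromosome=chrom,
        position=np.asarray(pos),
        animal_ids=np.asarray(animal_ids, dtype=object),
    )


@pytest.fixture
def toy_geno():
    """6 animals x 4 SNPs on two chromosomes (to exercise the boundary)."""
    rng = np.random.default_rng(42)
    markers = rng.integers(0, 3, size=(6, 4))
    markers[0] = [0, 1, 2, 1]  # guarantee polymorphism
    return make_geno(markers, chrom=[1, 1, 2, 2])


@pytest.fixture
def toy_pheno(toy_geno):
    rng = np.random.default_rng(7)
    return PhenotypeData(y=rng.standard_normal(toy_geno.n_animals))
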