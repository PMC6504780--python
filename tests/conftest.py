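import numpy as np
import pytest

from epipath.genotype_io import GenotypeMatrix, VariantRecord


def make_matrix(genotypes, phenotype, chrom="1", positions=None,
                snp_ids=None, alleles=None):
    """Build a GenotypeMatrix from raw arrays with generated metadata."""
    G = np.asarray(genotypes, dtype=np.int8)
    n, m = G.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if snp_ids is None:
        snp_ids = [f"rs{j + 1}" for j in range(m)]
    if alleles is None:
        alleles = [("A", "G")] * m
    variants = []
    for j in range(m):
        col = G[:, j]
        nonmiss = col[col >= 0]
        f = float(nonmiss.sum()) / (2 * nonmiss.size) if nonmiss.size else 0.0
        variants.append(VariantRecord(snp_ids[j], chrom, positions[j],
                                      alleles[j][0], alleles[j][1],
                                      min(f, 1 - f)))
    samples = [f"S{i + 1}" for i in range(n)]
    return GenotypeMatrix(variants, samples, G,
                          np.asarray(phenotype, dtype=np.int8))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
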