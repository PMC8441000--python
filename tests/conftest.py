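import numpy as np
import pandas as pd
import pytest

from prsgxe.geno_io import GenotypeMatrix, GwasSummary


def make_geno(dosages, pos=None, chrom="1", snp_ids=None, alleles=None):
    """Build a GenotypeMatrix from a samples x SNPs array with defaults."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if snp_ids is None:
        snp_ids = [f"snp{j + 1:03d}" for j in range(m)]
    if pos is None:
        pos = [1000 * (j + 1) for j in range(m)]
    if alleles is None:
        alleles = [("A", "G")] * m
    meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom if isinstance(chrom, list) else [chrom] * m,
            "pos": pos,
            "counted_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
        }
    )
    samples = [f"s{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(samples, meta, dosages)


def make_gwas(snp_ids, betas, pvals, pos=None, chrom="1", alleles=None):
    m = len(snp_ids)
    if pos is None:
        pos = [1000 * (j + 1) for j in range(m)]
    if alleles is None:
        alleles = [("A", "G")] * m
    return GwasSummary(
        pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": chrom if isinstance(chrom, list) else [chrom] * m,
                "pos": pos,
                "effect_allele": [a for a, _ in alleles],
                "other_allele": [b for _, b in alleles],
                "beta": betas,
                "p_value": pvals,
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geno_factory():
    return make_geno


@pytest.fixture
def gwas_factory():
    return make_gwas
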