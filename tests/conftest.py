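import numpy as np
import pytest

from kinchem.genotype_io import (
    DIPLOID,
    PSEUDO_HAPLOID,
    GenotypeMatrix,
    SampleRecord,
    SNPRecord,
)


def make_matrix(calls, chromosomes=None, ploidy_modes=None, populations=None):
    """Build a GenotypeMatrix from a (samples x snps) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_snps = calls.shape
    if chromosomes is None:
        chromosomes = ["1"] * n_snps
    positions = {}
    snps = []
    for j, chrom in enumerate(chromosomes):
        positions[chrom] = positions.get(chrom, 0) + 100
        snps.append(
            SNPRecord(
                snp_id=f"rs{j}",
                chromosome=chrom,
                position_bp=positions[chrom],
                ref_allele="A",
                alt_allele="G",
            )
        )
    if populations is None:
        populations = [f"pop{i}" for i in range(n_samples)]
    samples = [
        SampleRecord(sample_id=f"s{i}", population_label=populations[i])
        for i in range(n_samples)
    ]
    return GenotypeMatrix(
        samples=samples,
        snps=snps,
        calls=calls,
        ploidy_modes=list(ploidy_modes) if ploidy_modes else [],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
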