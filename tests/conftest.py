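import numpy as np
import pytest

from snpruns import GenotypeDataset, SampleRecord, SnpRecord


def make_dataset(
    calls,
    positions=None,
    chrom="1",
    breeds=None,
    chroms=None,
):
    """Build a small GenotypeDataset from a call matrix.

    ``positions`` default to 10 kb spacing; ``chroms`` (per SNP) overrides
    the single ``chrom`` label; ``breeds`` (per sample) defaults to one
    breed "B1".
    """
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [10_000 * (j + 1) for j in range(m)]
    if chroms is None:
        chroms = [chrom] * m
    if breeds is None:
        breeds = ["B1"] * n
    samples = [
        SampleRecord(sample_id=f"s{i + 1}", breed=breeds[i]) for i in range(n)
    ]
    snps = [
        SnpRecord(chrom=chroms[j], snp_id=f"m{j + 1}", bp=int(positions[j]))
        for j in range(m)
    ]
    return GenotypeDataset(samples=samples, snps=snps, calls=calls)


@pytest.fixture
def toy_dataset():
    """4 samples x 3 SNPs with a missing call and two breeds."""
    return make_dataset(
        [
            [0, 1, 0],
            [0, 2, -1],
            [1, 1, 0],
            [2, 0, 0],
        ],
        breeds=["B1", "B1", "B2", "B2"],
    )
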