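import numpy as np
import pytest

from popsweep import CohortDesign, GenotypeMatrix, PopulationMap, simulate_structured_cohort


def make_matrix(gt, pos=None, chrom="chr1", haplotypes=None, chrom_length=None):
    """Small GenotypeMatrix builder for hand-written fixtures."""
    gt = np.asarray(gt, dtype=np.int8)
    n_samples, n_variants = gt.shape
    if pos is None:
        pos = np.arange(1, n_variants + 1) * 10
    lengths = {chrom: chrom_length} if chrom_length else {}
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        chrom=np.array([chrom] * n_variants, dtype=object),
        pos=np.asarray(pos),
        ref=np.array(["A"] * n_variants, dtype=object),
        alt=np.array(["T"] * n_variants, dtype=object),
        gt=gt,
        haplotypes=haplotypes,
        chrom_lengths=lengths,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort shared by several tests."""
    design = CohortDesign(n_snps=3000, chrom_length=3_000_000, seed=11)
    return simulate_structured_cohort(design)


@pytest.fixture
def two_pop_map():
    def build(samples_a, samples_b, pop_a="P1", pop_b="P2"):
        recs = [(s, pop_a, "R1") for s in samples_a]
        recs += [(s, pop_b, "R2") for s in samples_b]
        return PopulationMap.from_records(recs)

    return build
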