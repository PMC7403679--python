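import numpy as np
import pandas as pd
import pytest

from nichescan import AlleleCounts, GenotypeMatrix, SimConfig


def counts_from_arrays(pos, counts, totals, hets=None, contig="chr1",
                       populations=("popA", "popB")):
    """Build an AlleleCounts directly from per-site arrays (toy inputs)."""
    counts = np.asarray(counts)
    totals = np.asarray(totals)
    if hets is None:
        hets = np.zeros_like(counts)
    return AlleleCounts(
        contig=np.asarray([contig] * len(pos), dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        populations=list(populations),
        counts=counts,
        totals=totals,
        hets=np.asarray(hets),
    )


@pytest.fixture
def small_config():
    return SimConfig(n_contigs=2, contig_length=50_000, n_snps=800, seed=11)


@pytest.fixture
def random_genotypes():
    """A small random genotype matrix with two populations and missingness."""
    rng = np.random.default_rng(5)
    n_snps, n_per_pop = 60, 8
    geno = rng.integers(0, 3, size=(n_snps, 2 * n_per_pop)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.1] = -1
    samples = [f"a{i}" for i in range(n_per_pop)] + [f"b{i}" for i in range(n_per_pop)]
    pops = np.array(["popA"] * n_per_pop + ["popB"] * n_per_pop, dtype=object)
    return GenotypeMatrix(
        contig=np.array(["chr1"] * n_snps, dtype=object),
        pos=np.arange(0, n_snps * 50, 50),
        geno=geno,
        samples=samples,
        sample_pops=pops,
    )
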