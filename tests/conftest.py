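import numpy as np
import pytest

from terk.intervals import GenomicInterval, TELocus
from terk.simulate import make_annotation


@pytest.fixture(scope="session")
def small_annotation():
    """A compact 2-chromosome annotation shared by read-level tests."""
    ann, truth = make_annotation(
        11, n_chroms=2, chrom_len=200_000, families=3, loci_per_family=15, n_genes=20
    )
    return ann, truth


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"), span=10_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 500))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


def random_loci(rng: np.random.Generator, n: int, families=("A", "B", "C"), span=50_000):
    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(100, 1200))
        fam = str(rng.choice(families))
        out.append(
            TELocus(
                GenomicInterval(str(rng.choice(["chr1", "chr2"])), start, start + length,
                                str(rng.choice(["+", "-"]))),
                fam,
                locus_id=f"L{i}:{fam}",
            )
        )
    return out
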