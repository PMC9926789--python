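import numpy as np
import pytest

from mirevo.io import AnnotationSet, MirnaLocus


@pytest.fixture
def five_loci():
    """Two near neighbours, one distant locus on chr1; two on chr2."""
    return [
        MirnaLocus("mirA", "chr1", 100, 180),
        MirnaLocus("mirB", "chr1", 5000, 5080),
        MirnaLocus("mirC", "chr1", 30000, 30080),
        MirnaLocus("mirD", "chr2", 200, 280),
        MirnaLocus("mirE", "chr2", 900, 980),
    ]


@pytest.fixture
def simple_annotation():
    return AnnotationSet(
        intervals=[
            ("chr1", 50, 150, "repeat"),
            ("chr1", 120, 300, "exon"),
            ("chr1", 4000, 6000, "intron"),
            ("chr2", 100, 1000, "intron"),
        ],
        chrom_lengths={"chr1": 50_000, "chr2": 10_000},
    )


def random_loci(rng: np.random.Generator, n: int, n_chrom: int = 3,
                chrom_len: int = 200_000, locus_len: int = 80):
    """Uniform random loci for oracle-equivalence checks."""
    loci = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(0, chrom_len - locus_len))
        loci.append(MirnaLocus(f"m{i}", chrom, start, start + locus_len))
    return loci
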