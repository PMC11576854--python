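import numpy as np
import pytest

from chromtraj.core_io import GeneAnnotation, GenomicInterval
from chromtraj.synthetic_data import StudyConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (seed 42), shared read-only across tests."""
    return simulate_study(StudyConfig())


@pytest.fixture(scope="session")
def small_study():
    """A small study for cheap end-to-end checks."""
    cfg = StudyConfig(
        n_per_class={"PO": 30, "CO": 30, "OC": 30, "NEVER": 30, "TRANSIENT": 30},
        n_pseudo=2000, n_linked_genes=60, n_unlinked_genes=10,
        n_targets={"alpha": 30, "beta": 15}, n_shared_sites=5, seed=7)
    return simulate_study(cfg)


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                     span: int = 20_000, max_len: int = 300) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


def random_genes(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                 span: int = 40_000) -> list[GeneAnnotation]:
    genes = []
    for i in range(n):
        chrom = str(rng.choice(chroms))
        tss = int(rng.integers(0, span))
        genes.append(GeneAnnotation(f"g{i:03d}", chrom, "+", tss,
                                    GenomicInterval(chrom, tss, tss + 1000)))
    return genes
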