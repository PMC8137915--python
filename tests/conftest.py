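import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from robfusion3d.genome import GenomeAssembly, Karyotype, make_bin_table, simulate_genome
from robfusion3d.matrix import ContactMatrix
from robfusion3d.profiles import default_profile


def matrix_from_dense(
    dense: np.ndarray,
    chrom_lengths: dict[str, int],
    resolution: int,
    mask: np.ndarray | None = None,
    metadata: dict | None = None,
) -> ContactMatrix:
    """Build a ContactMatrix from a dense symmetric array (test helper)."""
    genome = GenomeAssembly(
        chrom_names=list(chrom_lengths),
        chrom_lengths=dict(chrom_lengths),
        centromere_pos={c: 0 for c in chrom_lengths},
    )
    bins = make_bin_table(genome, resolution)
    assert len(bins) == dense.shape[0]
    mat = ContactMatrix(
        resolution,
        bins,
        sp.csr_matrix(np.asarray(dense, dtype=float)),
        mask=mask,
        metadata=metadata or {},
    )
    return mat


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(3, [40_000_000, 35_000_000, 25_000_000], seed=7)


@pytest.fixture(scope="session")
def rs_profile():
    return default_profile("RS")


@pytest.fixture(scope="session")
def fib_profile():
    return default_profile("fibroblast")


@pytest.fixture(scope="session")
def no_fusion():
    return Karyotype([], {})


@pytest.fixture(scope="session")
def one_fusion():
    return Karyotype([("chr1", "chr2")], {("chr1", "chr2"): "homozygous"})
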