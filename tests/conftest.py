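import numpy as np
import pytest

from hlacall import (
    EvidenceMatrix,
    PanelSpec,
    make_panel,
)


@pytest.fixture(scope="session")
def small_panel():
    """2 genes x 8 alleles, one exon-2/3 twin pair per gene."""
    return make_panel(PanelSpec(n_genes=2, alleles_per_gene=8, seed=11))


@pytest.fixture(scope="session")
def default_panel():
    """The 3 genes x 20 alleles panel used by the larger experiments."""
    return make_panel(PanelSpec(seed=7))


def dense_evidence(ll: np.ndarray, read_bases: int = 100) -> EvidenceMatrix:
    """EvidenceMatrix from a dense log-likelihood array (test helper)."""
    N, M = ll.shape
    reads = [f"r{i:04d}" for i in range(N)]
    alleles = [f"Z*{j + 1:02d}:01" for j in range(M)]
    entries = {
        (reads[i], alleles[j]): float(ll[i, j])
        for i in range(N)
        for j in range(M)
        if np.isfinite(ll[i, j])
    }
    return EvidenceMatrix(
        reads=reads,
        alleles=alleles,
        entries=entries,
        read_bases={r: read_bases for r in reads},
    )
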