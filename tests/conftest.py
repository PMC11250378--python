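import numpy as np
import pandas as pd
import pytest

from proxbias.genome import assign_arms
from proxbias.maps import SimilarityMap


def toy_loci_arms():
    """Two chromosomes x two arms x five genes, mixed strands."""
    arms = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2", "chr2"],
        "arm": ["p", "q", "p", "q"],
        "arm_start": [1, 130, 1, 130],
        "arm_end": [100, 260, 100, 260],
        "acrocentric": [False] * 4,
    })
    rows = []
    gid = 0
    for chrom in ("chr1", "chr2"):
        for base in (0, 129):
            for k in range(5):
                gid += 1
                start = base + 10 + 18 * k
                rows.append((f"g{gid:02d}", f"G{gid}", chrom, start, start + 5,
                             "+" if gid % 2 else "-"))
    loci = pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"])
    return loci, arms


@pytest.fixture(scope="session")
def toy_index():
    loci, arms = toy_loci_arms()
    return assign_arms(loci, arms)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


def random_map(n_genes, d=32, seed=0, index=None):
    """Cosine map of iid Gaussian vectors, optionally arm-annotated."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_genes, d))
    U = X / np.linalg.norm(X, axis=1, keepdims=True)
    S = np.clip(U @ U.T, -1, 1)
    np.fill_diagonal(S, 1.0)
    genes = pd.Index([f"g{i:02d}" for i in range(1, n_genes + 1)])
    arms = index.arm_of.reindex(genes) if index is not None else None
    return SimilarityMap(genes, S, arms)
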