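import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for the oracles module

from resmnn.mnn import find_mnn_pairs
from resmnn.preprocess import (fit_pca, normalize_and_log, qc_filter,
                               scale_and_clip, select_hvgs)
from resmnn.simulate import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_data():
    """Two batches x 300 cells, 3 cell types, 400 genes; default batch shift."""
    return generate(SyntheticConfig(
        n_batches=2, cells_per_batch=[300, 300], n_genes=400, n_celltypes=3,
        seed=1))


@pytest.fixture(scope="session")
def preprocessed(small_data):
    """The small dataset taken through the full preprocessing chain."""
    clean = qc_filter(small_data, min_genes_per_cell=10, min_cells_per_gene=3)
    normlog = normalize_and_log(clean)
    hvgs = select_hvgs(normlog, clean.gene_ids, n_top=200)
    scaled = scale_and_clip(normlog, clean.gene_ids, hvgs)
    pca, emb = fit_pca(scaled, n_pc=30)
    pairs = find_mnn_pairs(emb, clean.batch, k=20, method="exact", seed=1)
    return {"data": clean, "normlog": normlog, "hvgs": hvgs, "scaled": scaled,
            "pca": pca, "embedding": emb, "pairs": pairs}
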