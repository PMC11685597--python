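"""Shared fixtures: toy datasets and a session-scoped simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crosstype.containers import ExpressionDataset
from crosstype.simulate import SimConfig, simulate_pair


def make_dataset(
    counts: np.ndarray,
    species: str = "sp1",
    cell_types=None,
    cell_classes=None,
    samples=None,
    gene_ids=None,
) -> ExpressionDataset:
    """Build a small validated dataset from a dense count array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_ids = (
        list(gene_ids) if gene_ids is not None else [f"g{i:03d}" for i in range(n_genes)]
    )
    cell_meta = pd.DataFrame(
        {
            "species": species,
            "sample": list(samples) if samples is not None else f"{species}_s0",
            "cell_class": list(cell_classes) if cell_classes is not None else "",
            "cell_type": list(cell_types) if cell_types is not None else "",
        },
        index=pd.Index([f"{species}_c{i:03d}" for i in range(n_cells)], name="cell_id"),
    )
    gene_meta = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    gene_meta["symbol"] = gene_ids
    return ExpressionDataset(
        counts=sp.csr_matrix(counts), cell_meta=cell_meta, gene_meta=gene_meta
    )


# A small but realistic simulation shared by recovery-style tests. Smaller
# than the defaults so the suite stays fast; effect sizes are the defaults.
SMALL_SIM = SimConfig(
    seed=7,
    n_types_A=4,
    n_types_B=4,
    cells_per_type=90,
    n_genes=600,
    markers_per_type=25,
    n_regulators=9,
    targets_per_regulator=25,
)


@pytest.fixture(scope="session")
def small_pair():
    return simulate_pair(SMALL_SIM)


@pytest.fixture(scope="session")
def small_activity(small_pair):
    from crosstype import qc_cluster, rosa

    ds_A = small_pair[0]
    regulons = small_pair[3]
    X = qc_cluster.normalize_log_cpm(ds_A)
    Z = rosa.coarse_grain(rosa.expression_zscores(X), 100)
    return rosa.rosa_nes(
        Z,
        ds_A.gene_ids,
        regulons,
        cell_ids=ds_A.cell_ids,
        cell_classes=ds_A.cell_meta["cell_class"],
    )
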