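import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from trajlink.simulate import SimulationConfig, simulate_bundle
from trajlink.types import CellAnnotation, ExpressionMatrix, GeneTraitTable


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # degenerate-input warnings are part of several contracts under test;
    # keep the output readable without hiding unexpected ones per-test
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """4 genes x 3 cells with hand-checkable counts."""
    counts = np.array(
        [
            [1, 0, 2],
            [1, 3, 0],
            [0, 1, 1],
            [2, 0, 5],
        ]
    )
    return ExpressionMatrix(
        gene_ids=np.array(["g1", "g2", "g3", "g4"], dtype=object),
        cell_ids=np.array(["c1", "c2", "c3"], dtype=object),
        counts=sp.csr_matrix(counts),
    )


def make_gene_table(rng, n_genes, covariates=("length",)) -> GeneTraitTable:
    from scipy import stats

    z = rng.normal(size=n_genes)
    data = {"z": z, "p": stats.norm.sf(z), "n_snps": 1}
    for cov in covariates:
        data[cov] = rng.lognormal(size=n_genes)
    idx = pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene_id")
    return GeneTraitTable(pd.DataFrame(data, index=idx), list(covariates))


def make_annotation(cell_ids, pseudotime, branch=None, n_detected=100) -> CellAnnotation:
    frame = pd.DataFrame(
        {
            "pseudotime": np.asarray(pseudotime, dtype=float),
            "branch": branch if branch is not None else "main",
            "n_detected": n_detected,
        },
        index=pd.Index(list(cell_ids), name="cell_id"),
    )
    return CellAnnotation(frame)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest planted scenario reused by pipeline-level tests."""
    config = SimulationConfig(
        n_genes=600,
        n_cells=300,
        n_trait_genes=60,
        n_induced_genes=60,
        n_overlap=30,
        n_sets=10,
        seed=42,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_bundle(config, n_decoy_traits=1)
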