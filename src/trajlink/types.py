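"""Core in-memory containers shared by all pipeline stages.

The containers are thin wrappers around pandas / scipy.sparse objects: they
carry the identifiers, enforce the structural invariants once at
construction, and expose the handful of derived quantities (average
normalized expression, detected-gene counts) that several stages need.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

__all__ = [
    "GeneTraitTable",
    "ExpressionMatrix",
    "CellAnnotation",
    "GeneSetCollection",
    "DEFAULT_BRANCH",
]

#: branch label used when an annotation file carries no branch column
DEFAULT_BRANCH = "main"


@dataclass
class GeneTraitTable:
    """Per-gene GWAS association statistics plus technical covariates.

    ``table`` is indexed by gene id and holds at least the columns ``z``
    (gene association Z-score), ``p`` (gene association p-value) and
    ``n_snps``; ``covariates`` names the additional numeric columns (gene
    length at minimum when available) that enter regression designs as the
    technical-confounder block.
    """

    table: pd.DataFrame
    covariates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in trait table: {dups}")
        for col in ("z", "p"):
            if col not in self.table.columns:
                raise ValidationError(f"trait table missing column {col!r}")
        missing = [c for c in self.covariates if c not in self.table.columns]
        if missing:
            raise ValidationError(f"covariate columns absent from table: {missing}")
        if self.covariates and self.table[self.covariates].isna().any().any():
            raise ValidationError("covariate columns contain missing values")

    @property
    def genes(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy(dtype=float)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        """Technical covariates as an (n_genes, n_covariates) array."""
        if not self.covariates:
            return np.empty((len(self.table), 0))
        return self.table[self.covariates].to_numpy(dtype=float)

    def subset(self, genes) -> "GeneTraitTable":
        return GeneTraitTable(self.table.loc[list(genes)], list(self.covariates))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ExpressionMatrix:
    """Genes x cells count matrix with optional log-normalized layer."""

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: sp.csr_matrix
    lognorm: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in expression matrix")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids in expression matrix")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative values in count matrix")
        if self.lognorm is not None:
            self.lognorm = sp.csr_matrix(self.lognorm)
            if self.lognorm.shape != self.counts.shape:
                raise ValidationError("lognorm layer shape differs from counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cells_detected_per_gene(self) -> np.ndarray:
        """Number of cells with a nonzero count, per gene."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def genes_detected_per_cell(self) -> np.ndarray:
        """Number of genes with a nonzero count, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0), dtype=float).ravel()

    def average_lognorm(self) -> pd.Series:
        """Mean log-normalized expression per gene across all cells (the
        dataset-average expression covariate of the cell-scoring model)."""
        if self.lognorm is None:
            raise ValidationError("lognorm layer not computed; normalize first")
        avg = np.asarray(self.lognorm.mean(axis=1)).ravel()
        return pd.Series(avg, index=self.gene_ids, name="avg_lognorm")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to (and reorder by) the given gene ids."""
        pos = pd.Index(self.gene_ids).get_indexer(list(genes))
        if (pos < 0).any():
            missing = [g for g, i in zip(genes, pos) if i < 0]
            raise ValidationError(f"genes absent from expression matrix: {missing[:5]}")
        return ExpressionMatrix(
            gene_ids=np.asarray(list(genes), dtype=object),
            cell_ids=self.cell_ids,
            counts=self.counts[pos],
            lognorm=None if self.lognorm is None else self.lognorm[pos],
        )

    def lognorm_dense(self, gene_order=None) -> np.ndarray:
        """Dense (genes, cells) log-normalized matrix, optionally reordered."""
        if self.lognorm is None:
            raise ValidationError("lognorm layer not computed; normalize first")
        if gene_order is None:
            return self.lognorm.toarray()
        pos = pd.Index(self.gene_ids).get_indexer(list(gene_order))
        if (pos < 0).any():
            raise ValidationError("gene_order contains unknown gene ids")
        return self.lognorm[pos].toarray()


@dataclass
class CellAnnotation:
    """Per-cell metadata: pseudotime, branch label, detected-gene count.

    ``frame`` is indexed by cell id with columns ``pseudotime``, ``branch``
    and ``n_detected``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "pseudotime" not in self.frame.columns:
            raise ValidationError("cell annotation missing 'pseudotime' column")
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate cell ids in annotation")
        pt = self.frame["pseudotime"].to_numpy(dtype=float)
        if not np.isfinite(pt).all():
            raise ValidationError("non-finite pseudotime values")
        if (pt < 0).any():
            raise ValidationError("negative pseudotime values")
        if "branch" not in self.frame.columns:
            self.frame = self.frame.assign(branch=DEFAULT_BRANCH)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def pseudotime(self) -> pd.Series:
        return self.frame["pseudotime"].astype(float)

    @property
    def branch(self) -> pd.Series:
        return self.frame["branch"]

    @property
    def n_detected(self) -> pd.Series:
        if "n_detected" not in self.frame.columns:
            raise ValidationError("annotation has no 'n_detected' column")
        return self.frame["n_detected"].astype(float)

    def branch_labels(self, exclude=()) -> list:
        labels = sorted(set(self.frame["branch"]) - set(exclude))
        return labels

    def subset(self, cell_ids) -> "CellAnnotation":
        return CellAnnotation(self.frame.loc[list(cell_ids)].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique set names, unique members."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.sets.items():
            seen, uniq = set(), []
            for g in members:
                if g not in seen:
                    seen.add(g)
                    uniq.append(g)
            clean[name] = uniq
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name) -> list:
        return self.sets[name]

    def __contains__(self, name) -> bool:
        return name in self.sets

    def names(self) -> list:
        return list(self.sets)

    def items(self):
        return self.sets.items()
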