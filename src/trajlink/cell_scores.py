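"""Per-cell trait-association scores.

Each cell is scored by regressing the genes' GWAS Z-scores on that cell's
log-normalized expression, adjusting for the dataset-average expression and
the technical covariates of the trait table:

    Z = b0 + C*bc + A*bA + B*bB + e

where C is the cell's expression vector, A the average expression across
cells and B the technical-confounder block (gene length at minimum). The
t-statistic of ``bc`` is the cell-trait association score: it measures
whether trait-associated genes are preferentially expressed in that cell,
over and above what average expression and gene-level technicalities
explain. The fit is plain OLS with a homoskedastic t-test; no gene-gene LD
correlation structure is modelled (that would require an external reference
panel), which makes the score an approximation of the reference
gene-property statistic of the same form.

Scoring all cells shares one fixed design block, so the whole pass reduces
to residualizing Z and each cell vector against that block once
(Frisch-Waugh-Lovell) and costs a single matrix product per chunk of cells.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ValidationError
from .io import intersect_genes
from .types import ExpressionMatrix, GeneTraitTable

log = logging.getLogger(__name__)

__all__ = ["DesignBlock", "build_design", "cell_trait_score", "score_all_cells"]

# relative tolerance below which a residualized cell vector is considered
# to lie in the span of the fixed design (score undefined)
_SPAN_RTOL = 1e-12


@dataclass
class DesignBlock:
    """Fixed regressors shared by every cell: intercept, average expression,
    technical covariates."""

    matrix: np.ndarray  # (n_genes, k)
    columns: list
    genes: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


def build_design(genes, gene_table: GeneTraitTable, avg_expr) -> DesignBlock:
    """Assemble the fixed design block [intercept, avg_expr, covariates...].

    Zero-variance covariate columns are dropped with a warning; a
    rank-deficient result raises, naming the collinear columns.
    """
    genes = np.asarray(list(genes), dtype=object)
    table = gene_table.subset(genes)
    avg = pd.Series(avg_expr).reindex(genes) if not isinstance(avg_expr, pd.Series) else avg_expr.reindex(genes)
    if avg.isna().any():
        raise ValidationError("avg_expr missing values for some genes")
    cols = {"intercept": np.ones(len(genes)), "avg_expr": avg.to_numpy(dtype=float)}
    cov = table.covariate_matrix()
    for name, values in zip(gene_table.covariates, cov.T):
        cols[name] = values.astype(float)

    kept_names, kept_cols = [], []
    for name, values in cols.items():
        if name != "intercept" and np.ptp(values) == 0:
            warnings.warn(f"design column {name!r} is constant across genes; dropped")
            continue
        kept_names.append(name)
        kept_cols.append(values)
    X = np.column_stack(kept_cols)

    # rank check: name the columns whose R-diagonal collapses
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = 1e-10 * max(diag.max(), 1.0)
    bad = [kept_names[i] for i in np.flatnonzero(diag <= tol)]
    if bad:
        raise ValidationError(f"design is rank deficient; collinear column(s): {bad}")
    return DesignBlock(matrix=X, columns=kept_names, genes=genes)


def cell_trait_score(cell_lognorm, z, design: DesignBlock):
    """Score one cell: OLS of Z on [design block, C]; returns (beta_c, t, se).

    A cell with constant expression across genes has no defined score and
    yields NaNs with a warning.
    """
    c = np.asarray(cell_lognorm, dtype=float)
    z = np.asarray(z, dtype=float)
    if c.shape[0] != design.n_genes or z.shape[0] != design.n_genes:
        raise ValidationError("length mismatch between cell vector, z and design")
    if np.ptp(c) == 0:
        warnings.warn("cell expression vector is constant; score undefined")
        return (np.nan, np.nan, np.nan)
    X = np.column_stack([design.matrix, c])
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    rss = float(resid @ resid)
    df = n - k
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(rss / df * xtx_inv[-1, -1]))
    if se == 0 or not np.isfinite(se):
        return (float(beta[-1]), np.nan, np.nan)
    return (float(beta[-1]), float(beta[-1] / se), se)


def score_all_cells(
    expr: ExpressionMatrix,
    gene_table: GeneTraitTable,
    trait: str = "trait",
    chunk_size: int = 1024,
) -> pd.DataFrame:
    """Score every cell against one trait.

    Genes are restricted to the expression/trait-table intersection, the
    fixed design block is built once, and cells are processed in chunks via
    residualization so memory stays bounded by one chunk of dense expression.
    Returns a frame with columns cell_id, trait, score, beta_c, se,
    n_genes_used; cells with undefined scores carry NaN.
    """
    if expr.lognorm is None:
        raise ValidationError("expression must be log-normalized before scoring")
    expr_s, table_s = intersect_genes(expr, gene_table)
    avg = expr_s.average_lognorm()
    design = build_design(expr_s.gene_ids, table_s, avg)
    z = table_s.z
    n, k = design.matrix.shape
    df = n - k - 1
    if df < 1:
        raise ValidationError("fewer genes than design parameters")

    q, _ = np.linalg.qr(design.matrix)
    z_res = z - q @ (q.T @ z)
    z_ss = float(z_res @ z_res)

    n_cells = expr_s.n_cells
    beta = np.full(n_cells, np.nan)
    tstat = np.full(n_cells, np.nan)
    se_arr = np.full(n_cells, np.nan)
    lognorm = expr_s.lognorm.tocsc()
    for start in range(0, n_cells, chunk_size):
        stop = min(start + chunk_size, n_cells)
        C = np.asarray(lognorm[:, start:stop].todense())  # (n_genes, m)
        const = np.ptp(C, axis=0) == 0
        C_res = C - q @ (q.T @ C)
        den = np.einsum("ij,ij->j", C_res, C_res)
        num = z_res @ C_res
        c_ss = np.einsum("ij,ij->j", C, C)
        undef = const | (den <= _SPAN_RTOL * np.maximum(c_ss, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            b = num / den
            rss = z_ss - num**2 / den
            rss = np.maximum(rss, 0.0)
            se = np.sqrt(rss / df / den)
            t = b / se
        beta[start:stop] = np.where(undef, np.nan, b)
        se_arr[start:stop] = np.where(undef, np.nan, se)
        tstat[start:stop] = np.where(undef, np.nan, t)

    n_undef = int(np.isnan(tstat).sum())
    if n_undef:
        warnings.warn(f"{n_undef} of {n_cells} cells have undefined scores")
    if n_undef > 0.5 * n_cells:
        raise ComputationError(
            f"{n_undef}/{n_cells} cells have undefined scores; input looks degenerate"
        )
    return pd.DataFrame(
        {
            "cell_id": expr_s.cell_ids,
            "trait": trait,
            "score": tstat,
            "beta_c": beta,
            "se": se_arr,
            "n_genes_used": n,
        }
    )
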