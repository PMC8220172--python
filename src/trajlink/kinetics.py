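"""Per-gene pseudotime effects and the ranked gene list that feeds GSEA.

Each gene's expression kinetics along the trajectory is summarized by the
t-statistic of the pseudotime coefficient in a Gaussian GLM (i.e. OLS) of
its log-normalized expression on pseudotime, with the number of detected
genes per cell as a covariate:

    lognorm ~ 1 + pseudotime + n_detected

For branch-specific kinetics the pseudotime term is replaced by
branch:pseudotime interactions, fitted on the duplicated-progenitor table,
and the requested branch's interaction t is returned. Genes are then ranked
ascending by effect t: the head of the list holds genes whose expression
declines along the trajectory, the tail genes that are induced.

All genes share the same (cells x 3) design, so the whole scan is a single
QR factorization plus one matrix product per chunk of genes.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import ComputationError, ParameterError, ValidationError
from .types import CellAnnotation, ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "pseudotime_effect",
    "pseudotime_effects",
    "branch_pseudotime_effect",
    "branch_pseudotime_effects",
    "rank_genes",
]


def _effects_for_design(Y: np.ndarray, X: np.ndarray, coef_index: int) -> np.ndarray:
    """t-statistics of one coefficient across many responses.

    ``Y`` is (cells, genes); ``X`` (cells, k). Zero-variance responses get
    t = 0 by convention (they carry no kinetic signal and stay mid-list).
    """
    n, k = X.shape
    if n < k + 1:
        raise ValidationError(f"need >= {k + 1} cells for a {k}-parameter kinetic fit")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise ComputationError(
            "kinetic design is collinear (is pseudotime proportional to the "
            "detected-genes covariate?)"
        )
    beta = np.linalg.solve(r, q.T @ Y)  # (k, genes)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    df = n - k
    r_inv = np.linalg.solve(r, np.eye(k))
    c_jj = float(np.sum(r_inv[coef_index] ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df * c_jj)
        t = beta[coef_index] / se
    # exact fits (rss == 0) on a non-constant response: +/- inf by slope sign
    exact = (rss <= 0) & (np.ptp(Y, axis=0) > 0)
    t[exact] = np.sign(beta[coef_index, exact]) * np.inf
    zero_var = np.ptp(Y, axis=0) == 0
    t[zero_var] = 0.0
    n_zero = int(zero_var.sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero-variance genes scored t=0")
    return t


def _kinetic_design(pt: np.ndarray, ndet: np.ndarray) -> np.ndarray:
    """[1, pseudotime, n_detected], dropping a constant detected-genes
    covariate (it is then redundant with the intercept)."""
    cols = [np.ones_like(pt), pt]
    if np.ptp(ndet) > 0:
        cols.append(ndet)
    return np.column_stack(cols)


def pseudotime_effects(
    expr: ExpressionMatrix, annot: CellAnnotation, chunk_size: int = 512
) -> pd.Series:
    """Pseudotime-effect t for every gene (vectorized whole-trajectory scan)."""
    if expr.lognorm is None:
        raise ValidationError("expression must be log-normalized first")
    annot_aligned = annot.subset(expr.cell_ids)
    pt = annot_aligned.pseudotime.to_numpy()
    ndet = annot_aligned.n_detected.to_numpy()
    X = _kinetic_design(pt, ndet)
    out = np.empty(expr.n_genes)
    lognorm = expr.lognorm.tocsr()
    for start in range(0, expr.n_genes, chunk_size):
        stop = min(start + chunk_size, expr.n_genes)
        Y = np.asarray(lognorm[start:stop].todense()).T  # cells x genes
        out[start:stop] = _effects_for_design(Y, X, coef_index=1)
    return pd.Series(out, index=expr.gene_ids, name="effect_t")


def pseudotime_effect(gene_lognorm, annot: CellAnnotation) -> float:
    """Pseudotime-effect t for a single gene's per-cell expression vector."""
    y = np.asarray(gene_lognorm, dtype=float)
    pt = annot.pseudotime.to_numpy()
    ndet = annot.n_detected.to_numpy()
    if len(y) != len(pt):
        raise ValidationError("gene vector length does not match annotation")
    if len(y) < 4:
        raise ValidationError("need >= 4 cells")
    X = _kinetic_design(pt, ndet)
    return float(_effects_for_design(y[:, None], X, coef_index=1)[0])


def _branch_design(assignment: pd.DataFrame, annot: CellAnnotation):
    """Duplicated-progenitor design for branch-interaction kinetics."""
    labels = sorted(assignment["branch"].unique())
    cell_pos = pd.Index(annot.cell_ids.astype(str)).get_indexer(assignment["cell_id"].astype(str))
    if (cell_pos < 0).any():
        raise ValidationError("assignment contains cells absent from annotation")
    ndet = annot.n_detected.to_numpy()[cell_pos]
    pt = assignment["pseudotime"].to_numpy(dtype=float)
    cols = [np.ones(len(assignment))]
    if np.ptp(ndet) > 0:
        cols.append(ndet)
    slope_offset = len(cols)
    for lab in labels:
        cols.append(pt * (assignment["branch"] == lab).to_numpy(dtype=float))
    return np.column_stack(cols), labels, cell_pos, slope_offset


def branch_pseudotime_effects(
    expr: ExpressionMatrix,
    annot: CellAnnotation,
    assignment: pd.DataFrame,
    branch: str,
    chunk_size: int = 512,
) -> pd.Series:
    """Branch-specific pseudotime-effect t for every gene.

    Fits ``lognorm ~ 1 + n_detected + branch:pseudotime`` on the
    duplicated-progenitor table and returns the t of the requested branch's
    interaction coefficient.
    """
    if expr.lognorm is None:
        raise ValidationError("expression must be log-normalized first")
    X, labels, cell_pos, slope_offset = _branch_design(assignment, annot)
    if branch not in labels:
        raise ParameterError(f"unknown branch {branch!r}; available: {labels}")
    coef_index = slope_offset + labels.index(branch)
    out = np.empty(expr.n_genes)
    lognorm = expr.lognorm.tocsr()
    for start in range(0, expr.n_genes, chunk_size):
        stop = min(start + chunk_size, expr.n_genes)
        Y = np.asarray(lognorm[start:stop].todense())[:, cell_pos].T
        out[start:stop] = _effects_for_design(Y, X, coef_index=coef_index)
    return pd.Series(out, index=expr.gene_ids, name="effect_t")


def branch_pseudotime_effect(
    gene_lognorm, annot: CellAnnotation, assignment: pd.DataFrame, branch: str
) -> float:
    """Single-gene version of :func:`branch_pseudotime_effects`."""
    y = np.asarray(gene_lognorm, dtype=float)
    X, labels, cell_pos, slope_offset = _branch_design(assignment, annot)
    if branch not in labels:
        raise ParameterError(f"unknown branch {branch!r}; available: {labels}")
    coef_index = slope_offset + labels.index(branch)
    return float(_effects_for_design(y[cell_pos][:, None], X, coef_index=coef_index)[0])


def rank_genes(effects: pd.Series) -> pd.DataFrame:
    """Sort genes ascending by effect t (declining first, induced last).

    Undefined (NaN) effects are excluded with a logged count; ties are
    broken by gene id for determinism. Rank 1 is the most declining gene.
    """
    effects = pd.Series(effects)
    defined = effects.dropna()
    n_dropped = len(effects) - len(defined)
    if n_dropped:
        log.info("rank_genes excluded %d genes with undefined effects", n_dropped)
    if len(defined) < 2:
        raise ValidationError("need >= 2 genes with defined effects to rank")
    df = defined.rename("effect_t").rename_axis("gene_id").reset_index()
    df["gene_id"] = df["gene_id"].astype(str)
    df = df.sort_values(["effect_t", "gene_id"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
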