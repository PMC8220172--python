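"""Readers, writers and preprocessing for the standard input formats.

Supported inputs: gene-level GWAS association tables (MAGMA ``.genes.out``
dialect or a generic TSV), MatrixMarket / dense-TSV count matrices, per-cell
annotation TSVs, GMT gene-set collections and two-column ortholog maps.
Preprocessing covers one-to-one ortholog mapping, minimum-cell gene
filtering and library-size log-normalization (counts scaled to a fixed
total per cell, then ``log1p``).
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy import stats

from .errors import FormatError, ParameterError, ValidationError
from .types import DEFAULT_BRANCH, CellAnnotation, ExpressionMatrix, GeneSetCollection, GeneTraitTable

log = logging.getLogger(__name__)

__all__ = [
    "p_to_z",
    "z_to_p",
    "read_gene_scores",
    "write_gene_scores",
    "read_expression",
    "write_expression_mtx",
    "write_expression_tsv",
    "map_orthologs",
    "read_ortholog_map",
    "filter_genes",
    "lognormalize",
    "read_gmt",
    "write_gmt",
    "read_cell_annotation",
    "write_cell_annotation",
    "intersect_genes",
]

# p-values are clamped to this range before the inverse-normal transform so
# that extreme but legitimate inputs map to large finite Z-scores.
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


def p_to_z(p):
    """Convert association p-values to Z-scores via the inverse normal.

    ``z = Phi^{-1}(1 - p)``, so small p maps to large positive z and
    ``p = 0.5`` maps to 0. Values outside ``[P_FLOOR, P_CEIL]`` are clamped
    (with a warning) to keep the transform finite while preserving order.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr <= 0).any() or (arr > 1).any()):
        raise ParameterError("p-values must lie in (0, 1]")
    clipped = np.clip(arr, P_FLOOR, P_CEIL)
    if (clipped != arr).any():
        warnings.warn("p-values clamped before inverse-normal transform")
    z = stats.norm.isf(clipped)
    return float(z) if np.isscalar(p) else z


def z_to_p(z):
    """Upper-tail normal probability, the inverse of :func:`p_to_z`."""
    p = stats.norm.sf(np.asarray(z, dtype=float))
    return float(p) if np.isscalar(z) else p


# ---------------------------------------------------------------------------
# gene-level GWAS tables
# ---------------------------------------------------------------------------

_MAGMA_REQUIRED = ("GENE", "NSNPS", "ZSTAT", "P")
_GENERIC_REQUIRED = ("gene_id",)


def read_gene_scores(path, dialect: str = "magma_genes_out") -> GeneTraitTable:
    """Read a gene-level GWAS association table.

    ``magma_genes_out`` is the whitespace-delimited MAGMA gene-analysis
    output (columns GENE, NSNPS, ZSTAT, P, ...); gene length is derived from
    START/STOP when present and exposed as a technical covariate. The
    ``generic_tsv`` dialect expects a header with ``gene_id`` plus ``z``
    and/or ``p``; any additional numeric column is treated as a covariate.
    Rows missing both z and p are dropped (count logged); a missing one of
    the pair is filled from the other through the normal transform.
    """
    path = Path(path)
    if dialect == "magma_genes_out":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        missing = [c for c in _MAGMA_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"{path.name}: missing required column(s) {missing}")
        out = pd.DataFrame(
            {
                "gene_id": df["GENE"].astype(str),
                "n_snps": df["NSNPS"],
                "z": pd.to_numeric(df["ZSTAT"], errors="coerce"),
                "p": pd.to_numeric(df["P"], errors="coerce"),
            }
        )
        covariates = []
        if {"START", "STOP"}.issubset(df.columns):
            out["length"] = (df["STOP"] - df["START"] + 1).astype(float)
            covariates.append("length")
    elif dialect == "generic_tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _GENERIC_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"{path.name}: missing required column(s) {missing}")
        if "z" not in df.columns and "p" not in df.columns:
            raise FormatError(f"{path.name}: need at least one of columns 'z', 'p'")
        out = pd.DataFrame({"gene_id": df["gene_id"].astype(str)})
        out["z"] = pd.to_numeric(df["z"], errors="coerce") if "z" in df.columns else np.nan
        out["p"] = pd.to_numeric(df["p"], errors="coerce") if "p" in df.columns else np.nan
        out["n_snps"] = df["n_snps"] if "n_snps" in df.columns else 0
        reserved = {"gene_id", "z", "p", "n_snps"}
        covariates = []
        for col in df.columns:
            if col in reserved:
                continue
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.notna().all():
                out[col] = vals
                covariates.append(col)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    dup = out["gene_id"][out["gene_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate gene_id in {path.name}: {dup}")

    both_missing = out["z"].isna() & out["p"].isna()
    if both_missing.any():
        log.info("dropping %d rows with neither z nor p", int(both_missing.sum()))
        out = out[~both_missing]
    fill_z = out["z"].isna() & out["p"].notna()
    if fill_z.any():
        out.loc[fill_z, "z"] = p_to_z(out.loc[fill_z, "p"].to_numpy())
    fill_p = out["p"].isna() & out["z"].notna()
    if fill_p.any():
        out.loc[fill_p, "p"] = z_to_p(out.loc[fill_p, "z"].to_numpy())

    both = out["z"].notna() & out["p"].notna()
    if both.any():
        # rounded upstream output can disagree slightly; warn, keep z as given
        dev = np.abs(out.loc[both, "z"].to_numpy() - p_to_z(out.loc[both, "p"].to_numpy()))
        if np.nanmax(dev, initial=0.0) > 1e-6:
            warnings.warn(
                "z and p columns are not mutually consistent to 1e-6 "
                "(max |z - Phi^{-1}(1-p)| = %.3g); keeping z as given" % float(np.nanmax(dev))
            )
    out = out.set_index("gene_id")
    return GeneTraitTable(out, covariates)


def write_gene_scores(table: GeneTraitTable, path) -> None:
    """Write a trait table in the ``generic_tsv`` dialect."""
    df = table.table.reset_index()
    if "index" in df.columns:
        df = df.rename(columns={"index": "gene_id"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _companion(path: Path, suffix: str) -> Path:
    stem = str(path)
    if stem.endswith(".mtx"):
        stem = stem[: -len(".mtx")]
    return Path(stem + suffix)


def read_expression(
    path,
    format: str = "mtx_triplet",
    genes_path=None,
    cells_path=None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a genes x cells count matrix.

    ``mtx_triplet`` expects a MatrixMarket coordinate file with companion
    newline-delimited gene and cell id files (default ``<stem>.genes.txt``
    and ``<stem>.cells.txt``). ``dense_tsv`` expects gene ids in the first
    column and cell ids in the header row; ``transpose`` flips that
    orientation.
    """
    path = Path(path)
    if format == "mtx_triplet":
        genes_path = _companion(path, ".genes.txt") if genes_path is None else Path(genes_path)
        cells_path = _companion(path, ".cells.txt") if cells_path is None else Path(cells_path)
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FormatError(f"companion id file not found: {p}")
        mat = scipy.io.mmread(str(path))
        gene_ids = [ln for ln in genes_path.read_text().splitlines() if ln]
        cell_ids = [ln for ln in cells_path.read_text().splitlines() if ln]
        if transpose:
            mat = mat.T
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise FormatError(
                f"matrix header claims {mat.shape} but id files list "
                f"{len(gene_ids)} genes and {len(cell_ids)} cells"
            )
        counts = sp.csr_matrix(mat)
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if transpose:
            df = df.T
        gene_ids = df.index.astype(str).tolist()
        cell_ids = df.columns.astype(str).tolist()
        counts = sp.csr_matrix(df.to_numpy(dtype=float))
    else:
        raise ParameterError(f"unknown expression format {format!r}")

    data = counts.data
    if data.size and (np.mod(data, 1) != 0).any():
        raise FormatError("count matrix contains non-integer values")
    counts.data = data.astype(np.int64)
    return ExpressionMatrix(np.array(gene_ids, dtype=object), np.array(cell_ids, dtype=object), counts)


def write_expression_mtx(expr: ExpressionMatrix, prefix) -> Path:
    """Write counts as ``<prefix>.mtx`` + gene/cell id files; returns mtx path."""
    prefix = Path(prefix)
    mtx = prefix.with_suffix(".mtx") if prefix.suffix != ".mtx" else prefix
    scipy.io.mmwrite(str(mtx), expr.counts.tocoo(), field="integer")
    _companion(mtx, ".genes.txt").write_text("\n".join(map(str, expr.gene_ids)) + "\n")
    _companion(mtx, ".cells.txt").write_text("\n".join(map(str, expr.cell_ids)) + "\n")
    return mtx


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.counts.toarray(), index=expr.gene_ids, columns=expr.cell_ids)
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def read_ortholog_map(path) -> pd.DataFrame:
    """Read a two-column (source_id, target_id) TSV ortholog map."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("ortholog map needs two columns (source_id, target_id)")
    df = df.iloc[:, :2]
    df.columns = ["source_id", "target_id"]
    return df


def map_orthologs(expr: ExpressionMatrix, ortholog_map: pd.DataFrame) -> ExpressionMatrix:
    """Rename genes to their one-to-one orthologs; drop everything else.

    Any source or target id appearing more than once in the map is excluded
    (the one-to-one rule, applied symmetrically); genes absent from the map
    are dropped. Counts of retained genes are untouched.
    """
    m = ortholog_map.iloc[:, :2].copy()
    m.columns = ["source_id", "target_id"]
    m = m.dropna()
    one_to_one = m[
        ~m["source_id"].duplicated(keep=False) & ~m["target_id"].duplicated(keep=False)
    ]
    lookup = dict(zip(one_to_one["source_id"], one_to_one["target_id"]))
    keep_mask = np.array([g in lookup for g in expr.gene_ids])
    if not keep_mask.any():
        raise ValidationError(
            "no expression gene maps through the ortholog table; "
            "check species or id scheme"
        )
    n_dropped = int((~keep_mask).sum())
    if n_dropped:
        log.info("ortholog mapping dropped %d of %d genes", n_dropped, expr.n_genes)
    idx = np.flatnonzero(keep_mask)
    new_ids = np.array([lookup[expr.gene_ids[i]] for i in idx], dtype=object)
    return ExpressionMatrix(
        gene_ids=new_ids,
        cell_ids=expr.cell_ids,
        counts=expr.counts[idx],
        lognorm=None if expr.lognorm is None else expr.lognorm[idx],
    )


def filter_genes(expr: ExpressionMatrix, min_cells: int = 10) -> ExpressionMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ParameterError("min_cells must be >= 0")
    detected = expr.cells_detected_per_gene()
    keep = detected >= min_cells
    if not keep.any():
        raise ValidationError(f"all genes expressed in < {min_cells} cells")
    if (~keep).any():
        log.info("gene filter (>=%d cells) dropped %d of %d genes", min_cells, int((~keep).sum()), expr.n_genes)
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        gene_ids=expr.gene_ids[idx],
        cell_ids=expr.cell_ids,
        counts=expr.counts[idx],
        lognorm=None if expr.lognorm is None else expr.lognorm[idx],
    )


def lognormalize(expr: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Library-size normalization: ``log(1 + scale * count / cell_total)``.

    Per cell, ``sum(exp(lognorm) - 1) == scale`` whenever the cell has at
    least one count; cells with a zero total are rejected.
    """
    if scale <= 0:
        raise ParameterError("scale must be positive")
    totals = expr.cell_totals()
    zero = totals == 0
    if zero.any():
        bad = [str(c) for c in expr.cell_ids[zero]][:10]
        raise ValidationError(f"cells with zero total counts: {bad}")
    norm = expr.counts.astype(float).multiply(scale / totals[None, :]).tocsr()
    norm.data = np.log1p(norm.data)
    return ExpressionMatrix(expr.gene_ids, expr.cell_ids, expr.counts, lognorm=norm)


def intersect_genes(expr: ExpressionMatrix, table: GeneTraitTable):
    """Restrict both containers to their common genes (expression order).

    Regressions of GWAS Z on expression require paired observations, so
    genes present in only one input are dropped (counts logged).
    """
    common = [g for g in expr.gene_ids if g in set(table.genes)]
    if not common:
        raise ValidationError("no genes shared between expression matrix and trait table")
    n_expr_only = expr.n_genes - len(common)
    n_table_only = len(table) - len(common)
    if n_expr_only or n_table_only:
        log.info(
            "gene intersection kept %d genes (dropped %d expression-only, %d table-only)",
            len(common), n_expr_only, n_table_only,
        )
    return expr.subset_genes(common), table.subset(common)


# ---------------------------------------------------------------------------
# gene sets and annotations
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name<TAB>description<TAB>member1<TAB>member2..."""
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{Path(path).name}:{lineno}: GMT line has < 3 fields")
            name, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise FormatError(f"{Path(path).name}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_cell_annotation(path, expr: ExpressionMatrix | None = None) -> CellAnnotation:
    """Read the per-cell TSV (cell_id, pseudotime[, branch][, n_detected]).

    When ``expr`` is given, ids are validated against the expression matrix,
    rows are reordered to match it, and ``n_detected`` is computed from the
    raw counts if absent. A missing branch column yields a single default
    label.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "pseudotime"):
        if col not in df.columns:
            raise FormatError(f"annotation missing required column {col!r}")
    df["cell_id"] = df["cell_id"].astype(str)
    if df["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id in annotation")
    df = df.set_index("cell_id")
    if "branch" not in df.columns:
        df["branch"] = DEFAULT_BRANCH
    if expr is not None:
        expr_ids = pd.Index(expr.cell_ids.astype(str))
        missing = expr_ids.difference(df.index)
        extra = df.index.difference(expr_ids)
        if len(missing) or len(extra):
            raise ValidationError(
                f"annotation/expression cell id mismatch: {len(missing)} missing, {len(extra)} extra"
            )
        df = df.loc[expr_ids]
        df.index.name = "cell_id"
        if "n_detected" not in df.columns:
            df["n_detected"] = expr.genes_detected_per_cell()
        elif (df["n_detected"].to_numpy() > expr.n_genes).any():
            raise ValidationError("n_detected exceeds number of genes")
    annot = CellAnnotation(df)
    return annot


def write_cell_annotation(annot: CellAnnotation, path) -> None:
    annot.frame.reset_index(names="cell_id").to_csv(path, sep="\t", index=False)
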