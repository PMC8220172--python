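"""Coupled synthetic data with planted trajectory-trait structure.

The generator emulates the statistical situation the pipeline is built for:
a GWAS gene-score table in which a subset of "trait genes" carries an
elevated mean Z, and a scRNA-seq count matrix in which a subset of
"induced genes" increases its expression along a (possibly branched)
pseudotime axis. The overlap between the two subsets is the planted
trajectory-trait link. Counts are negative-binomial with log-linear
pseudotime effects on the induced genes, per-cell library-size factors and
optional extra Bernoulli dropout, so that per-cell detected-gene fractions
land in the sparse regime typical of droplet scRNA-seq. A planted gene set
enriched for the overlap genes, among random decoy sets, exercises the
GSEA and competitive-test stages.

Every generator is deterministic given ``SimulationConfig.seed``; the two
main generators draw the planted gene roles from a shared derived stream so
GWAS and expression outputs are mutually consistent when produced
separately.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ParameterError
from .io import (
    write_cell_annotation,
    write_expression_mtx,
    write_gene_scores,
    write_gmt,
    z_to_p,
)
from .types import CellAnnotation, ExpressionMatrix, GeneSetCollection, GeneTraitTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationBundle",
    "simulate_gwas_scores",
    "simulate_decoy_gwas_scores",
    "simulate_trajectory_counts",
    "simulate_gene_sets",
    "simulate_bundle",
    "write_bundle",
]

_BRANCH_LABELS = ("B1", "B2", "B3")
PROGENITOR_LABEL = "progenitor"

# stream keys so each generator has its own reproducible substream
_STREAMS = {"roles": 11, "gwas": 23, "cells": 37, "counts": 41, "sets": 53, "decoy": 67}


@dataclass
class SimulationConfig:
    """Planted-scenario parameters.

    The defaults describe the standard "linked" scenario: 2,000 genes,
    500 cells on an unbranched unit-pseudotime axis, 100 trait genes with a
    mean Z shift of 2, 100 induced genes gaining one log-unit of expression
    per pseudotime unit, and 50 genes in the overlap carrying the planted
    link. Library sizes and dispersion put per-cell detection in the
    10-20% range typical of droplet data.
    """

    n_genes: int = 2000
    n_cells: int = 500
    n_branches: int = 1
    frac_progenitors: float = 0.4  # branch-point quantile of pseudotime
    n_trait_genes: int = 100
    n_induced_genes: int = 100
    n_overlap: int = 50
    trait_effect: float = 2.0
    induction_slope: float = 1.0
    nb_dispersion: float = 0.5
    library_size_mean: float = 450.0
    library_size_sigma: float = 0.3
    dropout_extra: float = 0.0
    length_z_coef: float = 0.0
    n_sets: int = 20
    planted_set_size: int = 100
    set_purity: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches not in (1, 2, 3):
            raise ParameterError("n_branches must be 1, 2 or 3")
        if self.n_overlap > min(self.n_trait_genes, self.n_induced_genes):
            raise ParameterError("n_overlap exceeds trait/induced gene counts")
        for name in ("n_trait_genes", "n_induced_genes", "n_overlap"):
            if getattr(self, name) > self.n_genes:
                raise ParameterError(f"{name} exceeds n_genes")
        if not (0 <= self.dropout_extra < 1):
            raise ParameterError("dropout_extra must be in [0, 1)")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ParameterError("dispersion and library size must be positive")
        if not (0 < self.frac_progenitors < 1):
            raise ParameterError("frac_progenitors must be in (0, 1)")
        if not (0 < self.set_purity <= 1):
            raise ParameterError("set_purity must be in (0, 1]")


@dataclass
class SimulationTruth:
    """Planted structure, sufficient to score recovery without re-derivation."""

    trait_genes: list
    induced_genes: list
    induced_branch: str | None
    overlap_genes: list
    planted_set_name: str | None
    planted_set_members: list
    pseudotime: dict
    branch: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulationBundle:
    config: SimulationConfig
    gene_tables: dict  # trait name -> GeneTraitTable
    expr: ExpressionMatrix
    annot: CellAnnotation
    collection: GeneSetCollection
    truth: SimulationTruth


def _rng(config: SimulationConfig, key: str, extra: int = 0):
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[key], extra]))


def _gene_ids(config: SimulationConfig) -> np.ndarray:
    width = len(str(config.n_genes))
    return np.array([f"G{i:0{width}d}" for i in range(config.n_genes)], dtype=object)


def _roles(config: SimulationConfig):
    """Planted gene roles, shared between the GWAS and count generators."""
    rng = _rng(config, "roles")
    gene_ids = _gene_ids(config)
    perm = rng.permutation(config.n_genes)
    induced_idx = perm[: config.n_induced_genes]
    overlap_idx = induced_idx[: config.n_overlap]
    rest = perm[config.n_induced_genes :]
    trait_idx = np.concatenate([overlap_idx, rest[: config.n_trait_genes - config.n_overlap]])
    return gene_ids, np.sort(induced_idx), np.sort(trait_idx), np.sort(overlap_idx)


def _gwas_table(config, rng, gene_ids, trait_idx) -> GeneTraitTable:
    n = config.n_genes
    length = rng.lognormal(mean=np.log(2.0e4), sigma=1.0, size=n)
    z = rng.normal(0.0, 1.0, size=n)
    z[trait_idx] += config.trait_effect
    if config.length_z_coef:
        log_len = np.log(length)
        z += config.length_z_coef * (log_len - log_len.mean()) / log_len.std()
    table = pd.DataFrame(
        {
            "z": z,
            "p": z_to_p(z),
            "n_snps": 1 + rng.poisson(length / 2000.0),
            "length": length,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneTraitTable(table, ["length"])


def simulate_gwas_scores(config: SimulationConfig):
    """Gene-level GWAS table with planted trait genes.

    Background genes draw Z from a standard normal; trait genes from
    ``Normal(trait_effect, 1)``; p is the upper-tail normal probability.
    Gene length is log-normal and can be correlated with Z through
    ``length_z_coef`` to exercise covariate adjustment.
    """
    gene_ids, induced_idx, trait_idx, overlap_idx = _roles(config)
    table = _gwas_table(config, _rng(config, "gwas"), gene_ids, trait_idx)
    truth_part = {
        "trait_genes": gene_ids[trait_idx].tolist(),
        "overlap_genes": gene_ids[overlap_idx].tolist(),
    }
    return table, truth_part


def simulate_decoy_gwas_scores(config: SimulationConfig, index: int) -> GeneTraitTable:
    """A decoy trait: same marginal structure, trait genes drawn at random
    from the non-induced genes so the decoy carries no trajectory link."""
    gene_ids, induced_idx, _, _ = _roles(config)
    rng = _rng(config, "decoy", extra=index)
    candidates = np.setdiff1d(np.arange(config.n_genes), induced_idx)
    trait_idx = rng.choice(candidates, size=config.n_trait_genes, replace=False)
    return _gwas_table(config, rng, gene_ids, trait_idx)


def simulate_trajectory_counts(config: SimulationConfig, max_resample: int = 5):
    """Negative-binomial counts whose log-means track pseudotime.

    Pseudotime is uniform on (0, 1). For branched configurations, cells
    before the branch-point quantile are progenitors; later cells are
    committed uniformly at random to the branches. Induced genes gain
    ``induction_slope`` log-units per pseudotime unit — on every cell for
    unbranched runs, and only on cells of the first branch for branched
    runs. Counts are gamma-Poisson (negative binomial) around per-cell
    library-size factors, with optional extra dropout; cells that end up
    with zero total counts are resampled with a warning.
    """
    gene_ids, induced_idx, _, _ = _roles(config)
    rng_cells = _rng(config, "cells")
    n_cells, n_genes = config.n_cells, config.n_genes

    pt = rng_cells.uniform(0.0, 1.0, size=n_cells)
    if config.n_branches == 1:
        branch = np.full(n_cells, _BRANCH_LABELS[0], dtype=object)
    else:
        labels = np.array(_BRANCH_LABELS[: config.n_branches], dtype=object)
        branch = np.where(
            pt < config.frac_progenitors,
            PROGENITOR_LABEL,
            labels[rng_cells.integers(0, config.n_branches, size=n_cells)],
        )

    rng_counts = _rng(config, "counts")
    base = rng_counts.normal(0.0, 1.0, size=n_genes)
    slope = np.zeros(n_genes)
    slope[induced_idx] = config.induction_slope
    if config.n_branches == 1:
        cell_effect = pt
        induced_branch = None
    else:
        induced_branch = _BRANCH_LABELS[0]
        cell_effect = pt * (branch == induced_branch)

    eta = base[:, None] + slope[:, None] * cell_effect[None, :]
    rho = np.exp(eta)
    rho /= rho.sum(axis=0, keepdims=True)
    lib = rng_counts.lognormal(np.log(config.library_size_mean), config.library_size_sigma, size=n_cells)
    mu = rho * lib[None, :]

    shape = 1.0 / config.nb_dispersion
    counts = rng_counts.poisson(rng_counts.gamma(shape, mu * config.nb_dispersion))
    if config.dropout_extra > 0:
        counts[rng_counts.random(counts.shape) < config.dropout_extra] = 0

    for _ in range(max_resample):
        empty = counts.sum(axis=0) == 0
        if not empty.any():
            break
        warnings.warn(f"resampling {int(empty.sum())} zero-count cells")
        redraw = rng_counts.poisson(rng_counts.gamma(shape, mu[:, empty] * config.nb_dispersion))
        if config.dropout_extra > 0:
            redraw[rng_counts.random(redraw.shape) < config.dropout_extra] = 0
        counts[:, empty] = redraw

    width = len(str(n_cells))
    cell_ids = np.array([f"C{i:0{width}d}" for i in range(n_cells)], dtype=object)
    expr = ExpressionMatrix(gene_ids, cell_ids, sp.csr_matrix(counts))
    annot = CellAnnotation(
        pd.DataFrame(
            {
                "pseudotime": pt,
                "branch": branch,
                "n_detected": expr.genes_detected_per_cell(),
            },
            index=pd.Index(cell_ids, name="cell_id"),
        )
    )
    truth_part = {
        "induced_genes": gene_ids[induced_idx].tolist(),
        "induced_branch": induced_branch,
        "pseudotime": dict(zip(cell_ids.tolist(), pt.tolist())),
        "branch": dict(zip(cell_ids.tolist(), branch.tolist())),
    }
    return expr, annot, truth_part


def simulate_gene_sets(config: SimulationConfig):
    """A planted set enriched for the overlap genes, plus random decoy sets.

    The planted set draws ``set_purity`` of its members from the planted
    signal pool (trait-and-induced overlap first, then the remaining
    induced genes) and the rest from the background; decoy sets are uniform
    draws with sizes inside the GSEA bounds (50, 500).
    """
    gene_ids, induced_idx, trait_idx, overlap_idx = _roles(config)
    rng = _rng(config, "sets")
    if not (50 < config.planted_set_size < 500):
        raise ParameterError("planted_set_size must lie in (50, 500)")

    pool = np.concatenate([overlap_idx, np.setdiff1d(induced_idx, overlap_idx)])
    n_signal = min(int(round(config.set_purity * config.planted_set_size)), len(pool))
    signal = pool[:n_signal]
    background = np.setdiff1d(np.arange(config.n_genes), signal)
    filler = rng.choice(background, size=config.planted_set_size - n_signal, replace=False)
    planted_members = gene_ids[np.sort(np.concatenate([signal, filler]))].tolist()

    sets = {"planted_program": planted_members}
    descriptions = {"planted_program": "planted trajectory-and-trait program"}
    for i in range(max(config.n_sets - 1, 0)):
        size = int(rng.integers(51, min(500, config.n_genes)))
        members = gene_ids[np.sort(rng.choice(config.n_genes, size=size, replace=False))].tolist()
        name = f"random_set_{i:03d}"
        sets[name] = members
        descriptions[name] = "random decoy set"
    return GeneSetCollection(sets, descriptions), "planted_program"


def simulate_bundle(config: SimulationConfig, n_decoy_traits: int = 0) -> SimulationBundle:
    """Generate the full coupled scenario: GWAS table(s), counts, annotation,
    gene sets and the truth record."""
    gene_table, gwas_truth = simulate_gwas_scores(config)
    expr, annot, cells_truth = simulate_trajectory_counts(config)
    collection, planted_name = simulate_gene_sets(config)
    gene_tables = {"planted_trait": gene_table}
    for i in range(n_decoy_traits):
        gene_tables[f"decoy_trait_{i:02d}"] = simulate_decoy_gwas_scores(config, i)
    truth = SimulationTruth(
        trait_genes=gwas_truth["trait_genes"],
        induced_genes=cells_truth["induced_genes"],
        induced_branch=cells_truth["induced_branch"],
        overlap_genes=gwas_truth["overlap_genes"],
        planted_set_name=planted_name,
        planted_set_members=collection[planted_name],
        pseudotime=cells_truth["pseudotime"],
        branch=cells_truth["branch"],
    )
    return SimulationBundle(config, gene_tables, expr, annot, collection, truth)


def write_bundle(bundle: SimulationBundle, outdir) -> dict:
    """Write a bundle in the exact formats the readers consume; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for trait, table in bundle.gene_tables.items():
        p = outdir / f"{trait}.gene_scores.tsv"
        write_gene_scores(table, p)
        paths[f"gene_scores:{trait}"] = p
    paths["expression"] = write_expression_mtx(bundle.expr, outdir / "counts.mtx")
    paths["annotation"] = outdir / "cells.tsv"
    write_cell_annotation(bundle.annot, paths["annotation"])
    paths["gene_sets"] = outdir / "sets.gmt"
    write_gmt(bundle.collection, paths["gene_sets"])
    paths["truth"] = outdir / "truth.json"
    bundle.truth.to_json(paths["truth"])
    return paths
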