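"""End-to-end orchestration of the three analysis tasks.

Task 1 links developmental trajectories to traits (cell scoring + pseudotime
regression, with branch-dependency tests for branched trajectories); Task 2
finds the biological processes behind a link (gene kinetics -> GSEA ->
competitive trait tests on leading edges); Task 3 prioritizes the candidate
genes that carry it. The in-memory entry points operate on the package's
containers; :func:`run_from_config` wires them to files for the CLI.

Gene kinetics and GSEA depend only on the expression data, so in
:func:`run_all` they are computed once and shared across traits; the
competitive tests and candidate tables are per trait.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_scores import score_all_cells
from .errors import ParameterError, ValidationError
from .gsea import gsea_all_sets, results_frame, select_trajectory_linked
from .io import (
    filter_genes,
    intersect_genes,
    lognormalize,
    map_orthologs,
    read_cell_annotation,
    read_expression,
    read_gene_scores,
    read_gmt,
    read_ortholog_map,
    write_gmt,
)
from .kinetics import branch_pseudotime_effects, pseudotime_effects, rank_genes
from .set_assoc import competitive_set_test, prioritize_genes
from .trajectory import (
    assign_progenitor_branches,
    branch_dependency_fdr,
    fit_spline_link,
    rank_traits,
    test_branch_dependency,
    test_branch_link,
    test_trajectory_link,
)
from .types import CellAnnotation, ExpressionMatrix, GeneSetCollection, GeneTraitTable

log = logging.getLogger(__name__)

__all__ = [
    "PipelineParams",
    "RunConfig",
    "Task1Result",
    "Task2Result",
    "PipelineResult",
    "preprocess",
    "run_task1",
    "run_task2",
    "run_task3",
    "run_all",
    "run_from_config",
]


@dataclass
class PipelineParams:
    """Thresholds and flags shared by the pipeline stages (defaults follow
    the standard procedure: >= 10-cell gene filter, scale-10,000
    log-normalization, GSEA sizes strictly between 50 and 500, q < 0.05
    with NES < 0 for trajectory-linked sets, p < 0.05 for competitive set
    significance and for gene-level candidacy)."""

    min_cells: int = 10
    scale: float = 10_000.0
    gsea_min_size: int = 50
    gsea_max_size: int = 500
    n_perm: int = 1000
    gsea_q: float = 0.05
    set_alpha: float = 0.05
    gene_alpha: float = 0.05
    branched: bool = False
    spline: bool = False
    branch: str | None = None
    progenitor_label: str = "progenitor"
    seed: int = 0


@dataclass
class Task1Result:
    scores: dict  # trait -> per-cell score frame
    links: list  # whole-trajectory TrajectoryLinkResult per trait
    ranking: pd.DataFrame  # traits ordered by -log10 p
    spline_links: list = field(default_factory=list)
    assignment: pd.DataFrame | None = None
    branch_dependency: list = field(default_factory=list)
    branch_links: dict = field(default_factory=dict)  # trait -> per-branch results


@dataclass
class Task2Result:
    gene_ranking: pd.DataFrame
    effects: pd.Series
    gsea_results: list
    linked_sets: list
    leading_edges: dict
    set_results: dict  # trait -> list[SetAssociationResult]


@dataclass
class PipelineResult:
    task1: Task1Result
    task2: Task2Result | None
    candidates: dict  # trait -> candidate frame


def preprocess(
    expr: ExpressionMatrix,
    ortholog_map: pd.DataFrame | None = None,
    min_cells: int = 10,
    scale: float = 10_000.0,
) -> ExpressionMatrix:
    """Ortholog-map (optional), filter genes by detection, log-normalize."""
    if ortholog_map is not None:
        expr = map_orthologs(expr, ortholog_map)
    expr = filter_genes(expr, min_cells=min_cells)
    return lognormalize(expr, scale=scale)


def run_task1(
    gene_tables: dict,
    expr: ExpressionMatrix,
    annot: CellAnnotation,
    params: PipelineParams | None = None,
) -> Task1Result:
    """Cell scoring and trajectory-link tests for every trait."""
    params = params or PipelineParams()
    scores, links, spline_links = {}, [], []
    for trait, table in gene_tables.items():
        s = score_all_cells(expr, table, trait=trait)
        scores[trait] = s
        links.append(test_trajectory_link(s, annot, trait=trait))
        if params.spline:
            spline_links.append(fit_spline_link(s, annot, trait=trait))
    result = Task1Result(scores=scores, links=links, ranking=rank_traits(links), spline_links=spline_links)

    committed = annot.branch_labels(exclude=(params.progenitor_label,))
    if params.branched or len(committed) > 1:
        if len(committed) < 2:
            raise ValidationError("branched analysis requested but only one branch label present")
        assignment = assign_progenitor_branches(
            annot, n_branches=len(committed), progenitor_label=params.progenitor_label
        )
        result.assignment = assignment
        deps = [test_branch_dependency(scores[t], assignment, trait=t) for t in gene_tables]
        result.branch_dependency = branch_dependency_fdr(deps)
        result.branch_links = {
            t: test_branch_link(scores[t], assignment, trait=t) for t in gene_tables
        }
    return result


def run_task2(
    expr: ExpressionMatrix,
    annot: CellAnnotation,
    collection: GeneSetCollection,
    gene_tables: dict,
    params: PipelineParams | None = None,
    assignment: pd.DataFrame | None = None,
) -> Task2Result:
    """Gene kinetics, GSEA and competitive trait tests on leading edges.

    When ``params.branch`` is set (branch-restricted analysis), the gene
    ranking uses the branch:pseudotime interaction on the
    duplicated-progenitor table; otherwise the whole-trajectory effect.
    """
    params = params or PipelineParams()
    if params.branch is not None:
        if assignment is None:
            assignment = assign_progenitor_branches(
                annot, progenitor_label=params.progenitor_label
            )
        effects = branch_pseudotime_effects(expr, annot, assignment, branch=params.branch)
    else:
        effects = pseudotime_effects(expr, annot)
    ranking = rank_genes(effects)
    gsea_results = gsea_all_sets(
        ranking,
        collection,
        min_size=params.gsea_min_size,
        max_size=params.gsea_max_size,
        n_perm=params.n_perm,
        seed=params.seed,
    )
    linked = select_trajectory_linked(gsea_results, q_threshold=params.gsea_q)
    leading_edges = {r.set_name: list(r.leading_edge) for r in linked}
    if not linked:
        log.info("no trajectory-linked gene sets (q < %g with NES < 0)", params.gsea_q)
    set_results = {}
    for trait, table in gene_tables.items():
        _, table_s = intersect_genes(expr, table)
        avg = expr.subset_genes(table_s.genes).average_lognorm()
        set_results[trait] = [
            competitive_set_test(table_s, leading_edges[name], set_name=name, avg_expr=avg)
            for name in sorted(leading_edges)
            if set(leading_edges[name]) & set(table_s.genes)
        ]
    return Task2Result(
        gene_ranking=ranking,
        effects=effects,
        gsea_results=gsea_results,
        linked_sets=linked,
        leading_edges=leading_edges,
        set_results=set_results,
    )


def run_task3(
    task2: Task2Result,
    gene_tables: dict,
    params: PipelineParams | None = None,
) -> dict:
    """Per-trait candidate genes from significant sets' leading edges."""
    params = params or PipelineParams()
    candidates = {}
    for trait, table in gene_tables.items():
        candidates[trait] = prioritize_genes(
            task2.set_results.get(trait, []),
            task2.leading_edges,
            table,
            effects=task2.effects,
            alpha=params.gene_alpha,
            set_alpha=params.set_alpha,
        )
    return candidates


def run_all(
    gene_tables: dict,
    expr: ExpressionMatrix,
    annot: CellAnnotation,
    collection: GeneSetCollection | None = None,
    params: PipelineParams | None = None,
    ortholog_map: pd.DataFrame | None = None,
    preprocessed: bool = False,
) -> PipelineResult:
    """Full pipeline: preprocess -> task 1 -> task 2 -> task 3."""
    params = params or PipelineParams()
    if not preprocessed:
        expr = preprocess(expr, ortholog_map, min_cells=params.min_cells, scale=params.scale)
        annot = annot.subset(expr.cell_ids)
        if "n_detected" not in annot.frame.columns:
            annot.frame["n_detected"] = expr.genes_detected_per_cell()
    task1 = run_task1(gene_tables, expr, annot, params)
    task2 = None
    candidates: dict = {}
    if collection is not None and len(collection):
        task2 = run_task2(expr, annot, collection, gene_tables, params, assignment=task1.assignment)
        candidates = run_task3(task2, gene_tables, params)
    return PipelineResult(task1=task1, task2=task2, candidates=candidates)


# ---------------------------------------------------------------------------
# file-based configuration for the CLI
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated file-based run configuration (YAML)."""

    gene_scores: list  # [{trait, path, dialect}]
    expression_path: Path
    expression_format: str
    annotation_path: Path
    outdir: Path
    gene_sets_path: Path | None = None
    ortholog_map_path: Path | None = None
    transpose: bool = False
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ParameterError("config must be a YAML mapping")
        try:
            gene_scores = [
                {
                    "trait": str(entry["trait"]),
                    "path": Path(entry["path"]),
                    "dialect": entry.get("dialect", "generic_tsv"),
                }
                for entry in raw["gene_scores"]
            ]
            expression = raw["expression"]
            cfg = cls(
                gene_scores=gene_scores,
                expression_path=Path(expression["path"]),
                expression_format=expression.get("format", "mtx_triplet"),
                transpose=bool(expression.get("transpose", False)),
                annotation_path=Path(raw["annotation"]),
                gene_sets_path=Path(raw["gene_sets"]) if raw.get("gene_sets") else None,
                ortholog_map_path=Path(raw["ortholog_map"]) if raw.get("ortholog_map") else None,
                outdir=Path(raw.get("outdir", "trajlink_out")),
            )
        except KeyError as exc:
            raise ParameterError(f"config missing required key: {exc}") from exc
        pfields = {f for f in PipelineParams.__dataclass_fields__}
        overrides = {k: v for k, v in raw.items() if k in pfields}
        cfg.params = PipelineParams(**overrides)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [e["path"] for e in self.gene_scores]
        paths += [self.expression_path, self.annotation_path]
        if self.gene_sets_path:
            paths.append(self.gene_sets_path)
        if self.ortholog_map_path:
            paths.append(self.ortholog_map_path)
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise ValidationError(f"config references missing file(s): {missing}")
        for name in ("min_cells", "scale", "n_perm", "gsea_min_size", "gsea_max_size"):
            if getattr(self.params, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _links_frame(links) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trait": [r.trait for r in links],
            "branch": [r.branch for r in links],
            "model": [r.model for r in links],
            "beta_pseudotime": [r.beta_pseudotime for r in links],
            "t": [r.t for r in links],
            "p_one_sided": [r.p_one_sided for r in links],
            "n_cells": [r.n_cells for r in links],
            "spline_vs_linear_p": [r.spline_vs_linear_p for r in links],
        }
    )


def run_from_config(config: RunConfig) -> PipelineResult:
    """Load inputs per the config, run everything, write TSV/JSON outputs."""
    t0 = time.time()
    gene_tables = {
        e["trait"]: read_gene_scores(e["path"], dialect=e["dialect"]) for e in config.gene_scores
    }
    expr = read_expression(
        config.expression_path, format=config.expression_format, transpose=config.transpose
    )
    annot = read_cell_annotation(config.annotation_path, expr=expr)
    collection = read_gmt(config.gene_sets_path) if config.gene_sets_path else None
    ortho = read_ortholog_map(config.ortholog_map_path) if config.ortholog_map_path else None
    log.info("inputs loaded in %.1fs", time.time() - t0)

    result = run_all(gene_tables, expr, annot, collection, config.params, ortholog_map=ortho)

    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    pd.concat(result.task1.scores.values(), ignore_index=True).to_csv(
        outdir / "cell_scores.tsv", sep="\t", index=False
    )
    _links_frame(result.task1.links + result.task1.spline_links).to_csv(
        outdir / "trajectory_links.tsv", sep="\t", index=False
    )
    result.task1.ranking.to_csv(outdir / "trait_ranking.tsv", sep="\t", index=False)
    if result.task1.branch_dependency:
        pd.DataFrame(
            {
                "trait": [r.trait for r in result.task1.branch_dependency],
                "lrt_stat": [r.lrt_stat for r in result.task1.branch_dependency],
                "df": [r.df for r in result.task1.branch_dependency],
                "p": [r.p for r in result.task1.branch_dependency],
                "q": [r.q for r in result.task1.branch_dependency],
            }
        ).to_csv(outdir / "branch_dependency.tsv", sep="\t", index=False)
        _links_frame(
            [r for res in result.task1.branch_links.values() for r in res]
        ).to_csv(outdir / "branch_links.tsv", sep="\t", index=False)
    if result.task2 is not None:
        result.task2.gene_ranking.to_csv(outdir / "gene_ranking.tsv", sep="\t", index=False)
        results_frame(result.task2.gsea_results).to_csv(outdir / "gsea.tsv", sep="\t", index=False)
        if result.task2.leading_edges:
            write_gmt(
                GeneSetCollection(dict(result.task2.leading_edges)),
                outdir / "leading_edges.gmt",
            )
        rows = [
            {
                "trait": trait,
                "set_name": r.set_name,
                "n_target": r.n_target,
                "beta_set": r.beta_set,
                "t": r.t,
                "p_one_sided": r.p_one_sided,
            }
            for trait, rs in result.task2.set_results.items()
            for r in rs
        ]
        pd.DataFrame(
            rows, columns=["trait", "set_name", "n_target", "beta_set", "t", "p_one_sided"]
        ).to_csv(outdir / "set_association.tsv", sep="\t", index=False)
        for trait, cand in result.candidates.items():
            cand.to_csv(outdir / f"candidates_{trait}.tsv", sep="\t", index=False)

    input_paths = {str(e["path"]) for e in config.gene_scores}
    input_paths |= {str(config.expression_path), str(config.annotation_path)}
    if config.gene_sets_path:
        input_paths.add(str(config.gene_sets_path))
    summary = {
        "version": __version__,
        "params": asdict(config.params),
        "model_formulas": {
            "cell_score": "Z ~ 1 + C + A + B (score = t of C)",
            "trajectory_link": "score ~ 1 + pseudotime (one-sided, slope > 0)",
            "branch_dependency": "score ~ pseudotime  vs  score ~ pseudotime + branch:pseudotime (LRT)",
            "branch_link": "score ~ 1 + branch:pseudotime",
            "gene_kinetics": "lognorm ~ 1 + pseudotime + n_detected (effect = t of pseudotime)",
            "competitive_set": "Z ~ 1 + A + B + in_set (one-sided, in_set > 0)",
        },
        "input_checksums": {p: _sha256(Path(p)) for p in sorted(input_paths)},
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return result
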