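"""Competitive trait association of gene subsets, and gene prioritization.

The competitive test asks whether a target set's genes (here: the GSEA
leading edge of a trajectory-linked set) carry more GWAS association signal
than the background genes, by regressing the gene-level Z-scores on a set
indicator while adjusting for the same technical design block used for
cell scoring (intercept, average expression when available, gene length and
friends); the indicator's coefficient gets a one-sided upper-tail t-test.
This is the covariate-adjusted regression form of a competitive gene-set
analysis, without gene-gene LD correlation adjustment.

Prioritization keeps the genes from significant sets' leading edges whose
own gene-level trait p-value clears the (strict) alpha threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .regress import ols_fit, one_sided_p
from .types import GeneTraitTable

log = logging.getLogger(__name__)

__all__ = ["SetAssociationResult", "competitive_set_test", "prioritize_genes"]


@dataclass
class SetAssociationResult:
    set_name: str
    n_target: int
    beta_set: float
    t: float
    p_one_sided: float


def competitive_set_test(
    gene_table: GeneTraitTable,
    target,
    set_name: str = "set",
    avg_expr: pd.Series | None = None,
) -> SetAssociationResult:
    """One-sided competitive test of a target gene set against background.

    OLS of Z on [intercept, (avg_expr), covariates, indicator(gene in
    target)]; the upper-tail t-test on the indicator asks whether target
    genes are more trait-associated than the rest of the universe.
    """
    universe = gene_table.genes
    target_set = set(target)
    indicator = np.fromiter((g in target_set for g in universe), dtype=float, count=len(universe))
    n_target = int(indicator.sum())
    if n_target == 0:
        raise ValidationError(f"no target gene of {set_name!r} is in the universe")
    if n_target == len(universe):
        raise ValidationError("target covers the whole universe; competitive test undefined")
    cols = [np.ones(len(universe))]
    if avg_expr is not None:
        avg = pd.Series(avg_expr).reindex(universe)
        if avg.isna().any():
            raise ValidationError("avg_expr missing values for some universe genes")
        cols.append(avg.to_numpy(dtype=float))
    cov = gene_table.covariate_matrix()
    for values in cov.T:
        if np.ptp(values) > 0:
            cols.append(values.astype(float))
    cols.append(indicator)
    fit = ols_fit(np.column_stack(cols), gene_table.z)
    t = float(fit.t[-1])
    return SetAssociationResult(
        set_name=set_name,
        n_target=n_target,
        beta_set=float(fit.beta[-1]),
        t=t,
        p_one_sided=one_sided_p(t, fit.df_resid),
    )


def prioritize_genes(
    set_results: list,
    leading_edges: dict,
    gene_table: GeneTraitTable,
    effects: pd.Series | None = None,
    alpha: float = 0.05,
    set_alpha: float = 0.05,
) -> pd.DataFrame:
    """Candidate genes behind significant trajectory-trait-pathway links.

    Takes the union of the leading edges of sets with competitive
    ``p_one_sided < set_alpha``, keeps genes with gene-level trait p
    strictly below ``alpha``, and reports them sorted by trait p with the
    contributing sets listed. The result does not depend on the order in
    which sets are supplied.
    """
    significant = sorted(
        (r for r in set_results if np.isfinite(r.p_one_sided) and r.p_one_sided < set_alpha),
        key=lambda r: r.set_name,
    )
    table = gene_table.table
    gene_sources: dict = {}
    for r in significant:
        for g in leading_edges.get(r.set_name, []):
            gene_sources.setdefault(g, []).append(r.set_name)
    rows = []
    for g, sources in gene_sources.items():
        if g not in table.index:
            continue
        trait_p = float(table.loc[g, "p"])
        if trait_p < alpha:
            rows.append(
                {
                    "gene_id": g,
                    "trait_p": trait_p,
                    "gene_z": float(table.loc[g, "z"]),
                    "effect_t": float(effects.get(g, np.nan)) if effects is not None else np.nan,
                    "source_sets": ",".join(sorted(set(sources))),
                }
            )
    out = pd.DataFrame(rows, columns=["gene_id", "trait_p", "gene_z", "effect_t", "source_sets"])
    if len(out):
        out = out.sort_values(["trait_p", "gene_id"], kind="mergesort").reset_index(drop=True)
    return out
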