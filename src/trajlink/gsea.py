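"""Self-contained gene-set enrichment analysis on a ranked gene list.

Conventions, fixed explicitly because sign conventions differ between
implementations: the input ranking is ascending by pseudotime-effect t
(most declining gene first, most induced last). The running sum therefore
dips negative when a set's members concentrate at the *end* of the list, so
sets of trajectory-induced genes receive negative ES/NES; the selection
rule for trajectory-linked sets is FDR q < 0.05 and NES < 0.

The enrichment score is the classic weighted Kolmogorov-Smirnov statistic:
walking down the ranked list, hits add ``|effect|^w`` (normalized), misses
subtract ``1/(N - N_hits)``; ES is the signed maximum deviation of the
walk. The null is gene-label permutation (random same-size sets), NES
divides ES by the mean |ES| of same-sign permutations, the permutation p
is computed within the sign class, and FDR is Benjamini-Hochberg across
sets. The leading edge is the member suffix (negative ES) or prefix
(positive ES) delimited by the running-sum extremum.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .types import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "GseaResult",
    "enrichment_score",
    "leading_edge",
    "gsea_all_sets",
    "select_trajectory_linked",
    "results_frame",
]


@dataclass
class GseaResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_perm: float
    q: float
    leading_edge: list = field(default_factory=list)
    direction: str = "end_of_list"  # end_of_list (es<0) or start_of_list (es>0)


def _ranking_arrays(ranking: pd.DataFrame, weight_exponent: float):
    genes = ranking["gene_id"].to_numpy(dtype=object)
    weights = np.abs(ranking["effect_t"].to_numpy(dtype=float)) ** weight_exponent
    weights = np.where(np.isfinite(weights), weights, np.nanmax(weights[np.isfinite(weights)], initial=1.0))
    return genes, weights


def enrichment_score(ranking: pd.DataFrame, members, weight_exponent: float = 1.0):
    """Weighted KS running-sum enrichment score.

    Returns ``(es, running_sum, extremum_index)`` where ``extremum_index``
    is the 1-based rank at which the signed maximum deviation is attained.
    A set covering the whole universe is degenerate and scores 0; a set with
    no member in the universe is undefined (NaN).
    """
    genes, weights = _ranking_arrays(ranking, weight_exponent)
    n = len(genes)
    member_set = set(members)
    hit = np.fromiter((g in member_set for g in genes), dtype=bool, count=n)
    nh = int(hit.sum())
    if nh == 0:
        warnings.warn("no set member present in the ranked universe")
        return np.nan, None, None
    if nh == n:
        warnings.warn("set covers the whole universe; ES = 0 by construction")
        return 0.0, np.zeros(n), 0
    hit_w = weights[hit]
    total = hit_w.sum()
    steps = np.full(n, -1.0 / (n - nh))
    steps[hit] = hit_w / total if total > 0 else 1.0 / nh
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running, idx + 1


def leading_edge(ranking: pd.DataFrame, members, es: float, extremum_index: int) -> list:
    """Member genes between the running-sum extremum and the enriched end.

    For end-of-list enrichment (es < 0 under the ascending ranking) the
    leading edge is the members at ranks >= the extremum; for start-of-list
    enrichment the members at ranks <= the extremum. Returned in rank order.
    """
    if not np.isfinite(es):
        return []
    genes = ranking["gene_id"].to_numpy(dtype=object)
    member_set = set(members)
    if es == 0:
        return []
    if es < 0:
        zone = genes[extremum_index - 1 :]
    else:
        zone = genes[:extremum_index]
    return [g for g in zone if g in member_set]


def _permutation_es(weights: np.ndarray, nh: int, n_perm: int, rng) -> np.ndarray:
    """ES of ``n_perm`` random same-size member sets, vectorized.

    The running sum only attains extrema immediately before or after a hit,
    so each permutation is evaluated at its 2*nh candidate points.
    """
    n = len(weights)
    # distinct hit positions per permutation: partial argsort of random keys
    keys = rng.random((n_perm, n))
    hits = np.argpartition(keys, nh - 1, axis=1)[:, :nh]
    hits.sort(axis=1)
    w = weights[hits]
    cw = np.cumsum(w, axis=1)
    totals = cw[:, -1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        W = cw / totals
    flat = (totals.ravel() == 0)
    if flat.any():  # all-zero hit weights: fall back to uniform increments
        W[flat] = np.arange(1, nh + 1) / nh
    dm = 1.0 / (n - nh)
    j = np.arange(1, nh + 1)
    after = W - (hits + 1 - j) * dm
    before = np.concatenate([np.zeros((n_perm, 1)), W[:, :-1]], axis=1) - (hits - (j - 1)) * dm
    amax = after.max(axis=1)
    bmin = before.min(axis=1)
    return np.where(amax >= -bmin, amax, bmin)


def gsea_all_sets(
    ranking: pd.DataFrame,
    collection: GeneSetCollection,
    min_size: int = 50,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int | None = 0,
    weight_exponent: float = 1.0,
    rng=None,
) -> list:
    """Run GSEA over a collection with a gene-label permutation null.

    Set sizes are counted within the ranked universe and filtered with the
    strict bounds ``min_size < size < max_size``. Deterministic for a fixed
    seed. Returns one :class:`GseaResult` per retained set.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable permutation p-values and FDR")
    if rng is None:
        rng = np.random.default_rng(seed)
    genes, weights = _ranking_arrays(ranking, weight_exponent)
    universe = set(genes)

    retained = []
    for name in sorted(collection.names()):
        members = [g for g in collection[name] if g in universe]
        if min_size < len(members) < max_size:
            retained.append((name, members))
    if not retained:
        raise ValidationError(
            f"no gene set has size in ({min_size}, {max_size}) within the universe"
        )

    results = []
    for name, members in retained:
        es, running, ext = enrichment_score(ranking, members, weight_exponent)
        le = leading_edge(ranking, members, es, ext)
        perm = _permutation_es(weights, len(members), n_perm, rng)
        pos = perm[perm > 0]
        neg = perm[perm < 0]
        if es > 0:
            same = pos
            denom = pos.mean() if len(pos) else np.nan
        elif es < 0:
            same = -neg
            denom = -neg.mean() if len(neg) else np.nan
        else:
            same = np.abs(perm)
            denom = np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        p_perm = (1.0 + float((same >= abs(es)).sum())) / (1.0 + len(same))
        results.append(
            GseaResult(
                set_name=name,
                size=len(members),
                es=es,
                nes=float(nes) if np.isfinite(nes) else np.nan,
                p_perm=float(p_perm),
                q=np.nan,
                leading_edge=le,
                direction="start_of_list" if es > 0 else "end_of_list",
            )
        )
    qvals = multipletests([r.p_perm for r in results], method="fdr_bh")[1]
    for r, qv in zip(results, qvals):
        r.q = float(qv)
    return results


def select_trajectory_linked(results: list, q_threshold: float = 0.05) -> list:
    """Sets linked to the trajectory: FDR q below threshold and NES < 0
    (members concentrated among trajectory-induced genes)."""
    return [r for r in results if np.isfinite(r.q) and r.q < q_threshold and r.nes < 0]


def results_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "size": [r.size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_perm": [r.p_perm for r in results],
            "q": [r.q for r in results],
            "direction": [r.direction for r in results],
            "leading_edge": [",".join(map(str, r.leading_edge)) for r in results],
        }
    )
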