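"""Calibration, power and oracle-equivalence studies.

These routines re-derive the package's statistical guarantees from scratch:
exact agreement of the fast vectorized regressions with independent
textbook least-squares fits, type-I error calibration of the trajectory
test under a null generator, power to recover planted trait-trajectory
links, branch-dependency LRT power and null distribution, brute-force
verification of the GSEA running sum, and end-to-end planted-structure
recovery. They are used by the test suite and by the acceptance script;
each takes an explicit seed and returns plain numbers.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cell_scores import DesignBlock, build_design, cell_trait_score, score_all_cells
from .gsea import enrichment_score, gsea_all_sets, leading_edge
from .kinetics import pseudotime_effect, pseudotime_effects, rank_genes
from .pipeline import PipelineParams, run_all
from .set_assoc import competitive_set_test
from .simulate import SimulationConfig, simulate_bundle, simulate_trajectory_counts
from .trajectory import (
    assign_progenitor_branches,
    test_branch_dependency,
    test_trajectory_link,
)
from .types import CellAnnotation, GeneTraitTable

__all__ = [
    "ols_oracle_max_dev",
    "hand_fixture",
    "type_one_error_rate",
    "planted_power",
    "branch_lrt_power",
    "branch_lrt_null_ks",
    "brute_force_es",
    "gsea_bruteforce_max_dev",
    "gsea_null_pvalue_ks",
    "end_to_end_recovery",
    "progenitor_assignment_check",
]


# ---------------------------------------------------------------------------
# oracle equivalence of the fast regressions
# ---------------------------------------------------------------------------


def _random_gene_table(rng, n_genes: int, n_cov: int) -> GeneTraitTable:
    idx = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    z = rng.normal(size=n_genes)
    data = {"z": z, "p": stats.norm.sf(z), "n_snps": 1}
    covs = []
    for j in range(n_cov):
        data[f"cov{j}"] = rng.lognormal(size=n_genes)
        covs.append(f"cov{j}")
    return GeneTraitTable(pd.DataFrame(data, index=idx), covs)


def ols_oracle_max_dev(seed: int = 0, n_fixtures: int = 100) -> float:
    """Largest |t - t_oracle| across random fixtures for the three fast
    regression paths (cell scoring, gene kinetics, competitive set test),
    with statsmodels OLS as the independent oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(50, 501))
        n_cov = int(rng.integers(1, 4))
        table = _random_gene_table(rng, n, n_cov)
        avg = pd.Series(rng.lognormal(size=n), index=table.genes)
        c = rng.lognormal(size=n)
        design = build_design(table.genes, table, avg)

        # cell scoring: t of the cell-expression coefficient
        _, t_fast, _ = cell_trait_score(c, table.z, design)
        X = sm.add_constant(np.column_stack([avg.to_numpy(), table.covariate_matrix(), c]))
        t_oracle = sm.OLS(table.z, X).fit().tvalues[-1]
        worst = max(worst, abs(t_fast - t_oracle))

        # gene kinetics: t of the pseudotime coefficient
        pt = rng.uniform(size=n)
        ndet = rng.integers(20, 200, size=n).astype(float)
        y = rng.normal(size=n)
        annot = CellAnnotation(
            pd.DataFrame(
                {"pseudotime": pt, "branch": "main", "n_detected": ndet},
                index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
            )
        )
        t_fast = pseudotime_effect(y, annot)
        t_oracle = sm.OLS(y, sm.add_constant(np.column_stack([pt, ndet]))).fit().tvalues[1]
        worst = max(worst, abs(t_fast - t_oracle))

        # competitive set test: t of the membership indicator
        target = table.genes[rng.random(n) < 0.2]
        if 0 < len(target) < n:
            r = competitive_set_test(table, target, avg_expr=avg)
            ind = np.isin(table.genes, target).astype(float)
            X = sm.add_constant(np.column_stack([avg.to_numpy(), table.covariate_matrix(), ind]))
            t_oracle = sm.OLS(table.z, X).fit().tvalues[-1]
            worst = max(worst, abs(r.t - t_oracle))
    return float(worst)


def hand_fixture() -> dict:
    """The 4-point simple-regression fixture: C=[0,1,2,3], Z=[0,1,2,2]."""
    design = DesignBlock(
        matrix=np.ones((4, 1)), columns=["intercept"], genes=np.array(list("abcd"), dtype=object)
    )
    beta, t, se = cell_trait_score(
        np.array([0.0, 1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0, 2.0]), design
    )
    return {"beta_c": beta, "t": t, "se": se}


# ---------------------------------------------------------------------------
# trajectory-link calibration and power
# ---------------------------------------------------------------------------


def _null_config(seed: int) -> SimulationConfig:
    # the planted scenario minus the trajectory coupling: expression
    # kinetics are flat (induction_slope=0), so cell scores are independent
    # of pseudotime and the one-sided link test should hold its level
    return SimulationConfig(
        n_genes=500,
        n_cells=200,
        n_trait_genes=50,
        n_induced_genes=50,
        n_overlap=0,
        induction_slope=0.0,
        seed=seed,
    )


def type_one_error_rate(seed: int = 0, n_reps: int = 1000, alpha: float = 0.05) -> float:
    """Rejection rate of the one-sided trajectory test under the null
    generator (trait genes disjoint from induced genes)."""
    rejections = 0
    for rep in range(n_reps):
        bundle = simulate_bundle(_null_config(seed * n_reps + rep))
        res = run_all(
            bundle.gene_tables,
            bundle.expr,
            bundle.annot,
            collection=None,
            params=PipelineParams(seed=seed),
        )
        if res.task1.links[0].p_one_sided < alpha:
            rejections += 1
    return rejections / n_reps


def planted_power(seed: int = 0, n_reps: int = 200, n_decoys: int = 5) -> dict:
    """Power of the planted link at the default scenario: how often the
    planted trait ranks first among decoys, and how often its one-sided
    link p is below 0.05."""
    first, significant = 0, 0
    for rep in range(n_reps):
        config = SimulationConfig(seed=seed * n_reps + rep)
        bundle = simulate_bundle(config, n_decoy_traits=n_decoys)
        res = run_all(
            bundle.gene_tables,
            bundle.expr,
            bundle.annot,
            collection=None,
            params=PipelineParams(seed=seed),
        )
        if res.task1.ranking.iloc[0]["trait"] == "planted_trait":
            first += 1
        p = next(r.p_one_sided for r in res.task1.links if r.trait == "planted_trait")
        if p < 0.05:
            significant += 1
    return {"rank_first_rate": first / n_reps, "significant_rate": significant / n_reps}


# ---------------------------------------------------------------------------
# branch dependency
# ---------------------------------------------------------------------------


def _branch_scores(rng, n_per_branch: int, slopes=(1.0, 0.0), noise_sd: float = 0.5):
    n = n_per_branch * len(slopes)
    pt = rng.uniform(0.0, 1.0, size=n)
    branch = np.repeat([f"B{i+1}" for i in range(len(slopes))], n_per_branch)
    slope = np.repeat(list(slopes), n_per_branch)
    score = slope * pt + rng.normal(0.0, noise_sd, size=n)
    cells = [f"c{i}" for i in range(n)]
    scores = pd.DataFrame({"cell_id": cells, "trait": "t", "score": score})
    annot = CellAnnotation(
        pd.DataFrame(
            {"pseudotime": pt, "branch": branch, "n_detected": 100},
            index=pd.Index(cells, name="cell_id"),
        )
    )
    return scores, annot


def branch_lrt_power(
    seed: int = 0, n_reps: int = 100, n_per_branch: int = 300, noise_sd: float = 0.5
) -> float:
    """Fraction of replicates with LRT p < 1e-6 when the score slope is 1
    in one branch and 0 in the other."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        scores, annot = _branch_scores(rng, n_per_branch, slopes=(1.0, 0.0), noise_sd=noise_sd)
        with np.errstate(all="ignore"):
            assignment = assign_progenitor_branches(annot)
        res = test_branch_dependency(scores, assignment)
        if res.p < 1e-6:
            hits += 1
    return hits / n_reps


def branch_lrt_null_ks(seed: int = 0, n_reps: int = 1000, n_per_branch: int = 100) -> float:
    """KS p-value of the null LRT statistic against chi-square(1)."""
    rng = np.random.default_rng(seed)
    stats_out = np.empty(n_reps)
    for i in range(n_reps):
        scores, annot = _branch_scores(rng, n_per_branch, slopes=(0.0, 0.0), noise_sd=1.0)
        assignment = assign_progenitor_branches(annot)
        stats_out[i] = test_branch_dependency(scores, assignment).lrt_stat
    return float(stats.kstest(stats_out, stats.chi2(1).cdf).pvalue)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


def brute_force_es(ranking: pd.DataFrame, members, weight_exponent: float = 1.0):
    """Literal running-sum recomputation evaluated at every list position.

    Independent of the production path: walks the ranked list one gene at a
    time, accumulating hit/miss increments, and records the signed maximum
    deviation and its position.
    """
    genes = ranking["gene_id"].tolist()
    weights = np.abs(ranking["effect_t"].to_numpy(dtype=float)) ** weight_exponent
    member_set = set(members)
    nh = sum(g in member_set for g in genes)
    n = len(genes)
    if nh == 0 or nh == n:
        return None
    total = sum(w for g, w in zip(genes, weights) if g in member_set)
    running, best, best_idx = 0.0, 0.0, 0
    values = []
    for i, (g, w) in enumerate(zip(genes, weights), start=1):
        if g in member_set:
            running += (w / total) if total > 0 else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        values.append(running)
        if abs(running) > abs(best):
            best, best_idx = running, i
    return best, np.array(values), best_idx


def gsea_bruteforce_max_dev(seed: int = 0, n_fixtures: int = 50, max_n: int = 200) -> dict:
    """Compare the production enrichment score and leading edge with the
    brute-force recomputation on random fixtures of up to ``max_n`` genes."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    le_mismatch = 0
    for _ in range(n_fixtures):
        n = int(rng.integers(10, max_n + 1))
        effects = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        ranking = rank_genes(effects)
        size = int(rng.integers(1, max(2, n // 2)))
        members = list(rng.choice(ranking["gene_id"], size=size, replace=False))
        es, _, ext = enrichment_score(ranking, members)
        oracle = brute_force_es(ranking, members)
        assert oracle is not None
        es_o, _, ext_o = oracle
        worst = max(worst, abs(es - es_o))
        le = leading_edge(ranking, members, es, ext)
        genes = ranking["gene_id"].tolist()
        zone = genes[ext_o - 1 :] if es_o < 0 else genes[:ext_o]
        le_oracle = [g for g in zone if g in set(members)]
        if le != le_oracle:
            le_mismatch += 1
    return {"max_abs_es_dev": float(worst), "leading_edge_mismatches": le_mismatch}


def gsea_null_pvalue_ks(
    seed: int = 0, n_sets: int = 200, n_perm: int = 200, n_genes: int = 1000
) -> float:
    """KS p-value of permutation p-values against uniform under a null
    ranking with random gene sets."""
    rng = np.random.default_rng(seed)
    effects = pd.Series(rng.normal(size=n_genes), index=[f"g{i}" for i in range(n_genes)])
    ranking = rank_genes(effects)
    from .types import GeneSetCollection

    sets = {
        f"s{i:03d}": list(rng.choice(effects.index, size=int(rng.integers(60, 120)), replace=False))
        for i in range(n_sets)
    }
    results = gsea_all_sets(
        ranking, GeneSetCollection(sets), min_size=50, max_size=500, n_perm=n_perm, seed=seed
    )
    pvals = np.array([r.p_perm for r in results])
    return float(stats.kstest(pvals, "uniform").pvalue)


# ---------------------------------------------------------------------------
# end-to-end planted recovery
# ---------------------------------------------------------------------------


def end_to_end_recovery(seed: int = 0, n_reps: int = 50) -> dict:
    """Full-pipeline recovery of the planted structure at default settings.

    Per replicate: does the planted set pass both the GSEA selection
    (q < 0.05, NES < 0) and the competitive trait test (p < 0.05)? What
    fraction of the planted trait-and-induced overlap genes that clear the
    gene-level significance filter (trait p < 0.05, part of the candidate
    definition) appear in the candidate table? The unconditional fraction
    over all overlap genes is reported alongside.
    """
    set_hits, recovery, recovery_unconditional = 0, [], []
    both_rates = 0
    for rep in range(n_reps):
        config = SimulationConfig(seed=seed * n_reps + rep)
        bundle = simulate_bundle(config)
        res = run_all(
            bundle.gene_tables,
            bundle.expr,
            bundle.annot,
            bundle.collection,
            params=PipelineParams(seed=seed),
        )
        planted = bundle.truth.planted_set_name
        selected = {r.set_name for r in res.task2.linked_sets}
        comp = {r.set_name: r.p_one_sided for r in res.task2.set_results["planted_trait"]}
        set_ok = planted in selected and comp.get(planted, 1.0) < 0.05
        set_hits += set_ok

        table = bundle.gene_tables["planted_trait"].table
        overlap = [g for g in bundle.truth.overlap_genes if g in table.index]
        eligible = [g for g in overlap if table.loc[g, "p"] < 0.05]
        cand = set(res.candidates["planted_trait"]["gene_id"])
        frac = len(cand & set(eligible)) / len(eligible) if eligible else np.nan
        frac_u = len(cand & set(overlap)) / len(overlap) if overlap else np.nan
        recovery.append(frac)
        recovery_unconditional.append(frac_u)
        if set_ok and frac >= 0.8:
            both_rates += 1
    return {
        "set_detection_rate": set_hits / n_reps,
        "mean_gene_recovery": float(np.nanmean(recovery)),
        "mean_gene_recovery_unconditional": float(np.nanmean(recovery_unconditional)),
        "full_success_rate": both_rates / n_reps,
    }


def progenitor_assignment_check() -> dict:
    """Exactness of the deterministic progenitor-splitting rule."""
    def annot_for(n_prog, labels):
        rows = {}
        for i in range(n_prog):
            rows[f"p{i}"] = {"pseudotime": 0.1 * (i + 1), "branch": "progenitor"}
        for j, lab in enumerate(labels):
            for k in range(3):
                rows[f"{lab}_c{k}"] = {"pseudotime": 0.8 + 0.01 * k + 0.001 * j, "branch": lab}
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "cell_id"
        frame["n_detected"] = 10
        return CellAnnotation(frame)

    out = {}
    a2 = assign_progenitor_branches(annot_for(5, ["A", "B"]), n_branches=2)
    sets2 = {
        lab: {c for c in a2[a2["branch"] == lab]["cell_id"] if c.startswith("p")}
        for lab in ["A", "B"]
    }
    expected2 = [{"p0", "p2", "p4"}, {"p0", "p1", "p3"}]  # ranks {1,3,5} and {1,2,4}
    out["two_branch_exact"] = sorted(sets2.values(), key=sorted) == sorted(expected2, key=sorted)

    a3 = assign_progenitor_branches(annot_for(6, ["A", "B", "C"]), n_branches=3)
    sets3 = {
        lab: {c for c in a3[a3["branch"] == lab]["cell_id"] if c.startswith("p")}
        for lab in ["A", "B", "C"]
    }
    # 1+3n, 2+3n, 3+3n with the rank-1 cell copied into every branch
    expected3 = {"A": {"p0", "p3"}, "B": {"p0", "p1", "p4"}, "C": {"p0", "p2", "p5"}}
    out["three_branch_exact"] = sets3 == expected3
    return out
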