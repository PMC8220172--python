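"""Linking cell-trait scores to pseudotime and trajectory branches.

The whole-trajectory link is a one-sided OLS test of the pseudotime slope in
``score ~ pseudotime``: significance means that cells' association with the
trait increases as they mature along the trajectory. For branched
trajectories the module provides (i) the deterministic rule that splits
pre-branch progenitors across branches by pseudotime-rank parity, with the
earliest progenitor copied into every branch; (ii) a likelihood-ratio test
comparing ``score ~ pseudotime`` against the branch-interaction model
``score ~ pseudotime + branch:pseudotime`` (branch dependency); (iii) a
per-branch model ``score ~ branch:pseudotime`` with one slope per branch and
a shared intercept; and (iv) a natural-cubic-spline alternative to the
linear link, with a nested F-test flagging non-monotone trait-trajectory
patterns.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, ParameterError, ValidationError
from .regress import OlsFit, ols_fit, one_sided_p
from .types import CellAnnotation

log = logging.getLogger(__name__)

__all__ = [
    "TrajectoryLinkResult",
    "BranchDependencyResult",
    "test_trajectory_link",
    "assign_progenitor_branches",
    "test_branch_dependency",
    "branch_dependency_fdr",
    "test_branch_link",
    "natural_spline_basis",
    "fit_spline_link",
    "rank_traits",
]

#: branch label used for whole-trajectory results
ALL_BRANCHES = "ALL"


@dataclass
class TrajectoryLinkResult:
    trait: str
    branch: str
    beta_pseudotime: float
    t: float
    p_one_sided: float
    n_cells: int
    model: str = "linear"
    spline_vs_linear_p: float | None = None


@dataclass
class BranchDependencyResult:
    trait: str
    lrt_stat: float
    df: int
    p: float
    q: float | None = None


def _merged(scores: pd.DataFrame, annot: CellAnnotation) -> pd.DataFrame:
    df = scores.merge(
        annot.frame.reset_index(names="cell_id")[["cell_id", "pseudotime"]],
        on="cell_id",
        how="inner",
    )
    df = df.dropna(subset=["score", "pseudotime"])
    return df


def test_trajectory_link(
    scores: pd.DataFrame,
    annot: CellAnnotation,
    trait: str | None = None,
    branch: str = ALL_BRANCHES,
) -> TrajectoryLinkResult:
    """One-sided test that cell-trait scores increase along pseudotime."""
    df = _merged(scores, annot)
    if len(df) < 3:
        raise ValidationError("need >= 3 cells with defined scores and pseudotime")
    pt = df["pseudotime"].to_numpy(dtype=float)
    y = df["score"].to_numpy(dtype=float)
    if np.ptp(pt) == 0:
        raise ValidationError("pseudotime is constant; trajectory test undefined")
    fit = ols_fit(np.column_stack([np.ones_like(pt), pt]), y)
    trait = trait if trait is not None else str(df["trait"].iloc[0])
    return TrajectoryLinkResult(
        trait=trait,
        branch=branch,
        beta_pseudotime=float(fit.beta[1]),
        t=float(fit.t[1]),
        p_one_sided=one_sided_p(float(fit.t[1]), fit.df_resid),
        n_cells=len(df),
    )


def assign_progenitor_branches(
    annot: CellAnnotation,
    n_branches: int | None = None,
    progenitor_label: str = "progenitor",
) -> pd.DataFrame:
    """Split unbranched progenitors across branches for branch-aware models.

    Progenitors are ranked by pseudotime (ties broken by cell id); the
    rank-1 progenitor is copied into every branch; the remaining progenitors
    go to branch ``k`` when ``(rank - 1) mod n_branches == k`` — i.e. odd /
    even ranks alternate between two branches, or the arithmetic sequences
    1+3n / 2+3n / 3+3n feed three. Committed cells keep their labels.
    Returns one row per (cell, branch) membership with columns cell_id,
    branch, pseudotime, duplicated.
    """
    frame = annot.frame
    labels = sorted(set(frame["branch"]) - {progenitor_label})
    if not labels:
        raise ValidationError("no committed branch labels in annotation")
    if n_branches is None:
        n_branches = len(labels)
    if n_branches not in (2, 3):
        raise ParameterError("n_branches must be 2 or 3")
    if n_branches != len(labels):
        raise ValidationError(
            f"annotation has {len(labels)} committed branches but n_branches={n_branches}"
        )

    committed = frame[frame["branch"] != progenitor_label]
    rows = [
        pd.DataFrame(
            {
                "cell_id": committed.index,
                "branch": committed["branch"].to_numpy(),
                "pseudotime": committed["pseudotime"].to_numpy(dtype=float),
                "duplicated": False,
            }
        )
    ]
    prog = frame[frame["branch"] == progenitor_label]
    if len(prog) == 0:
        warnings.warn("no progenitor cells; assignment is the identity")
        return pd.concat(rows, ignore_index=True)

    order = prog.assign(_cell=prog.index.astype(str)).sort_values(
        ["pseudotime", "_cell"], kind="mergesort"
    )
    ranked = order.index.to_numpy()
    pt = order["pseudotime"].to_numpy(dtype=float)
    rank0 = np.arange(len(ranked))
    branch_of_rank = np.array(labels, dtype=object)[rank0 % n_branches]
    rows.append(
        pd.DataFrame(
            {"cell_id": ranked, "branch": branch_of_rank, "pseudotime": pt, "duplicated": False}
        )
    )
    # rank-1 progenitor is copied into every remaining branch
    extra_labels = [lab for lab in labels if lab != branch_of_rank[0]]
    if extra_labels:
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": [ranked[0]] * len(extra_labels),
                    "branch": extra_labels,
                    "pseudotime": pt[0],
                    "duplicated": True,
                }
            )
        )
        # mark the original row of the duplicated cell as well
        rows[-2].loc[rows[-2]["cell_id"] == ranked[0], "duplicated"] = True
    return pd.concat(rows, ignore_index=True)


def _branch_table(scores: pd.DataFrame, assignment: pd.DataFrame) -> pd.DataFrame:
    df = assignment.merge(scores[["cell_id", "score"]], on="cell_id", how="inner")
    return df.dropna(subset=["score", "pseudotime"])


def _interaction_design(df: pd.DataFrame, labels, include_main_pt: bool) -> np.ndarray:
    pt = df["pseudotime"].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    if include_main_pt:
        cols.append(pt)
        slope_labels = labels[1:]  # first level absorbed by the main term
    else:
        slope_labels = labels
    for lab in slope_labels:
        cols.append(pt * (df["branch"] == lab).to_numpy(dtype=float))
    return np.column_stack(cols)


def test_branch_dependency(
    scores: pd.DataFrame,
    assignment: pd.DataFrame,
    trait: str | None = None,
) -> BranchDependencyResult:
    """Likelihood-ratio test of branch-specific pseudotime slopes.

    Compares ``score ~ pseudotime`` (reduced) with
    ``score ~ pseudotime + branch:pseudotime`` (full) on the
    duplicated-progenitor table, using Gaussian profile log-likelihoods of
    the two OLS fits; the statistic is referred to chi-square with
    ``n_branches - 1`` degrees of freedom.
    """
    df = _branch_table(scores, assignment)
    labels = sorted(df["branch"].unique())
    if len(labels) < 2:
        raise ValidationError("branch dependency needs >= 2 branches")
    counts = df["branch"].value_counts()
    if (counts < 3).any():
        raise ValidationError("every branch needs >= 3 cells")
    y = df["score"].to_numpy(dtype=float)
    reduced = ols_fit(_interaction_design(df, labels, include_main_pt=True)[:, :2], y)
    full = ols_fit(_interaction_design(df, labels, include_main_pt=True), y)
    lrt = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    dof = len(labels) - 1
    trait = trait if trait is not None else str(scores["trait"].iloc[0])
    return BranchDependencyResult(
        trait=trait, lrt_stat=float(lrt), df=dof, p=float(stats.chi2.sf(lrt, dof))
    )


def branch_dependency_fdr(results: list) -> list:
    """Benjamini-Hochberg adjustment across traits; fills the q field."""
    if not results:
        return results
    pvals = np.array([r.p for r in results])
    q = multipletests(pvals, method="fdr_bh")[1]
    for r, qv in zip(results, q):
        r.q = float(qv)
    return results


def test_branch_link(
    scores: pd.DataFrame,
    assignment: pd.DataFrame,
    trait: str | None = None,
) -> list:
    """Per-branch one-sided pseudotime tests from ``score ~ branch:pseudotime``.

    One model with a separate pseudotime slope per branch and a shared
    intercept; each slope gets its own upper-tail t-test. Branches with
    fewer than 3 cells are reported with undefined (NaN) statistics.
    """
    df = _branch_table(scores, assignment)
    trait = trait if trait is not None else str(scores["trait"].iloc[0])
    labels = sorted(df["branch"].unique())
    counts = df["branch"].value_counts()
    usable = [lab for lab in labels if counts.get(lab, 0) >= 3]
    results = []
    if len(usable) >= 1:
        sub = df[df["branch"].isin(usable)]
        y = sub["score"].to_numpy(dtype=float)
        X = _interaction_design(sub, usable, include_main_pt=False)
        fit = ols_fit(X, y)
        for i, lab in enumerate(usable):
            t = float(fit.t[1 + i])
            results.append(
                TrajectoryLinkResult(
                    trait=trait,
                    branch=lab,
                    beta_pseudotime=float(fit.beta[1 + i]),
                    t=t,
                    p_one_sided=one_sided_p(t, fit.df_resid),
                    n_cells=int(counts[lab]),
                )
            )
    for lab in labels:
        if lab not in usable:
            warnings.warn(f"branch {lab!r} has < 3 cells; result undefined")
            results.append(
                TrajectoryLinkResult(
                    trait=trait,
                    branch=lab,
                    beta_pseudotime=np.nan,
                    t=np.nan,
                    p_one_sided=np.nan,
                    n_cells=int(counts.get(lab, 0)),
                )
            )
    results.sort(key=lambda r: r.branch)
    return results


def natural_spline_basis(x: np.ndarray, df: int = 3, knots=None) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (linear term included).

    Boundary knots sit at the data range, interior knots at the quantiles
    ``i/df`` for ``i = 1..df-1``; the basis is linear beyond the boundary
    knots (the usual natural-spline constraint).
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ParameterError("spline df must be >= 2")
    if knots is None:
        probs = np.arange(1, df) / df
        interior = np.quantile(x, probs)
        knots = np.concatenate([[x.min()], interior, [x.max()]])
    knots = np.unique(np.asarray(knots, dtype=float))
    if len(knots) < df + 1:
        raise ComputationError("too few distinct knots for requested spline df")

    def d(k_idx):
        num = np.clip(x - knots[k_idx], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k_idx])

    cols = [x]
    d_last = d(len(knots) - 2)
    for k_idx in range(len(knots) - 2):
        cols.append(d(k_idx) - d_last)
    return np.column_stack(cols)[:, :df]


def fit_spline_link(
    scores: pd.DataFrame,
    annot: CellAnnotation,
    df: int = 3,
    trait: str | None = None,
    branch: str = ALL_BRANCHES,
) -> TrajectoryLinkResult:
    """Natural-spline link model with a nested F-test against the linear one.

    The spline basis spans the linear trend, so the F comparison is a test
    for non-linearity of the score-pseudotime relationship; a small
    ``spline_vs_linear_p`` flags non-monotone (e.g. mid-trajectory-peaking)
    links that the linear model would miss. The headline slope/t/p of the
    result remain those of the linear fit.
    """
    if df < 2:
        raise ParameterError("spline df must be >= 2")
    merged = _merged(scores, annot)
    if len(merged) < df + 2:
        raise ValidationError(f"need >= {df + 2} cells for a df={df} spline fit")
    pt = merged["pseudotime"].to_numpy(dtype=float)
    y = merged["score"].to_numpy(dtype=float)
    if np.ptp(pt) == 0:
        raise ValidationError("pseudotime is constant; spline fit undefined")
    basis = natural_spline_basis(pt, df=df)
    lin = ols_fit(np.column_stack([np.ones_like(pt), pt]), y)
    spl = ols_fit(np.column_stack([np.ones_like(pt), basis]), y)
    extra = basis.shape[1] - 1
    if spl.df_resid < 1 or extra < 1:
        raise ComputationError("spline model is saturated; reduce df")
    f = ((lin.rss - spl.rss) / extra) / (spl.rss / spl.df_resid)
    comparison_p = float(stats.f.sf(max(f, 0.0), extra, spl.df_resid))
    trait = trait if trait is not None else str(merged["trait"].iloc[0])
    return TrajectoryLinkResult(
        trait=trait,
        branch=branch,
        beta_pseudotime=float(lin.beta[1]),
        t=float(lin.t[1]),
        p_one_sided=one_sided_p(float(lin.t[1]), lin.df_resid),
        n_cells=len(merged),
        model="spline",
        spline_vs_linear_p=comparison_p,
    )


def rank_traits(results: list) -> pd.DataFrame:
    """Order trait link results by significance (descending -log10 p)."""
    if not results:
        raise ValidationError("no trait results to rank")
    rows = pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "branch": [r.branch for r in results],
            "p_one_sided": [r.p_one_sided for r in results],
        }
    )
    with np.errstate(divide="ignore"):
        rows["neg_log10_p"] = -np.log10(rows["p_one_sided"])
    rows = rows.sort_values(
        ["neg_log10_p", "trait"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return rows
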