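import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_annotation
from trajlink.errors import ParameterError, ValidationError
from trajlink.trajectory import (
    TrajectoryLinkResult,
    assign_progenitor_branches,
    fit_spline_link,
    natural_spline_basis,
    rank_traits,
)
from trajlink.trajectory import test_branch_dependency as branch_dependency_test
from trajlink.trajectory import test_branch_link as branch_link_test
from trajlink.trajectory import test_trajectory_link as trajectory_link_test


def scores_frame(values, cells=None, trait="t"):
    cells = cells if cells is not None else [f"c{i}" for i in range(len(values))]
    return pd.DataFrame({"cell_id": cells, "trait": trait, "score": np.asarray(values, float)})


class TestTrajectoryLink:
    def test_planted_positive_slope(self):
        rng = np.random.default_rng(0)
        pt = rng.uniform(size=200)
        annot = make_annotation([f"c{i}" for i in range(200)], pt)
        res = trajectory_link_test(scores_frame(pt + rng.normal(0, 0.01, 200)), annot)
        assert res.p_one_sided < 1e-10
        assert res.beta_pseudotime > 0

    def test_negative_slope_one_sided_p_near_one(self):
        rng = np.random.default_rng(1)
        pt = rng.uniform(size=100)
        annot = make_annotation([f"c{i}" for i in range(100)], pt)
        res = trajectory_link_test(scores_frame(-pt + rng.normal(0, 0.01, 100)), annot)
        assert res.p_one_sided > 1 - 1e-10

    def test_null_p_values_uniform(self):
        """Scores independent of pseudotime give uniform one-sided p."""
        rng = np.random.default_rng(2)
        pt = rng.uniform(size=60)
        annot = make_annotation([f"c{i}" for i in range(60)], pt)
        ps = [
            trajectory_link_test(scores_frame(rng.normal(size=60)), annot).p_one_sided
            for _ in range(400)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    @given(st.floats(0, 5), st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_affine_pseudotime_invariance(self, a, b):
        rng = np.random.default_rng(3)
        pt = rng.uniform(size=50)
        y = 0.5 * pt + rng.normal(0, 0.5, size=50)
        cells = [f"c{i}" for i in range(50)]
        r0 = trajectory_link_test(scores_frame(y, cells), make_annotation(cells, pt))
        r1 = trajectory_link_test(scores_frame(y, cells), make_annotation(cells, a + b * pt))
        assert r1.t == pytest.approx(r0.t, abs=1e-9)
        assert r1.p_one_sided == pytest.approx(r0.p_one_sided, abs=1e-9)

    def test_constant_pseudotime_rejected(self):
        annot = make_annotation(["c0", "c1", "c2"], [1.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="constant"):
            trajectory_link_test(scores_frame([0.0, 1.0, 2.0]), annot)

    def test_too_few_cells(self):
        annot = make_annotation(["c0", "c1"], [0.0, 1.0])
        with pytest.raises(ValidationError):
            trajectory_link_test(scores_frame([0.0, 1.0]), annot)


class TestProgenitorAssignment:
    def _annot(self, n_prog, labels, prog_pt=None):
        cells, pts, branches = [], [], []
        prog_pt = prog_pt if prog_pt is not None else [0.1 * (i + 1) for i in range(n_prog)]
        for i in range(n_prog):
            cells.append(f"p{i}")
            pts.append(prog_pt[i])
            branches.append("progenitor")
        for lab in labels:
            for k in range(3):
                cells.append(f"{lab}{k}")
                pts.append(0.9 + 0.01 * k)
                branches.append(lab)
        return make_annotation(cells, pts, branch=branches)

    @staticmethod
    def _prog_sets(assignment, labels):
        return {
            lab: {c for c in assignment[assignment["branch"] == lab]["cell_id"] if c.startswith("p")}
            for lab in labels
        }

    def test_five_progenitors_two_branches(self):
        """Rank parity split with the rank-1 cell in both branches."""
        a = assign_progenitor_branches(self._annot(5, ["A", "B"]), n_branches=2)
        sets = self._prog_sets(a, ["A", "B"])
        assert sorted(map(sorted, sets.values())) == sorted(
            [sorted({"p0", "p1", "p3"}), sorted({"p0", "p2", "p4"})]
        )
        dup_rows = a[a["duplicated"]]
        assert set(dup_rows["cell_id"]) == {"p0"}
        assert len(dup_rows) == 2

    def test_six_progenitors_three_branches(self):
        """1+3n / 2+3n / 3+3n sequences; rank-1 copied everywhere."""
        a = assign_progenitor_branches(self._annot(6, ["A", "B", "C"]), n_branches=3)
        sets = self._prog_sets(a, ["A", "B", "C"])
        assert sets == {"A": {"p0", "p3"}, "B": {"p0", "p1", "p4"}, "C": {"p0", "p2", "p5"}}

    def test_union_and_intersection_invariants(self):
        a = assign_progenitor_branches(self._annot(7, ["A", "B"]), n_branches=2)
        sets = self._prog_sets(a, ["A", "B"])
        assert sets["A"] | sets["B"] == {f"p{i}" for i in range(7)}
        assert sets["A"] & sets["B"] == {"p0"}
        assert abs(len(sets["A"]) - len(sets["B"])) <= 1

    def test_pseudotime_ties_broken_by_cell_id(self):
        a = assign_progenitor_branches(
            self._annot(4, ["A", "B"], prog_pt=[0.2, 0.2, 0.2, 0.2]), n_branches=2
        )
        sets = self._prog_sets(a, ["A", "B"])
        # lexicographic ranks: p0 < p1 < p2 < p3
        assert sets == {"A": {"p0", "p2"}, "B": {"p0", "p1", "p3"}}

    def test_no_progenitors_warns_identity(self):
        annot = self._annot(0, ["A", "B"])
        with pytest.warns(UserWarning, match="no progenitor"):
            a = assign_progenitor_branches(annot, n_branches=2)
        assert len(a) == 6
        assert not a["duplicated"].any()

    def test_bad_branch_count(self):
        with pytest.raises(ParameterError):
            assign_progenitor_branches(self._annot(3, ["A", "B"]), n_branches=4)


def _two_branch_data(rng, slopes, n_per_branch=150, noise_sd=0.5):
    n = 2 * n_per_branch
    pt = rng.uniform(size=n)
    branch = np.repeat(["A", "B"], n_per_branch)
    slope = np.repeat(slopes, n_per_branch)
    y = slope * pt + rng.normal(0, noise_sd, size=n)
    cells = [f"c{i}" for i in range(n)]
    scores = scores_frame(y, cells)
    annot = make_annotation(cells, pt, branch=branch)
    with pytest.warns(UserWarning, match="no progenitor"):
        assignment = assign_progenitor_branches(annot)
    return scores, assignment


class TestBranchDependency:
    def test_identical_branch_data_gives_zero_lrt(self):
        rng = np.random.default_rng(0)
        pt = rng.uniform(size=50)
        y = pt + rng.normal(0, 0.3, size=50)
        cells_a = [f"a{i}" for i in range(50)]
        cells_b = [f"b{i}" for i in range(50)]
        scores = pd.concat([scores_frame(y, cells_a), scores_frame(y, cells_b)], ignore_index=True)
        assignment = pd.DataFrame(
            {
                "cell_id": cells_a + cells_b,
                "branch": ["A"] * 50 + ["B"] * 50,
                "pseudotime": np.concatenate([pt, pt]),
                "duplicated": False,
            }
        )
        res = branch_dependency_test(scores, assignment)
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_branch_specific_slope_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(10):
            scores, assignment = _two_branch_data(rng, (1.0, 0.0), n_per_branch=300)
            if branch_dependency_test(scores, assignment).p < 1e-6:
                hits += 1
        assert hits >= 9

    def test_null_lrt_matches_chi_square(self):
        rng = np.random.default_rng(2)
        lrts = []
        for _ in range(400):
            scores, assignment = _two_branch_data(rng, (0.0, 0.0), n_per_branch=60, noise_sd=1.0)
            lrts.append(branch_dependency_test(scores, assignment).lrt_stat)
        assert stats.kstest(lrts, stats.chi2(1).cdf).pvalue > 0.01

    def test_nesting_full_loglik_at_least_reduced(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores, assignment = _two_branch_data(
                rng, tuple(rng.normal(size=2)), n_per_branch=20, noise_sd=1.0
            )
            assert branch_dependency_test(scores, assignment).lrt_stat >= 0.0

    def test_small_branch_rejected(self):
        scores = scores_frame([0.0, 1.0, 2.0, 3.0])
        assignment = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(4)],
                "branch": ["A", "A", "A", "B"],
                "pseudotime": [0.1, 0.2, 0.3, 0.4],
                "duplicated": False,
            }
        )
        with pytest.raises(ValidationError, match=">= 3"):
            branch_dependency_test(scores, assignment)


class TestBranchLink:
    def test_planted_slope_in_one_branch(self):
        rng = np.random.default_rng(4)
        good = 0
        for _ in range(10):
            scores, assignment = _two_branch_data(rng, (1.0, 0.0), n_per_branch=200)
            results = {r.branch: r for r in branch_link_test(scores, assignment)}
            if results["A"].p_one_sided < 0.05 and results["B"].p_one_sided > 0.05:
                good += 1
        assert good >= 9

    def test_identical_branches_equal_slopes(self):
        rng = np.random.default_rng(5)
        pt = rng.uniform(size=40)
        y = 0.5 * pt + rng.normal(0, 0.2, size=40)
        cells_a = [f"a{i}" for i in range(40)]
        cells_b = [f"b{i}" for i in range(40)]
        scores = pd.concat([scores_frame(y, cells_a), scores_frame(y, cells_b)], ignore_index=True)
        assignment = pd.DataFrame(
            {
                "cell_id": cells_a + cells_b,
                "branch": ["A"] * 40 + ["B"] * 40,
                "pseudotime": np.concatenate([pt, pt]),
                "duplicated": False,
            }
        )
        res = {r.branch: r for r in branch_link_test(scores, assignment)}
        assert res["A"].beta_pseudotime == pytest.approx(res["B"].beta_pseudotime, abs=1e-8)

    def test_relabeling_swaps_results(self):
        rng = np.random.default_rng(6)
        scores, assignment = _two_branch_data(rng, (1.0, 0.0), n_per_branch=50)
        res = {r.branch: r for r in branch_link_test(scores, assignment)}
        swapped = assignment.assign(branch=assignment["branch"].map({"A": "B", "B": "A"}))
        res_sw = {r.branch: r for r in branch_link_test(scores, swapped)}
        assert res["A"].t == pytest.approx(res_sw["B"].t, abs=1e-10)
        assert res["B"].t == pytest.approx(res_sw["A"].t, abs=1e-10)

    def test_tiny_branch_marked_undefined(self):
        scores = scores_frame(np.arange(6, dtype=float))
        assignment = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(6)],
                "branch": ["A"] * 4 + ["B"] * 2,
                "pseudotime": np.linspace(0, 1, 6),
                "duplicated": False,
            }
        )
        with pytest.warns(UserWarning, match="B"):
            res = {r.branch: r for r in branch_link_test(scores, assignment)}
        assert np.isnan(res["B"].t)
        assert np.isfinite(res["A"].t)


class TestSplineLink:
    def test_basis_contains_linear_term_and_df_columns(self):
        x = np.linspace(0, 1, 50)
        basis = natural_spline_basis(x, df=3)
        assert basis.shape == (50, 3)
        np.testing.assert_allclose(basis[:, 0], x)

    def test_linear_truth_comparison_p_uniform(self):
        rng = np.random.default_rng(7)
        cells = [f"c{i}" for i in range(80)]
        ps = []
        for _ in range(300):
            pt = rng.uniform(size=80)
            y = pt + rng.normal(0, 0.5, size=80)
            res = fit_spline_link(scores_frame(y, cells), make_annotation(cells, pt))
            ps.append(res.spline_vs_linear_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_mid_trajectory_bump_detected(self):
        rng = np.random.default_rng(8)
        cells = [f"c{i}" for i in range(200)]
        hits = 0
        for _ in range(20):
            pt = rng.uniform(size=200)
            y = -4.0 * (pt - 0.5) ** 2 + rng.normal(0, 0.3, size=200)
            res = fit_spline_link(scores_frame(y, cells), make_annotation(cells, pt))
            if res.spline_vs_linear_p < 0.05:
                hits += 1
        assert hits >= 18

    def test_df_below_two_rejected(self):
        cells = [f"c{i}" for i in range(20)]
        annot = make_annotation(cells, np.linspace(0, 1, 20))
        with pytest.raises(ParameterError):
            fit_spline_link(scores_frame(np.zeros(20), cells), annot, df=1)

    def test_saturated_fit_guarded(self):
        cells = [f"c{i}" for i in range(5)]
        annot = make_annotation(cells, np.linspace(0, 1, 5))
        with pytest.raises((ValidationError, ParameterError)):
            fit_spline_link(scores_frame(np.zeros(5), cells), annot, df=4)


class TestRankTraits:
    @staticmethod
    def _result(trait, p):
        return TrajectoryLinkResult(
            trait=trait, branch="ALL", beta_pseudotime=0.0, t=0.0, p_one_sided=p, n_cells=10
        )

    def test_orders_by_significance(self):
        frame = rank_traits([self._result("weak", 0.5), self._result("strong", 0.001)])
        assert list(frame["trait"]) == ["strong", "weak"]

    def test_ties_broken_lexicographically(self):
        frame = rank_traits([self._result("b", 0.01), self._result("a", 0.01)])
        assert list(frame["trait"]) == ["a", "b"]
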