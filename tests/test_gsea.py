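import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trajlink.errors import ValidationError
from trajlink.gsea import (
    GseaResult,
    enrichment_score,
    gsea_all_sets,
    leading_edge,
    results_frame,
    select_trajectory_linked,
)
from trajlink.kinetics import rank_genes
from trajlink.types import GeneSetCollection
from trajlink.validation import brute_force_es


def ranking_from(effects: dict) -> pd.DataFrame:
    return rank_genes(pd.Series(effects))


def random_ranking(rng, n):
    return rank_genes(pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)]))


class TestEnrichmentScore:
    def test_bottom_ranks_give_negative_es_matching_oracle(self):
        """Members at the three lowest-effect ranks concentrate at the list
        start; the classic running sum matches the brute-force oracle."""
        rng = np.random.default_rng(0)
        ranking = random_ranking(rng, 10)
        members = list(ranking["gene_id"].iloc[-3:])  # end of ascending list
        es, running, ext = enrichment_score(ranking, members)
        es_o, running_o, ext_o = brute_force_es(ranking, members)
        assert es == pytest.approx(es_o, abs=1e-12)
        np.testing.assert_allclose(running, running_o, atol=1e-12)
        assert ext == ext_o
        assert es < 0  # end-of-list enrichment under ascending ranking

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        ranking = random_ranking(rng, n)
        members = list(rng.choice(ranking["gene_id"], size=int(rng.integers(1, n // 2 + 1)), replace=False))
        es, _, ext = enrichment_score(ranking, members)
        es_o, _, ext_o = brute_force_es(ranking, members)
        assert es == pytest.approx(es_o, abs=1e-12)
        assert ext == ext_o

    def test_whole_universe_set_is_degenerate_zero(self):
        rng = np.random.default_rng(1)
        ranking = random_ranking(rng, 20)
        with pytest.warns(UserWarning, match="whole universe"):
            es, _, _ = enrichment_score(ranking, list(ranking["gene_id"]))
        assert es == 0.0

    def test_no_members_undefined(self):
        rng = np.random.default_rng(2)
        ranking = random_ranking(rng, 20)
        with pytest.warns(UserWarning, match="no set member"):
            es, _, _ = enrichment_score(ranking, ["absent"])
        assert np.isnan(es)

    def test_reversed_ranking_flips_sign_unweighted(self):
        rng = np.random.default_rng(3)
        ranking = random_ranking(rng, 50)
        reversed_ranking = ranking.iloc[::-1].reset_index(drop=True)
        members = list(rng.choice(ranking["gene_id"], size=8, replace=False))
        es_f, _, _ = enrichment_score(ranking, members, weight_exponent=0.0)
        es_r, _, _ = enrichment_score(reversed_ranking, members, weight_exponent=0.0)
        assert es_r == pytest.approx(-es_f, abs=1e-12)


class TestLeadingEdge:
    def test_members_in_suffix_from_extremum(self):
        rng = np.random.default_rng(4)
        ranking = random_ranking(rng, 10)
        genes = list(ranking["gene_id"])
        members = [genes[1], genes[7], genes[8], genes[9]]
        es, _, ext = enrichment_score(ranking, members)
        le = leading_edge(ranking, members, es, ext)
        assert es < 0
        assert le == [g for g in genes[ext - 1 :] if g in set(members)]
        assert set(le) <= set(members)

    def test_single_member_set(self):
        rng = np.random.default_rng(5)
        ranking = random_ranking(rng, 15)
        member = [ranking["gene_id"].iloc[-1]]
        es, _, ext = enrichment_score(ranking, member)
        assert leading_edge(ranking, member, es, ext) == member

    @pytest.mark.parametrize("seed", range(5))
    def test_leading_edge_is_contiguous_in_member_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        ranking = random_ranking(rng, 60)
        members = list(rng.choice(ranking["gene_id"], size=12, replace=False))
        es, _, ext = enrichment_score(ranking, members)
        le = leading_edge(ranking, members, es, ext)
        ranks = ranking.set_index("gene_id")["rank"]
        member_order = sorted(members, key=lambda g: ranks[g])
        if es < 0:
            assert le == member_order[len(member_order) - len(le) :]
        else:
            assert le == member_order[: len(le)]


class TestGseaAllSets:
    def _collection_with_sizes(self, rng, universe, sizes):
        return GeneSetCollection(
            {
                f"size_{s}": list(rng.choice(universe, size=s, replace=False))
                for s in sizes
            }
        )

    def test_strict_size_bounds(self):
        rng = np.random.default_rng(6)
        ranking = random_ranking(rng, 600)
        coll = self._collection_with_sizes(rng, ranking["gene_id"], [50, 51, 499, 500])
        results = gsea_all_sets(ranking, coll, n_perm=100)
        names = {r.set_name for r in results}
        assert names == {"size_51", "size_499"}

    def test_no_retained_sets_is_error(self):
        rng = np.random.default_rng(7)
        ranking = random_ranking(rng, 100)
        coll = self._collection_with_sizes(rng, ranking["gene_id"], [10])
        with pytest.raises(ValidationError):
            gsea_all_sets(ranking, coll, n_perm=100)

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        ranking = random_ranking(rng, 300)
        coll = self._collection_with_sizes(rng, ranking["gene_id"], [60, 80, 100])
        f1 = results_frame(gsea_all_sets(ranking, coll, n_perm=200, seed=5))
        f2 = results_frame(gsea_all_sets(ranking, coll, n_perm=200, seed=5))
        pd.testing.assert_frame_equal(f1, f2)

    def test_planted_set_attains_best_q(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 400
            effects = pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])
            planted = list(effects.sample(60, random_state=seed).index)
            effects[planted] += 2.5
            ranking = rank_genes(effects)
            sets = {"planted": planted}
            for i in range(9):
                sets[f"rand{i}"] = list(
                    rng.choice(effects.index, size=60, replace=False)
                )
            results = gsea_all_sets(ranking, GeneSetCollection(sets), n_perm=500, seed=seed)
            best = min(results, key=lambda r: (r.q, r.p_perm))
            if best.set_name == "planted" and best.nes < 0:
                hits += 1
        assert hits >= 4

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(9)
        fractions = []
        for seed in range(3):
            ranking = random_ranking(rng, 500)
            coll = self._collection_with_sizes(rng, ranking["gene_id"], [60] * 1)
            sets = {
                f"s{i}": list(rng.choice(ranking["gene_id"], size=60, replace=False))
                for i in range(40)
            }
            results = gsea_all_sets(ranking, GeneSetCollection(sets), n_perm=200, seed=seed)
            fractions.append(np.mean([r.q < 0.05 for r in results]))
        assert np.mean(fractions) <= 0.05

    def test_fdr_monotone_in_p(self):
        rng = np.random.default_rng(10)
        ranking = random_ranking(rng, 300)
        sets = {
            f"s{i}": list(rng.choice(ranking["gene_id"], size=55, replace=False))
            for i in range(20)
        }
        results = gsea_all_sets(ranking, GeneSetCollection(sets), n_perm=200, seed=0)
        ordered = sorted(results, key=lambda r: r.p_perm)
        qs = [r.q for r in ordered]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))


class TestSelectionRule:
    @staticmethod
    def _res(q, nes):
        return GseaResult(set_name="s", size=60, es=-0.5 if nes < 0 else 0.5,
                          nes=nes, p_perm=q / 2, q=q, leading_edge=["g"])

    def test_selects_significant_induced_sets(self):
        assert select_trajectory_linked([self._res(0.01, -1.8)]) != []

    def test_rejects_declining_program(self):
        assert select_trajectory_linked([self._res(0.01, 1.8)]) == []

    def test_rejects_above_threshold(self):
        assert select_trajectory_linked([self._res(0.06, -2.0)]) == []
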