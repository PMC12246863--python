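import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astrokin.enrichment import (bh_adjust, consensus_pathways, gsea_preranked,
                                 jaccard_filter, jaccard_index, ora,
                                 running_sum_es, top_bottom_slice)


def naive_es(scores, is_hit, weight_p=1.0):
    """Independent O(N) re-walk of the weighted KS running sum."""
    n = len(scores)
    n_hits = sum(is_hit)
    tot = sum(abs(s) ** weight_p for s, h in zip(scores, is_hit) if h)
    run, best = 0.0, 0.0
    for s, h in zip(scores, is_hit):
        run += (abs(s) ** weight_p / tot) if h else -1.0 / (n - n_hits)
        if abs(run) > abs(best):
            best = run
    return best


class TestGseaRunningSum:
    FIXTURE_SCORES = [3.0, 2.5, 2.0, 1.5, 1.0, 0.8, 0.5, 0.2]

    def test_eight_gene_fixture_matches_hand_walk(self):
        """Set at ranks {1, 4, 6} of the printed 8-score fixture."""
        is_hit = [i in (0, 3, 5) for i in range(8)]
        es = running_sum_es(np.array(self.FIXTURE_SCORES), np.array(is_hit))
        assert es == pytest.approx(0.5660377358490566)
        assert es == pytest.approx(naive_es(self.FIXTURE_SCORES, is_hit))

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_naive_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        scores = np.sort(rng.normal(0, 2, n))[::-1]
        is_hit = rng.random(n) < 0.25
        if not 0 < is_hit.sum() < n:
            is_hit[0] = True
            is_hit[-1] = False
        assert running_sum_es(scores, is_hit) == pytest.approx(
            naive_es(list(scores), list(is_hit)))

    def test_top_k_set_es_positive_and_maximal_at_k(self):
        scores = np.linspace(5, -5, 40)
        is_hit = np.array([True] * 5 + [False] * 35)
        w = np.abs(scores)
        steps = np.where(is_hit, w / w[is_hit].sum(), -1 / 35)
        path = np.cumsum(steps)
        assert running_sum_es(scores, is_hit) > 0
        assert np.argmax(path) == 4  # peak exactly after the k-th hit

    def test_degenerate_sets_rejected(self):
        with pytest.raises(ValueError):
            running_sum_es(np.ones(5), np.zeros(5, dtype=bool))


class TestGseaPreranked:
    def _ranked(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n)]
        return pd.DataFrame({"gene": genes,
                             "score": np.sort(rng.normal(0, 2, n))[::-1]})

    def test_planted_top_set_significant_up(self):
        ranked = self._ranked()
        sets = {"TOP": ("top genes", set(ranked["gene"].iloc[:8])),
                "RAND": ("random", set(ranked["gene"].iloc[::7]))}
        res = gsea_preranked(ranked, sets, n_perm=500, seed=1).set_index("set_id")
        assert res.loc["TOP", "direction"] == "up"
        assert res.loc["TOP", "pvalue"] < 0.01
        assert res.loc["TOP", "es"] > abs(res.loc["RAND", "es"])

    def test_deterministic_given_seed(self):
        ranked = self._ranked()
        sets = {"A": ("", set(ranked["gene"].iloc[5:15]))}
        r1 = gsea_preranked(ranked, sets, n_perm=200, seed=9)
        r2 = gsea_preranked(ranked, sets, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_set_outside_universe_skipped(self):
        ranked = self._ranked()
        sets = {"GHOST": ("", {"nope1", "nope2", "nope3", "nope4", "nope5"})}
        with pytest.warns(UserWarning, match="GHOST"):
            res = gsea_preranked(ranked, sets, n_perm=100, seed=0)
        assert res.empty


class TestOra:
    def test_exact_overlap_closed_form(self):
        """hits = the set itself in a 10-gene universe: p = 1/C(10,3)."""
        universe = {f"g{i}" for i in range(10)}
        members = {"g0", "g1", "g2"}
        res = ora(members, universe, {"S": ("", members)})
        assert res["pvalue"][0] == pytest.approx(1 / comb(10, 3))

    def test_disjoint_hits_give_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = ora({"g8", "g9"}, universe, {"S": ("", {"g0", "g1"})})
        assert res["pvalue"][0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universe(self):
        """Tail probability vs explicit enumeration of all C(12,4) hit draws."""
        universe = {f"g{i}" for i in range(12)}
        members = {"g0", "g1", "g2", "g3", "g4"}
        hits = {"g0", "g1", "g2", "g11"}
        obs = len(hits & members)
        count = sum(1 for draw in itertools.combinations(sorted(universe), 4)
                    if len(set(draw) & members) >= obs)
        expected = count / comb(12, 4)
        res = ora(hits, universe, {"S": ("", members)})
        assert res["pvalue"][0] == pytest.approx(expected)

    def test_empty_hits_error(self):
        with pytest.raises(ValueError):
            ora(set(), {"g"}, {})


class TestTopBottomSlice:
    def test_floor_sizes(self):
        ranked = pd.DataFrame({"gene": [f"g{i}" for i in range(100)],
                               "score": range(100, 0, -1)})
        top, bottom = top_bottom_slice(ranked, 0.1)
        assert len(top) == len(bottom) == 10
        assert "g0" in top and "g99" in bottom

    def test_small_list_warns_empty(self):
        ranked = pd.DataFrame({"gene": list("abcdefg"), "score": range(7)})
        with pytest.warns(UserWarning):
            top, bottom = top_bottom_slice(ranked, 0.1)
        assert top == set() and bottom == set()


class TestConsensus:
    def _res(self, rows):
        return pd.DataFrame(rows, columns=["set_id", "padj", "direction"])

    def test_disjoint_and_identical(self):
        a = self._res([("S1", 0.01, "up")])
        b = self._res([("S2", 0.01, "up")])
        assert consensus_pathways(a, b) == []
        assert consensus_pathways(a, a) == ["S1"]

    def test_direction_and_significance_required(self):
        gsea = self._res([("S1", 0.01, "up"), ("S2", 0.01, "up"),
                          ("S3", 0.2, "up")])
        ora_res = self._res([("S1", 0.01, "up"), ("S2", 0.01, "down"),
                             ("S3", 0.01, "up")])
        # S2 discordant, S3 not significant in GSEA
        assert consensus_pathways(gsea, ora_res) == ["S1"]


class TestJaccardFilter:
    def test_identical_sets_keep_more_significant(self):
        members = {"a", "b", "c"}
        sets = {"S1": ("", members), "S2": ("", set(members))}
        res = pd.DataFrame({"set_id": ["S1", "S2"], "padj": [0.04, 0.01]})
        kept = jaccard_filter(res, sets)
        assert list(kept["set_id"]) == ["S2"]

    def test_disjoint_sets_both_kept(self):
        sets = {"S1": ("", {"a"}), "S2": ("", {"b"})}
        res = pd.DataFrame({"set_id": ["S1", "S2"], "padj": [0.01, 0.02]})
        assert len(jaccard_filter(res, sets)) == 2

    def test_greedy_hand_walk(self):
        """Hand walk: J(s1,s2)=0.5 (not <0.5, drop), J(s1,s3)=1/7 (keep)."""
        s1 = {"a", "b", "c", "d", "e"}
        s2 = {"a", "b", "c", "x"}  # |∩|=3, |∪|=6
        s3 = {"e", "y", "z"}       # |∩|=1, |∪|=7
        sets = {"S1": ("", s1), "S2": ("", s2), "S3": ("", s3)}
        res = pd.DataFrame({"set_id": ["S1", "S2", "S3"],
                            "padj": [0.001, 0.01, 0.02]})
        kept = jaccard_filter(res, sets, max_jaccard=0.5)
        assert list(kept["set_id"]) == ["S1", "S3"]

    @pytest.mark.parametrize("seed", range(3))
    def test_postcondition_all_pairwise_below_threshold(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(30)]
        sets = {f"S{i}": ("", set(rng.choice(universe, 8, replace=False)))
                for i in range(12)}
        res = pd.DataFrame({"set_id": sorted(sets),
                            "padj": rng.uniform(0, 0.1, 12)})
        kept = list(jaccard_filter(res, sets, 0.5)["set_id"])
        for a, b in itertools.combinations(kept, 2):
            assert jaccard_index(sets[a][1], sets[b][1]) < 0.5


class TestBhAdjust:
    def test_hand_values(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        assert (bh_adjust(p) >= p - 1e-15).all()

    @given(st.permutations(list(range(6))))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, perm):
        base = np.array([0.001, 0.01, 0.04, 0.2, 0.5, 0.9])
        adjusted = bh_adjust(base)
        shuffled = bh_adjust(base[list(perm)])
        assert shuffled == pytest.approx(adjusted[list(perm)])
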