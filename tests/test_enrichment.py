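"""Over-representation statistics against closed-form and enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from netconcord.enrichment import (
    PathwayCollection,
    common_pathways,
    enrich,
    random_set_fdr,
    read_gmt,
    write_gmt,
)
from netconcord.network import InteractionNetwork


def hypergeom_tail_oracle(k, N, K, q):
    """Upper-tail P(X >= k) from the closed-form PMF (math.comb)."""
    lo, hi = max(0, q - (N - K)), min(K, q)
    return sum(math.comb(K, i) * math.comb(N - K, q - i) / math.comb(N, q)
               for i in range(max(k, lo), hi + 1))


@pytest.fixture()
def small_coll():
    bg = [f"B{i}" for i in range(10)]
    return PathwayCollection.from_sets(
        {"PATH1": bg[:5], "PATH2": bg[5:]}, background=bg)


class TestCollection:
    def test_members_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            PathwayCollection({"P": frozenset({"A", "B"})},
                              frozenset({"A"}))

    def test_restriction_drops_outside_members(self, caplog):
        coll = PathwayCollection.from_sets(
            {"P": ["A", "B", "Z"], "TINY": ["Y", "Z"]},
            background=["A", "B", "C"])
        assert coll.pathways == {"P": frozenset({"A", "B"})}

    def test_small_pathway_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            PathwayCollection({"P": frozenset({"A"})}, frozenset({"A", "B"}))

    def test_gmt_round_trip(self, tmp_path, small_coll):
        p = tmp_path / "c.gmt"
        write_gmt(small_coll, p)
        again = read_gmt(p, background=sorted(small_coll.background))
        assert again.pathways == small_coll.pathways

    def test_gmt_needs_enough_fields(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("short\tdesc\tonly_one\n")
        with pytest.raises(ValueError, match="members"):
            read_gmt(p)


class TestEnrich:
    def test_disjoint_pathway_p_one(self, small_coll):
        tab = enrich(["B0", "B1"], small_coll).set_index("pathway")
        assert tab.loc["PATH2", "overlap"] == 0
        assert tab.loc["PATH2", "p"] == 1.0

    def test_closed_form_example(self, small_coll):
        """|bg|=10, pathway 5, query 4, overlap 4: p = C(5,4)/C(10,4)."""
        tab = enrich(["B0", "B1", "B2", "B3"], small_coll).set_index("pathway")
        assert tab.loc["PATH1", "p"] == pytest.approx(5 / 210)
        # cross-check by enumerating every possible 4-feature query
        bg = sorted(small_coll.background)
        hits = sum(1 for q in itertools.combinations(bg, 4)
                   if len(set(q) & small_coll.pathways["PATH1"]) >= 4)
        assert hits / math.comb(10, 4) == pytest.approx(5 / 210)

    def test_tails_match_enumeration_small_backgrounds(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            N = int(rng.integers(4, 16))
            bg = [f"F{i}" for i in range(N)]
            K = int(rng.integers(2, N))
            q = int(rng.integers(1, N))
            coll = PathwayCollection.from_sets({"P": bg[:K]}, background=bg)
            query = list(rng.choice(bg, size=q, replace=False))
            tab = enrich(query, coll).set_index("pathway")
            k = len(set(query) & set(bg[:K]))
            assert tab.loc["P", "p"] == pytest.approx(
                hypergeom_tail_oracle(k, N, K, q), abs=1e-12)

    def test_empty_query_after_intersection_is_error(self, small_coll):
        with pytest.raises(ValueError, match="no overlap"):
            enrich(["NOPE"], small_coll)

    def test_fdr_invariant_to_pathway_order(self, small_coll):
        reordered = PathwayCollection.from_sets(
            {n: sorted(small_coll.pathways[n])
             for n in reversed(sorted(small_coll.pathways))},
            background=sorted(small_coll.background))
        a = enrich(["B0", "B1", "B2"], small_coll).set_index("pathway")
        b = enrich(["B0", "B1", "B2"], reordered).set_index("pathway")
        assert a["fdr"].to_dict() == b["fdr"].to_dict()

    def test_monotone_in_query_growth_along_pathway(self, small_coll):
        prev = 1.1
        for size in range(1, 6):
            tab = enrich([f"B{i}" for i in range(size)],
                         small_coll).set_index("pathway")
            p = tab.loc["PATH1", "p"]
            assert p <= prev + 1e-12
            prev = p

    def test_planted_pathway_ranks_first(self, default_scenario):
        scn = default_scenario
        name = scn.truth.planted_pathways[0]
        tab = enrich(scn.pathways.pathways[name], scn.pathways)
        assert tab.iloc[0]["pathway"] == name
        assert tab.iloc[0]["rank"] == 1

    def test_ranks_are_permutation_and_p_sorted(self, default_scenario):
        scn = default_scenario
        tab = enrich(scn.truth.model_seeds["model_A"]["up"], scn.pathways)
        assert sorted(tab["rank"]) == list(range(1, len(tab) + 1))
        assert (tab["p"].diff().dropna() >= -1e-12).all()
        assert (tab["fdr"] >= tab["p"] - 1e-12).all()


class TestCommonPathways:
    def test_identical_tables_return_topk_significant(self, small_coll):
        tab = enrich(["B0", "B1", "B2", "B3"], small_coll)
        common = common_pathways(tab, tab, top_k=10)
        expect = sorted(tab[tab["significant"]]["pathway"])
        assert sorted(common) == expect

    def test_disjoint_significant_sets_empty(self, small_coll):
        a = enrich(["B0", "B1", "B2", "B3"], small_coll)
        b = a.copy()
        b["significant"] = False
        assert common_pathways(a, b) == []

    def test_direct_common_subset_of_topological(self, default_scenario):
        """The study's headline contrast: the direct layer finds no common
        pathway while the topological layer finds the planted ones."""
        from netconcord.toposcore import score_nodes

        scn = default_scenario
        direct_tabs = {}
        topo_tabs = {}
        for i, model in enumerate(sorted(scn.truth.model_seeds)):
            seeds = scn.truth.model_seeds[model]["up"]
            direct_tabs[model] = enrich(seeds, scn.pathways)
            scores = score_nodes(scn.network, seeds, rng_seed=11 + i)
            topo_tabs[model] = enrich(
                sorted(scores.index[scores["significant"]]), scn.pathways)
        direct_common = common_pathways(*direct_tabs.values())
        topo_common = common_pathways(*topo_tabs.values())
        assert set(direct_common) <= set(topo_common)
        assert direct_common == []
        assert set(topo_common) & set(scn.truth.planted_pathways)


class TestRandomSetFDR:
    def build_net(self, n=40):
        edges = [(f"N{i}", f"N{(i + 1) % n}") for i in range(n)]
        edges += [(f"N{i}", f"N{(i + 7) % n}") for i in range(n)]
        return InteractionNetwork.from_edges(edges)

    def test_absent_target_has_zero_fdr(self):
        net = self.build_net()
        bg = sorted(net.nodes)
        coll = PathwayCollection.from_sets({"P": bg[:5]}, background=bg)
        fdr = random_set_fdr(net, coll, ["MISSING"], n_sets=3, set_size=5,
                             rng_seed=0, n_resamples=10)
        assert fdr == {"MISSING": 0.0}

    def test_whole_background_pathway_saturates(self):
        net = self.build_net()
        bg = sorted(net.nodes)
        coll = PathwayCollection.from_sets({"ALL": bg}, background=bg)
        fdr = random_set_fdr(net, coll, ["ALL"], n_sets=3, set_size=5,
                             rng_seed=0, n_resamples=10)
        assert fdr == {"ALL": 1.0}

    def test_set_size_validated(self):
        net = self.build_net()
        bg = sorted(net.nodes)
        coll = PathwayCollection.from_sets({"P": bg[:5]}, background=bg)
        with pytest.raises(ValueError, match="set_size"):
            random_set_fdr(net, coll, ["P"], set_size=100)
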