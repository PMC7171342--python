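import itertools
import math

import numpy as np
import pytest

from amnioscan.pathway import (
    PathwayDefinition,
    enrich,
    holm_adjust,
    hypergeom_p,
    pathway_impact,
    relative_betweenness,
)
from amnioscan.simulate import TOY8_CENTRALITY, generate_toy_pathways


def betweenness_bfs_oracle(pathway):
    """Relative betweenness by brute-force shortest-path enumeration."""
    nodes = pathway.compounds
    adj = {v: set() for v in nodes}
    for a, b in pathway.edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_shortest_paths(s, t):
        paths, frontier = [], [[s]]
        found_len = None
        while frontier and found_len is None:
            nxt = []
            for path in frontier:
                if path[-1] == t:
                    paths.append(path)
                    found_len = len(path)
            if paths:
                break
            for path in frontier:
                for nb in adj[path[-1]]:
                    if nb not in path:
                        nxt.append(path + [nb])
            frontier = nxt
        return paths

    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    denom = (n - 1) * (n - 2) / 2
    return {v: (score[v] / denom if denom else 0.0) for v in nodes}


class TestHypergeom:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_p(20, 5, 4, 0) == 1.0

    def test_fully_enriched_toy_case(self):
        # all 5 draws land in a 5-member pathway out of 10: 1 / C(10,5)
        assert hypergeom_p(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-9)

    def test_pathway_equals_background(self):
        assert hypergeom_p(8, 8, 3, 3) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_p(10, 5, 4, 5)
        with pytest.raises(ValueError):
            hypergeom_p(10, 11, 4, 2)

    def test_matches_exhaustive_enumeration(self):
        """Agreement with brute-force enumeration for every configuration
        with background size N <= 12."""
        for N in range(1, 13):
            for K in range(0, N + 1):
                pathway = set(range(K))
                for n in range(0, N + 1):
                    tally = [0] * (min(K, n) + 1)
                    total = 0
                    for draw in itertools.combinations(range(N), n):
                        tally[len(pathway.intersection(draw))] += 1
                        total += 1
                    for k in range(0, min(K, n) + 1):
                        expected = sum(tally[k:]) / total
                        assert hypergeom_p(N, K, n, k) == pytest.approx(
                            expected, rel=1e-9, abs=1e-12
                        ), (N, K, n, k)


class TestHolm:
    def test_hand_computed_step_down(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_dominance_and_monotonicity(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 12)))
            adj = holm_adjust(p)
            assert all(a >= r for a, r in zip(adj, p))
            assert all(a <= min(1.0, len(p) * r) + 1e-12 for a, r in zip(adj, p))
            order = np.argsort(p)
            assert all(np.diff(np.asarray(adj)[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestBetweenness:
    def test_star_center_dominates(self):
        star = generate_toy_pathways()[0]
        cent = relative_betweenness(star)
        assert cent["center"] == pytest.approx(1.0)
        assert all(cent[f"leaf{i}"] == 0.0 for i in (1, 2, 3, 4))

    def test_chain_midpoint(self):
        chain = generate_toy_pathways()[1]
        cent = relative_betweenness(chain)
        assert cent == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_complete_graph_has_no_intermediaries(self):
        complete = generate_toy_pathways()[2]
        assert set(relative_betweenness(complete).values()) == {0.0}

    def test_toy8_matches_shipped_table_and_bfs_oracle(self):
        toy8 = generate_toy_pathways()[3]
        cent = relative_betweenness(toy8)
        for node, expected in TOY8_CENTRALITY.items():
            assert cent[node] == pytest.approx(expected, abs=1e-12)
        oracle = betweenness_bfs_oracle(toy8)
        for node in toy8.compounds:
            assert cent[node] == pytest.approx(oracle[node], abs=1e-12)

    def test_random_graphs_match_bfs_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(3, 8))
            nodes = [f"c{i}" for i in range(n)]
            edges = [
                (a, b)
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.45
            ]
            pw = PathwayDefinition("rand", nodes, edges)
            cent = relative_betweenness(pw)
            oracle = betweenness_bfs_oracle(pw)
            for v in nodes:
                assert cent[v] == pytest.approx(oracle[v], abs=1e-9)


class TestPathwayImpact:
    def test_limits_on_toys(self):
        star, chain, complete, toy8 = generate_toy_pathways()
        assert pathway_impact(star, {"center"}) == 1.0
        assert pathway_impact(star, {"leaf1"}) == 0.0
        assert pathway_impact(chain, {"a", "b"}) == pytest.approx(1.0)
        assert pathway_impact(complete, set(complete.compounds)) == 0.0

    def test_monotone_under_inclusion(self):
        toy8 = generate_toy_pathways()[3]
        rng = np.random.default_rng(13)
        for _ in range(20):
            nodes = list(toy8.compounds)
            k = int(rng.integers(0, len(nodes)))
            matched = set(rng.choice(nodes, size=k, replace=False))
            extra = set(rng.choice(nodes, size=min(k + 1, len(nodes)), replace=False))
            assert pathway_impact(toy8, matched | extra) >= pathway_impact(toy8, matched)

    def test_full_match_has_unit_impact(self):
        for pw in generate_toy_pathways():
            total = sum(relative_betweenness(pw).values())
            impact = pathway_impact(pw, set(pw.compounds))
            assert impact == pytest.approx(1.0 if total > 0 else 0.0)

    def test_non_member_match_rejected(self):
        star = generate_toy_pathways()[0]
        with pytest.raises(ValueError, match="not members"):
            pathway_impact(star, {"stranger"})


class TestEnrich:
    def _bundle(self):
        a = PathwayDefinition("A", ["x", "y", "z"], [("x", "y"), ("y", "z")])
        b = PathwayDefinition("B", ["u", "v", "w"], [("u", "v"), ("v", "w")])
        background = {"x", "y", "z", "u", "v", "w", "q1", "q2", "q3", "q4"}
        return [a, b], background

    def test_empty_hits_give_null_results(self):
        pathways, background = self._bundle()
        results = enrich(pathways, set(), background)
        assert all(r.raw_p == 1.0 for r in results)
        assert all(r.impact == 0.0 for r in results)

    def test_fully_hit_pathway_ranks_first(self):
        pathways, background = self._bundle()
        results = enrich(pathways, {"x", "y", "z"}, background)
        assert results[0].name == "A"
        assert results[0].impact == pytest.approx(1.0)
        assert results[0].raw_p < results[1].raw_p

    def test_one_result_per_pathway(self):
        pathways, background = self._bundle()
        assert len(enrich(pathways, {"x"}, background)) == len(pathways)

    def test_holm_dominates_raw(self):
        pathways, background = self._bundle()
        for r in enrich(pathways, {"x", "y", "u"}, background):
            assert r.holm_p >= r.raw_p
            assert r.holm_p <= min(1.0, len(pathways) * r.raw_p) + 1e-12

    def test_log_base_option(self):
        pathways, background = self._bundle()
        res_e = enrich(pathways, {"x", "y", "z"}, background, log_base="e")
        res_10 = enrich(pathways, {"x", "y", "z"}, background, log_base="10")
        assert res_e[0].neg_log_p == pytest.approx(-math.log(res_e[0].raw_p))
        assert res_10[0].neg_log_p == pytest.approx(-math.log10(res_10[0].raw_p))

    def test_empty_background_rejected(self):
        pathways, _ = self._bundle()
        with pytest.raises(ValueError, match="background"):
            enrich(pathways, set(), set())


def test_pathway_definition_validation():
    with pytest.raises(ValueError, match="self-loop"):
        PathwayDefinition("bad", ["a"], [("a", "a")])
    with pytest.raises(ValueError, match="non-member"):
        PathwayDefinition("bad", ["a", "b"], [("a", "c")])
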