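"""Gene-order matching: projections, MCS detection, iterated matchings.

The brute-force oracles here (order filtering, adjacency enumeration,
exhaustive run and matching enumeration) are written independently of
the implementation and only touch toy-sized inputs.
"""

import itertools
import math

import numpy as np
import pytest

from conftest import make_genome, make_pair_graph
from synterho.ffadj import (FFAdjParams, find_mcs, objective, project,
                            relax_in_paralogs, run_ffadj)

# ---------------------------------------------------------------- oracles


def oracle_project(order, active):
    return [g for g in order if g in active]


def oracle_objective(edges, orders_a, orders_b, weights, alpha):
    """Direct double-loop adjacency count over filtered orders."""
    active_a = {a for a, _ in weights}
    active_b = {b for _, b in weights}
    proj_a = [oracle_project(o, active_a) for o in orders_a]
    proj_b = [oracle_project(o, active_b) for o in orders_b]

    def adjacent(projs, g1, g2):
        return any(abs(p.index(g1) - p.index(g2)) == 1
                   for p in projs if g1 in p and g2 in p)

    total = (1 - alpha) * sum(weights[e] for e in edges)
    for e1, e2 in itertools.combinations(edges, 2):
        if adjacent(proj_a, e1[0], e2[0]) and adjacent(proj_b, e1[1], e2[1]):
            total += alpha * math.sqrt(weights[e1] * weights[e2])
    return total


def oracle_runs(edges, order_a, order_b):
    """All maximal diagonal/anti-diagonal runs, single chromosome pair."""
    pos_a = {g: i for i, g in enumerate(oracle_project(order_a, {a for a, _ in edges}))}
    pos_b = {g: i for i, g in enumerate(oracle_project(order_b, {b for _, b in edges}))}
    cells = {(pos_a[a], pos_b[b]): (a, b) for a, b in edges}
    runs = set()
    for (i, j) in cells:
        for d in (1, -1):
            if (i - 1, j - d) in cells:
                continue  # not a start
            run = [(i, j)]
            while (run[-1][0] + 1, run[-1][1] + d) in cells:
                run.append((run[-1][0] + 1, run[-1][1] + d))
            if d == 1 or len(run) >= 2:
                runs.add(tuple(cells[c] for c in run))
    return runs


def enumerate_matchings(edges):
    """Every matching (any subset with disjoint endpoints)."""
    edges = list(edges)

    def rec(i, used_a, used_b, current):
        if i == len(edges):
            yield tuple(current)
            return
        yield from rec(i + 1, used_a, used_b, current)
        a, b = edges[i]
        if a not in used_a and b not in used_b:
            current.append((a, b))
            yield from rec(i + 1, used_a | {a}, used_b | {b}, current)
            current.pop()

    yield from rec(0, set(), set(), [])


def weight_greedy_baseline(pg, w):
    """Independent weight-descending maximal matching with the documented
    positional tie-break (chromosome, rank of both endpoints)."""
    pos_a = {g.gene_id: (c, g.rank) for c, genes in pg.genome_a.chromosomes.items()
             for g in genes}
    pos_b = {g.gene_id: (c, g.rank) for c, genes in pg.genome_b.chromosomes.items()
             for g in genes}
    greedy, ua, ub = [], set(), set()
    for (a, b) in sorted(pg.edges, key=lambda e: (-w[e], pos_a[e[0]], pos_b[e[1]])):
        if a not in ua and b not in ub:
            greedy.append((a, b))
            ua.add(a)
            ub.add(b)
    return greedy


def random_pair_graph(rng, n_a=6, n_b=6, density=0.4, n_chrom=1):
    ids_a = [f"a{i}" for i in range(n_a)]
    ids_b = [f"b{i}" for i in range(n_b)]

    def split(ids):
        if n_chrom == 1 or len(ids) < 2:
            return {"c1": ids}
        cut = int(rng.integers(1, len(ids)))
        return {"c1": ids[:cut], "c2": ids[cut:]}

    ga = make_genome("A", split(list(rng.permutation(ids_a))))
    gb = make_genome("B", split(list(rng.permutation(ids_b))))
    edges = {(a, b): float(rng.integers(1, 101))
             for a in ids_a for b in ids_b if rng.random() < density}
    return make_pair_graph(ga, gb, edges)


# ----------------------------------------------------------------- tests


class TestProject:
    def test_hidden_gene_creates_adjacency(self):
        ga = make_genome("A", {"c": ["g1", "gX", "g2"]})
        gb = make_genome("B", {"c": ["h1", "h2"]})
        pg = make_pair_graph(ga, gb, {("g1", "h1"): 1.0, ("g2", "h2"): 1.0})
        proj_a, _ = project(pg)
        assert proj_a.orders == {"c": ["g1", "g2"]}
        assert proj_a.adjacent("g1", "g2")

    def test_all_active_is_identity(self):
        ga = make_genome("A", {"c": ["g1", "g2"]})
        gb = make_genome("B", {"c": ["h1", "h2"]})
        pg = make_pair_graph(ga, gb, {("g1", "h1"): 1.0, ("g2", "h2"): 1.0})
        proj_a, proj_b = project(pg)
        assert proj_a.orders["c"] == ["g1", "g2"]
        assert proj_b.orders["c"] == ["h1", "h2"]

    def test_matches_filter_oracle_under_random_deletions(self, rng):
        ids_a = [f"a{i}" for i in range(8)]
        ids_b = [f"b{i}" for i in range(8)]
        ga = make_genome("A", {"c": ids_a})
        gb = make_genome("B", {"c": ids_b})
        for _ in range(30):
            edges = {(a, b): 1.0 for a in ids_a for b in ids_b
                     if rng.random() < 0.15}
            pg = make_pair_graph(ga, gb, edges)
            proj_a, proj_b = project(pg)
            assert proj_a.orders.get("c", []) == \
                oracle_project(ids_a, {a for a, _ in edges})
            assert proj_b.orders.get("c", []) == \
                oracle_project(ids_b, {b for _, b in edges})


class TestObjective:
    def test_alpha_zero_is_weight_sum(self):
        ga = make_genome("A", {"c": ["a1", "a2"]})
        gb = make_genome("B", {"c": ["b1", "b2"]})
        pg = make_pair_graph(ga, gb, {("a1", "b1"): 100.0, ("a2", "b2"): 50.0})
        proj = project(pg)
        w = pg.normalized_edges()
        assert objective(pg.edges, *proj, w, alpha=0.0) == pytest.approx(1.5)

    def test_two_conserved_adjacent_unit_edges(self):
        ga = make_genome("A", {"c": ["a1", "a2"]})
        gb = make_genome("B", {"c": ["b1", "b2"]})
        pg = make_pair_graph(ga, gb, {("a1", "b1"): 7.0, ("a2", "b2"): 7.0})
        w = pg.normalized_edges()
        assert objective(pg.edges, *project(pg), w, alpha=0.5) == pytest.approx(1.5)

    def test_matches_bruteforce_on_random_matchings(self, rng):
        for _ in range(40):
            pg = random_pair_graph(rng, 8, 8, 0.3)
            w = pg.normalized_edges()
            matchings = [m for m in itertools.islice(enumerate_matchings(pg.edges), 200)]
            if not matchings:
                continue
            pick = matchings[int(rng.integers(len(matchings)))]
            got = objective(pick, *project(pg), w, 0.5)
            orders_a = [[g.gene_id for g in c] for c in pg.genome_a.chromosomes.values()]
            orders_b = [[g.gene_id for g in c] for c in pg.genome_b.chromosomes.values()]
            assert got == pytest.approx(
                oracle_objective(pick, orders_a, orders_b, w, 0.5))


class TestFindMCS:
    def simple(self, order_b, edges):
        ga = make_genome("A", {"c": ["a1", "a2", "a3"]})
        gb = make_genome("B", {"c": order_b})
        return make_pair_graph(ga, gb, edges)

    def test_diagonal_run_of_three(self):
        pg = self.simple(["b1", "b2", "b3"],
                         {(f"a{i}", f"b{i}"): 1.0 for i in (1, 2, 3)})
        runs = find_mcs(pg, project(pg))
        assert len(runs) == 1
        assert [e for e in runs[0].edges] == [("a1", "b1"), ("a2", "b2"), ("a3", "b3")]
        assert runs[0].direction == 1

    def test_reversed_order_gives_antidiagonal_run(self):
        pg = self.simple(["b3", "b2", "b1"],
                         {(f"a{i}", f"b{i}"): 1.0 for i in (1, 2, 3)})
        runs = [r for r in find_mcs(pg, project(pg)) if r.size == 3]
        assert len(runs) == 1 and runs[0].direction == -1

    def test_matches_run_enumeration_oracle(self, rng):
        for _ in range(60):
            pg = random_pair_graph(rng, 10, 10, 0.12)
            runs = find_mcs(pg, project(pg))
            got = {tuple(r.edges) for r in runs}
            order_a = [g.gene_id for g in pg.genome_a.chromosomes["c1"]]
            order_b = [g.gene_id for g in pg.genome_b.chromosomes["c1"]]
            assert got == oracle_runs(pg.edges, order_a, order_b)


class TestMatching:
    def test_context_resolves_duplicated_pair(self, toy_duplication_pair_graph):
        matching = run_ffadj(toy_duplication_pair_graph)
        pairs = set(matching.pairs())
        assert ("A1", "B1") in pairs and ("A2", "B2") in pairs
        assert ("A1", "B2") not in pairs and ("A2", "B1") not in pairs

    def test_single_edge_graph(self):
        ga = make_genome("A", {"c": ["a1"]})
        gb = make_genome("B", {"c": ["b1"]})
        pg = make_pair_graph(ga, gb, {("a1", "b1"): 5.0})
        assert run_ffadj(pg).pairs() == [("a1", "b1")]

    def test_tandem_duplicated_block_recovered_in_second_round(self):
        ga = make_genome("A", {"c": ["x1", "y1", "x2", "y2"]})
        gb = make_genome("B", {"c": ["x", "y"]})
        pg = make_pair_graph(ga, gb, {("x1", "x"): 1.0, ("x2", "x"): 1.0,
                                      ("y1", "y"): 1.0, ("y2", "y"): 1.0})
        matching = run_ffadj(pg, FFAdjParams(n_iterations=1, min_mcs_size=2))
        round1 = {(e.gene_a, e.gene_b) for e in matching.edges if e.round_index == 1}
        round2 = {(e.gene_a, e.gene_b) for e in matching.edges if e.round_index == 2}
        assert round1 == {("x1", "x"), ("y1", "y")}
        assert round2 == {("x2", "x"), ("y2", "y")}

    def test_no_iterations_gives_plain_matching(self):
        ga = make_genome("A", {"c": ["x1", "x2"]})
        gb = make_genome("B", {"c": ["x"]})
        pg = make_pair_graph(ga, gb, {("x1", "x"): 2.0, ("x2", "x"): 1.0})
        matching = run_ffadj(pg, FFAdjParams(n_iterations=0))
        assert matching.pairs() == [("x1", "x")]

    def test_output_is_matching_per_round_and_subset_of_input(self, rng):
        for _ in range(50):
            pg = random_pair_graph(rng, 6, 6, 0.45,
                                   n_chrom=int(rng.integers(1, 3)))
            matching = run_ffadj(pg, FFAdjParams(n_iterations=1, min_mcs_size=2))
            by_round = {}
            for e in matching.edges:
                by_round.setdefault(e.round_index, []).append(e)
                assert (e.gene_a, e.gene_b) in pg.edges  # never invents edges
            for edges in by_round.values():
                assert len({e.gene_a for e in edges}) == len(edges)
                assert len({e.gene_b for e in edges}) == len(edges)

    def test_objective_bracket_on_toys(self, rng):
        """Heuristic lands between weight-greedy and the exhaustive optimum."""
        for _ in range(60):
            pg = random_pair_graph(rng, 5, 5, 0.4)
            if not pg.edges:
                continue
            matching = run_ffadj(pg, FFAdjParams(n_iterations=0))
            w = pg.normalized_edges()
            orders_a = [[g.gene_id for g in c] for c in pg.genome_a.chromosomes.values()]
            orders_b = [[g.gene_id for g in c] for c in pg.genome_b.chromosomes.values()]

            def obj(m):
                return oracle_objective(m, orders_a, orders_b, w, 0.5)

            best = max(obj(m) for m in enumerate_matchings(pg.edges))
            greedy = weight_greedy_baseline(pg, w)
            got = obj(matching.pairs())
            assert got <= best + 1e-9
            assert got >= obj(greedy) - 1e-9

    def test_alpha_increases_conserved_adjacencies_in_aggregate(self, rng):
        def count_adjacencies(pg, pairs):
            proj_a, proj_b = project(pg)
            return sum(1 for e1, e2 in itertools.combinations(pairs, 2)
                       if proj_a.adjacent(e1[0], e2[0])
                       and proj_b.adjacent(e1[1], e2[1]))

        totals = {0.1: 0, 0.9: 0}
        for _ in range(40):
            pg = random_pair_graph(rng, 6, 6, 0.4)
            for alpha in totals:
                m = run_ffadj(pg, FFAdjParams(alpha=alpha, n_iterations=0))
                totals[alpha] += count_adjacencies(pg, m.pairs())
        assert totals[0.9] >= totals[0.1]

    def test_linearizing_a_circular_order_loses_at_most_two_adjacencies(self, rng):
        """Rotating (re-cutting) a circular gene order changes the conserved
        adjacency count of a full identity matching by at most 2."""
        n = 8
        ids = [f"g{i}" for i in range(n)]
        pairs = [(g, g.replace("g", "h")) for g in ids]

        def adjacencies(shift):
            order_a = ids
            order_b = [g.replace("g", "h") for g in ids[shift:] + ids[:shift]]
            ga = make_genome("A", {"c": order_a})
            gb = make_genome("B", {"c": order_b})
            pg = make_pair_graph(ga, gb, {p: 1.0 for p in pairs})
            proj_a, proj_b = project(pg)
            return sum(1 for e1, e2 in itertools.combinations(pairs, 2)
                       if proj_a.adjacent(e1[0], e2[0])
                       and proj_b.adjacent(e1[1], e2[1]))

        base = adjacencies(0)
        for shift in range(1, n):
            assert base - adjacencies(shift) <= 2


class TestRelaxInParalogs:
    def setup(self, order_a, best_map):
        ga = make_genome("A", {"c": order_a})
        gb = make_genome("B", {"c": ["z", "z2"]})
        edges = {}
        for g, (partner, score) in best_map.items():
            edges[(g, partner)] = score
        return make_pair_graph(ga, gb, edges)

    def test_adjacent_shared_best_hit_adds_both_edges(self):
        pg = self.setup(["x", "y"], {"x": ("z", 100.0), "y": ("z", 99.0)})
        matching = run_ffadj(pg, FFAdjParams(n_iterations=0))
        assert set(matching.pairs()) == {("x", "z")}
        relaxed = relax_in_paralogs(pg, matching)
        assert set(relaxed.pairs()) == {("x", "z"), ("y", "z")}
        flags = {(e.gene_a, e.gene_b): e.in_paralog for e in relaxed.edges}
        assert flags[("y", "z")] and not flags[("x", "z")]

    def test_different_best_hits_no_augmentation(self):
        pg = self.setup(["x", "y"], {"x": ("z", 100.0), "y": ("z2", 99.0)})
        matching = relax_in_paralogs(pg, run_ffadj(pg, FFAdjParams(n_iterations=0)))
        assert not any(e.in_paralog for e in matching.edges)

    def test_non_adjacent_shared_best_hit_no_augmentation(self):
        ga = make_genome("A", {"c": ["x", "mid", "y"]})
        gb = make_genome("B", {"c": ["z", "zmid"]})
        pg = make_pair_graph(ga, gb, {("x", "z"): 100.0, ("y", "z"): 99.0,
                                      ("mid", "zmid"): 50.0})
        matching = relax_in_paralogs(pg, run_ffadj(pg, FFAdjParams(n_iterations=0)))
        assert not any(e.in_paralog for e in matching.edges)
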