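"""Gene-order (synteny) filtering of bipartite candidate graphs.

Each genome pair's candidate graph is pruned to a near-matching that
maximizes a trade-off between total (normalized) edge weight and the
weight of conserved adjacencies.  Candidate edges are grouped into
*maximum common substrings* (MCSs): maximal runs of edges whose
endpoints occupy consecutive positions, in the same or exactly reversed
direction, in both genomes' *projected* orders.  The projection hides
genes without any candidate edge, so such genes neither form nor break
adjacencies.

Duplicated genes and regions are recovered by iterated matchings:
after the first matching, previously selected edges are removed and the
matching is repeated, accepting only MCSs of a minimum size.  Finally,
adjacent genes whose best partner is one and the same gene on the other
side are both linked to it (in-paralog relaxation), deliberately
breaking the matching property for likely recent duplicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .genome_io import Genome
from .simgraph import PairGraph

__all__ = ["FFAdjParams", "Projection", "MCS", "MatchEdge", "Matching",
           "project", "objective", "find_mcs", "match_round", "run_ffadj",
           "relax_in_paralogs"]

Edge = Tuple[str, str]


@dataclass(frozen=True)
class FFAdjParams:
    """Tunables of the gene-order matching heuristic.

    alpha: relative importance of the adjacency term vs. the edge-weight
        term in the objective (0 = weights only, 1 = adjacencies only).
    n_iterations: extra matching rounds after the first, for duplicated
        genes and regions.
    min_mcs_size: minimum gene pairs per MCS accepted in rounds >= 2.
    circular: treat chromosomes as circular, linearized at rank 0 (the
        two adjacencies across the cut are the only information lost).
    """

    alpha: float = 0.5
    n_iterations: int = 1
    min_mcs_size: int = 3
    circular: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.min_mcs_size < 1:
            raise ValueError("min_mcs_size must be >= 1")


@dataclass
class Projection:
    """Active-gene order of one genome: per chromosome, the subsequence of
    genes carrying at least one candidate edge, re-ranked 0..k-1."""

    orders: Dict[str, List[str]] = field(default_factory=dict)
    pos: Dict[str, Tuple[str, int]] = field(default_factory=dict)

    @classmethod
    def from_genome(cls, genome: Genome, active: Set[str]) -> "Projection":
        proj = cls()
        for chrom_id in sorted(genome.chromosomes):
            sub = [g.gene_id for g in genome.chromosomes[chrom_id] if g.gene_id in active]
            if sub:
                proj.orders[chrom_id] = sub
                for i, gid in enumerate(sub):
                    proj.pos[gid] = (chrom_id, i)
        return proj

    def adjacent(self, g1: str, g2: str) -> bool:
        """Neighbors in the projected order of one chromosome (unoriented)."""
        p1, p2 = self.pos.get(g1), self.pos.get(g2)
        if p1 is None or p2 is None or p1[0] != p2[0]:
            return False
        return abs(p1[1] - p2[1]) == 1


@dataclass
class MCS:
    """A maximal common substring: edges on consecutive projected ranks in
    both genomes, diagonal (direction=+1) or anti-diagonal (direction=-1)."""

    edges: List[Edge]
    direction: int
    score: float = 0.0

    @property
    def size(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class MatchEdge:
    gene_a: str
    gene_b: str
    weight: float          # raw symmetric bit score
    norm_weight: float     # weight / max weight of the pair graph
    round_index: int
    mcs_index: int
    in_paralog: bool = False


@dataclass
class Matching:
    """Result of the gene-order filter for one genome pair."""

    species_a: str
    species_b: str
    edges: List[MatchEdge] = field(default_factory=list)
    objective_value: float = 0.0

    def pairs(self, include_relaxed: bool = True) -> List[Edge]:
        return [(e.gene_a, e.gene_b) for e in self.edges
                if include_relaxed or not e.in_paralog]


def project(pair_graph: PairGraph,
            edges: Optional[Iterable[Edge]] = None) -> Tuple[Projection, Projection]:
    """Projected orders of both genomes given the current candidate edges.

    ``edges`` defaults to the full candidate edge set; iterated matching
    rounds pass the still-unselected subset.
    """
    edge_list = list(edges) if edges is not None else list(pair_graph.edges)
    active_a = {a for a, _ in edge_list}
    active_b = {b for _, b in edge_list}
    return (Projection.from_genome(pair_graph.genome_a, active_a),
            Projection.from_genome(pair_graph.genome_b, active_b))


def objective(edges: Iterable[Edge],
              proj_a: Projection,
              proj_b: Projection,
              weights: Mapping[Edge, float],
              alpha: float) -> float:
    """alpha * sum over conserved adjacencies of sqrt(w*w') +
    (1-alpha) * sum of edge weights, weights already normalized to (0,1].

    Two edges form a conserved adjacency iff their A endpoints are
    projected neighbors in A and their B endpoints projected neighbors
    in B (forward or reversed order alike).
    """
    edge_list = list(edges)
    edge_sum = sum(weights[e] for e in edge_list)
    adj_sum = 0.0
    # index edges by their A endpoint's projected position for O(n) adjacency scan
    by_pos: Dict[Tuple[str, int], Edge] = {}
    for e in edge_list:
        p = proj_a.pos.get(e[0])
        if p is not None:
            # a gene may carry several selected edges only via relaxation;
            # relaxed edges are excluded from objectives upstream
            by_pos[p] = e
    for (chrom, i), e in by_pos.items():
        e2 = by_pos.get((chrom, i + 1))
        if e2 is not None and proj_b.adjacent(e[1], e2[1]):
            adj_sum += math.sqrt(weights[e] * weights[e2])
    return alpha * adj_sum + (1.0 - alpha) * edge_sum


def _score_run(run: List[Edge], weights: Mapping[Edge, float], alpha: float) -> float:
    s = (1.0 - alpha) * sum(weights[e] for e in run)
    for e1, e2 in zip(run, run[1:]):
        s += alpha * math.sqrt(weights[e1] * weights[e2])
    return s


def find_mcs(pair_graph: PairGraph,
             projections: Tuple[Projection, Projection],
             edges: Optional[Iterable[Edge]] = None,
             alpha: float = 0.5,
             weights: Optional[Mapping[Edge, float]] = None) -> List[MCS]:
    """All maximal diagonal and anti-diagonal runs of the projected dot plot.

    Every edge between two placed genes appears in exactly one forward
    run (possibly of size 1); anti-diagonal runs are reported only at
    size >= 2 (a single edge has no direction).  Edges involving
    unplaced genes cannot take part in runs and are left to the size-1
    fallback of the matching round.
    """
    proj_a, proj_b = projections
    edge_list = list(edges) if edges is not None else list(pair_graph.edges)
    if weights is None:
        weights = pair_graph.normalized_edges()

    # (chromA, i, chromB, j) -> edge, for placed endpoints only
    grid: Dict[Tuple[str, int, str, int], Edge] = {}
    for e in edge_list:
        pa, pb = proj_a.pos.get(e[0]), proj_b.pos.get(e[1])
        if pa is None or pb is None:
            continue
        grid[(pa[0], pa[1], pb[0], pb[1])] = e

    runs: List[MCS] = []
    for (ca, i, cb, j), e in sorted(grid.items()):
        if (ca, i - 1, cb, j - 1) not in grid:        # forward-run start
            run = [e]
            k = 1
            while (ca, i + k, cb, j + k) in grid:
                run.append(grid[(ca, i + k, cb, j + k)])
                k += 1
            runs.append(MCS(run, +1, _score_run(run, weights, alpha)))
        if (ca, i - 1, cb, j + 1) not in grid:        # anti-diagonal start
            run = [e]
            k = 1
            while (ca, i + k, cb, j - k) in grid:
                run.append(grid[(ca, i + k, cb, j - k)])
                k += 1
            if len(run) >= 2:
                runs.append(MCS(run, -1, _score_run(run, weights, alpha)))
    return runs


def _edge_sort_key(e: Edge, proj_a: Projection, proj_b: Projection):
    pa = proj_a.pos.get(e[0])
    pb = proj_b.pos.get(e[1])
    ka = (0, pa[0], pa[1]) if pa is not None else (1, e[0], 0)
    kb = (0, pb[0], pb[1]) if pb is not None else (1, e[1], 0)
    return (ka, kb)


def _mcs_sort_key(m: MCS, proj_a: Projection, proj_b: Projection):
    # score desc, size desc, then lexicographically smallest start position
    return (-m.score, -m.size, _edge_sort_key(m.edges[0], proj_a, proj_b))


def match_round(pair_graph: PairGraph,
                params: FFAdjParams,
                forbidden: Set[Edge],
                round_index: int = 1,
                weights: Optional[Mapping[Edge, float]] = None) -> List[Tuple[List[Edge], int]]:
    """One complete matching pass over the edges not yet selected.

    Greedy by MCS score: repeatedly accept the best-scoring run all of
    whose genes are still free this round; runs touching matched genes
    are split at the conflicts and re-scored.  Round 1 finishes with a
    size-1 fallback over the remaining free edges (weight-descending);
    rounds >= 2 accept only runs of at least ``min_mcs_size`` pairs and
    have no fallback.

    Returns a list of (edge run, mcs ordinal) selections.
    """
    working = [e for e in pair_graph.edges if e not in forbidden]
    if not working:
        return []
    if weights is None:
        weights = pair_graph.normalized_edges()
    proj_a, proj_b = project(pair_graph, working)
    runs = find_mcs(pair_graph, (proj_a, proj_b), working, params.alpha, weights)

    min_size = 2 if round_index == 1 else params.min_mcs_size
    matched_a: Set[str] = set()
    matched_b: Set[str] = set()
    selected: List[Tuple[List[Edge], int]] = []
    mcs_counter = 0

    pool = [m for m in runs if m.size >= min_size]
    while pool:
        # split runs at genes matched earlier in this round, drop short pieces
        fresh: List[MCS] = []
        for m in pool:
            piece: List[Edge] = []
            for e in m.edges:
                if e[0] in matched_a or e[1] in matched_b:
                    if len(piece) >= min_size:
                        fresh.append(MCS(piece, m.direction,
                                         _score_run(piece, weights, params.alpha)))
                    piece = []
                else:
                    piece.append(e)
            if len(piece) >= min_size:
                fresh.append(MCS(piece, m.direction,
                                 _score_run(piece, weights, params.alpha)))
        if not fresh:
            break
        fresh.sort(key=lambda m: _mcs_sort_key(m, proj_a, proj_b))
        best = fresh[0]
        # one-to-one inside the accepted run
        run_edges: List[Edge] = []
        seen_a: Set[str] = set()
        seen_b: Set[str] = set()
        for e in best.edges:
            if e[0] in seen_a or e[1] in seen_b:
                continue
            run_edges.append(e)
            seen_a.add(e[0])
            seen_b.add(e[1])
        selected.append((run_edges, mcs_counter))
        mcs_counter += 1
        matched_a |= seen_a
        matched_b |= seen_b
        pool = fresh[1:]

    if round_index == 1:
        # size-1 fallback: free edges, heaviest first
        free = [e for e in working
                if e[0] not in matched_a and e[1] not in matched_b]
        free.sort(key=lambda e: (-weights[e], _edge_sort_key(e, proj_a, proj_b)))
        for e in free:
            if e[0] in matched_a or e[1] in matched_b:
                continue
            selected.append(([e], mcs_counter))
            mcs_counter += 1
            matched_a.add(e[0])
            matched_b.add(e[1])
    return selected


def _weight_greedy(pair_graph: PairGraph,
                   weights: Mapping[Edge, float],
                   proj_a: Projection,
                   proj_b: Projection) -> List[Edge]:
    """Plain maximal matching by descending weight (no synteny)."""
    order = sorted(pair_graph.edges,
                   key=lambda e: (-weights[e], _edge_sort_key(e, proj_a, proj_b)))
    used_a: Set[str] = set()
    used_b: Set[str] = set()
    out: List[Edge] = []
    for a, b in order:
        if a not in used_a and b not in used_b:
            out.append((a, b))
            used_a.add(a)
            used_b.add(b)
    return out


def run_ffadj(pair_graph: PairGraph, params: Optional[FFAdjParams] = None) -> Matching:
    """Full gene-order filter for one genome pair.

    Round 1 is guaranteed to reach at least the objective of a pure
    weight-greedy matching: if the MCS-driven pass scores lower (runs of
    mid-weight edges can lock genes needed by heavier isolated edges),
    the weight-greedy matching is used instead.  Further rounds recover
    duplicated genes/regions by re-matching the leftover edges under the
    MCS-size constraint.
    """
    params = params or FFAdjParams()
    result = Matching(pair_graph.species_a, pair_graph.species_b)
    if not pair_graph.edges:
        return result
    weights = pair_graph.normalized_edges()
    proj_a, proj_b = project(pair_graph)

    round1 = match_round(pair_graph, params, set(), 1, weights)
    round1_edges = [e for run, _ in round1 for e in run]
    obj_mcs = objective(round1_edges, proj_a, proj_b, weights, params.alpha)
    greedy = _weight_greedy(pair_graph, weights, proj_a, proj_b)
    obj_greedy = objective(greedy, proj_a, proj_b, weights, params.alpha)
    if obj_greedy > obj_mcs + 1e-12:
        round1 = [([e], i) for i, e in enumerate(greedy)]
        result.objective_value = obj_greedy
    else:
        result.objective_value = obj_mcs

    forbidden: Set[Edge] = set()
    for run, mcs_id in round1:
        for a, b in run:
            result.edges.append(MatchEdge(a, b, pair_graph.edges[(a, b)],
                                          weights[(a, b)], 1, mcs_id))
            forbidden.add((a, b))

    for rnd in range(2, params.n_iterations + 2):
        picked = match_round(pair_graph, params, forbidden, rnd, weights)
        if not picked:
            break
        for run, mcs_id in picked:
            for a, b in run:
                result.edges.append(MatchEdge(a, b, pair_graph.edges[(a, b)],
                                              weights[(a, b)], rnd, mcs_id))
                forbidden.add((a, b))
    return result


def _best_partner(gene: str, side: int, pair_graph: PairGraph) -> Optional[str]:
    """Highest-weight candidate partner (ties -> smallest id)."""
    best: Optional[Tuple[float, str]] = None
    for (a, b), w in pair_graph.edges.items():
        g, partner = (a, b) if side == 0 else (b, a)
        if g != gene:
            continue
        if best is None or (w, ) > (best[0], ) or (w == best[0] and partner < best[1]):
            best = (w, partner)
    return best[1] if best else None


def relax_in_paralogs(pair_graph: PairGraph, matching: Matching) -> Matching:
    """Add both edges when two chromosome neighbors share one best partner.

    If adjacent genes x, y (consecutive ranks on one chromosome) both
    have the same gene z on the other side as their best-scoring
    candidate, both (x,z) and (y,z) enter the output, flagged, even
    though this breaks the matching property: x and y are likely recent
    in-paralogs and a choice based on a marginal score difference would
    be arbitrary.  Applied to neighbors in either genome.
    """
    weights = pair_graph.normalized_edges()
    present = set(matching.pairs())
    out = Matching(matching.species_a, matching.species_b,
                   list(matching.edges), matching.objective_value)

    for side, genome in ((0, pair_graph.genome_a), (1, pair_graph.genome_b)):
        best_cache: Dict[str, Optional[str]] = {}

        def best(g: str) -> Optional[str]:
            if g not in best_cache:
                best_cache[g] = _best_partner(g, side, pair_graph)
            return best_cache[g]

        for chrom in genome.chromosomes.values():
            for x, y in zip(chrom, chrom[1:]):
                z = best(x.gene_id)
                if z is None or best(y.gene_id) != z:
                    continue
                for g in (x.gene_id, y.gene_id):
                    e = (g, z) if side == 0 else (z, g)
                    if e in present or e not in pair_graph.edges:
                        continue
                    out.edges.append(MatchEdge(e[0], e[1], pair_graph.edges[e],
                                               weights[e], 0, -1, in_paralog=True))
                    present.add(e)
    return out
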