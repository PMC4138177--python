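"""The similarity graph: adaptive best-hit filtering and reciprocal merging.

A directed edge x -> y (x in genome A, y in genome B) survives when the
bit score s(x,y) is at least a fraction ``f`` of x's best score against B,
the E-value passes, and both sequences are sufficiently covered by the
alignment.  Only reciprocally surviving pairs enter the bipartite
candidate graph of the genome pair, with the two directed bit scores
averaged into one symmetric edge weight.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .genome_io import Genome, SimilarityHit

logger = logging.getLogger(__name__)

__all__ = ["FilterParams", "PairGraph", "best_hit_filter", "reciprocal_merge",
           "build_all_pairs", "group_hits_by_pair"]


@dataclass(frozen=True)
class FilterParams:
    """Stringency settings for candidate-edge selection.

    f: keep a hit if its bit score is >= f * (query's best bit score);
       f=1 keeps only ties with the best hit, f=0 disables the filter.
    evalue_max: classic E-value cutoff (default 1e-5).
    min_coverage: minimum alignment coverage required on both sequences.
    """

    f: float = 0.95
    evalue_max: float = 1e-5
    min_coverage: float = 0.5
    min_bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.f <= 1):
            raise ValueError(f"stringency f must be in [0, 1], got {self.f}")


@dataclass
class PairGraph:
    """Bipartite candidate graph between one pair of genomes.

    ``edges`` maps (gene_id_in_A, gene_id_in_B) -> symmetric weight
    (the mean of the two directed bit scores).
    """

    species_a: str
    species_b: str
    genome_a: Genome
    genome_b: Genome
    edges: Dict[Tuple[str, str], float] = field(default_factory=dict)

    @property
    def max_weight(self) -> float:
        return max(self.edges.values()) if self.edges else 0.0

    def normalized_edges(self) -> Dict[Tuple[str, str], float]:
        """Edge weights scaled into (0, 1] by the pair's maximum weight."""
        mw = self.max_weight
        if mw <= 0:
            return {e: 1.0 for e in self.edges}
        return {e: w / mw for e, w in self.edges.items()}


def _collapse_hsps(hits: Iterable[SimilarityHit]) -> Dict[Tuple[str, str], SimilarityHit]:
    """Keep, per (query, subject), the HSP with the highest bit score."""
    best: Dict[Tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or h.bitscore > prev.bitscore:
            best[key] = h
    return best


def best_hit_filter(
    hits: Iterable[SimilarityHit], params: FilterParams
) -> Dict[Tuple[str, str], float]:
    """Directed adaptive best-hit filter for one ordered genome pair.

    Returns (query, subject) -> bitscore for the hits kept.  The
    reference score s* for each query is its best bit score against the
    target genome (after HSP collapsing); a hit is kept iff
    bitscore >= f * s*, evalue <= evalue_max and both coverages pass.
    """
    collapsed = _collapse_hsps(hits)
    best_score: Dict[str, float] = {}
    for (q, _s), h in collapsed.items():
        if h.bitscore > best_score.get(q, 0.0):
            best_score[q] = h.bitscore
    kept: Dict[Tuple[str, str], float] = {}
    for (q, s), h in collapsed.items():
        if h.evalue > params.evalue_max:
            continue
        if h.query_coverage < params.min_coverage or h.subject_coverage < params.min_coverage:
            continue
        if h.bitscore < params.min_bitscore:
            continue
        if h.bitscore >= params.f * best_score[q]:
            kept[(q, s)] = h.bitscore
    return kept


def reciprocal_merge(
    forward: Mapping[Tuple[str, str], float],
    backward: Mapping[Tuple[str, str], float],
    genome_a: Genome,
    genome_b: Genome,
) -> PairGraph:
    """Keep reciprocally surviving pairs; weight = mean of the two scores."""
    pg = PairGraph(genome_a.species_id, genome_b.species_id, genome_a, genome_b)
    for (a, b), s_ab in forward.items():
        s_ba = backward.get((b, a))
        if s_ba is not None:
            pg.edges[(a, b)] = 0.5 * (s_ab + s_ba)
    return pg


def group_hits_by_pair(
    hits: Iterable[SimilarityHit], species_of: Mapping[str, str]
) -> Dict[Tuple[str, str], List[SimilarityHit]]:
    """Partition hits by ordered (query species, subject species) pair.

    Self-species hits are discarded: paralogy within a species is never
    an edge of the orthology graph.
    """
    by_pair: Dict[Tuple[str, str], List[SimilarityHit]] = {}
    for h in hits:
        sq = species_of.get(h.query_id)
        ss = species_of.get(h.subject_id)
        if sq is None or ss is None or sq == ss:
            continue
        by_pair.setdefault((sq, ss), []).append(h)
    return by_pair


def build_all_pairs(
    genomes: Mapping[str, Genome],
    hits: Iterable[SimilarityHit],
    params: Optional[FilterParams] = None,
) -> Dict[Tuple[str, str], PairGraph]:
    """One PairGraph per unordered species pair (A < B lexicographically).

    Each pair is computed independently from its own directed hit sets,
    so results do not depend on evaluation order.  Pairs with no hits
    yield empty graphs with a warning.
    """
    params = params or FilterParams()
    species_of = {g.gene_id: s for s, gnm in genomes.items() for g in gnm.genes()}
    by_pair = group_hits_by_pair(hits, species_of)

    out: Dict[Tuple[str, str], PairGraph] = {}
    for a, b in itertools.combinations(sorted(genomes), 2):
        fwd = best_hit_filter(by_pair.get((a, b), []), params)
        bwd = best_hit_filter(by_pair.get((b, a), []), params)
        pg = reciprocal_merge(fwd, bwd, genomes[a], genomes[b])
        if not by_pair.get((a, b)) and not by_pair.get((b, a)):
            logger.warning("no similarity hits between %s and %s", a, b)
        out[(a, b)] = pg
    return out
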