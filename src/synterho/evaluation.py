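"""Scoring predictions against a truth set at the pairwise level.

Orthology is evaluated over unordered cross-species gene pairs inside a
fixed universe (all cross-species pairs among genes the truth set
covers).  Group-level references are converted to pairwise relations by
assuming all cross-species members of a group orthologous — an estimate
that strictly overestimates the relation, and is flagged as such.  Two
dataset descriptors come along: a breakpoint-related distance between
matched gene orders and the subdivision of reference groups by the
prediction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .genome_io import Genome

logger = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "groups_to_pairs", "confusion", "metrics",
           "breakpoint_distance", "subdivision_stats"]

Pair = Tuple[str, str]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _norm(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def groups_to_pairs(
    groups: Iterable[Iterable[str]],
    gene_species: Mapping[str, str],
    warn_overestimate: bool = True,
) -> Set[Pair]:
    """All cross-species pairs within each group (same-species excluded).

    This strictly overestimates the orthology relation of a co-ortholog
    group, since paralogs from different duplication branches of one
    group are counted as orthologs too.
    """
    if warn_overestimate:
        logger.warning(
            "estimating pairwise orthology from groups strictly overestimates "
            "the relation"
        )
    pairs: Set[Pair] = set()
    for group in groups:
        members = sorted(group)
        for a, b in itertools.combinations(members, 2):
            if gene_species[a] != gene_species[b]:
                pairs.add(_norm(a, b))
    return pairs


def confusion(
    predicted: Iterable[Pair],
    truth: Iterable[Pair],
    universe_genes: Mapping[str, str],
) -> ConfusionCounts:
    """2x2 counts over all cross-species pairs among the covered genes.

    ``universe_genes`` maps gene id -> species for every gene of the
    truth set; predictions outside it are ignored so that genes unknown
    to the reference cannot bias the evaluation.
    """
    def restrict(pairs: Iterable[Pair]) -> Set[Pair]:
        out = set()
        for a, b in pairs:
            if a in universe_genes and b in universe_genes \
                    and universe_genes[a] != universe_genes[b]:
                out.add(_norm(a, b))
        return out

    pred = restrict(predicted)
    tru = restrict(truth)

    by_species: Dict[str, int] = {}
    for sp in universe_genes.values():
        by_species[sp] = by_species.get(sp, 0) + 1
    counts = list(by_species.values())
    n_universe = sum(ci * cj for ci, cj in itertools.combinations(counts, 2))

    tp = len(pred & tru)
    fp = len(pred - tru)
    fn = len(tru - pred)
    tn = n_universe - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts) -> Dict[str, Optional[float]]:
    """precision, recall, accuracy, tn_rate; undefined ratios are None."""
    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return {
        "precision": ratio(counts.tp, counts.tp + counts.fp),
        "recall": ratio(counts.tp, counts.tp + counts.fn),
        "accuracy": ratio(counts.tp + counts.tn, counts.total),
        "tn_rate": ratio(counts.tn, counts.tn + counts.fp),
    }


def _matched_projection(genome: Genome, matched: Set[str]) -> List[List[str]]:
    return [
        [g.gene_id for g in chrom if g.gene_id in matched]
        for chrom in genome.chromosomes.values()
    ]


def breakpoint_distance(
    genome_a: Genome,
    genome_b: Genome,
    matching: Iterable[Pair],
) -> int:
    """Adjacency-violation count between two matched gene orders.

    Restricted to one partner per gene (extra in-paralog edges must be
    removed upstream).  An adjacency of matched genes in one genome is a
    breakpoint when the two partners are not neighbors (in either
    direction) in the other genome's matched-only order; the reported
    distance is the larger of the two directional counts, so identical
    and exactly reversed orders both measure 0.
    """
    pairs = list(matching)
    a_to_b = dict(pairs)
    b_to_a = {b: a for a, b in pairs}
    if len(a_to_b) != len(pairs) or len(b_to_a) != len(pairs):
        raise ValueError("matching must be one-to-one")
    if len(pairs) < 2:
        return 0

    def neighbors(projection: List[List[str]]) -> Set[Pair]:
        adj: Set[Pair] = set()
        for chrom in projection:
            for x, y in zip(chrom, chrom[1:]):
                adj.add(_norm(x, y))
        return adj

    proj_a = _matched_projection(genome_a, set(a_to_b))
    proj_b = _matched_projection(genome_b, set(b_to_a))
    adj_b = neighbors(proj_b)
    adj_a = neighbors(proj_a)

    bp_a = sum(
        1
        for chrom in proj_a
        for x, y in zip(chrom, chrom[1:])
        if _norm(a_to_b[x], a_to_b[y]) not in adj_b
    )
    bp_b = sum(
        1
        for chrom in proj_b
        for x, y in zip(chrom, chrom[1:])
        if _norm(b_to_a[x], b_to_a[y]) not in adj_a
    )
    return max(bp_a, bp_b)


def subdivision_stats(
    reference_groups: Sequence[Iterable[str]],
    predicted_groups: Sequence[Iterable[str]],
) -> Tuple[List[int], Optional[float]]:
    """Per reference group: number of predicted groups intersecting it.

    Returns the per-group counts and their mean (None without groups).
    """
    pred_sets = [set(g) for g in predicted_groups]
    counts = []
    for ref in reference_groups:
        ref_set = set(ref)
        counts.append(sum(1 for p in pred_sets if p & ref_set))
    mean = sum(counts) / len(counts) if counts else None
    return counts, mean
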