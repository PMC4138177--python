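"""Shared fixtures: toy genomes, candidate graphs and small simulations."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from synterho.genome_io import Gene, Genome, SimilarityHit
from synterho.simgraph import PairGraph


def make_genome(species: str, chromosomes: dict[str, list[str]],
                seqs: dict[str, str] | None = None) -> Genome:
    """Genome from {chromosome: [gene ids in order]}."""
    genome = Genome(species_id=species)
    for chrom, ids in chromosomes.items():
        genome.chromosomes[chrom] = [
            Gene(gene_id=g, species_id=species, chromosome_id=chrom, rank=i,
                 strand="+", seq=(seqs or {}).get(g))
            for i, g in enumerate(ids)
        ]
    return genome


def make_pair_graph(genome_a: Genome, genome_b: Genome,
                    edges: dict[tuple[str, str], float]) -> PairGraph:
    return PairGraph(genome_a.species_id, genome_b.species_id,
                     genome_a, genome_b, dict(edges))


def reciprocal_hits(scores: dict[tuple[str, str], float],
                    evalue: float = 1e-30) -> list[SimilarityHit]:
    """Symmetric hit list (both directions share one score)."""
    hits = []
    for (a, b), s in scores.items():
        hits.append(SimilarityHit(a, b, s, evalue))
        hits.append(SimilarityHit(b, a, s, evalue))
    return hits


@pytest.fixture
def rng():
    return np.random.default_rng(20140819)


@pytest.fixture
def toy_duplication_graph():
    """Two species; genes 1 and 2 of one family duplicated before the
    split, embedded in six-gene contexts that disambiguate them.

    Anchor genes Ax'/Bx' are mutual unique best hits; the four focal
    genes A1, A2, B1, B2 are all cross-similar with equal scores.
    """
    order = ["{p}p1", "{p}1", "{p}p2", "{p}p3", "{p}2", "{p}p4"]
    genome_a = make_genome("A", {"chr1": [o.format(p="A") for o in order]})
    genome_b = make_genome("B", {"chr1": [o.format(p="B") for o in order]})
    scores = {(f"Ap{i}", f"Bp{i}"): 500.0 for i in range(1, 5)}
    for i, j in itertools.product((1, 2), (1, 2)):
        scores[(f"A{i}", f"B{j}")] = 100.0
    return genome_a, genome_b, scores


@pytest.fixture
def toy_duplication_pair_graph(toy_duplication_graph):
    genome_a, genome_b, scores = toy_duplication_graph
    return make_pair_graph(genome_a, genome_b, scores)
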