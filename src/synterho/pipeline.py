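"""End-to-end orchestration: similarity graph -> gene-order filter -> groups.

Genome pairs are independent, so the gene-order stage can run on a
process pool; results are collected in sorted pair order, making the
output bit-identical for any worker count.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import networkx as nx

from . import clustering, ffadj, simgraph
from .genome_io import Genome, SimilarityHit, write_groups, write_pairs

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "DataError"]


class DataError(ValueError):
    """Inconsistent or missing data at pipeline level."""


@dataclass
class PipelineResult:
    groups: List[clustering.OrthoGroup]
    graph: nx.Graph
    pair_graphs: Dict[Tuple[str, str], simgraph.PairGraph]
    matchings: Optional[Dict[Tuple[str, str], ffadj.Matching]]
    gene_species: Dict[str, str]
    pair_log: List[dict] = field(default_factory=list)

    def pairwise_edges(self) -> List[Tuple[str, str, float]]:
        """Final pairwise orthology relation with raw (bit score) weights."""
        return [(a, b, d.get("raw_weight", d.get("weight", 1.0)))
                for a, b, d in self.graph.edges(data=True)]

    def write(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        species = sorted({s for s in self.gene_species.values()})
        write_groups(self.groups, species, os.path.join(out_dir, "groups.tsv"),
                     gene_species=self.gene_species)
        write_pairs(self.pairwise_edges(), self.gene_species,
                    os.path.join(out_dir, "pairs.tsv"))


def _ffadj_worker(args) -> Tuple[Tuple[str, str], ffadj.Matching]:
    key, pair_graph, params = args
    matching = ffadj.run_ffadj(pair_graph, params)
    matching = ffadj.relax_in_paralogs(pair_graph, matching)
    return key, matching


def run_pipeline(
    genomes: Mapping[str, Genome],
    hits: Iterable[SimilarityHit],
    filter_params: Optional[simgraph.FilterParams] = None,
    ffadj_params: Optional[ffadj.FFAdjParams] = None,
    synteny: bool = True,
    conn_threshold: float = 0.1,
    conn_normalize: bool = True,
    n_workers: int = 1,
    strict_hits: bool = False,
) -> PipelineResult:
    """Run the full orthology-detection workflow in memory.

    With ``synteny=False`` the gene-order filter is skipped and the
    reciprocal-best-hit candidate edges go to clustering directly
    (pure similarity mode).
    """
    filter_params = filter_params or simgraph.FilterParams()
    ffadj_params = ffadj_params or ffadj.FFAdjParams()
    hits = list(hits)
    gene_species = {g.gene_id: s for s, gnm in genomes.items() for g in gnm.genes()}

    pair_graphs = simgraph.build_all_pairs(genomes, hits, filter_params)
    if strict_hits:
        species_of = gene_species
        covered = {tuple(sorted((species_of[h.query_id], species_of[h.subject_id])))
                   for h in hits
                   if h.query_id in species_of and h.subject_id in species_of
                   and species_of[h.query_id] != species_of[h.subject_id]}
        missing = [k for k in pair_graphs if k not in covered]
        if missing:
            raise DataError(
                "no similarity hits for genome pair(s): "
                + ", ".join(f"{a}/{b}" for a, b in sorted(missing))
            )

    pair_log: List[dict] = []
    matchings: Optional[Dict[Tuple[str, str], ffadj.Matching]] = None
    pair_edges: Dict[Tuple[str, str], list] = {}

    if synteny:
        keys = sorted(pair_graphs)
        jobs = [(k, pair_graphs[k], ffadj_params) for k in keys]
        if n_workers > 1:
            with ProcessPoolExecutor(max_workers=n_workers) as pool:
                results = dict(pool.map(_ffadj_worker, jobs))
        else:
            results = dict(map(_ffadj_worker, jobs))
        matchings = {k: results[k] for k in keys}
        for k in keys:
            pair_edges[k] = matchings[k].edges
            pair_log.append({
                "pair": k,
                "candidate_edges": len(pair_graphs[k].edges),
                "kept_edges": len(matchings[k].edges),
            })
            logger.info("%s/%s: %d candidate -> %d synteny-filtered edges",
                        k[0], k[1], len(pair_graphs[k].edges), len(matchings[k].edges))
    else:
        for k in sorted(pair_graphs):
            norm = pair_graphs[k].normalized_edges()
            pair_edges[k] = [(a, b, norm[(a, b)]) for a, b in sorted(pair_graphs[k].edges)]
            pair_log.append({
                "pair": k,
                "candidate_edges": len(pair_graphs[k].edges),
                "kept_edges": len(pair_graphs[k].edges),
            })

    graph = clustering.merge(pair_edges, gene_species)
    # carry raw weights for reporting in similarity-only mode too
    if not synteny:
        for k, pg in pair_graphs.items():
            for (a, b), w in pg.edges.items():
                if graph.has_edge(a, b):
                    graph[a][b]["raw_weight"] = w
    groups = clustering.split_components(graph, conn_threshold=conn_threshold,
                                         normalize=conn_normalize)
    return PipelineResult(groups, graph, pair_graphs, matchings, gene_species, pair_log)
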