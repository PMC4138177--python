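"""Simulate -> predict -> score, with and without the gene-order filter.

This reproduces the comparison protocol used on simulated data: one
dataset with known gene trees, the pipeline run once in pure similarity
mode and once with the synteny filter, and both predictions scored
against the true pairwise orthology relation.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

from . import evaluation, simulator
from .align import all_vs_all_hits
from .ffadj import FFAdjParams
from .genome_io import SimilarityHit, read_hits
from .pipeline import PipelineResult, run_pipeline
from .simgraph import FilterParams

__all__ = ["hits_from_rows", "evaluate_result", "run_benchmark"]


def hits_from_rows(rows: Iterable[tuple],
                   seq_lengths: Optional[Dict[str, int]] = None) -> List[SimilarityHit]:
    """Convert 12-column tabular rows to SimilarityHit objects.

    Coverage is alignment length (column 4) over sequence length when
    lengths are supplied, else 1.
    """
    hits = []
    for r in rows:
        qid, sid = str(r[0]), str(r[1])
        aln_len = int(r[3])
        evalue, bit = float(r[10]), float(r[11])
        qcov = scov = 1.0
        if seq_lengths:
            if seq_lengths.get(qid):
                qcov = min(1.0, aln_len / seq_lengths[qid])
            if seq_lengths.get(sid):
                scov = min(1.0, aln_len / seq_lengths[sid])
        hits.append(SimilarityHit(qid, sid, bit, evalue, qcov, scov))
    return hits


def evaluate_result(
    result: PipelineResult,
    dataset: simulator.SimulatedDataset,
) -> Dict[str, object]:
    """Score one pipeline run against the simulated truth.

    Returns confusion counts, the four standard ratios, the mean
    breakpoint-related distance over genome pairs (synteny runs only)
    and the mean subdivision of true families by the predicted groups.
    """
    predicted = [(a, b) for a, b, _ in result.pairwise_edges()]
    counts = evaluation.confusion(predicted, dataset.truth_pairs, dataset.gene_species)
    out: Dict[str, object] = {
        "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
    }
    out.update(evaluation.metrics(counts))

    if result.matchings is not None:
        dists = []
        for (a, b), matching in sorted(result.matchings.items()):
            strict = matching.pairs(include_relaxed=False)
            # one partner per gene: drop later duplicates from extra rounds
            seen_a: set = set()
            seen_b: set = set()
            one_to_one = []
            for x, y in strict:
                if x in seen_a or y in seen_b:
                    continue
                one_to_one.append((x, y))
                seen_a.add(x)
                seen_b.add(y)
            dists.append(evaluation.breakpoint_distance(
                result.pair_graphs[(a, b)].genome_a,
                result.pair_graphs[(a, b)].genome_b,
                one_to_one,
            ))
        out["mean_breakpoint_distance"] = sum(dists) / len(dists) if dists else None
    else:
        out["mean_breakpoint_distance"] = None

    refs = [g for g in dataset.families_as_groups() if len(g) >= 2]
    pred_groups = [g.genes for g in result.groups]
    _, mean_sub = evaluation.subdivision_stats(refs, pred_groups)
    out["mean_subdivision"] = mean_sub
    out["n_groups"] = len(result.groups)
    out["n_pairwise"] = len(predicted)
    return out


def run_benchmark(
    params: simulator.SimParams,
    filter_params: Optional[FilterParams] = None,
    ffadj_params: Optional[FFAdjParams] = None,
    conn_threshold: float = 0.1,
    dataset: Optional[simulator.SimulatedDataset] = None,
) -> Dict[str, Dict[str, object]]:
    """Both pipeline modes on one simulated dataset.

    Returns {"similarity": metrics, "synteny": metrics, "dataset": descriptors}.
    """
    if dataset is None:
        dataset = simulator.simulate(params)
    rows = all_vs_all_hits(dataset.genomes)
    seq_lengths = {g.gene_id: len(g.seq or "") for gnm in dataset.genomes.values()
                   for g in gnm.genes()}
    hits = hits_from_rows(rows, seq_lengths)

    report: Dict[str, Dict[str, object]] = {}
    for mode, use_synteny in (("similarity", False), ("synteny", True)):
        result = run_pipeline(dataset.genomes, hits,
                              filter_params=filter_params,
                              ffadj_params=ffadj_params,
                              synteny=use_synteny,
                              conn_threshold=conn_threshold)
        report[mode] = evaluate_result(result, dataset)
    report["dataset"] = {
        "n_species": params.n_species,
        "n_families": params.n_families,
        "n_genes": sum(g.n_genes() for g in dataset.genomes.values()),
        "n_truth_pairs": len(dataset.truth_pairs),
    }
    return report
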