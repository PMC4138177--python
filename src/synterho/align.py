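"""Internal all-vs-all protein similarity search.

Smith-Waterman local alignment (BLOSUM62, gap open 11 / extend 1) over
every cross-species sequence pair, emitting rows in the 12-column BLAST
tabular dialect so the pipeline runs without an external aligner.  The
score column holds a bit-like score (raw score / 2); E-values follow
Karlin-Altschul statistics with the published gapped BLOSUM62(11,1)
constants.  Alignment coordinates (and hence coverages) are computed by
traceback only for pairs passing a loose E-value pre-threshold; the
remaining pairs are score-only and never reported.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Genome, write_hits

__all__ = ["all_vs_all_hits", "write_hit_table", "karlin_altschul_evalue"]

# gapped BLOSUM62 with open 11 / extend 1 (BLAST's defaults)
_LAMBDA = 0.267
_K = 0.041


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def karlin_altschul_evalue(raw_score: float, m: int, n: int) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    return _K * m * n * math.exp(-_LAMBDA * raw_score)


def all_vs_all_hits(
    genomes: Mapping[str, Genome],
    evalue_report: float = 1e-3,
) -> List[Tuple]:
    """12-column rows for every cross-species pair below ``evalue_report``.

    Both directions of each pair are emitted (with identical raw scores,
    as Smith-Waterman is symmetric); downstream reciprocal filtering
    still applies its own stringency per direction.
    """
    al = _aligner()
    seqs: List[Tuple[str, str, str]] = []       # (species, gene_id, seq)
    for sp in sorted(genomes):
        for g in genomes[sp].genes():
            if g.seq:
                seqs.append((sp, g.gene_id, g.seq))

    rows: List[Tuple] = []
    for (sp1, id1, s1), (sp2, id2, s2) in itertools.combinations(seqs, 2):
        if sp1 == sp2:
            continue
        raw = al.score(s1, s2)
        if raw <= 0:
            continue
        evalue = karlin_altschul_evalue(raw, len(s1), len(s2))
        if evalue > evalue_report:
            continue
        aln = al.align(s1, s2)[0]
        blocks_q, blocks_s = aln.aligned
        qstart, qend = int(blocks_q[0][0]) + 1, int(blocks_q[-1][1])
        sstart, send = int(blocks_s[0][0]) + 1, int(blocks_s[-1][1])
        aligned_pairs = sum(int(b[1] - b[0]) for b in blocks_q)
        matches = sum(
            1
            for (q0, q1), (t0, t1) in zip(blocks_q, blocks_s)
            for a, b in zip(s1[q0:q1], s2[t0:t1])
            if a == b
        )
        mismatches = aligned_pairs - matches
        gapopens = len(blocks_q) - 1
        # column 4 is the alignment length including gaps
        aln_len = max(qend - qstart, send - sstart) + 1
        pid = 100.0 * matches / aligned_pairs if aligned_pairs else 0.0
        bitlike = raw / 2.0
        for (qid, qs, qe, sid, ss, se) in (
            (id1, qstart, qend, id2, sstart, send),
            (id2, sstart, send, id1, qstart, qend),
        ):
            rows.append((qid, sid, f"{pid:.2f}", aln_len, mismatches, gapopens,
                         qs, qe, ss, se, f"{evalue:.3g}", f"{bitlike:.1f}"))
    rows.sort(key=lambda r: (r[0], r[1]))
    return rows


def write_hit_table(rows: Iterable[Sequence], path) -> None:
    write_hits(rows, path)
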