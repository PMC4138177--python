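"""Reading and writing the pipeline's on-disk formats.

Proteomes come in as protein FASTA, gene coordinates as GFF3, and
precomputed all-vs-all similarity searches as 12-column BLAST tabular
(``-outfmt 6``) files.  Outputs are plain TSV: an orthologous-group table
(one row per group, one column per species, Proteinortho-style) and a
pairwise orthology edge list.

Coordinates follow the GFF3 convention (1-based, inclusive) on disk;
internally every gene carries a 0-based *rank*, its position among the
genes of its chromosome ordered by start coordinate.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "Genome",
    "SimilarityHit",
    "read_proteome",
    "read_gene_order",
    "read_hits",
    "write_hits",
    "write_fasta",
    "write_gff3",
    "write_groups",
    "write_pairs",
    "GenomeIOError",
]


class GenomeIOError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass(frozen=True)
class Gene:
    """A located sequence feature; no functional meaning implied.

    ``rank`` is the 0-based position among genes on the same chromosome
    (ordered by start coordinate); it is ``None`` for genes that have a
    sequence but no coordinates, which take part in similarity filtering
    but are invisible to the gene-order model.
    """

    gene_id: str
    species_id: str
    chromosome_id: Optional[str] = None
    rank: Optional[int] = None
    strand: str = "?"
    seq: Optional[str] = None

    @property
    def placed(self) -> bool:
        return self.chromosome_id is not None and self.rank is not None


@dataclass
class Genome:
    """All genes of one species, ordered along (possibly several) chromosomes."""

    species_id: str
    chromosomes: Dict[str, List[Gene]] = field(default_factory=dict)
    unplaced: List[Gene] = field(default_factory=list)

    def genes(self) -> Iterator[Gene]:
        for chrom in self.chromosomes.values():
            yield from chrom
        yield from self.unplaced

    def gene_map(self) -> Dict[str, Gene]:
        return {g.gene_id: g for g in self.genes()}

    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes.values()) + len(self.unplaced)

    def validate(self) -> None:
        seen: set[str] = set()
        for chrom_id, chrom in self.chromosomes.items():
            for i, g in enumerate(chrom):
                if g.rank != i:
                    raise GenomeIOError(
                        f"{self.species_id}/{chrom_id}: gene {g.gene_id} has rank "
                        f"{g.rank}, expected {i}"
                    )
                if g.gene_id in seen:
                    raise GenomeIOError(f"duplicate gene id {g.gene_id!r}")
                seen.add(g.gene_id)
        for g in self.unplaced:
            if g.gene_id in seen:
                raise GenomeIOError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)


@dataclass(frozen=True)
class SimilarityHit:
    """One directed similarity search hit (best HSP of a query/subject pair)."""

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    query_coverage: float = 1.0
    subject_coverage: float = 1.0


def read_proteome(fasta_path: str | os.PathLike, species_id: str) -> List[Gene]:
    """Read a protein FASTA into sequence-only (unplaced) genes.

    Record ids must be unique; sequences are uppercased, non-standard
    residues are preserved verbatim.
    """
    genes: List[Gene] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise GenomeIOError(f"{fasta_path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        genes.append(Gene(gene_id=rec.id, species_id=species_id, seq=str(rec.seq).upper()))
    if not genes:
        raise GenomeIOError(f"{fasta_path}: no FASTA records")
    return genes


def read_gene_order(
    gff3_path: str | os.PathLike,
    genes: Sequence[Gene],
    feature_type: str = "CDS",
    id_attribute: str = "ID",
) -> Genome:
    """Place genes on chromosomes from a GFF3 file and assign ranks.

    Features of ``feature_type`` whose ``id_attribute`` matches a gene id
    define that gene's location.  Genes without a matching feature stay
    unplaced (similarity-only mode); a gene matched on two chromosomes is
    an error.  Ties in start coordinate break by (end, gene id).
    """
    if not genes:
        raise GenomeIOError("no genes supplied")
    species_id = genes[0].species_id
    by_id = {g.gene_id: g for g in genes}

    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    # gene_id -> (chrom, start, end, strand)
    loc: Dict[str, Tuple[str, int, int, str]] = {}
    for feat in db.features_of_type(feature_type):
        for fid in feat.attributes.get(id_attribute, []):
            if fid not in by_id:
                continue
            if fid in loc:
                prev = loc[fid]
                if prev[0] != feat.seqid:
                    raise GenomeIOError(
                        f"{gff3_path}: gene {fid!r} mapped to chromosomes "
                        f"{prev[0]!r} and {feat.seqid!r}"
                    )
                # same chromosome twice (e.g. multi-part CDS): extend the span
                loc[fid] = (prev[0], min(prev[1], feat.start), max(prev[2], feat.end), prev[3])
            else:
                loc[fid] = (feat.seqid, feat.start, feat.end, feat.strand or "?")

    if not loc:
        raise GenomeIOError(f"{gff3_path}: zero genes could be placed")

    placed: Dict[str, List[Tuple[int, int, str, Gene]]] = {}
    unplaced: List[Gene] = []
    for g in genes:
        if g.gene_id in loc:
            chrom, start, end, strand = loc[g.gene_id]
            placed.setdefault(chrom, []).append((start, end, g.gene_id, replace(g, strand=strand)))
        else:
            unplaced.append(g)
    if unplaced:
        logger.warning(
            "%s: %d gene(s) absent from %s; excluded from synteny",
            species_id, len(unplaced), gff3_path,
        )

    genome = Genome(species_id=species_id, unplaced=unplaced)
    for chrom in sorted(placed):
        entries = sorted(placed[chrom], key=lambda t: (t[0], t[1], t[2]))
        genome.chromosomes[chrom] = [
            replace(g, chromosome_id=chrom, rank=i)
            for i, (_, _, _, g) in enumerate(entries)
        ]
    genome.validate()
    return genome


def read_hits(
    table_path: str | os.PathLike,
    species_of: Mapping[str, str],
    seq_lengths: Optional[Mapping[str, int]] = None,
) -> Tuple[List[SimilarityHit], int]:
    """Parse a 12-column BLAST tabular file.

    ``species_of`` maps gene id -> species id and defines the known-id
    universe; rows referencing unknown ids are dropped and counted.
    Coverages are alignment length over sequence length when lengths are
    known, else 1.  Returns ``(hits, n_dropped)``.
    """
    hits: List[SimilarityHit] = []
    dropped = 0
    with open(table_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise GenomeIOError(
                    f"{table_path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            try:
                aln_len = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise GenomeIOError(f"{table_path}:{lineno}: {exc}") from None
            if q not in species_of or s not in species_of:
                dropped += 1
                continue
            qcov = scov = 1.0
            if seq_lengths is not None:
                if q in seq_lengths and seq_lengths[q] > 0:
                    qcov = min(1.0, aln_len / seq_lengths[q])
                if s in seq_lengths and seq_lengths[s] > 0:
                    scov = min(1.0, aln_len / seq_lengths[s])
            hits.append(SimilarityHit(q, s, bitscore, evalue, qcov, scov))
    if dropped:
        logger.warning("%s: dropped %d hit(s) with unknown gene ids", table_path, dropped)
    return hits, dropped


def write_hits(rows: Iterable[Sequence], path: str | os.PathLike) -> None:
    """Write 12-column BLAST-tabular rows (any sequence of 12 fields)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_fasta(genes: Iterable[Gene], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            if g.seq is None:
                raise GenomeIOError(f"gene {g.gene_id!r} has no sequence")
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.seq), 60):
                fh.write(g.seq[i : i + 60] + "\n")


def write_gff3(
    genome: Genome,
    path: str | os.PathLike,
    feature_type: str = "CDS",
    codon_width: int = 3,
    spacing: int = 100,
) -> None:
    """Write gene coordinates as GFF3, preserving each chromosome's order.

    Synthetic coordinates: gene i starts right after gene i-1 plus
    ``spacing`` bp; length is ``codon_width * len(seq)`` (or 300 when no
    sequence is attached).  Only order matters downstream.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom_id, chrom in genome.chromosomes.items():
            pos = 1
            for g in chrom:
                length = codon_width * len(g.seq) if g.seq else 300
                start, end = pos, pos + length - 1
                strand = g.strand if g.strand in "+-" else "+"
                fh.write(
                    f"{chrom_id}\tsynterho\t{feature_type}\t{start}\t{end}\t.\t"
                    f"{strand}\t0\tID={g.gene_id}\n"
                )
                pos = end + 1 + spacing


def write_groups(
    groups: Sequence,
    species_ids: Sequence[str],
    path: str | os.PathLike,
    gene_species: Optional[Mapping[str, str]] = None,
) -> None:
    """Write the orthologous-group table.

    ``groups`` are objects with ``genes`` (iterable of gene ids) and
    ``connectivity`` attributes, or plain iterables of gene ids (then
    ``gene_species`` must map gene id -> species).  Rows are ordered by
    group size descending, then by lexicographically smallest member.
    """
    species_ids = sorted(species_ids)

    def unpack(grp):
        if hasattr(grp, "genes"):
            gene_ids = sorted(grp.genes)
            conn = getattr(grp, "connectivity", None)
            sp = getattr(grp, "gene_species", None) or gene_species
        else:
            gene_ids = sorted(grp)
            conn, sp = None, gene_species
        if sp is None:
            raise GenomeIOError("write_groups needs a gene -> species mapping")
        return gene_ids, conn, sp

    rows = []
    for grp in groups:
        gene_ids, conn, sp = unpack(grp)
        per_species: Dict[str, List[str]] = {s: [] for s in species_ids}
        for gid in gene_ids:
            per_species[sp[gid]].append(gid)
        n_species = sum(1 for s in species_ids if per_species[s])
        cells = [",".join(per_species[s]) if per_species[s] else "*" for s in species_ids]
        conn_str = f"{conn:.3f}" if conn is not None else "."
        rows.append((len(gene_ids), gene_ids[0], [str(n_species), str(len(gene_ids)), conn_str] + cells))

    rows.sort(key=lambda r: (-r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("# Species\tGenes\tAlg.-Conn.\t" + "\t".join(species_ids) + "\n")
        for _, _, cells in rows:
            fh.write("\t".join(cells) + "\n")


def read_groups(path: str | os.PathLike) -> Tuple[List[List[str]], Dict[str, str]]:
    """Read a group table back: (groups as gene-id lists, gene -> species)."""
    groups: List[List[str]] = []
    gene_species: Dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise GenomeIOError(f"{path}: missing group-table header")
        species = header.lstrip("# ").split("\t")[3:]
        for lineno, line in enumerate(fh, 2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3 + len(species):
                raise GenomeIOError(f"{path}:{lineno}: wrong column count")
            members: List[str] = []
            for sp, cell in zip(species, cells[3:]):
                if cell == "*":
                    continue
                for gid in cell.split(","):
                    members.append(gid)
                    gene_species[gid] = sp
            groups.append(members)
    return groups, gene_species


def read_pairs(path: str | os.PathLike) -> Tuple[List[Tuple[str, str, float]], Dict[str, str]]:
    """Read a pairwise edge list back: (edges, gene -> species)."""
    edges: List[Tuple[str, str, float]] = []
    gene_species: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 4:
                raise GenomeIOError(f"{path}:{lineno}: expected >= 4 columns")
            sa, a, sb, b = cells[:4]
            w = float(cells[4]) if len(cells) > 4 else 1.0
            gene_species[a] = sa
            gene_species[b] = sb
            edges.append((a, b, w))
    return edges, gene_species


def write_pairs(
    edges: Iterable[Tuple[str, str, float]],
    gene_species: Mapping[str, str],
    path: str | os.PathLike,
) -> None:
    """Write the pairwise orthology edge list: speciesA geneA speciesB geneB weight."""
    rows = []
    for a, b, w in edges:
        sa, sb = gene_species[a], gene_species[b]
        if (sa, a) > (sb, b):
            sa, a, sb, b = sb, b, sa, a
        rows.append((sa, a, sb, b, w))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("# SpeciesA\tGeneA\tSpeciesB\tGeneB\tWeight\n")
        for sa, a, sb, b, w in rows:
            fh.write(f"{sa}\t{a}\t{sb}\t{b}\t{w:.6g}\n")
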