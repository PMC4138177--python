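"""Benchmark data generator with known orthology truth.

Species trees grow under the Age Model (the lineage chosen to speciate
is picked with probability proportional to its age) and are rescaled to
unit root-to-leaf depth.  Along every species-tree edge, each gene
family is subject to Poisson-sampled gene duplications, cluster
duplications, whole-genome duplications and gene losses; a duplicate
created on an edge is purged again with probability 0.3 before the next
speciation, mimicking the loss of redundant copies that never diverge.
Gene order evolves by inversions and translocations whose count is
Poisson in the branch length.  Amino-acid sequences evolve with
PAM-biased substitutions (expected substituted fraction =
branch_scale * branch length, i.e. about half the residues on a
root-to-leaf path at the default scale 0.5) and Zipfian-length indels.

The byproduct of the simulation is an event-labeled gene tree per
family, which defines the true orthology relation: two genes are
orthologs iff their most recent common ancestor is a speciation.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .genome_io import Gene, Genome, write_fasta, write_gff3

logger = logging.getLogger(__name__)

__all__ = ["SimParams", "PRESETS", "TreeNode", "GeneNode", "SimulatedDataset",
           "simulate_species_tree", "evolve_gene_content", "rearrange",
           "evolve_sequences", "true_orthology", "simulate", "zipf_truncated"]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# classic Dayhoff amino-acid background frequencies (order as AMINO_ACIDS)
_DAYHOFF_FREQS = np.array([
    0.087, 0.041, 0.040, 0.047, 0.033, 0.038, 0.050, 0.089, 0.034, 0.037,
    0.085, 0.081, 0.015, 0.040, 0.051, 0.070, 0.058, 0.010, 0.030, 0.065,
])
_DAYHOFF_FREQS = _DAYHOFF_FREQS / _DAYHOFF_FREQS.sum()


@dataclass(frozen=True)
class SimParams:
    """Simulation settings; rates are events per unit branch length."""

    n_species: int = 20
    n_families: int = 50
    r_dup: float = 0.3
    r_clusterdup: float = 0.05
    r_genomedup: float = 0.0
    r_loss: float = 0.3
    r_rearr: float = 2.0
    p_redundant_loss: float = 0.3
    seed: int = 0
    seq_len_range: Tuple[int, int] = (100, 1000)
    branch_scale: float = 0.5
    indel_rate: float = 0.01          # indel events per site per unit branch length
    zipf_exponent: float = 1.7
    indel_max_frac_range: Tuple[float, float] = (0.01, 0.10)
    cluster_mean_len: float = 4.0     # geometric mean window of cluster duplications
    rearr_mean_len: float = 3.0       # geometric mean segment of inversions/translocations
    p_inversion: float = 0.5
    n_chromosomes: int = 1

    def __post_init__(self) -> None:
        for name in ("r_dup", "r_clusterdup", "r_genomedup", "r_loss", "r_rearr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.p_redundant_loss <= 1.0):
            raise ValueError("p_redundant_loss must be in [0, 1]")


PRESETS: Dict[str, Dict] = {
    # regimes mirroring the three benchmark datasets: individual gene and
    # cluster duplications everywhere; whole-genome duplications only in
    # the "d" variant
    "F50-like": {"n_families": 50},
    "F80d-like": {"n_families": 80, "r_genomedup": 0.02},
    "F100-like": {"n_families": 100},
}


class TreeNode:
    """Minimal rooted tree node for species trees."""

    __slots__ = ("name", "children", "length", "depth")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.children: List["TreeNode"] = []
        self.length = length        # edge length above this node
        self.depth = 0.0            # normalized distance from the root

    def leaves(self) -> List["TreeNode"]:
        if not self.children:
            return [self]
        out: List[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def total_length(self) -> float:
        return self.length + sum(c.total_length() for c in self.children)

    def newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            if not n.children:
                return f"{n.name}:{n.length:.6f}"
            inner = ",".join(fmt(c) for c in n.children)
            return f"({inner}){n.name}:{n.length:.6f}"
        return fmt(self) + ";"


def simulate_species_tree(n: int, rng: np.random.Generator) -> TreeNode:
    """Grow an Age-Model tree to ``n`` leaves, normalized to unit depth.

    At discrete step t the leaf to speciate is drawn with probability
    proportional to its age (steps since its creation); speciation times
    are then mapped linearly so every root-to-leaf path has length 1.
    """
    if n < 2:
        raise ValueError("need at least 2 species")
    root = TreeNode()
    birth = {id(root): 0}
    leaves = [root]
    split_step: Dict[int, int] = {}
    for t in range(1, n):
        ages = np.array([t - birth[id(x)] for x in leaves], dtype=float)
        probs = ages / ages.sum()
        chosen = leaves[int(rng.choice(len(leaves), p=probs))]
        split_step[id(chosen)] = t
        kids = [TreeNode(), TreeNode()]
        for k in kids:
            birth[id(k)] = t
        chosen.children = kids
        leaves.remove(chosen)
        leaves.extend(kids)

    # speciation steps 1..n-1; leaves terminate at step n; rescale so the
    # root (step 1) to leaf (step n) distance is 1
    span = float(n - 1)

    def assign(node: TreeNode, parent_depth: float) -> None:
        if node.children:
            node.depth = (split_step[id(node)] - 1) / span
        else:
            node.depth = 1.0
        node.length = node.depth - parent_depth
        for c in node.children:
            assign(c, node.depth)

    assign(root, 0.0)
    for i, leaf in enumerate(root.leaves()):
        leaf.name = f"S{i + 1:02d}"
    return root


class GeneNode:
    """Gene-tree node; built incrementally while traversing the species tree."""

    __slots__ = ("family", "label", "children", "depth", "species", "gene_id", "seq")

    def __init__(self, family: int, depth: float):
        self.family = family
        self.label = "tip"          # tip|speciation|duplication|loss|leaf
        self.children: List["GeneNode"] = []
        self.depth = depth
        self.species: Optional[str] = None
        self.gene_id: Optional[str] = None
        self.seq: Optional[str] = None

    def leaves(self) -> List["GeneNode"]:
        if self.label == "leaf":
            return [self]
        out: List[GeneNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def rearrange(order: List, length: float, params: SimParams,
              rng: np.random.Generator,
              log: Optional[List] = None, where: str = "") -> List:
    """Shuffle gene order by Poisson(r_rearr * length) inversions and
    translocations with geometric segment lengths; the multiset of genes
    is unchanged."""
    order = list(order)
    n = len(order)
    if n < 2 or length <= 0 or params.r_rearr <= 0:
        return order
    k = rng.poisson(params.r_rearr * length)
    for _ in range(k):
        seg = min(int(rng.geometric(1.0 / params.rearr_mean_len)), n - 1)
        start = int(rng.integers(0, n - seg + 1))
        if rng.random() < params.p_inversion:
            order[start:start + seg] = order[start:start + seg][::-1]
            op = "inversion"
        else:
            segment = order[start:start + seg]
            del order[start:start + seg]
            dest = int(rng.integers(0, len(order) + 1))
            order[dest:dest] = segment
            op = "translocation"
        if log is not None:
            log.append({"edge": where, "type": op, "start": start, "len": seg})
    return order


def _geom_window(params: SimParams, rng: np.random.Generator, n: int) -> int:
    return min(int(rng.geometric(1.0 / params.cluster_mean_len)), n)


def evolve_gene_content(
    species_tree: TreeNode, params: SimParams, rng: np.random.Generator
) -> Tuple[Dict[str, List[GeneNode]], List[GeneNode], List[dict]]:
    """Evolve ordered gene content along the species tree.

    Returns (per-species ordered extant gene lists, pruned family gene
    trees, event log).  Families extinct everywhere are dropped with a
    warning.
    """
    roots = [GeneNode(i, 0.0) for i in range(params.n_families)]
    genomes: Dict[str, List[GeneNode]] = {}
    log: List[dict] = []

    def apply_edge(genes: List[GeneNode], t0: float, t1: float, where: str) -> List[GeneNode]:
        l = t1 - t0
        genes = list(genes)
        recent: Set[int] = set()
        if l > 0:
            counts = {
                "duplication": rng.poisson(params.r_dup * l),
                "cluster_duplication": rng.poisson(params.r_clusterdup * l),
                "genome_duplication": rng.poisson(params.r_genomedup * l),
                "loss": rng.poisson(params.r_loss * l),
            }
            events = [(float(rng.uniform(t0, t1)), etype)
                      for etype, c in counts.items() for _ in range(c)]
            events.sort(key=lambda e: e[0])
            for t, etype in events:
                if not genes:
                    break
                if etype == "duplication":
                    i = int(rng.integers(len(genes)))
                    genes[i:i + 1] = _duplicate(genes[i], t, recent)
                elif etype == "cluster_duplication":
                    w = _geom_window(params, rng, len(genes))
                    u = int(rng.integers(0, len(genes) - w + 1))
                    genes[u:u + w] = _duplicate_block(genes[u:u + w], t, recent)
                elif etype == "genome_duplication":
                    genes = _duplicate_genome(genes, t, recent)
                else:  # loss
                    i = int(rng.integers(len(genes)))
                    genes[i].label = "loss"
                    del genes[i]
                log.append({"edge": where, "time": round(t, 6), "type": etype,
                            "n_genes": len(genes)})
        # purge redundant recent duplicates before the next speciation
        survivors: List[GeneNode] = []
        for g in genes:
            if id(g) in recent and rng.random() < params.p_redundant_loss:
                g.label = "loss"
                log.append({"edge": where, "time": round(t1, 6),
                            "type": "redundant_loss", "n_genes": len(genes)})
            else:
                survivors.append(g)
        return rearrange(survivors, l, params, rng, log, where)

    def _duplicate(g: GeneNode, t: float, recent: Set[int]) -> List[GeneNode]:
        g.label = "duplication"
        g.depth = t
        kids = [GeneNode(g.family, t), GeneNode(g.family, t)]
        g.children = kids
        if id(g) in recent:            # a copy of a recent copy stays recent
            recent.add(id(kids[0]))
        recent.add(id(kids[1]))        # tandem copy, purge candidate
        return kids

    def _duplicate_block(block: List[GeneNode], t: float, recent: Set[int]) -> List[GeneNode]:
        originals: List[GeneNode] = []
        copies: List[GeneNode] = []
        for g in block:
            g.label = "duplication"
            g.depth = t
            kids = [GeneNode(g.family, t), GeneNode(g.family, t)]
            g.children = kids
            if id(g) in recent:
                recent.add(id(kids[0]))
            originals.append(kids[0])
            copies.append(kids[1])
            recent.add(id(kids[1]))
        return originals + copies

    def _duplicate_genome(genes: List[GeneNode], t: float, recent: Set[int]) -> List[GeneNode]:
        return _duplicate_block(genes, t, recent)

    counters: Dict[str, int] = {}

    def walk(node: TreeNode, genes: List[GeneNode], parent_depth: float) -> None:
        genes = apply_edge(genes, parent_depth, node.depth, node.name or "internal")
        if not node.children:
            ordered: List[GeneNode] = []
            for g in genes:
                g.label = "leaf"
                g.species = node.name
                idx = counters.get(node.name, 0)
                counters[node.name] = idx + 1
                g.gene_id = f"{node.name}_{idx:04d}"
                ordered.append(g)
            genomes[node.name] = ordered
            return
        for g in genes:
            g.label = "speciation"
            g.depth = node.depth
            g.children = [GeneNode(g.family, node.depth) for _ in node.children]
        for k, child in enumerate(node.children):
            walk(child, [g.children[k] for g in genes], node.depth)

    walk(species_tree, roots, 0.0)

    pruned: List[GeneNode] = []
    for r in roots:
        p = _prune(r)
        if p is None:
            logger.warning("family %d extinct in all species; dropped", r.family)
            continue
        pruned.append(p)
    return genomes, pruned, log


def _prune(node: GeneNode) -> Optional[GeneNode]:
    """Drop extinct lineages and suppress unary internal nodes."""
    if node.label == "leaf":
        return node
    if node.label in ("loss", "tip"):
        return None
    kept = [c for c in (_prune(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = kept
    return node


def zipf_truncated(rng: np.random.Generator, s: float, cap: int) -> int:
    """Zipf(s) sample truncated to 1..cap by rejection."""
    if cap <= 1:
        return 1
    while True:
        x = int(rng.zipf(s))
        if x <= cap:
            return x


def _pam_replacement_matrix() -> np.ndarray:
    """Conditional replacement distribution derived from PAM250 log-odds.

    q(j | i) is proportional to pi_j * 10^(S_ij / 10) for j != i, so
    substitutions are biased toward exchangeable residues while the
    expected substituted fraction stays exactly the per-site Bernoulli
    probability applied by the caller.
    """
    pam = substitution_matrices.load("PAM250")
    q = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i == j:
                continue
            q[i, j] = _DAYHOFF_FREQS[j] * 10.0 ** (pam[a, b] / 10.0)
        q[i] /= q[i].sum()
    return q


_PAM_Q: Optional[np.ndarray] = None
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _mutate_sequence(seq: str, length: float, max_frac: float,
                     params: SimParams, rng: np.random.Generator) -> str:
    global _PAM_Q
    if _PAM_Q is None:
        _PAM_Q = _pam_replacement_matrix()
    if length <= 0:
        return seq
    arr = np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    p_sub = min(1.0, params.branch_scale * length)
    mask = rng.random(arr.size) < p_sub
    orig = arr.copy()  # select by the pre-substitution residue: one event per site
    for aa in range(20):
        sites = np.nonzero(mask & (orig == aa))[0]
        if sites.size:
            arr[sites] = rng.choice(20, size=sites.size, p=_PAM_Q[aa])
    chars = [AMINO_ACIDS[i] for i in arr]

    n_indels = rng.poisson(params.indel_rate * length * len(chars))
    for _ in range(n_indels):
        cap = max(1, int(max_frac * len(chars)))
        size = zipf_truncated(rng, params.zipf_exponent, cap)
        if rng.random() < 0.5:  # insertion
            pos = int(rng.integers(0, len(chars) + 1))
            ins = rng.choice(20, size=size, p=_DAYHOFF_FREQS)
            chars[pos:pos] = [AMINO_ACIDS[i] for i in ins]
        else:                    # deletion, never below length 1
            size = min(size, len(chars) - 1)
            if size < 1:
                continue
            pos = int(rng.integers(0, len(chars) - size + 1))
            del chars[pos:pos + size]
    return "".join(chars)


def evolve_sequences(family_trees: Sequence[GeneNode], params: SimParams,
                     rng: np.random.Generator) -> None:
    """Attach amino-acid sequences to every extant gene (in place).

    Each family starts from a uniform-composition seed of uniform length
    in ``seq_len_range`` and a family-wide maximal indel length fraction
    drawn from ``indel_max_frac_range``.
    """
    lo, hi = params.seq_len_range
    for root in family_trees:
        n0 = int(rng.integers(lo, hi + 1))
        root.seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n0))
        max_frac = float(rng.uniform(*params.indel_max_frac_range))

        stack = [root]
        while stack:
            node = stack.pop()
            for child in node.children:
                child.seq = _mutate_sequence(node.seq, child.depth - node.depth,
                                             max_frac, params, rng)
                stack.append(child)


def true_orthology(family_trees: Sequence[GeneNode]) -> Set[Tuple[str, str]]:
    """Cross-species gene pairs whose MRCA in the gene tree is a speciation."""
    pairs: Set[Tuple[str, str]] = set()
    for root in family_trees:
        # record, for every internal node, the leaf sets of its child subtrees;
        # the MRCA of two leaves is the node where they sit in different subtrees
        def walk(node: GeneNode) -> List[GeneNode]:
            if node.label == "leaf":
                return [node]
            child_leaves = [walk(c) for c in node.children]
            if node.label == "speciation":
                for i in range(len(child_leaves)):
                    for j in range(i + 1, len(child_leaves)):
                        for x in child_leaves[i]:
                            for y in child_leaves[j]:
                                if x.species != y.species:
                                    pairs.add(tuple(sorted((x.gene_id, y.gene_id))))
            return [leaf for sub in child_leaves for leaf in sub]

        walk(root)
    return pairs


@dataclass
class SimulatedDataset:
    """A complete simulated benchmark instance."""

    params: SimParams
    species_tree: TreeNode
    genomes: Dict[str, Genome]
    family_trees: List[GeneNode]
    truth_pairs: Set[Tuple[str, str]]
    gene_family: Dict[str, int]
    gene_species: Dict[str, str]
    event_log: List[dict] = field(default_factory=list)

    def families_as_groups(self) -> List[List[str]]:
        """Reference groups for subdivision statistics: one per family."""
        grouped: Dict[int, List[str]] = {}
        for gid, fam in self.gene_family.items():
            grouped.setdefault(fam, []).append(gid)
        return [sorted(g) for _, g in sorted(grouped.items())]

    def emit(self, out_dir: str | os.PathLike, hits: bool = False) -> None:
        """Write FASTA + GFF3 per species, truth tables and the event log."""
        os.makedirs(out_dir, exist_ok=True)
        for sp in sorted(self.genomes):
            genome = self.genomes[sp]
            write_fasta(genome.genes(), os.path.join(out_dir, f"{sp}.faa"))
            write_gff3(genome, os.path.join(out_dir, f"{sp}.gff3"))
        with open(os.path.join(out_dir, "truth_pairs.tsv"), "w") as fh:
            fh.write("# GeneA\tGeneB\n")
            for a, b in sorted(self.truth_pairs):
                fh.write(f"{a}\t{b}\n")
        with open(os.path.join(out_dir, "families.tsv"), "w") as fh:
            fh.write("# Gene\tSpecies\tFamily\n")
            for gid in sorted(self.gene_family):
                fh.write(f"{gid}\t{self.gene_species[gid]}\t{self.gene_family[gid]}\n")
        with open(os.path.join(out_dir, "events.json"), "w") as fh:
            json.dump(self.event_log, fh, indent=0)
        with open(os.path.join(out_dir, "species_tree.nwk"), "w") as fh:
            fh.write(self.species_tree.newick() + "\n")
        if hits:
            from .align import all_vs_all_hits, write_hit_table
            rows = all_vs_all_hits(self.genomes)
            write_hit_table(rows, os.path.join(out_dir, "hits.tsv"))


def _to_genome(species: str, ordered: List[GeneNode], n_chromosomes: int) -> Genome:
    genome = Genome(species_id=species)
    n = len(ordered)
    if n == 0:
        return genome
    k = max(1, min(n_chromosomes, n))
    bounds = [round(i * n / k) for i in range(k + 1)]
    for c in range(k):
        chunk = ordered[bounds[c]:bounds[c + 1]]
        if not chunk:
            continue
        chrom_id = f"chr{c + 1}"
        genome.chromosomes[chrom_id] = [
            Gene(gene_id=g.gene_id, species_id=species, chromosome_id=chrom_id,
                 rank=i, strand="+", seq=g.seq)
            for i, g in enumerate(chunk)
        ]
    return genome


def simulate(params: SimParams) -> SimulatedDataset:
    """Run the full simulation pipeline for one parameter set."""
    rng = np.random.default_rng(params.seed)
    tree = simulate_species_tree(params.n_species, rng)
    gene_orders, family_trees, log = evolve_gene_content(tree, params, rng)
    evolve_sequences(family_trees, params, rng)
    truth = true_orthology(family_trees)

    genomes = {sp: _to_genome(sp, order, params.n_chromosomes)
               for sp, order in gene_orders.items()}
    gene_family: Dict[str, int] = {}
    gene_species: Dict[str, str] = {}
    for order in gene_orders.values():
        for g in order:
            gene_family[g.gene_id] = g.family
            gene_species[g.gene_id] = g.species
    return SimulatedDataset(params, tree, genomes, family_trees, truth,
                            gene_family, gene_species, log)
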