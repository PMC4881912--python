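"""Concatenated-PCG matrices, p-distances, neighbour joining and topology
comparison.

Third codon positions saturate quickly at the between-family divergences
seen in psyllid mitogenomes, so the phylogenetic matrix is built from
codon-aware per-gene alignments with every third position removed (nt12),
alongside the amino-acid matrix.  Neighbour joining on p-distances provides
a deterministic, desk-scale tree; it recovers additive distance matrices
exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mito_io import AnnotatedMitogenome, PCG_NAMES
from .alignment import GAP, MultipleAlignment

__all__ = [
    "ConcatenatedMatrix", "DistanceMatrix", "PhyloTree", "Node",
    "build_matrix", "strip_third_positions", "p_distance", "nj_tree",
    "robinson_foulds", "same_topology", "write_phylip",
]

# concatenation follows the conventional PCG table order
GENE_ORDER = list(PCG_NAMES)


@dataclass
class ConcatenatedMatrix:
    taxa: list[str]
    gene_blocks: dict[str, MultipleAlignment]      # codon-aligned nucleotides
    aa_blocks: dict[str, MultipleAlignment]
    block_order: list[str]

    def concatenated(self, mode: str = "nt12") -> MultipleAlignment:
        """Concatenate per-gene blocks: 'nt' (all positions), 'nt12'
        (third codon positions removed) or 'aa'."""
        rows = {t: [] for t in self.taxa}
        for gene in self.block_order:
            block = (self.aa_blocks if mode == "aa"
                     else self.gene_blocks)[gene]
            for t in self.taxa:
                row = block.row(t)
                if mode == "nt12":
                    row = _strip_third(row)
                rows[t].append(row)
        return MultipleAlignment(list(self.taxa),
                                 ["".join(rows[t]) for t in self.taxa])


def _strip_third(codon_row: str) -> str:
    if len(codon_row) % 3:
        raise ValueError("row length is not a codon multiple; refusing to "
                         "strip third positions of a non-codon matrix")
    return "".join(codon_row[i:i + 2] for i in range(0, len(codon_row), 3))


def strip_third_positions(aln: MultipleAlignment) -> MultipleAlignment:
    """Remove every codon's third column from a codon-aligned matrix."""
    return MultipleAlignment(list(aln.names), [_strip_third(r) for r in aln.rows])


def build_matrix(genomes: list[AnnotatedMitogenome],
                 taxa: list[str] | None = None) -> ConcatenatedMatrix:
    """Codon-aware per-gene alignments over all genomes, concatenated.

    Every genome must carry the 13 canonical PCGs; taxa default to each
    genome's accession metadata.
    """
    from .alignment import codon_aware_alignment
    from .codons import translate

    if taxa is None:
        taxa = [g.metadata.get("accession", f"taxon{i}")
                for i, g in enumerate(genomes, start=1)]
    gene_blocks: dict[str, MultipleAlignment] = {}
    aa_blocks: dict[str, MultipleAlignment] = {}
    for gene in GENE_ORDER:
        records = []
        for taxon, g in zip(taxa, genomes):
            try:
                feat = g.get(gene)
            except KeyError:
                raise ValueError(f"genome {taxon!r} is missing PCG {gene!r}")
            records.append((taxon, feat.sense_sequence(g.sequence)))
        nt = codon_aware_alignment(records)
        gene_blocks[gene] = nt
        aa_rows = []
        for t in taxa:
            row = nt.row(t)
            aa_rows.append("".join(
                "-" if row[i:i + 3] == "---"
                else translate(row[i:i + 3] + "TAA")
                for i in range(0, len(row), 3)))
        aa_blocks[gene] = MultipleAlignment(list(taxa), aa_rows)
    return ConcatenatedMatrix(list(taxa), gene_blocks, aa_blocks,
                              list(GENE_ORDER))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


_AA_VALID = set("ACDEFGHIKLMNPQRSTVWY")
_NT_VALID = set("ACGT")


def p_distance(matrix: ConcatenatedMatrix | MultipleAlignment,
               mode: str = "nt12") -> DistanceMatrix:
    """Pairwise proportion of differing sites, with pairwise deletion of
    gaps/ambiguities."""
    if isinstance(matrix, ConcatenatedMatrix):
        aln = matrix.concatenated(mode)
    else:
        aln = matrix
    valid_set = _AA_VALID if mode == "aa" else _NT_VALID
    arr = aln.to_array()
    valid = np.isin(arr, np.frombuffer("".join(sorted(valid_set)).encode(),
                                       dtype="S1"))
    n = aln.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            both = valid[i] & valid[k]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no valid sites between {aln.names[i]} and {aln.names[k]}")
            D[i, k] = D[k, i] = int((arr[i][both] != arr[k][both]).sum()) / m
    return DistanceMatrix(list(aln.names), D)


# ---------------------------------------------------------------------------
# trees

@dataclass
class Node:
    name: str | None = None
    children: list["Node"] = field(default_factory=list)
    branch_length: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted tree, stored with an arbitrary internal root."""

    root: Node

    @property
    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.root.leaves())

    def newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf():
                base = node.name or ""
            else:
                base = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.branch_length is not None:
                base += f":{node.branch_length:.6f}"
            return base
        return fmt(self.root) + ";"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the smaller-side leaf set
        (ties broken lexicographically) — rooting-independent."""
        all_leaves = self.leaf_names
        out: set[frozenset] = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                a, b = sorted([below, other],
                              key=lambda s: (len(s), sorted(s)))
                out.add(a)
            return below

        walk(self.root)
        return out


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Standard neighbour joining with deterministic tie-breaking.

    The pair minimising the Q criterion is joined at each step; ties are
    broken by the lexicographically smallest label pair.  Negative branch
    lengths are clamped to zero (with a warning).  Additive matrices are
    recovered exactly.
    """
    import warnings as _w

    labels = list(d.labels)
    if len(labels) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    D = d.values.astype(float).copy()
    nodes = [Node(name=l) for l in labels]
    keys = list(labels)          # lexicographic identity for tie-breaking

    def clamp(x: float) -> float:
        if x < -1e-9:
            _w.warn(f"negative NJ branch length {x:.4g} clamped to 0")
        return max(x, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((keys[i], keys[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = clamp(li)
        child_j.branch_length = clamp(lj)
        new = Node(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
    # join the final three nodes at an unrooted trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    ls = (0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02),
          0.5 * (d02 + d12 - d01))
    for node, l in zip(nodes, ls):
        node.branch_length = clamp(l)
    return PhyloTree(Node(children=list(nodes)))


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Number of non-trivial splits present in exactly one tree."""
    if a.leaf_names != b.leaf_names:
        diff = sorted(a.leaf_names ^ b.leaf_names)
        raise ValueError(f"leaf sets differ: {diff}")
    return len(a.splits() ^ b.splits())


def same_topology(a: PhyloTree, b: PhyloTree) -> bool:
    return robinson_foulds(a, b) == 0


def parse_newick(text: str) -> PhyloTree:
    """Minimal newick reader (names, branch lengths, nesting)."""
    pos = 0
    text = text.strip().rstrip(";")

    def parse() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ",():":
            pos += 1
        label = text[start:pos]
        if label:
            node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            node.branch_length = float(text[start:pos])
        return node

    return PhyloTree(parse())


def write_phylip(aln: MultipleAlignment, path) -> None:
    """Relaxed PHYLIP export of a character matrix."""
    with open(path, "w") as fh:
        fh.write(f" {aln.n_rows} {aln.n_cols}\n")
        for name, row in zip(aln.names, aln.rows):
            fh.write(f"{name}  {row}\n")
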