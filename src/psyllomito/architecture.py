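"""Circular-genome architecture audits: strand usage, overlaps, spacers,
control-region identification and gene-order comparison.

All position arithmetic is done on explicit position sets over the circle,
so origin-wrapping features need no special-casing beyond their two spans.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mito_io import AnnotatedMitogenome, Feature

__all__ = [
    "OverlapRecord", "SpacerRecord", "GeneOrderSignature",
    "strand_partition", "find_overlaps", "intergenic_regions",
    "identify_control_region", "gene_order_signature", "compare_gene_order",
]


@dataclass(frozen=True)
class OverlapRecord:
    feature_a: str
    feature_b: str
    pair_class: str          # "PCG-PCG" | "tRNA-tRNA" | "PCG-tRNA" | "other"
    overlap_bp: int


@dataclass(frozen=True)
class SpacerRecord:
    upstream_feature: str
    downstream_feature: str
    start: int               # [start, end) on the circle; end may exceed L
    end: int
    length_bp: int


@dataclass(frozen=True)
class GeneOrderSignature:
    """Signed circular gene order, anchored for rotation invariance.

    The order is read clockwise on the J-strand starting from the anchor
    gene (trnI when present, else the lexicographically first PCG).
    """

    order: tuple[tuple[str, str], ...]   # (gene name, "+"|"-"), "+" = J

    def __len__(self):
        return len(self.order)

    @property
    def genes(self) -> frozenset:
        return frozenset(name for name, _ in self.order)


def strand_partition(genome: AnnotatedMitogenome):
    """Count genes on the J and N strands, with a per-class breakdown."""
    genes = genome.genes()
    if not genes:
        raise ValueError("genome has no gene features")
    per_class: dict[str, dict[str, int]] = {}
    for f in genes:
        d = per_class.setdefault(f.feature_class, {"J": 0, "N": 0})
        d[f.strand] += 1
    count_j = sum(d["J"] for d in per_class.values())
    count_n = sum(d["N"] for d in per_class.values())
    return count_j, count_n, per_class


def _position_set(f: Feature) -> set[int]:
    out: set[int] = set()
    for s, e in f.spans:
        out.update(range(s, e))
    return out


def _pair_class(a: Feature, b: Feature) -> str:
    classes = {a.feature_class, b.feature_class}
    if classes == {"PCG"}:
        return "PCG-PCG"
    if classes == {"tRNA"}:
        return "tRNA-tRNA"
    if classes == {"PCG", "tRNA"}:
        return "PCG-tRNA"
    return "other"


def find_overlaps(genome: AnnotatedMitogenome) -> list[OverlapRecord]:
    """One record per unordered pair of genes whose position sets intersect."""
    genes = genome.genes()
    psets = [_position_set(f) for f in genes]
    records = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            n = len(psets[i] & psets[j])
            if n:
                records.append(OverlapRecord(genes[i].name, genes[j].name,
                                             _pair_class(genes[i], genes[j]), n))
    records.sort(key=lambda r: -r.overlap_bp)
    return records


def intergenic_regions(genome: AnnotatedMitogenome) -> list[SpacerRecord]:
    """Maximal uncovered runs on the circle, sorted by length descending.

    Coverage considers gene features only, so an annotated control region
    does not hide itself.
    """
    L = len(genome)
    genes = genome.genes()
    covered = np.zeros(L, dtype=bool)
    for f in genes:
        for s, e in f.spans:
            covered[s:e] = True
    if covered.all():
        return []
    # rotate so position 0 is covered, making runs non-wrapping in the
    # rotated frame (if nothing is covered the whole circle is one spacer)
    if not covered.any():
        return [SpacerRecord("", "", 0, L, L)]
    first_cov = int(np.argmax(covered))
    rolled = np.roll(covered, -first_cov)
    runs = []
    in_run = False
    for i, c in enumerate(rolled):
        if not c and not in_run:
            in_run, run_start = True, i
        elif c and in_run:
            in_run = False
            runs.append((run_start, i))
    if in_run:
        runs.append((run_start, L))
    out = []
    for rs, re_ in runs:
        start = (rs + first_cov) % L
        end = start + (re_ - rs)          # may exceed L (wrapping spacer)
        up = _neighbour(genes, L, start, upstream=True)
        down = _neighbour(genes, L, end % L, upstream=False)
        out.append(SpacerRecord(up, down, start, end, re_ - rs))
    out.sort(key=lambda r: (-r.length_bp, r.start))
    return out


def _neighbour(genes: list[Feature], L: int, pos: int, upstream: bool) -> str:
    """Gene abutting a spacer boundary: ends at pos (upstream) or starts at it."""
    for f in genes:
        for s, e in f.spans:
            if upstream and e % L == pos % L:
                return f.name
            if not upstream and s % L == pos % L:
                return f.name
    # overlap geometry can leave no exact abutment; fall back to nearest
    best, bestd = "", L + 1
    for f in genes:
        for s, e in f.spans:
            d = (pos - e) % L if upstream else (s - pos) % L
            if d < bestd:
                best, bestd = f.name, d
    return best


def identify_control_region(genome: AnnotatedMitogenome) -> SpacerRecord:
    """The largest intergenic region; ties go to the smallest start."""
    spacers = intergenic_regions(genome)
    if not spacers:
        raise ValueError("genome has no intergenic region")
    return spacers[0]


def gene_order_signature(genome: AnnotatedMitogenome,
                         anchor: str | None = None) -> GeneOrderSignature:
    genes = sorted(genome.genes(), key=lambda f: (f.start, f.end))
    names = [f.name for f in genes]
    if anchor is None:
        anchor = "trnI" if "trnI" in names else min(
            (f.name for f in genes if f.feature_class == "PCG"), default=names[0])
    if anchor not in names:
        raise ValueError(f"anchor gene {anchor!r} not present")
    k = names.index(anchor)
    rotated = genes[k:] + genes[:k]
    return GeneOrderSignature(tuple((f.name, "+" if f.strand == "J" else "-")
                                    for f in rotated))


def _adjacencies(order) -> set[tuple[tuple[str, str], tuple[str, str]]]:
    """Signed circular adjacencies, orientation-normalised.

    The adjacency a→b is equivalent to the reverse-complement reading
    -b→-a; both normalised to one canonical tuple.
    """
    flip = {"+": "-", "-": "+"}
    adj = set()
    n = len(order)
    for i in range(n):
        a, b = order[i], order[(i + 1) % n]
        rc = ((b[0], flip[b[1]]), (a[0], flip[a[1]]))
        adj.add(min((a, b), rc))
    return adj


def compare_gene_order(a: GeneOrderSignature, b: GeneOrderSignature):
    """Classify two signatures as identical / rearranged, with breakpoints.

    Identical means one is a rotation of the other with equal strand signs
    (anchoring makes rotation explicit).  The breakpoint count is the number
    of signed adjacencies of ``a`` missing from ``b``.
    """
    if a.genes != b.genes:
        diff = sorted(a.genes ^ b.genes)
        raise ValueError(f"gene sets differ; symmetric difference: {diff}")
    adj_a, adj_b = _adjacencies(a.order), _adjacencies(b.order)
    breakpoints = len(adj_a - adj_b)
    # rotation + strand equality; order tuples are already anchored, but an
    # anchored pair may still be a rotation if anchors differ
    identical = False
    n = len(a.order)
    for shift in range(n):
        if tuple(b.order[(i + shift) % n] for i in range(n)) == a.order:
            identical = True
            break
    return ("identical" if identical else "rearranged"), breakpoints
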