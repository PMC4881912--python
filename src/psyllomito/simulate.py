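"""Synthetic annotated mitogenomes and evolved panels with known truth.

The generator emits a 37-gene circular genome in the ancestral insect gene
order (23 genes on the majority J-strand, 14 on the minority N-strand),
with published psyllid gene lengths and start/stop codons, small gene
overlaps (1-12 bp), 3-31 bp intergenic spacers, one large A+T-rich control
region, per-feature-class base-composition targets, and a primer pair whose
predicted amplicon wraps the origin.  Protein-coding genes are valid open
reading frames under the invertebrate mitochondrial code, including the
biological overlap idioms (an ATGATAA-style junction for 7 bp PCG-PCG
overlaps) and incomplete T stops.

``evolve_panel`` derives haplotypes or species along a star or tree, with
per-gene rates, optional hotspots and a replayable truth log.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mito_io import (AnnotatedMitogenome, CircularSequence, Feature,
                      genome_from_string, reverse_complement)
from .codons import INVERTEBRATE_MITO, load_reference_pcg_table
from .phylo import Node, PhyloTree

__all__ = [
    "GenomeSpec", "EvolutionSpec", "TruthLog", "Substitution",
    "generate_genome", "evolve_panel", "make_haplotype_panel",
    "divergence_for_pi", "BC_MITO_F", "BC_MITO_R",
    "DEFAULT_GENE_PI", "NAD5_HOTSPOT", "PSYLLID_TAXA", "OUTGROUP_TAXA",
    "REFERENCE_TOPOLOGY_NEWICK", "psyllid_diversity_spec",
    "psyllid_phylogeny_tree", "psyllid_phylogeny_spec",
    "partial_region_bounds", "exact_substitution_copy",
    "synonymous_third_position_snps", "psyllid_haplotype_panel",
    "HAPLOTYPE_SOURCES",
]

# the circularity-check primer pair (5'->3')
BC_MITO_F = "GGTATCTAATCCTGGTTTAGCGC"
BC_MITO_R = "TTGTCTAACATTGGAGTGGGG"

# ancestral insect mitochondrial gene order on the J-strand, clockwise
ANCESTRAL_GENE_ORDER: tuple[tuple[str, str, str], ...] = (
    ("trnI", "J", "tRNA"), ("trnQ", "N", "tRNA"), ("trnM", "J", "tRNA"),
    ("nad2", "J", "PCG"), ("trnW", "J", "tRNA"), ("trnC", "N", "tRNA"),
    ("trnY", "N", "tRNA"), ("cox1", "J", "PCG"), ("trnLeuUUR", "J", "tRNA"),
    ("cox2", "J", "PCG"), ("trnK", "J", "tRNA"), ("trnD", "J", "tRNA"),
    ("atp8", "J", "PCG"), ("atp6", "J", "PCG"), ("cox3", "J", "PCG"),
    ("trnG", "J", "tRNA"), ("nad3", "J", "PCG"), ("trnA", "J", "tRNA"),
    ("trnR", "J", "tRNA"), ("trnN", "J", "tRNA"), ("trnSerAGN", "J", "tRNA"),
    ("trnE", "J", "tRNA"), ("trnF", "N", "tRNA"), ("nad5", "N", "PCG"),
    ("trnH", "N", "tRNA"), ("nad4", "N", "PCG"), ("nad4L", "N", "PCG"),
    ("trnT", "J", "tRNA"), ("trnP", "N", "tRNA"), ("nad6", "J", "PCG"),
    ("cob", "J", "PCG"), ("trnSerUCN", "J", "tRNA"), ("nad1", "N", "PCG"),
    ("trnLeuCUN", "N", "tRNA"), ("rrnL", "N", "rRNA"), ("trnV", "N", "tRNA"),
    ("rrnS", "N", "rRNA"),
)

# overlap directives between adjacent genes (J-coordinate order), in bp:
# 4 PCG-PCG (1-7), 7 tRNA-tRNA (1-12), 3 PCG-tRNA (2-3)
DEFAULT_OVERLAPS: dict[tuple[str, str], int] = {
    ("atp8", "atp6"): 7, ("atp6", "cox3"): 1,
    ("nad4", "nad4L"): 7, ("nad6", "cob"): 1,
    ("trnI", "trnQ"): 3, ("trnQ", "trnM"): 1, ("trnC", "trnY"): 2,
    ("trnK", "trnD"): 1, ("trnA", "trnR"): 5, ("trnR", "trnN"): 1,
    ("trnN", "trnSerAGN"): 12,
    ("nad2", "trnW"): 2, ("cox1", "trnLeuUUR"): 3, ("cob", "trnSerUCN"): 2,
}

# per-class (%A+T, AT-skew, GC-skew) targets on the sense strand
DEFAULT_COMPOSITION: dict[str, tuple[float, float, float]] = {
    "PCG-J": (72.3, -0.084, -0.213),
    "PCG-N": (73.1, -0.248, 0.242),
    "tRNA-J": (76.9, 0.056, 0.022),
    "tRNA-N": (77.5, -0.032, 0.429),
    "rrnL": (76.0, -0.042, 0.333),
    "rrnS": (75.4, -0.024, 0.206),
    "noncoding": (82.7, -0.047, 0.006),
}

# residue-usage profile for coding genes.  The large entries are the usage
# levels reported for psyllid mitogenomes; the remainder is a realistic
# insect-mitochondrial spread, rescaled to sum to 100.
_AA_USAGE_FIXED = {"Ile": 10.79, "Phe": 9.60, "Leu-UUR": 8.98,
                   "Arg": 1.31, "Cys": 1.20}
_AA_USAGE_REST = {"Met": 6.5, "Leu-CUN": 3.5, "Ser-UCN": 5.0, "Ser-AGN": 3.0,
                  "Asn": 5.5, "Lys": 4.5, "Tyr": 4.5, "Thr": 4.0, "Val": 4.0,
                  "Gly": 5.5, "Ala": 4.0, "Pro": 3.5, "Trp": 2.5, "His": 2.5,
                  "Gln": 2.0, "Asp": 2.0, "Glu": 2.5}

_AA_KEY_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in INVERTEBRATE_MITO.table.items():
    if _aa == "L":
        _k = "Leu-UUR" if _codon in ("TTA", "TTG") else "Leu-CUN"
    elif _aa == "S":
        _k = "Ser-AGN" if _codon.startswith("AG") else "Ser-UCN"
    else:
        _k = {"A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
              "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
              "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro", "T": "Thr",
              "W": "Trp", "Y": "Tyr", "V": "Val"}[_aa]
    _AA_KEY_TO_CODONS.setdefault(_k, []).append(_codon)


def default_aa_usage() -> dict[str, float]:
    fixed_sum = sum(_AA_USAGE_FIXED.values())
    rest_sum = sum(_AA_USAGE_REST.values())
    scale = (100.0 - fixed_sum) / rest_sum
    usage = dict(_AA_USAGE_FIXED)
    usage.update({k: v * scale for k, v in _AA_USAGE_REST.items()})
    return usage


def base_probs(pct_at: float, at_skew_v: float, gc_skew_v: float
               ) -> dict[str, float]:
    """A/C/G/T probabilities realising a %A+T and skew target."""
    at = pct_at / 100.0
    return {
        "A": at * (1 + at_skew_v) / 2, "T": at * (1 - at_skew_v) / 2,
        "G": (1 - at) * (1 + gc_skew_v) / 2,
        "C": (1 - at) * (1 - gc_skew_v) / 2,
    }


def _default_pcg_table() -> dict[str, tuple[str, str, int]]:
    t = load_reference_pcg_table()
    sub = t[t.species == "B_cockerelli"]
    return {row.gene: (row.start_codon, row.stop_codon, int(row.length_bp))
            for _, row in sub.iterrows() if row.start_codon != "."}


def _default_rrna_lengths() -> dict[str, int]:
    t = load_reference_pcg_table()
    sub = t[(t.species == "B_cockerelli") & (t.start_codon == ".")]
    return {row.gene: int(row.length_bp) for _, row in sub.iterrows()}


@dataclass
class GenomeSpec:
    """Directives for one synthetic mitogenome.  Defaults reproduce the
    architecture and composition of a psyllid mitogenome."""

    gene_order: tuple = ANCESTRAL_GENE_ORDER
    pcg_table: dict | None = None            # gene -> (start, stop, length)
    rrna_lengths: dict | None = None
    trna_length_range: tuple[int, int] = (54, 75)
    spacer_range: tuple[int, int] = (3, 31)
    control_region_length: int = 975
    overlaps: dict | None = None
    composition: dict | None = None
    aa_usage: dict | None = None
    primer_pair: tuple[str, str] | None = (BC_MITO_F, BC_MITO_R)
    amplicon_length: int = 1285
    primer_fwd_offset_from_end: int = 1150
    accession: str = "SYNPSY001"
    organism: str = "synthetic psyllid"
    seed: int = 42

    def resolved(self) -> "GenomeSpec":
        return replace(
            self,
            pcg_table=self.pcg_table or _default_pcg_table(),
            rrna_lengths=self.rrna_lengths or _default_rrna_lengths(),
            overlaps=dict(DEFAULT_OVERLAPS if self.overlaps is None
                          else self.overlaps),
            composition=dict(DEFAULT_COMPOSITION if self.composition is None
                             else self.composition),
            aa_usage=self.aa_usage or default_aa_usage(),
        )


_BASE_ARR = np.array(list("ACGT"))


def _random_bases(n: int, probs: dict[str, float], rng) -> str:
    p = np.array([probs[b] for b in "ACGT"])
    return "".join(rng.choice(_BASE_ARR, size=n, p=p / p.sum()))


def _codon_weights(probs: dict[str, float]) -> dict[str, np.ndarray]:
    """Within-family codon weights: product of per-base probabilities."""
    out = {}
    for key, codons in _AA_KEY_TO_CODONS.items():
        w = np.array([probs[c[0]] * probs[c[1]] * probs[c[2]] for c in codons])
        out[key] = w / w.sum()
    return out


def _sample_codons(n: int, usage: dict[str, float],
                   cw: dict[str, np.ndarray], rng) -> list[str]:
    keys = sorted(usage)
    pk = np.array([usage[k] for k in keys], dtype=float)
    picks = rng.choice(len(keys), size=n, p=pk / pk.sum())
    out = []
    for k in picks:
        key = keys[k]
        codons = _AA_KEY_TO_CODONS[key]
        out.append(codons[rng.choice(len(codons), p=cw[key])])
    return out


def _pcg_sense(gene: str, start: str, stop: str, length: int,
               usage: dict, cw: dict, rng,
               prefix: list[str] | None = None,
               suffix: list[str] | None = None) -> str:
    """A valid ORF: start codon, non-stop body, complete or incomplete stop.

    ``prefix``/``suffix`` force codons at either end (overlap junctions);
    forced codons replace sampled ones after the start codon.
    """
    stop_len = len(stop)
    if (length - stop_len) % 3:
        raise ValueError(f"{gene}: length {length} incompatible with stop "
                         f"{stop!r}")
    n_codons = (length - stop_len) // 3
    if n_codons < 4:
        raise ValueError(f"{gene}: too short")
    body = _sample_codons(n_codons, usage, cw, rng)
    body[0] = start
    for k, c in enumerate(prefix or []):
        if c is not None:
            body[k] = c
    for k, c in enumerate(suffix or []):
        if c is not None:
            body[n_codons - len(suffix) + k] = c
    seq = "".join(body) + stop
    assert len(seq) == length
    return seq


def _junction_constraints(spec: GenomeSpec):
    """Per-gene forced codons implied by PCG-PCG overlap directives."""
    classes = {name: cls for name, _, cls in spec.gene_order}
    strands = {name: s for name, s, _ in spec.gene_order}
    prefix: dict[str, list] = {}
    suffix: dict[str, list] = {}
    for (a, b), k in spec.overlaps.items():
        if classes.get(a) != "PCG" or classes.get(b) != "PCG":
            continue
        if strands[a] != strands[b]:
            raise ValueError(f"unsupported PCG-PCG overlap across strands: "
                             f"{a}/{b}")
        # sense-upstream gene: J-upstream on strand J, J-downstream on N
        up, down = (a, b) if strands[a] == "J" else (b, a)
        start_up, stop_up, _ = spec.pcg_table[up]
        start_down, stop_down, _ = spec.pcg_table[down]
        if k == 1:
            if stop_up[-1] != start_down[0]:
                raise ValueError(
                    f"infeasible 1 bp overlap {up}->{down}: stop {stop_up} "
                    f"does not end with start base {start_down[0]}")
        elif k == 7:
            if start_down != "ATG" or stop_up not in ("TAA", "TAG"):
                raise ValueError(
                    f"infeasible 7 bp overlap {up}->{down}: needs ATG start "
                    "and complete stop")
            # shared bases are ATGATA + the stop's last base: the upstream
            # reading frame sees ...ATA TGA STOP, the downstream one sees
            # ATG ATA X.. -- the biological overlap idiom
            suffix[up] = ["ATA", "TGA"]
            prefix[down] = [None, "ATA", {"TAA": "ATT", "TAG": "GTT"}[stop_up]]
        else:
            raise ValueError(f"unsupported PCG-PCG overlap of {k} bp")
    return prefix, suffix


def _layout(spec: GenomeSpec, rng):
    """Assign coordinates to all genes plus the control region."""
    cursor = 0
    placed = []  # (name, strand, cls, start, end)
    prev = None
    lo, hi = spec.spacer_range
    for name, strand, cls in spec.gene_order:
        if cls == "PCG":
            length = spec.pcg_table[name][2]
        elif cls == "rRNA":
            length = spec.rrna_lengths[name]
        else:
            length = int(rng.integers(spec.trna_length_range[0],
                                      spec.trna_length_range[1] + 1))
        if prev is None:
            start = 0
        elif (prev, name) in spec.overlaps:
            k = spec.overlaps[(prev, name)]
            if k >= length or k >= (placed[-1][4] - placed[-1][3]):
                raise ValueError(f"infeasible overlap {prev}->{name}: {k} bp")
            start = cursor - k
        else:
            start = cursor + int(rng.integers(lo, hi + 1))
        placed.append((name, strand, cls, start, start + length))
        cursor = start + length
        prev = name
    L = cursor + spec.control_region_length
    return placed, L


def generate_genome(spec: GenomeSpec | None = None) -> AnnotatedMitogenome:
    """Deterministically generate an annotated circular mitogenome."""
    spec = (spec or GenomeSpec()).resolved()
    ss = np.random.SeedSequence(spec.seed)
    # independent streams per component so one change never perturbs others
    r_layout, r_bg, r_rrna, r_trna, r_pcg = (
        np.random.default_rng(c) for c in ss.spawn(5))

    placed, L = _layout(spec, r_layout)
    comp = spec.composition
    arr = np.array(list(_random_bases(L, base_probs(*comp["noncoding"]),
                                      r_bg)))

    def put(start: int, end: int, sense: str, strand: str):
        jseq = reverse_complement(sense) if strand == "N" else sense
        arr[start:end] = list(jseq)

    for name, strand, cls, s, e in placed:
        if cls == "rRNA":
            put(s, e, _random_bases(e - s, base_probs(*comp[name]), r_rrna),
                strand)
    for name, strand, cls, s, e in placed:
        if cls == "tRNA":
            put(s, e, _random_bases(e - s, base_probs(*comp[f"tRNA-{strand}"]),
                                    r_trna), strand)

    # embed primer binding sites so the amplicon wraps the origin
    if spec.primer_pair is not None:
        fwd, rev = (p.upper().replace(" ", "") for p in spec.primer_pair)
        f = L - spec.primer_fwd_offset_from_end
        r5 = (f + spec.amplicon_length - 1) % L
        if r5 >= f:
            raise ValueError("amplicon does not wrap; adjust offsets")
        arr[f:f + len(fwd)] = list(fwd)
        arr[r5 - len(rev) + 1:r5 + 1] = list(reverse_complement(rev))

    usage = spec.aa_usage
    prefix, suffix = _junction_constraints(spec)
    cw_by_strand = {st: _codon_weights(base_probs(*comp[f"PCG-{st}"]))
                    for st in ("J", "N")}
    for name, strand, cls, s, e in placed:
        if cls != "PCG":
            continue
        start_c, stop_c, length = spec.pcg_table[name]
        sense = _pcg_sense(name, start_c, stop_c, length, usage,
                           cw_by_strand[strand], r_pcg,
                           prefix.get(name), suffix.get(name))
        put(s, e, sense, strand)

    features = [Feature(name, cls, strand, ((s, e),),
                        incomplete_stop=(spec.pcg_table[name][1]
                                         if cls == "PCG"
                                         and len(spec.pcg_table[name][1]) < 3
                                         else None))
                for name, strand, cls, s, e in placed]
    cr_start = placed[-1][4]
    features.append(Feature("CR", "noncoding", "J", ((cr_start, L),)))
    return genome_from_string("".join(arr), features,
                              accession=spec.accession,
                              organism=spec.organism,
                              description="synthetic psyllid mitogenome")


# ---------------------------------------------------------------------------
# evolution

@dataclass(frozen=True)
class Substitution:
    taxon: str
    position: int          # J-strand coordinate
    ref: str
    alt: str
    gene: str | None
    codon_position: int | None   # sense-frame position 1/2/3 for PCGs


@dataclass
class TruthLog:
    substitutions: list[Substitution] = field(default_factory=list)

    def positions(self, taxon: str) -> set[int]:
        return {s.position for s in self.substitutions if s.taxon == taxon}

    def replay(self, ancestor: AnnotatedMitogenome) -> dict[str, str]:
        """Apply logged events per taxon; must reproduce each derived
        sequence exactly."""
        out = {}
        for taxon in sorted({s.taxon for s in self.substitutions}):
            seq = list(ancestor.sequence.residues)
            for s in self.substitutions:
                if s.taxon == taxon:
                    assert seq[s.position] == s.ref
                    seq[s.position] = s.alt
            out[taxon] = "".join(seq)
        return out

    def realized_divergence(self, taxon: str, gene_positions: set[int],
                            gene_length: int) -> float:
        hits = sum(1 for s in self.substitutions
                   if s.taxon == taxon and s.position in gene_positions)
        return hits / gene_length


@dataclass
class EvolutionSpec:
    """How to evolve a panel from an ancestor.

    ``tree`` is a :class:`psyllomito.phylo.Node` whose branch lengths are
    per-site substitution probabilities (scaled by per-gene rates).  Leaf
    names label the derived genomes.
    """

    tree: Node
    gene_rates: dict[str, float] = field(default_factory=dict)
    default_gene_rate: float = 0.0
    noncoding_rate: float = 0.0
    hotspots: tuple = ()        # (gene, sense_start, sense_end, rate)
    position_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kappa: float = 1.0          # transition/transversion weight
    seed: int = 0

    @staticmethod
    def star(names: list[str], branch_length: float = 1.0, **kw
             ) -> "EvolutionSpec":
        root = Node(children=[Node(name=n, branch_length=branch_length)
                              for n in names])
        return EvolutionSpec(tree=root, **kw)


def _site_annotations(genome: AnnotatedMitogenome):
    """(gene name, codon position, protected) per J position."""
    L = len(genome)
    gene = np.full(L, "", dtype=object)
    codon_pos = np.zeros(L, dtype=np.int8)
    protected = np.zeros(L, dtype=bool)
    for f in genome.genes():
        pos = f.positions(L)
        sense_order = pos if f.strand == "J" else pos[::-1]
        for k, p in enumerate(sense_order):
            gene[p] = f.name
            if f.feature_class == "PCG":
                off = k - (f.codon_start - 1)
                if off >= 0:
                    codon_pos[p] = off % 3 + 1
        if f.feature_class == "PCG":
            # protect start codon and (possibly incomplete) stop
            stop_len = len(f.incomplete_stop) if f.incomplete_stop else 3
            for p in sense_order[:3]:
                protected[p] = True
            for p in sense_order[-stop_len:]:
                protected[p] = True
    return gene, codon_pos, protected


def _rate_map(genome: AnnotatedMitogenome, spec: EvolutionSpec,
              gene, codon_pos, protected) -> np.ndarray:
    L = len(genome)
    rate = np.full(L, spec.noncoding_rate, dtype=float)
    for f in genome.genes():
        r = spec.gene_rates.get(f.name, spec.default_gene_rate)
        for p in f.positions(L):
            rate[p] = r
    for gname, s0, s1, r in spec.hotspots:
        f = genome.get(gname)
        pos = f.positions(L)
        sense_order = pos if f.strand == "J" else pos[::-1]
        for p in sense_order[s0:s1]:
            rate[p] = r
    w = np.asarray(spec.position_weights, dtype=float)
    w = 3.0 * w / w.sum()
    for cp in (1, 2, 3):
        mask = codon_pos == cp
        rate[mask] *= w[cp - 1]
    rate[protected] = 0.0
    return np.clip(rate, 0.0, 0.95)


_IDX = {b: i for i, b in enumerate("ACGT")}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _codon_membership(genome: AnnotatedMitogenome):
    """Per J position: the sense-ordered codon triples covering it.

    Only body codons count (start and stop codons are protected from
    mutation anyway); a position inside a PCG-PCG overlap belongs to two
    codons and must keep both stop-free.
    """
    L = len(genome)
    member: list[list] = [[] for _ in range(L)]
    for f in genome.genes():
        if f.feature_class != "PCG":
            continue
        pos = f.positions(L)
        order = pos if f.strand == "J" else pos[::-1]
        stop_len = len(f.incomplete_stop) if f.incomplete_stop else 3
        body = order[f.codon_start - 1:len(order) - stop_len]
        for c0 in range(0, len(body) - 2, 3):
            tri = tuple(body[c0:c0 + 3])
            for p in tri:
                member[p].append((f.strand, tri))
    return member


def _mutate(seq: str, rate: np.ndarray, kappa: float, rng,
            membership) -> tuple[str, list]:
    """One branch of evolution; returns (new sequence, events).

    At PCG sites the alternate base is resampled among bases that do not
    create an in-frame stop in any covering gene; a site with no such
    alternate is left unchanged.
    """
    arr = list(seq)
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    events = []
    for p in map(int, hit):
        old = arr[p]
        if old not in _IDX:
            continue
        allowed, wts = [], []
        for b in "ACGT":
            if b == old:
                continue
            ok = True
            for strand, tri in membership[p]:
                codon = "".join(
                    (b if q == p else arr[q]) if strand == "J"
                    else reverse_complement(b if q == p else arr[q])
                    for q in tri)
                if codon in INVERTEBRATE_MITO.stop_codons:
                    ok = False
                    break
            if ok:
                allowed.append(b)
                wts.append(kappa if _TRANSITION[old] == b else 1.0)
        if not allowed:
            continue
        w = np.asarray(wts, dtype=float)
        alt = allowed[int(rng.choice(len(allowed), p=w / w.sum()))]
        arr[p] = alt
        events.append((p, old, alt))
    return "".join(arr), events


def evolve_panel(ancestor: AnnotatedMitogenome, spec: EvolutionSpec
                 ) -> tuple[list[AnnotatedMitogenome], TruthLog]:
    """Evolve derived genomes along ``spec.tree``; annotations carry over.

    Substitutions that would create an in-frame stop inside a PCG are
    rejected and the alternate base resampled among stop-free choices
    (slightly skewing the alternate-base distribution at stop-adjacent
    sites); start and stop codons are held invariant.
    """
    gene, codon_pos, protected = _site_annotations(ancestor)
    rate = _rate_map(ancestor, spec, gene, codon_pos, protected)
    membership = _codon_membership(ancestor)
    rng = np.random.default_rng(spec.seed)
    log = TruthLog()
    out: list[AnnotatedMitogenome] = []

    def descend(node: Node, seq: str, events_so_far: list):
        for child in node.children:
            d = child.branch_length or 0.0
            new_seq, events = _mutate(seq, rate * d, spec.kappa, rng,
                                      membership)
            acc = events_so_far + events
            if child.is_leaf():
                name = child.name or f"taxon{len(out) + 1}"
                # net change vs the ancestor, collapsed per position
                anc = ancestor.sequence.residues
                for p in sorted({p for p, _, _ in acc}):
                    if new_seq[p] != anc[p]:
                        log.substitutions.append(Substitution(
                            name, p, anc[p], new_seq[p],
                            gene[p] or None,
                            int(codon_pos[p]) or None))
                out.append(AnnotatedMitogenome(
                    CircularSequence(new_seq,
                                     ancestor.sequence.topology),
                    list(ancestor.features),
                    {**ancestor.metadata, "accession": name,
                     "organism": name}))
            else:
                descend(child, new_seq, acc)

    descend(spec.tree, ancestor.sequence.residues, [])
    return out, log


def divergence_for_pi(pi: float) -> float:
    """Per-tip substitution probability on a star so that the expected
    pairwise diversity equals ``pi``.

    Two tips differ at a site with probability 2d(1-d) + (2/3)d^2 when each
    mutates independently with probability d (uniform alternate base).
    """
    if not 0 <= pi < 0.75:
        raise ValueError("pi must be in [0, 0.75)")
    return (2.0 - math.sqrt(4.0 - 16.0 * pi / 3.0)) * 3.0 / 8.0


# ---------------------------------------------------------------------------
# canonical study conditions: the divergence structure of the four-species
# psyllid comparison and its two outgroups

# per-gene mean nucleotide diversity among the four psyllid mitogenomes;
# genes without a published mean get a realistic mid-range level
DEFAULT_GENE_PI: dict[str, float] = {
    "nad2": 0.38, "cox1": 0.21, "cox2": 0.24, "atp8": 0.35, "atp6": 0.30,
    "cox3": 0.26, "nad3": 0.33, "nad5": 0.33, "nad4": 0.32, "nad4L": 0.37,
    "nad6": 0.38, "cob": 0.28, "nad1": 0.28, "rrnL": 0.25, "rrnS": 0.22,
}
# one 250 bp hotspot inside nad5 (sense coordinates) at the peak diversity
NAD5_HOTSPOT = ("nad5", 1000, 1250, 0.46)

PSYLLID_TAXA = ("BC", "PS", "CC", "PV")
OUTGROUP_TAXA = ("CQ", "AA")
REFERENCE_TOPOLOGY_NEWICK = "((BC,PS),(CC,PV),(CQ,AA));"


def psyllid_diversity_spec(seed: int = 0) -> EvolutionSpec:
    """Star evolution of four psyllid-like taxa whose per-gene expected
    pairwise diversities follow the study's per-gene profile."""
    rates = {g: divergence_for_pi(pi) for g, pi in DEFAULT_GENE_PI.items()}
    gene, s0, s1, pi = NAD5_HOTSPOT
    return EvolutionSpec.star(
        list(PSYLLID_TAXA), 1.0, gene_rates=rates,
        default_gene_rate=divergence_for_pi(0.20),       # tRNAs
        noncoding_rate=divergence_for_pi(0.40),          # CR / spacers
        hotspots=((gene, s0, s1, divergence_for_pi(pi)),),
        seed=seed)


def psyllid_phylogeny_tree() -> Node:
    """The two-family ingroup topology with two distant outgroups;
    branch lengths are per-site substitution probabilities."""
    return Node(children=[
        Node(branch_length=0.05, children=[
            Node(name="BC", branch_length=0.08),
            Node(name="PS", branch_length=0.08)]),
        Node(branch_length=0.05, children=[
            Node(name="CC", branch_length=0.09),
            Node(name="PV", branch_length=0.09)]),
        Node(branch_length=0.08, children=[
            Node(name="CQ", branch_length=0.22),
            Node(name="AA", branch_length=0.24)]),
    ])


def psyllid_phylogeny_spec(seed: int = 0) -> EvolutionSpec:
    return EvolutionSpec(tree=psyllid_phylogeny_tree(),
                         default_gene_rate=1.0, noncoding_rate=1.0,
                         gene_rates={}, seed=seed)


def partial_region_bounds(genome: AnnotatedMitogenome,
                          length: int = 3077) -> tuple[int, int]:
    """J-strand bounds of a partial-mitogenome region fully covering nad1
    and rrnL, mirroring the published 3,077 bp partial sequence."""
    nad1 = genome.get("nad1")
    rrnl = genome.get("rrnL")
    lo = min(nad1.start, rrnl.start)
    hi = max(nad1.end, rrnl.end)
    if hi - lo > length:
        raise ValueError("nad1+rrnL span exceeds the region length")
    pad = (length - (hi - lo)) // 2
    start = max(0, lo - pad)
    return start, start + length


# ---------------------------------------------------------------------------
# haplotype panels

def make_haplotype_panel(base: str, profiles: list[tuple[str, list[tuple[int, str]]]],
                         seed: int = 0) -> list[tuple[str, str]]:
    """Apply named SNP sets to a base sequence; one record per profile.

    Each profile is (name, [(position, alternate base), ...]).  Conflicting
    alternates at one position within a profile are an error.
    """
    base = base.upper()
    out = []
    for name, snps in profiles:
        seen: dict[int, str] = {}
        seq = list(base)
        for pos, alt in snps:
            if not 0 <= pos < len(base):
                raise ValueError(f"{name}: SNP position {pos} outside sequence")
            if pos in seen and seen[pos] != alt:
                raise ValueError(f"{name}: conflicting SNPs at position {pos}")
            seen[pos] = alt
            seq[pos] = alt.upper()
        out.append((name, "".join(seq)))
    return out


HAPLOTYPE_SOURCES = {
    "Western": ("JQ708095", "AY971885"),
    "Central": ("JQ708094", "FJ175374", "EF372597", "AY971888"),
    "Southwestern": ("KC305359",),
    "Northwestern": ("JQ708093", "KR534770", "KR534769", "KR534767",
                     "KR534766", "KR534765"),
}


def psyllid_haplotype_panel(genome: AnnotatedMitogenome, seed: int = 0,
                            region_offset: int = 60, region_length: int = 500):
    """Synthetic stand-ins for the four named cox1 haplotypes plus the
    M variant.

    The 500 bp classification region is taken from the genome's cox1 gene
    at a codon boundary; Western is the base sequence, Central differs by
    one synonymous third-position SNP, Southwestern by three, and
    Northwestern by four plus one non-synonymous second-position SNP
    (preferring a Thr->Ile change).  "M" is Northwestern plus one extra
    synonymous SNP, so it classifies as novel at distance 1.

    Returns (region sequence records, M record), both as (name, sequence).
    """
    if region_offset % 3:
        raise ValueError("region_offset must be a codon boundary")
    rng = np.random.default_rng(seed)
    cox1 = genome.feature_sequence("cox1")
    base = cox1[region_offset:region_offset + region_length]
    syn = synonymous_third_position_snps(base, 9, rng)
    nonsyn = _thr_ile_snp(base)
    profiles = [
        ("Western", []),
        ("Central", syn[0:1]),
        ("Southwestern", syn[1:4]),
        ("Northwestern", syn[4:8] + [nonsyn]),
    ]
    records = make_haplotype_panel(base, profiles)
    m_snp = syn[8]
    assert m_snp[0] not in {p for p, _ in profiles[3][1]}
    m_record = make_haplotype_panel(
        dict(records)["Northwestern"], [("M", [m_snp])])[0]
    return records, m_record


def _thr_ile_snp(region: str) -> tuple[int, str]:
    """A second-position SNP turning Thr (AC[TC]) into Ile, else any
    non-synonymous second-position change."""
    code = INVERTEBRATE_MITO.table
    fallback = None
    for c0 in range(0, len(region) - 2, 3):
        codon = region[c0:c0 + 3]
        if set(codon) - set("ACGT"):
            continue
        if codon in ("ACT", "ACC"):
            return c0 + 1, "T"
        if fallback is None:
            aa = code.get(codon)
            for b in "ACGT":
                alt = codon[0] + b + codon[2]
                if (b != codon[1] and alt not in INVERTEBRATE_MITO.stop_codons
                        and code.get(alt) not in (aa, None)):
                    fallback = (c0 + 1, b)
                    break
    if fallback is None:
        raise ValueError("no non-synonymous change available")
    return fallback


def synonymous_third_position_snps(cds_region: str, n: int, rng,
                                   frame_offset: int = 0
                                   ) -> list[tuple[int, str]]:
    """Pick n third-codon-position SNPs that leave the protein unchanged.

    ``frame_offset`` is the codon-position-1 offset of the region's first
    base within its gene frame.
    """
    code = INVERTEBRATE_MITO.table
    candidates = []
    start = (3 - frame_offset) % 3
    for c0 in range(start, len(cds_region) - 2, 3):
        codon = cds_region[c0:c0 + 3]
        if set(codon) - set("ACGT"):
            continue
        aa = code.get(codon)
        alts = [b for b in "ACGT"
                if b != codon[2] and code.get(codon[:2] + b) == aa]
        if aa and alts:
            candidates.append((c0 + 2, alts))
    if len(candidates) < n:
        raise ValueError("region too short for requested synonymous SNPs")
    picks = rng.choice(len(candidates), size=n, replace=False)
    return [(candidates[i][0],
             candidates[i][1][int(rng.integers(len(candidates[i][1])))])
            for i in sorted(picks)]


def exact_substitution_copy(genome: AnnotatedMitogenome,
                            region: tuple[int, int],
                            quotas: dict[str | None, int],
                            seed: int = 0) -> tuple[str, str, list[int]]:
    """A copy of a J-strand region carrying an exact number of substitutions.

    ``quotas`` maps gene names (or None for "anywhere else in the region")
    to substitution counts.  Substitutions never fall on protected sites
    and never create internal stops.  Returns (reference fragment, derived
    fragment, 0-based positions within the fragment).
    """
    rng = np.random.default_rng(seed)
    gene, codon_pos, protected = _site_annotations(genome)
    s0, s1 = region
    seq = list(genome.sequence.residues)
    L = len(seq)
    chosen: list[int] = []
    for gname, count in quotas.items():
        if gname is None:
            pool = [p for p in range(s0, s1)
                    if not protected[p] and gene[p] not in quotas]
        else:
            pool = [p for p in range(s0, s1)
                    if gene[p] == gname and not protected[p]]
        if len(pool) < count:
            raise ValueError(f"not enough sites for quota {gname}: {count}")
        chosen.extend(int(x) for x in rng.choice(pool, size=count,
                                                 replace=False))
    derived = list(seq)
    for p in sorted(chosen):
        old = derived[p]
        alts = [b for b in "ACGT" if b != old]
        rng.shuffle(alts)
        ok = False
        for alt in alts:
            derived[p] = alt
            if not _creates_internal_stop(derived, genome, p):
                ok = True
                break
        if not ok:
            derived[p] = old
            raise ValueError(f"cannot substitute position {p} without an "
                             "internal stop")
    ref_frag = "".join(seq[s0:s1])
    der_frag = "".join(derived[s0:s1])
    return ref_frag, der_frag, [p - s0 for p in sorted(chosen)]


def _creates_internal_stop(seq_list: list[str], genome: AnnotatedMitogenome,
                           p: int) -> bool:
    for f in genome.genes():
        if f.feature_class != "PCG":
            continue
        covered = False
        for s, e in f.spans:
            if s <= p < e:
                covered = True
        if not covered:
            continue
        pos = f.positions(len(seq_list))
        order = pos if f.strand == "J" else pos[::-1]
        k = order.index(p)
        off = k - (f.codon_start - 1)
        if off < 0:
            continue
        c0 = k - off % 3
        tri = order[c0:c0 + 3]
        if len(tri) < 3:
            continue
        codon = "".join(seq_list[q] if f.strand == "J"
                        else reverse_complement(seq_list[q]) for q in tri)
        if codon in INVERTEBRATE_MITO.stop_codons:
            return True
    return False
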