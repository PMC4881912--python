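"""Reading, writing and the in-memory model of annotated circular mitogenomes.

The central object is :class:`AnnotatedMitogenome`: a circular (or linear)
DNA sequence plus a feature table.  All coordinates are 0-based half-open on
the deposited strand, which is taken to be the J-strand (the majority strand
of an insect mitogenome).  A feature that wraps the origin of the circle is
represented by exactly two spans ``[s, L)`` and ``[0, e)``.

GenBank flat files are parsed with Biopython; the 1-based inclusive GenBank
convention is converted at this boundary and nowhere else.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularSequence",
    "Feature",
    "AnnotatedMitogenome",
    "MitoIOError",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "reverse_complement",
]

IUPAC_DNA = set("ACGTUNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")

# canonical labels for the 37 genes of the ancestral insect mitogenome
PCG_NAMES = ("nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
             "nad5", "nad4", "nad4L", "nad6", "cob", "nad1")
RRNA_NAMES = ("rrnL", "rrnS")

_NAME_SYNONYMS = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nad4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cytb": "cob", "cob": "cob", "ctyb": "cob",
    "atp6": "atp6", "atp8": "atp8",
    "16s": "rrnL", "rrnl": "rrnL", "l-rrna": "rrnL", "16s rrna": "rrnL",
    "12s": "rrnS", "rrns": "rrnS", "s-rrna": "rrnS", "12s rrna": "rrnS",
}


class MitoIOError(ValueError):
    """Raised on malformed input files or inconsistent feature tables."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_gene_name(raw: str) -> str:
    """Map common GenBank gene labels onto this package's canonical names."""
    key = raw.strip().lower()
    return _NAME_SYNONYMS.get(key, raw.strip())


@dataclass(frozen=True)
class CircularSequence:
    """A DNA sequence with explicit topology.

    ``residues`` are stored uppercase and must be IUPAC DNA symbols.
    """

    residues: str
    topology: str = "circular"

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise MitoIOError("empty sequence")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise MitoIOError(f"non-IUPAC symbols in sequence: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise MitoIOError(f"bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def fragment(self, start: int, end: int) -> str:
        """J-strand substring [start, end); end may exceed L on a circle."""
        L = len(self)
        if end <= L:
            return self.residues[start:end]
        if self.topology != "circular":
            raise MitoIOError("fragment runs past the end of a linear sequence")
        return self.residues[start:] + self.residues[: end - L]


@dataclass(frozen=True)
class Feature:
    """An annotated gene/region on the J-strand coordinate system.

    ``spans`` holds one span, or two when the feature wraps the origin
    (``[s, L)`` then ``[0, e)``).  ``strand`` is ``"J"`` for the deposited
    strand and ``"N"`` for its reverse complement.  ``incomplete_stop`` is
    ``"T"`` or ``"TA"`` for PCGs whose stop codon is completed by
    polyadenylation, else ``None``.
    """

    name: str
    feature_class: str          # PCG | tRNA | rRNA | noncoding
    strand: str                 # J | N
    spans: tuple[tuple[int, int], ...]
    codon_start: int = 1
    incomplete_stop: str | None = None

    def __post_init__(self):
        if self.feature_class not in ("PCG", "tRNA", "rRNA", "noncoding"):
            raise MitoIOError(f"bad feature_class {self.feature_class!r}")
        if self.strand not in ("J", "N"):
            raise MitoIOError(f"bad strand {self.strand!r}")
        if len(self.spans) not in (1, 2):
            raise MitoIOError("a feature has one span, or two when wrapping")
        for s, e in self.spans:
            if s < 0 or e <= s:
                raise MitoIOError(f"bad span [{s},{e}) in {self.name}")
        if self.codon_start not in (1, 2, 3):
            raise MitoIOError("codon_start must be 1, 2 or 3")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.spans)

    @property
    def wraps(self) -> bool:
        return len(self.spans) == 2

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def end(self) -> int:
        return self.spans[-1][1]

    def positions(self, genome_length: int) -> range | list[int]:
        """All J-strand positions covered, in 5'→3' J order."""
        out: list[int] = []
        for s, e in self.spans:
            out.extend(range(s, e))
        return out

    def j_sequence(self, seq: CircularSequence) -> str:
        return "".join(seq.residues[s:e] for s, e in self.spans)

    def sense_sequence(self, seq: CircularSequence) -> str:
        """The feature's own (coding/sense) strand sequence."""
        j = self.j_sequence(seq)
        return reverse_complement(j) if self.strand == "N" else j


@dataclass
class AnnotatedMitogenome:
    sequence: CircularSequence
    features: list[Feature] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        L = len(self.sequence)
        seen: set[tuple[str, str]] = set()
        for f in self.features:
            for s, e in f.spans:
                if e > L:
                    raise MitoIOError(
                        f"feature {f.name} span [{s},{e}) outside genome of {L} bp")
            key = (f.feature_class, f.name)
            if key in seen:
                raise MitoIOError(
                    f"duplicate feature name {f.name!r} within class {f.feature_class}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sequence)

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def genes(self) -> list[Feature]:
        """Features that count as genes (noncoding annotations excluded)."""
        return [f for f in self.features if f.feature_class != "noncoding"]

    def feature_sequence(self, name: str) -> str:
        return self.get(name).sense_sequence(self.sequence)


# ---------------------------------------------------------------------------
# GenBank

def _location_to_spans(loc, L: int) -> tuple[tuple[tuple[int, int], ...], str]:
    """Convert a Biopython location to (spans, strand) in J coordinates."""
    strand = "N" if loc.strand == -1 else "J"
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    spans = sorted((int(p.start), int(p.end)) for p in parts)
    if len(spans) == 1:
        return (spans[0],), strand
    if len(spans) == 2 and spans[1][1] == L and spans[0][0] == 0:
        # join over the origin: report [s, L) then [0, e)
        return (spans[1], spans[0]), strand
    if len(spans) == 2:
        return tuple(spans), strand
    raise MitoIOError(f"unsupported compound location with {len(spans)} parts")


def _classify(ftype: str) -> str | None:
    return {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
            "D-loop": "noncoding", "misc_feature": "noncoding"}.get(ftype)


def read_genbank(path) -> AnnotatedMitogenome:
    """Read a GenBank flat file into an :class:`AnnotatedMitogenome`.

    CDS entries become PCG features; ``complement(...)`` maps to strand N;
    a ``join(...)`` across the origin maps to a two-span wrapping feature.
    Topology comes from the LOCUS line (circular unless stated linear).
    """
    try:
        record = SeqIO.read(path, "genbank")
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise MitoIOError(f"cannot parse GenBank file {path}: {exc}") from exc
    topology = record.annotations.get("topology", "circular")
    seq = CircularSequence(str(record.seq), topology=topology)
    L = len(seq)

    features: list[Feature] = []
    seen: set[tuple[str, str]] = set()
    for sf in record.features:
        fclass = _classify(sf.type)
        if fclass is None:
            continue
        quals = sf.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note")
               or [sf.type])[0]
        name = canonical_gene_name(raw)
        spans, strand = _location_to_spans(sf.location, L)
        codon_start = int(quals.get("codon_start", ["1"])[0])
        incomplete = None
        if fclass == "PCG":
            length = sum(e - s for s, e in spans)
            rem = (length - codon_start + 1) % 3
            if rem:
                # infer the incomplete stop from the terminal residues
                tmp = Feature(name, "PCG", strand, spans, codon_start)
                sense = tmp.sense_sequence(seq)
                tail = sense[-rem:]
                if (rem, tail) in ((1, "T"), (2, "TA")):
                    incomplete = tail
                else:
                    warnings.warn(
                        f"CDS {name}: length {length} violates the codon "
                        "invariant and no T/TA incomplete stop is present; "
                        "feature kept with codon_start flag only")
        note = quals.get("note", [""])[0].lower()
        if incomplete is None and fclass == "PCG" and "incomplete" in note:
            incomplete = "T"
        key = (fclass, name)
        if key in seen:
            continue  # e.g. paired gene + CDS entries
        seen.add(key)
        features.append(Feature(name, fclass, strand, spans, codon_start,
                                incomplete))
    meta = {
        "accession": record.id,
        "organism": record.annotations.get("organism", ""),
        "source_file": str(path),
        "description": record.description,
    }
    return AnnotatedMitogenome(seq, features, meta)


_FEATURE_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                 "noncoding": "misc_feature"}


def write_genbank(genome: AnnotatedMitogenome, path) -> None:
    """Write a genome back to a GenBank flat file (round-trip safe)."""
    L = len(genome)
    record = SeqRecord(
        Seq(genome.sequence.residues),
        id=genome.metadata.get("accession", "SYN000001"),
        name=genome.metadata.get("accession", "SYN000001")[:16],
        description=genome.metadata.get("description", "synthetic mitogenome"),
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = genome.sequence.topology
    record.annotations["organism"] = genome.metadata.get("organism", "")
    for f in genome.features:
        bstrand = -1 if f.strand == "N" else 1
        locs = [SimpleLocation(s, e, strand=bstrand) for s, e in f.spans]
        if f.wraps and bstrand == -1:
            locs = locs[::-1]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.feature_class == "PCG":
            quals["codon_start"] = [str(f.codon_start)]
            if f.incomplete_stop:
                quals["note"] = [f"incomplete stop codon ({f.incomplete_stop})"]
        record.features.append(SeqFeature(loc, type=_FEATURE_TYPE[f.feature_class],
                                          qualifiers=quals))
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(records: list[tuple[str, str]], path_or_handle) -> None:
    """Write (name, sequence) records as 70-column wrapped FASTA."""
    if not records:
        raise MitoIOError("refusing to write an empty FASTA file")
    names = [n for n, _ in records]
    if len(set(names)) != len(names):
        raise MitoIOError("duplicate record names in FASTA output")
    if any(not n for n in names):
        raise MitoIOError("empty record name")
    own = isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__")
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    finally:
        if own:
            fh.close()


def read_fasta(path_or_handle) -> list[tuple[str, str]]:
    records = [(r.id if r.description == r.id else r.description.split()[0],
                str(r.seq).upper())
               for r in SeqIO.parse(path_or_handle, "fasta")]
    if not records:
        raise MitoIOError("no FASTA records found")
    return records


def read_alignment(path_or_handle):
    """Read an aligned FASTA into a MultipleAlignment (gap symbol '-')."""
    from .alignment import MultipleAlignment

    records = read_fasta(path_or_handle)
    width = len(records[0][1])
    for i, (name, seq) in enumerate(records, start=1):
        if len(seq) != width:
            raise MitoIOError(
                f"alignment rows differ in length: record {i} ({name!r}) has "
                f"{len(seq)} columns, expected {width}")
    return MultipleAlignment([n for n, _ in records], [s for _, s in records])


def write_alignment(aln, path_or_handle) -> None:
    write_fasta(list(zip(aln.names, aln.rows)), path_or_handle)


def genome_from_string(residues: str, features=(), topology: str = "circular",
                       **metadata) -> AnnotatedMitogenome:
    """Convenience constructor used throughout the test-suite and simulator."""
    return AnnotatedMitogenome(CircularSequence(residues, topology),
                               list(features), dict(metadata))


def rotate_genome(genome: AnnotatedMitogenome, offset: int
                  ) -> AnnotatedMitogenome:
    """Move the origin of a circular genome to ``offset``.

    Features crossing the new origin become two-span wrapping features;
    previously wrapping features may become contiguous.
    """
    if genome.sequence.topology != "circular":
        raise MitoIOError("cannot rotate a linear sequence")
    L = len(genome)
    offset %= L
    seq = genome.sequence.residues
    new_seq = seq[offset:] + seq[:offset]
    new_features = []
    for f in genome.features:
        start = (f.start - offset) % L
        length = f.length
        if start + length <= L:
            spans: tuple = ((start, start + length),)
        else:
            spans = ((start, L), (0, start + length - L))
        new_features.append(replace(f, spans=spans))
    return AnnotatedMitogenome(CircularSequence(new_seq, "circular"),
                               new_features, dict(genome.metadata))
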