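"""Translation under the invertebrate mitochondrial code, start/stop codon
bookkeeping, amino-acid usage and relative synonymous codon usage (RSCU).

The genetic code is NCBI translation table 5, under which AGA/AGG encode
serine and ATA encodes methionine.  Incomplete stop codons (a trailing T or
TA completed to TAA by polyadenylation) are recognised and excluded from
codon counts: they are not codons.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio.Data import CodonTable

from .mito_io import AnnotatedMitogenome, PCG_NAMES

__all__ = [
    "GeneticCode", "INVERTEBRATE_MITO", "CodonReport", "translate",
    "extract_codon_report", "amino_acid_usage", "rscu",
    "load_reference_pcg_table", "encoded_residue_total",
]

_BASES = "TCAG"


@dataclass(frozen=True)
class GeneticCode:
    """A codon table plus permitted start and stop codon sets."""

    table: dict          # codon -> one-letter amino acid (stops excluded)
    start_codons: frozenset
    stop_codons: frozenset

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(dict(t.forward_table), frozenset(t.start_codons),
                   frozenset(t.stop_codons))

    def families(self) -> dict[str, list[str]]:
        """Synonymous codon families keyed by amino acid."""
        fam: dict[str, list[str]] = {}
        for codon, aa in sorted(self.table.items()):
            fam.setdefault(aa, []).append(codon)
        return fam


INVERTEBRATE_MITO = GeneticCode.from_ncbi_id(5)


class InternalStopError(ValueError):
    pass


def _codons(cds: str, codon_start: int = 1):
    body = cds[codon_start - 1:]
    return [body[i:i + 3] for i in range(0, len(body) - len(body) % 3, 3)]


def translate(cds: str, code: GeneticCode = INVERTEBRATE_MITO,
              codon_start: int = 1) -> str:
    """Translate a sense-strand CDS, stopping before the trailing stop.

    A trailing complete stop codon, or an incomplete T/TA stop, is not
    translated.  Codons containing ambiguity codes become ``X``.  An
    in-frame stop before the terminus raises :class:`InternalStopError`.
    """
    cds = cds.upper()
    cods = _codons(cds, codon_start)
    if cods and cods[-1] in code.stop_codons:
        cods = cods[:-1]
    if not cods:
        raise ValueError("empty effective coding sequence")
    out = []
    for i, c in enumerate(cods):
        if c in code.stop_codons:
            raise InternalStopError(
                f"internal stop codon {c} at codon {i + 1}")
        out.append(code.table.get(c, "X"))
    return "".join(out)


@dataclass(frozen=True)
class CodonReport:
    gene: str
    start_codon: str
    stop_codon: str          # TAA | TAG | TA | T
    length_bp: int
    protein_length_aa: int
    incomplete_stop: bool


def _gene_report(name: str, sense: str, codon_start: int,
                 code: GeneticCode) -> CodonReport:
    body = sense[codon_start - 1:]
    rem = len(body) % 3
    if rem == 0:
        tail = body[-3:]
        if tail not in code.stop_codons:
            raise ValueError(f"{name}: no stop codon at terminus ({tail})")
        stop, incomplete = tail, False
    elif rem == 1 and body.endswith("T"):
        stop, incomplete = "T", True
    elif rem == 2 and body.endswith("TA"):
        stop, incomplete = "TA", True
    else:
        raise ValueError(f"{name}: length {len(sense)} has no complete or "
                         "incomplete (T/TA) stop codon")
    protein = translate(sense, code, codon_start)
    n_aa = (len(sense) - codon_start + 1 - len(stop)) // 3
    assert n_aa == len(protein)
    return CodonReport(name, body[:3], stop, len(sense), n_aa, incomplete)


def extract_codon_report(genome: AnnotatedMitogenome,
                         code: GeneticCode = INVERTEBRATE_MITO
                         ) -> list[CodonReport]:
    """Start/stop codons and lengths for every PCG, in canonical gene order."""
    reports = []
    by_name = {f.name: f for f in genome.features if f.feature_class == "PCG"}
    order = [g for g in PCG_NAMES if g in by_name] + \
            sorted(set(by_name) - set(PCG_NAMES))
    for name in order:
        f = by_name[name]
        reports.append(_gene_report(name, f.sense_sequence(genome.sequence),
                                    f.codon_start, code))
    return reports


def _coding_codons(genome: AnnotatedMitogenome, code: GeneticCode):
    """All complete non-stop codons of all PCGs (terminal stops excluded)."""
    for f in genome.features:
        if f.feature_class != "PCG":
            continue
        sense = f.sense_sequence(genome.sequence)
        cods = _codons(sense, f.codon_start)
        if cods and cods[-1] in code.stop_codons:
            cods = cods[:-1]
        for c in cods:
            if set(c) <= set("ACGT") and c not in code.stop_codons:
                yield c


def amino_acid_usage(genomes, code: GeneticCode = INVERTEBRATE_MITO
                     ) -> pd.Series:
    """Residue usage percentages over all PCGs of one or more genomes.

    Leucine is split into Leu-UUR (TTA/TTG) and Leu-CUN, serine into
    Ser-AGN and Ser-UCN, mirroring their distinct tRNAs.  Start codons
    count as their table-5 amino acid.
    """
    if isinstance(genomes, AnnotatedMitogenome):
        genomes = [genomes]
    counts: dict[str, int] = {}
    total = 0
    for g in genomes:
        for codon in _coding_codons(g, code):
            aa = code.table[codon]
            if aa == "L":
                key = "Leu-UUR" if codon in ("TTA", "TTG") else "Leu-CUN"
            elif aa == "S":
                key = "Ser-AGN" if codon.startswith("AG") else "Ser-UCN"
            else:
                key = _THREE_LETTER.get(aa, aa)
            counts[key] = counts.get(key, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("no codons found")
    ser = pd.Series({k: 100.0 * v / total for k, v in counts.items()})
    return ser.sort_values(ascending=False)


_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "M": "Met",
    "F": "Phe", "P": "Pro", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def rscu(genomes, code: GeneticCode = INVERTEBRATE_MITO) -> pd.DataFrame:
    """RSCU per codon: observed count over the within-family mean count.

    Within each synonymous family the RSCU values sum to the family size.
    Families with zero total count get NaN (undefined, not zero).  Stop
    codons are excluded.
    """
    if isinstance(genomes, AnnotatedMitogenome):
        genomes = [genomes]
    counts = {c: 0 for c in code.table}
    for g in genomes:
        for codon in _coding_codons(g, code):
            counts[codon] += 1
    rows = []
    for aa, fam in sorted(code.families().items()):
        fam_total = sum(counts[c] for c in fam)
        mean = fam_total / len(fam)
        for c in fam:
            val = counts[c] / mean if fam_total else float("nan")
            rows.append({"codon": c, "amino_acid": aa, "count": counts[c],
                         "rscu": val, "family_size": len(fam)})
    return pd.DataFrame(rows).set_index("codon")


# ---------------------------------------------------------------------------
# the published Psylloidea PCG/rRNA table (printed lengths and codons)

def load_reference_pcg_table() -> pd.DataFrame:
    """Published start/stop codons and gene lengths for the four psyllid
    mitogenomes, as a long-format DataFrame."""
    with resources.files("psyllomito.data").joinpath(
            "psylloidea_pcg_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def encoded_residue_total(table: pd.DataFrame, species: str) -> int:
    """Total encoded residues over the 13 PCGs of one species.

    Computed from printed gene lengths and stop-codon completeness: a
    complete TAA/TAG stop occupies 3 bp, an incomplete TA or T stop 2 or
    1 bp; the remainder is coding and contributes length/3 residues.
    """
    sub = table[(table.species == species) & (table.gene.isin(PCG_NAMES))]
    if len(sub) != 13:
        raise ValueError(f"expected 13 PCG rows for {species}, got {len(sub)}")
    total = 0
    for _, row in sub.iterrows():
        stop_len = len(row.stop_codon)   # TAA/TAG=3, TA=2, T=1
        coding = row.length_bp - stop_len
        if coding % 3:
            raise ValueError(f"{row.gene}: coding length {coding} not a "
                             "codon multiple")
        total += coding // 3
    return total
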