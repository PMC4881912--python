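"""Nucleotide diversity (π), sliding-window diversity tracks, SNP calling
and cox1 haplotype classification.

π follows the DnaSP-style pairwise-deletion convention: for each pair of
rows, a valid site is a column where both rows carry an unambiguous base
(no gap, no ambiguity code); the pair's contribution is differences over
valid sites, and π is the average over all row pairs.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, MultipleAlignment, pairwise_align

__all__ = [
    "DiversityTrack", "SnpRecord", "HaplotypeProfile", "HaplotypeRegion",
    "nucleotide_diversity", "sliding_window_pi", "call_snps",
    "build_profiles", "classify_haplotype",
]

_VALID = np.frombuffer(b"ACGT", dtype="S1")


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    return np.isin(arr, _VALID)


def nucleotide_diversity(aln: MultipleAlignment,
                         region: tuple[int, int] | None = None) -> float:
    """Average pairwise proportion of differing valid sites (π).

    Returns NaN when no pair has any valid site.
    """
    if aln.n_rows < 2:
        raise ValueError("π needs at least two rows")
    arr = aln.to_array()
    if region is not None:
        arr = arr[:, region[0]:region[1]]
    valid = _valid_mask(arr)
    vals = []
    n = arr.shape[0]
    for i in range(n):
        for k in range(i + 1, n):
            both = valid[i] & valid[k]
            m = int(both.sum())
            if m:
                vals.append(int((arr[i][both] != arr[k][both]).sum()) / m)
    return float(np.mean(vals)) if vals else math.nan


@dataclass
class DiversityTrack:
    name: str
    windows: list[tuple[int, int, float]]     # (start, end, π)
    mean_pi: float
    whole_pi: float

    @property
    def max_pi(self) -> float:
        finite = [p for _, _, p in self.windows if not math.isnan(p)]
        return max(finite) if finite else math.nan


def sliding_window_pi(aln: MultipleAlignment, window: int = 250,
                      step: int = 25, name: str = "",
                      keep_partial: bool = False) -> DiversityTrack:
    """π in sliding windows over alignment columns.

    Windows start at 0, window, ... advancing by ``step``; only full
    windows are evaluated unless ``keep_partial``.  An alignment shorter
    than one window yields a single full-length window with a warning.
    """
    L = aln.n_cols
    spans: list[tuple[int, int]] = []
    if L < window:
        warnings.warn(f"alignment ({L} columns) shorter than the {window} bp "
                      "window; using one full-length window")
        spans = [(0, L)]
    else:
        start = 0
        while start + window <= L:
            spans.append((start, start + window))
            start += step
        if keep_partial and spans[-1][1] < L:
            spans.append((spans[-1][0] + step, L))
    out = [(s, e, nucleotide_diversity(aln, (s, e))) for s, e in spans]
    finite = [p for _, _, p in out if not math.isnan(p)]
    mean_pi = float(np.mean(finite)) if finite else math.nan
    return DiversityTrack(name, out, mean_pi, nucleotide_diversity(aln))


# ---------------------------------------------------------------------------
# SNP calling

@dataclass(frozen=True)
class SnpRecord:
    column: int                      # 1-based alignment column
    reference: str
    alternates: tuple[str, ...]
    codon_position: int | None       # 1/2/3 or None when no frame given
    synonymous: bool | None


def call_snps(aln: MultipleAlignment, reference: str,
              frame: tuple[int, int, int] | None = None,
              code=None) -> list[SnpRecord]:
    """Columns where a non-reference unambiguous state occurs.

    Columns containing a gap in any row are indel columns and are not
    reported as SNPs.  ``frame`` annotates codon position and synonymy:
    it is ``(gene_start_col, gene_end_col, codon_start)`` in 0-based
    reference-row ungapped coordinates.
    """
    if code is None:
        from .codons import INVERTEBRATE_MITO as code
    ref_row = aln.row(reference)
    arr = aln.to_array()
    iref = aln.names.index(reference)
    valid = _valid_mask(arr)
    gap_col = (arr == GAP.encode()).any(axis=0)

    # map alignment columns to ungapped reference coordinates
    ref_arr = np.frombuffer(ref_row.encode(), dtype="S1")
    ungapped_pos = np.cumsum(ref_arr != GAP.encode()) - 1
    ref_ungapped = ref_row.replace(GAP, "")

    records = []
    for col in range(aln.n_cols):
        if gap_col[col] or not valid[iref, col]:
            continue
        ref_base = arr[iref, col].decode()
        alts = sorted({arr[r, col].decode() for r in range(aln.n_rows)
                       if r != iref and valid[r, col]
                       and arr[r, col] != arr[iref, col]})
        if not alts:
            continue
        codon_pos = syn = None
        if frame is not None:
            gs, ge, cs = frame
            p = int(ungapped_pos[col])
            if gs + cs - 1 <= p < ge:
                off = p - (gs + cs - 1)
                codon_pos = off % 3 + 1
                c0 = gs + cs - 1 + (off // 3) * 3
                codon = ref_ungapped[c0:c0 + 3]
                if len(codon) == 3 and set(codon) <= set("ACGT"):
                    syn = all(
                        code.table.get(codon[:off % 3] + a + codon[off % 3 + 1:])
                        == code.table.get(codon) for a in alts)
        records.append(SnpRecord(col + 1, ref_base, tuple(alts),
                                 codon_pos, syn))
    return records


# ---------------------------------------------------------------------------
# haplotype classification over a fixed cox1 region

@dataclass(frozen=True)
class HaplotypeRegion:
    """The classification region: an anchor sequence and its coordinates.

    ``anchor`` is the reference sequence of the region (conventionally the
    Western-haplotype segment of cox1); fingerprints are states at
    ``columns`` (0-based positions within the anchor).
    """

    anchor: str
    columns: tuple[int, ...]


@dataclass(frozen=True)
class HaplotypeProfile:
    name: str
    sequence: str                         # full region states
    fingerprint: tuple[str, ...]          # states at region.columns
    source_accessions: tuple[str, ...] = ()


def build_profiles(named_sequences: list[tuple[str, str]],
                   sources: dict[str, tuple[str, ...]] | None = None
                   ) -> tuple[HaplotypeRegion, list[HaplotypeProfile]]:
    """Derive a region definition and profiles from reference sequences.

    All sequences must be the same length (the region is assumed gap-free
    among conspecific haplotypes); the defining columns are the variable
    positions among the references, and the first sequence is the anchor.
    """
    if not named_sequences:
        raise ValueError("no reference sequences")
    L = {len(s) for _, s in named_sequences}
    if len(L) != 1:
        raise ValueError("haplotype reference sequences differ in length")
    seqs = [s.upper() for _, s in named_sequences]
    cols = tuple(i for i in range(len(seqs[0]))
                 if len({s[i] for s in seqs}) > 1)
    region = HaplotypeRegion(seqs[0], cols)
    profiles = [HaplotypeProfile(name, seq.upper(),
                                 tuple(seq.upper()[i] for i in cols),
                                 (sources or {}).get(name, ()))
                for name, seq in named_sequences]
    return region, profiles


def classify_haplotype(query: str, region: HaplotypeRegion,
                       profiles: list[HaplotypeProfile],
                       min_coverage: float = 0.9):
    """Assign a query cox1 fragment to a haplotype, or call it novel.

    The query is globally aligned to the region anchor and compared to each
    profile over the whole region (positions the query covers with an
    unambiguous base).  A zero-distance profile gives that label; otherwise
    the label is "novel" and distances to every profile are reported, so a
    variant one SNP away from a named haplotype is detected even when the
    SNP falls outside the profile-defining columns.
    """
    _, aln = pairwise_align(region.anchor, query.upper(),
                            names=("anchor", "query"))
    anchor_row, query_row = aln.rows
    covered = sum(1 for x, y in zip(anchor_row, query_row)
                  if x != GAP and y != GAP)
    if covered / len(region.anchor) < min_coverage:
        raise ValueError(
            f"query covers only {covered}/{len(region.anchor)} anchor bases "
            f"({100 * covered / len(region.anchor):.1f}% < "
            f"{100 * min_coverage:.0f}%)")
    # anchor-coordinate states of the query
    states: dict[int, str] = {}
    p = -1
    for x, y in zip(anchor_row, query_row):
        if x != GAP:
            p += 1
            if y in "ACGT":
                states[p] = y
    distances = {
        prof.name: sum(1 for p, b in states.items()
                       if prof.sequence[p] in "ACGT" and b != prof.sequence[p])
        for prof in profiles}
    for prof in profiles:
        if distances[prof.name] == 0:
            return prof.name, distances
    return "novel", distances
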