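"""In-silico PCR on circular templates: primer site search and amplicon
prediction, used to verify genome circularity (a product spanning the
origin can only form on a circular molecule).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mito_io import CircularSequence, reverse_complement

__all__ = ["PrimerPair", "PrimerSite", "AmpliconPrediction",
           "find_primer_sites", "predict_amplicon", "AmpliconError"]


class AmpliconError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    max_mismatches: int = 0

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if len(p) < 10:
                raise ValueError("primers must be at least 10 nt")


@dataclass(frozen=True)
class PrimerSite:
    position: int        # 5' position of the primer on its strand, in [0, L)
    strand: str          # J | N
    mismatches: int


@dataclass(frozen=True)
class AmpliconPrediction:
    forward_site: PrimerSite
    reverse_site: PrimerSite
    length_bp: int
    wraps_origin: bool


def _scan(template: np.ndarray, primer: str, L: int, kmax: int,
          circular: bool) -> list[tuple[int, int]]:
    """(start, mismatches) of primer occurrences on a linear byte array,
    scanning around the origin when circular."""
    p = np.frombuffer(primer.encode(), dtype="S1")
    k = len(p)
    n_starts = L if circular else L - k + 1
    if n_starts <= 0:
        return []
    hits = []
    for s in range(n_starts):
        window = template[s:s + k]
        mm = int((window != p).sum())
        if mm <= kmax:
            hits.append((s, mm))
    return hits


def find_primer_sites(genome: CircularSequence, primer: str,
                      max_mismatches: int = 0) -> list[PrimerSite]:
    """All binding sites of a primer on both strands.

    On a circular template the search wraps the origin (the sequence is
    doubled around it).  A site's ``position`` is the primer's 5' end on
    its own strand: for a J hit the leftmost matched base, for an N hit
    the rightmost matched base in J coordinates.
    """
    primer = primer.upper().replace(" ", "")
    L = len(genome)
    circular = genome.topology == "circular"
    doubled = genome.residues + (genome.residues[:len(primer) - 1]
                                 if circular else "")
    arr = np.frombuffer(doubled.encode(), dtype="S1")
    sites = []
    for s, mm in _scan(arr, primer, L, max_mismatches, circular):
        sites.append(PrimerSite(s % L, "J", mm))
    rc = reverse_complement(primer)
    for s, mm in _scan(arr, rc, L, max_mismatches, circular):
        # rc match at [s, s+k): primer 5' end sits at the right edge
        sites.append(PrimerSite((s + len(primer) - 1) % L, "N", mm))
    sites.sort(key=lambda t: (t.position, t.strand))
    return sites


def predict_amplicon(genome: CircularSequence, pair: PrimerPair
                     ) -> AmpliconPrediction:
    """The PCR product for a primer pair on a (possibly circular) template.

    A productive configuration has the forward primer on one strand and the
    reverse primer on the other with 3' ends facing; the product length is
    the circular distance from the forward 5' end to the reverse 5' end,
    inclusive of both primers.  On a circular template every facing pair has
    two arcs; the shorter one is reported.
    """
    L = len(genome)
    fwd_sites = find_primer_sites(genome, pair.forward, pair.max_mismatches)
    rev_sites = find_primer_sites(genome, pair.reverse, pair.max_mismatches)
    circular = genome.topology == "circular"
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.strand == r.strand:
                continue
            if f.strand == "J":
                span = (r.position - f.position) % L + 1
                wraps = r.position < f.position
            else:
                span = (f.position - r.position) % L + 1
                wraps = f.position < r.position
            if not circular and wraps:
                continue
            if span <= max(len(pair.forward), len(pair.reverse)):
                continue  # degenerate overlap of the two primers
            products.append(AmpliconPrediction(f, r, span, wraps))
    if not products:
        raise AmpliconError("no amplicon: no productive primer orientation")
    products.sort(key=lambda a: a.length_bp)
    distinct = {(a.forward_site, a.reverse_site) for a in products}
    if len(distinct) > 1:
        # a circular template always offers the complementary long arc for
        # the same site pair; only distinct site pairs count as multiple
        site_pairs = {(a.forward_site.position, a.reverse_site.position)
                      for a in products}
        if len(site_pairs) > 1:
            lengths = sorted(a.length_bp for a in products)
            raise AmpliconError(
                f"multiple products predicted (lengths {lengths})")
    return products[0]
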