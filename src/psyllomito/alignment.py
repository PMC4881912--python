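"""Global alignment with affine gap costs, progressive MSA, and codon-aware
(back-translated) nucleotide alignments.

One Gotoh dynamic-programming engine serves both sequence-sequence and
profile-profile alignment: a sequence is a one-row profile.  A gap of
length k costs ``gap_open + k * gap_extend`` (both penalties positive).
Default protein parameters follow the Clustal-style settings commonly used
for mitochondrial PCG alignments: the Gonnet matrix with gap opening 35 /
extension 0.75 for pairs and 15 / 0.3 for multiple alignment.

Traceback tie-breaking is deterministic: diagonal (match/mismatch) is
preferred over a gap in the second sequence, which is preferred over a gap
in the first.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "MultipleAlignment", "AlignmentParams", "DNA_DEFAULTS",
    "PROTEIN_PAIRWISE_DEFAULTS", "PROTEIN_MSA_DEFAULTS",
    "pairwise_align", "progressive_msa", "codon_aware_alignment",
]

GAP = "-"
_NEG = -1e30


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters; ``matrix`` overrides match/mismatch when set."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 2.0
    gap_extend: float = 1.0
    matrix: str | None = None        # name of a Biopython substitution matrix

    def scoring(self) -> tuple[str, np.ndarray]:
        """(alphabet, score matrix) for single symbols."""
        if self.matrix is None:
            alphabet = "ACGTUN"
            n = len(alphabet)
            S = np.full((n, n), self.mismatch, dtype=np.float32)
            np.fill_diagonal(S, self.match)
            iN = alphabet.index("N")
            S[iN, :] = S[:, iN] = 0.0    # ambiguity scores neutrally
            return alphabet, S
        m = substitution_matrices.load(self.matrix)
        alphabet = str(m.alphabet)
        return alphabet, np.asarray(m, dtype=np.float32)


DNA_DEFAULTS = AlignmentParams(match=1.0, mismatch=-1.0,
                               gap_open=5.0, gap_extend=0.5)
PROTEIN_PAIRWISE_DEFAULTS = AlignmentParams(gap_open=35.0, gap_extend=0.75,
                                            matrix="GONNET1992")
PROTEIN_MSA_DEFAULTS = AlignmentParams(gap_open=15.0, gap_extend=0.3,
                                       matrix="GONNET1992")


@dataclass
class MultipleAlignment:
    """Named rows of equal length; gap symbol '-'."""

    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate row names")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows differ in length: {sorted(widths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def ungapped(self, name: str) -> str:
        return self.row(name).replace(GAP, "")

    def slice(self, start: int, end: int) -> "MultipleAlignment":
        return MultipleAlignment(list(self.names),
                                 [r[start:end] for r in self.rows])

    def to_array(self) -> np.ndarray:
        """(n_rows, n_cols) array of single-byte symbols."""
        return np.frombuffer("".join(self.rows).encode(),
                             dtype="S1").reshape(self.n_rows, self.n_cols)


# ---------------------------------------------------------------------------
# the DP engine

def _profile_freqs(rows: list[str], alphabet: str) -> np.ndarray:
    """(n_cols, |alphabet|) non-gap symbol frequencies per column."""
    idx = {c: i for i, c in enumerate(alphabet)}
    n_cols = len(rows[0])
    F = np.zeros((n_cols, len(alphabet)), dtype=np.float32)
    for r in rows:
        for j, ch in enumerate(r):
            if ch != GAP:
                k = idx.get(ch)
                if k is not None:
                    F[j, k] += 1.0
    return F / max(len(rows), 1)


def _gotoh(M_scores: np.ndarray, go: float, ge: float):
    """Affine-gap global DP over a precomputed column-pair score matrix.

    Returns (score, operations) where operations is a list of 'D' (pair of
    columns), 'U' (column of A against gaps) and 'L' (column of B against
    gaps) read 5'->3'.
    """
    n, m = M_scores.shape
    go, ge = float(go), float(ge)
    M = np.full(m + 1, _NEG, dtype=np.float64)
    Ix = np.full(m + 1, _NEG, dtype=np.float64)   # gap columns in B (up)
    Iy = np.full(m + 1, _NEG, dtype=np.float64)   # gap columns in A (left)
    M[0] = 0.0
    j = np.arange(1, m + 1, dtype=np.float64)
    Iy[1:] = -(go + j * ge)
    # pointer codes per cell: which of (M, Ix, Iy) fed each matrix
    ptrM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    for i in range(1, n + 1):
        prevM, prevX, prevY = M, Ix, Iy
        M = np.full(m + 1, _NEG)
        Ix = np.empty(m + 1)
        Iy = np.full(m + 1, _NEG)
        # vertical gaps: extend down
        openx = prevM - (go + ge)
        extx = prevX - ge
        Ix = np.where(openx >= extx, openx, extx)
        ptrX[i] = np.where(openx >= extx, 0, 1)
        Ix[0] = -(go + i * ge)
        ptrX[i, 0] = 0 if i == 1 else 1
        # diagonal
        best_prev = np.maximum(prevM, np.maximum(prevX, prevY))
        M[1:] = best_prev[:-1] + M_scores[i - 1]
        ptrM[i, 1:] = np.where(prevM[:-1] >= np.maximum(prevX[:-1], prevY[:-1]),
                               0, np.where(prevX[:-1] >= prevY[:-1], 1, 2))
        # horizontal gaps via max-scan: Iy[j] = max(M[j-1]-go-ge, Iy[j-1]-ge)
        # substitute B_j = Iy[j] + j*ge, giving a cumulative maximum
        cand = M[:-1] - go + (j - 1) * ge
        B = np.maximum.accumulate(cand)
        Iy[1:] = B - j * ge
        opened = (M[:-1] - (go + ge)) >= (Iy[:-1] - ge)
        ptrY[i, 1:] = np.where(opened, 0, 2)
        Iy[0] = _NEG
    finals = (M[m], Ix[m], Iy[m])
    # deterministic preference M > Ix > Iy on ties
    if finals[0] >= finals[1] and finals[0] >= finals[2]:
        which = 0
    elif finals[1] >= finals[2]:
        which = 1
    else:
        which = 2
    score = finals[which]
    # traceback
    ops = []
    i_, j_ = n, m
    state = which
    while i_ > 0 or j_ > 0:
        if state == 0:
            if i_ == 0 or j_ == 0:
                # boundary: only gaps remain
                state = 1 if i_ > 0 else 2
                continue
            ops.append("D")
            state = ptrM[i_, j_]
            i_, j_ = i_ - 1, j_ - 1
        elif state == 1:
            ops.append("U")
            state = ptrX[i_, j_]
            i_ -= 1
        else:
            ops.append("L")
            state = ptrY[i_, j_]
            j_ -= 1
    ops.reverse()
    return float(score), ops


def _merge_profiles(rows_a: list[str], rows_b: list[str], ops: list[str]):
    """Apply DP operations to produce merged gapped rows (A rows then B)."""
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
        if op in ("D", "L"):
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def align_profiles(a: MultipleAlignment, b: MultipleAlignment,
                   params: AlignmentParams) -> tuple[float, MultipleAlignment]:
    """Profile-profile alignment; once a gap, always a gap."""
    alphabet, S = params.scoring()
    FA = _profile_freqs(a.rows, alphabet)
    FB = _profile_freqs(b.rows, alphabet)
    M_scores = (FA @ S @ FB.T).astype(np.float64)
    score, ops = _gotoh(M_scores, params.gap_open, params.gap_extend)
    rows_a, rows_b = _merge_profiles(a.rows, b.rows, ops)
    return score, MultipleAlignment(a.names + b.names, rows_a + rows_b)


def pairwise_align(a: str, b: str, params: AlignmentParams | None = None,
                   mode: str = "dna", names: tuple[str, str] = ("a", "b"),
                   ) -> tuple[float, MultipleAlignment]:
    """Optimal global alignment of two sequences under affine gap costs."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if params is None:
        params = DNA_DEFAULTS if mode == "dna" else PROTEIN_PAIRWISE_DEFAULTS
    pa = MultipleAlignment([names[0]], [a])
    pb = MultipleAlignment([names[1]], [b])
    return align_profiles(pa, pb, params)


def _pairwise_identity_distance(a: str, b: str, params: AlignmentParams) -> float:
    _, aln = pairwise_align(a, b, params)
    r1, r2 = aln.rows
    valid = diff = 0
    for x, y in zip(r1, r2):
        if x != GAP and y != GAP:
            valid += 1
            diff += x != y
    return diff / valid if valid else 1.0


def progressive_msa(seqs: list[tuple[str, str]],
                    params: AlignmentParams | None = None,
                    mode: str = "dna") -> MultipleAlignment:
    """Progressive multiple alignment over an NJ guide tree.

    Pairwise p-distances from global alignments feed neighbour joining;
    profiles are merged bottom-up in guide-tree order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if params is None:
        params = (AlignmentParams(match=1.0, mismatch=-1.0, gap_open=5.0,
                                  gap_extend=0.5) if mode == "dna"
                  else PROTEIN_MSA_DEFAULTS)
    names = [n for n, _ in seqs]
    if len(seqs) == 2:
        return pairwise_align(seqs[0][1], seqs[1][1], params,
                              names=(names[0], names[1]))[1]
    from .phylo import DistanceMatrix, nj_tree  # local import: no cycle at load

    n = len(seqs)
    D = np.zeros((n, n))
    pair_params = params if mode == "dna" else PROTEIN_PAIRWISE_DEFAULTS
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _pairwise_identity_distance(
                seqs[i][1], seqs[j][1], pair_params)
    tree = nj_tree(DistanceMatrix(names, D))
    profiles = {n_: MultipleAlignment([n_], [s]) for n_, s in seqs}

    def merge(node) -> MultipleAlignment:
        if node.is_leaf():
            return profiles[node.name]
        parts = [merge(c) for c in node.children]
        acc = parts[0]
        for p in parts[1:]:
            _, acc = align_profiles(acc, p, params)
        return acc

    merged = merge(tree.root)
    # restore input row order
    order = [merged.names.index(n_) for n_ in names]
    return MultipleAlignment(names, [merged.rows[k] for k in order])


# ---------------------------------------------------------------------------
# codon-aware nucleotide alignment

def codon_aware_alignment(cds_records: list[tuple[str, str]],
                          params: AlignmentParams | None = None
                          ) -> MultipleAlignment:
    """Align CDSs via their proteins; map residues back to codons.

    Trailing stop codons (complete TAA/TAG or incomplete T/TA) are trimmed
    before translation; each aligned residue expands to its source codon
    and each gap to three gap columns, so frame is preserved in every row.
    """
    from .codons import INVERTEBRATE_MITO, translate

    trimmed: list[tuple[str, str]] = []
    for name, cds in cds_records:
        cds = cds.upper()
        rem = len(cds) % 3
        if rem and cds[-rem:] in ("T", "TA"):
            cds = cds[:-rem]
        elif rem:
            raise ValueError(f"{name}: length not a codon multiple and no "
                             "incomplete stop to trim")
        if cds[-3:] in INVERTEBRATE_MITO.stop_codons:
            cds = cds[:-3]
        if not cds:
            raise ValueError(f"{name}: empty coding sequence")
        trimmed.append((name, cds))
    proteins = [(name, translate(cds + "TAA")) for name, cds in trimmed]
    if len(proteins) == 2:
        aa_aln = pairwise_align(proteins[0][1], proteins[1][1],
                                params or PROTEIN_PAIRWISE_DEFAULTS,
                                names=(proteins[0][0], proteins[1][0]))[1]
    else:
        aa_aln = progressive_msa(proteins, params, mode="protein")
    nt_rows = []
    for name, cds in trimmed:
        row = aa_aln.row(name)
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        it = iter(codons)
        nt_rows.append("".join("---" if ch == GAP else next(it) for ch in row))
    return MultipleAlignment([n for n, _ in trimmed], nt_rows)
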