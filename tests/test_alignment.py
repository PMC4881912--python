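"""Affine-gap alignment: DP engine vs exhaustive and naive oracles."""
import itertools

import numpy as np
import pytest

from psyllomito.alignment import (GAP, AlignmentParams, MultipleAlignment,
                                  codon_aware_alignment, pairwise_align,
                                  progressive_msa)
from psyllomito.codons import translate


# ---------------------------------------------------------------------------
# oracle 1: brute-force enumeration of every global alignment (tiny inputs)

def _enumerate_alignments(a, b):
    """Yield all gapped row pairs for a global alignment of a and b."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in _enumerate_alignments(a[1:], b):
            yield a[0] + ra, GAP + rb
    if b:
        for ra, rb in _enumerate_alignments(a, b[1:]):
            yield GAP + ra, b[0] + rb
    if a and b:
        for ra, rb in _enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def _score_alignment(ra, rb, params):
    """Score one gapped pair; a gap run of length k costs open + k*extend."""
    score = 0.0
    for row_self, row_other in ((ra, rb), (rb, ra)):
        in_gap = False
        for ch in row_self:
            if ch == GAP:
                if not in_gap:
                    score -= params.gap_open
                score -= params.gap_extend
                in_gap = True
            else:
                in_gap = False
    for x, y in zip(ra, rb):
        if GAP not in (x, y):
            score += params.match if x == y else params.mismatch
    return score


def _brute_best(a, b, params):
    return max(_score_alignment(ra, rb, params)
               for ra, rb in _enumerate_alignments(a, b))


@pytest.mark.parametrize("a,b", [
    ("ACGT", "AGT"), ("ACGT", "ACGT"), ("AAAA", "TTTT"), ("A", "ACGTACG"),
    ("GATTACA", "GCATGCT"), ("ACACAC", "CACACA"),
])
def test_dp_score_equals_enumeration_oracle(a, b):
    params = AlignmentParams(match=1, mismatch=-1, gap_open=2, gap_extend=1)
    score, aln = pairwise_align(a, b, params)
    assert score == pytest.approx(_brute_best(a, b, params))
    # the reported alignment itself realises the reported score
    assert _score_alignment(*aln.rows, params) == pytest.approx(score)


def test_dp_score_oracle_randomised_small_pairs():
    rng = np.random.default_rng(7)
    params = AlignmentParams(match=2, mismatch=-1, gap_open=3, gap_extend=0.5)
    for _ in range(15):
        a = "".join(rng.choice(list("ACGT"), rng.integers(1, 8)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(1, 8)))
        score, aln = pairwise_align(a, b, params)
        assert score == pytest.approx(_brute_best(a, b, params))


def test_identity_alignment_has_no_gaps():
    score, aln = pairwise_align("ACGT", "ACGT")
    assert aln.rows == ["ACGT", "ACGT"]


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        pairwise_align("", "ACGT")


# ---------------------------------------------------------------------------
# oracle 2: an independent, naive Gotoh re-implementation (protein mode)

def _naive_gotoh(a, b, params):
    alphabet, S = params.scoring()
    idx = {c: i for i, c in enumerate(alphabet)}
    go, ge = params.gap_open, params.gap_extend
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + i * ge)
    for j in range(1, m + 1):
        Y[0][j] = -(go + j * ge)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[idx[a[i - 1]], idx[b[j - 1]]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - go - ge, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go - ge, Y[i][j - 1] - ge)
    return max(M[n][m], X[n][m], Y[n][m])


def test_protein_mode_matches_naive_dp_with_gonnet():
    rng = np.random.default_rng(8)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    params = AlignmentParams(gap_open=35, gap_extend=0.75, matrix="GONNET1992")
    for _ in range(5):
        a = "".join(rng.choice(aas, 20))
        b = "".join(rng.choice(aas, 20))
        score, _ = pairwise_align(a, b, params, mode="protein")
        assert score == pytest.approx(_naive_gotoh(a, b, params), abs=1e-4)


# ---------------------------------------------------------------------------
# progressive MSA

def test_identical_triplet_aligns_gap_free():
    aln = progressive_msa([("a", "ACGTACGT"), ("b", "ACGTACGT"),
                           ("c", "ACGTACGT")])
    assert all(GAP not in r for r in aln.rows)
    assert aln.n_cols == 8


def test_msa_requires_two_sequences():
    with pytest.raises(ValueError):
        progressive_msa([("a", "ACGT")])


def _pairwise_identity(aln, i, j):
    same = tot = 0
    for x, y in zip(aln.rows[i], aln.rows[j]):
        if GAP not in (x, y):
            tot += 1
            same += x == y
    return same / tot


def test_msa_recovers_simulated_divergence():
    """Four sequences at ~5% pairwise divergence from a common ancestor."""
    rng = np.random.default_rng(9)
    anc = "".join(rng.choice(list("ACGT"), 400))
    seqs = []
    for k in range(4):
        s = list(anc)
        for p in rng.choice(400, size=10, replace=False):   # ~2.5% per tip
            s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
        seqs.append((f"t{k}", "".join(s)))
    aln = progressive_msa(seqs)
    truth = {}
    for i in range(4):
        for j in range(i + 1, 4):
            diff = sum(x != y for x, y in zip(seqs[i][1], seqs[j][1])) / 400
            assert abs((1 - _pairwise_identity(aln, i, j)) - diff) <= 0.02


def test_msa_stability_after_gap_removal(diversity_panel):
    panel, _ = diversity_panel
    rows = [(p.metadata["accession"],
             p.get("rrnS").sense_sequence(p.sequence)) for p in panel]
    aln1 = progressive_msa(rows)
    again = progressive_msa([(n, r.replace(GAP, ""))
                             for n, r in zip(aln1.names, aln1.rows)])
    assert abs(again.n_cols - aln1.n_cols) <= 5


# ---------------------------------------------------------------------------
# codon-aware alignment

def test_codon_alignment_identical_pair_gap_free():
    cds = "ATGAAATTTGGGTAA"
    aln = codon_aware_alignment([("a", cds), ("b", cds)])
    assert aln.rows == [cds[:-3], cds[:-3]]


def test_codon_alignment_single_codon_deletion():
    a = "ATGAAATTTGGGCATTAA"
    b = "ATGAAAGGGCATTAA"          # TTT codon deleted
    aln = codon_aware_alignment([("a", a), ("b", b)])
    row_b = aln.row("b")
    assert aln.n_cols % 3 == 0
    assert row_b.count(GAP) == 3
    i = row_b.index(GAP)
    assert row_b[i:i + 3] == "---" and i % 3 == 0


def test_codon_alignment_preserves_frame_round_trip(diversity_panel):
    panel, _ = diversity_panel
    records = [(p.metadata["accession"],
                p.get("cox3").sense_sequence(p.sequence)) for p in panel]
    aln = codon_aware_alignment(records)
    for name, cds in records:
        back = aln.row(name).replace(GAP, "")
        assert translate(back + "TAA") == translate(cds)


def test_codon_alignment_rejects_frameshifted_input():
    with pytest.raises(ValueError):
        codon_aware_alignment([("a", "ATGAAATAA"), ("b", "ATGAAAG")])
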