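"""The synthetic-mitogenome generator and the evolution engine."""
import numpy as np
import pytest

from psyllomito.architecture import find_overlaps, identify_control_region, \
    strand_partition
from psyllomito.alignment import MultipleAlignment
from psyllomito.codons import extract_codon_report
from psyllomito.diversity import call_snps
from psyllomito.mito_io import AnnotatedMitogenome
from psyllomito.simulate import (EvolutionSpec, GenomeSpec,
                                 exact_substitution_copy, evolve_panel,
                                 generate_genome, make_haplotype_panel,
                                 partial_region_bounds,
                                 psyllid_diversity_spec,
                                 synonymous_third_position_snps)


def test_generator_determinism():
    a = generate_genome(GenomeSpec(seed=9))
    b = generate_genome(GenomeSpec(seed=9))
    c = generate_genome(GenomeSpec(seed=10))
    assert a.sequence.residues == b.sequence.residues
    assert [f.spans for f in a.features] == [f.spans for f in b.features]
    assert a.sequence.residues != c.sequence.residues


def test_generator_spec_echo(genome):
    assert len(genome.genes()) == 37
    j, n, _ = strand_partition(genome)
    assert (j, n) == (23, 14)
    assert identify_control_region(genome).length_bp == 975
    from collections import Counter
    pairs = Counter(o.pair_class for o in find_overlaps(genome))
    assert pairs == {"tRNA-tRNA": 7, "PCG-PCG": 4, "PCG-tRNA": 3}
    sizes = {o.pair_class: [] for o in find_overlaps(genome)}
    for o in find_overlaps(genome):
        sizes[o.pair_class].append(o.overlap_bp)
    assert all(1 <= x <= 7 for x in sizes["PCG-PCG"])
    assert all(1 <= x <= 12 for x in sizes["tRNA-tRNA"])
    assert all(2 <= x <= 3 for x in sizes["PCG-tRNA"])


def test_generated_pcgs_are_valid_orfs(genome):
    reports = extract_codon_report(genome)   # raises on any internal stop
    assert {r.gene for r in reports} == {
        "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3", "nad5",
        "nad4", "nad4L", "nad6", "cob", "nad1"}
    incomplete = {r.gene for r in reports if r.incomplete_stop}
    assert incomplete == {"cox1", "cox2", "nad5", "nad4"}


def test_composition_target_recovery():
    spec = GenomeSpec(seed=3)
    g = generate_genome(spec)
    from psyllomito.composition import base_composition, percent_at
    cr = identify_control_region(g)
    seq = g.sequence.fragment(cr.start, cr.end)
    at = percent_at(base_composition(seq))
    se = 100 * np.sqrt(0.827 * 0.173 / len(seq))
    assert abs(at - 82.7) < 3 * se


def test_infeasible_overlap_spec_rejected():
    spec = GenomeSpec(overlaps={("atp8", "atp6"): 3})
    with pytest.raises(ValueError, match="unsupported PCG-PCG overlap"):
        generate_genome(spec)


def test_zero_rate_evolution_is_identity(genome):
    spec = EvolutionSpec.star(["x", "y"], 0.0, seed=1)
    panel, log = evolve_panel(genome, spec)
    assert log.substitutions == []
    for p in panel:
        assert p.sequence.residues == genome.sequence.residues


def test_evolution_determinism_and_replay(genome):
    spec = psyllid_diversity_spec(seed=77)
    p1, l1 = evolve_panel(genome, spec)
    p2, l2 = evolve_panel(genome, psyllid_diversity_spec(seed=77))
    assert [g.sequence.residues for g in p1] == \
        [g.sequence.residues for g in p2]
    assert l1.substitutions == l2.substitutions
    replayed = l1.replay(genome)
    for g in p1:
        assert replayed[g.metadata["accession"]] == g.sequence.residues


def test_evolved_pcgs_remain_valid(diversity_panel):
    panel, _ = diversity_panel
    for g in panel:
        reports = extract_codon_report(g)    # no internal stops anywhere
        assert len(reports) == 13


def test_third_position_bias_and_synonymy_tally(genome):
    """Third-position-only evolution: the caller's synonymy annotation
    agrees with a direct code-table tally; most changes are silent."""
    spec = EvolutionSpec.star(["h1"], 1.0, default_gene_rate=0.01,
                              noncoding_rate=0.0,
                              position_weights=(0.0, 0.0, 1.0), seed=23)
    panel, log = evolve_panel(genome, spec)
    subs = [s for s in log.substitutions if s.gene and s.codon_position]
    pcg_subs = [s for s in subs if s.codon_position == 3]
    non_pcg = {f.name for f in genome.genes() if f.feature_class != "PCG"}
    assert all(s.codon_position == 3 for s in subs if s.gene not in non_pcg)
    assert len(pcg_subs) > 20
    # synonymy fraction via an independent code-table tally
    from psyllomito.codons import INVERTEBRATE_MITO as code
    from psyllomito.mito_io import reverse_complement
    syn = 0
    for s in pcg_subs:
        f = genome.get(s.gene)
        pos = f.positions(len(genome))
        order = pos if f.strand == "J" else pos[::-1]
        k = order.index(s.position)
        c0 = k - (k % 3)
        tri = order[c0:c0 + 3]
        seq = genome.sequence.residues

        def codon(base_at):
            out = []
            for q in tri:
                b = base_at if q == s.position else seq[q]
                out.append(b if f.strand == "J" else reverse_complement(b))
            return "".join(out)

        before = codon(s.ref)
        after = codon(s.alt)
        syn += code.table.get(before) == code.table.get(after)
    # with a uniform alternate base, four-fold sites are always silent and
    # two-fold sites silent 1/3 of the time: a clear majority, not all
    assert 0.5 < syn / len(pcg_subs) < 1.0

    # the caller's per-SNP synonymy annotation agrees with a direct
    # translate-and-compare oracle on a J-strand gene
    from psyllomito.codons import translate
    h1 = panel[0]
    nad2 = genome.get("nad2")
    anc_cds = nad2.sense_sequence(genome.sequence)
    der_cds = nad2.sense_sequence(h1.sequence)
    aln = MultipleAlignment(["anc", "h1"], [anc_cds, der_cds])
    recs = call_snps(aln, "anc", frame=(0, len(anc_cds), 1))
    assert recs
    anc_prot = translate(anc_cds)
    der_prot = translate(der_cds)
    for r in recs:
        codon_idx = (r.column - 1) // 3
        assert r.synonymous == (anc_prot[codon_idx] == der_prot[codon_idx])


def test_make_haplotype_panel_edges():
    base = "ATGAAACCCGGG"
    (rec,) = make_haplotype_panel(base, [("w", [])])
    assert rec == ("w", base)
    with pytest.raises(ValueError, match="conflicting"):
        make_haplotype_panel(base, [("x", [(2, "A"), (2, "C")])])
    with pytest.raises(ValueError, match="outside"):
        make_haplotype_panel(base, [("x", [(99, "A")])])


def test_synonymous_snp_picker_is_silent():
    from psyllomito.codons import translate
    rng = np.random.default_rng(24)
    cds = "ATGAAATTTGGGCATCTTACAGAA" * 4 + "TAA"
    snps = synonymous_third_position_snps(cds[:-3], 5, rng)
    mutated = list(cds)
    for pos, alt in snps:
        assert pos % 3 == 2
        mutated[pos] = alt
    assert translate("".join(mutated)) == translate(cds)


def test_exact_substitution_copy_counts_and_orf_safety(genome):
    s0, s1 = partial_region_bounds(genome)
    assert s1 - s0 == 3077
    nad1, rrnl = genome.get("nad1"), genome.get("rrnL")
    assert s0 <= nad1.start and nad1.end <= s1
    assert s0 <= rrnl.start and rrnl.end <= s1
    ref, der, positions = exact_substitution_copy(
        genome, (s0, s1), {"nad1": 14, None: 17}, seed=3)
    assert len(positions) == 31
    assert sum(a != b for a, b in zip(ref, der)) == 31
    # grafting the derived fragment back leaves every ORF intact
    seq = genome.sequence.residues
    grafted = seq[:s0] + der + seq[s1:]
    g2 = AnnotatedMitogenome(
        type(genome.sequence)(grafted), list(genome.features), {})
    assert len(extract_codon_report(g2)) == 13
    in_nad1 = [p for p in positions
               if nad1.start <= p + s0 < nad1.end]
    assert len(in_nad1) == 14
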