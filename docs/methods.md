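# Methods

`psyllomito` implements the comparative analyses commonly applied to newly
sequenced insect mitochondrial genomes, using the potato psyllid
(*Bactericera cockerelli*) and its published Psylloidea relatives as the
reference system. This note records the models, conventions and numerical
choices behind each stage, and what the synthetic-data generator does and
does not emulate.

## Coordinate model

A mitogenome is a circular DNA of ~15 kb. Internally all coordinates are
0-based half-open intervals on the deposited strand, which is defined to be
the J-strand (the majority strand carrying most genes). GenBank's 1-based
inclusive convention is converted only at the file boundary. A feature that
crosses the replication origin is stored as exactly two spans `[s, L)` and
`[0, e)`; every downstream computation works on explicit position sets over
the circle, so wrapping needs no special cases. The deposited orientation is
taken as authoritative: the package never re-orients genomes.

## Architecture audits

Strand partition counts genes (never the control region) per strand; for
the ancestral insect arrangement this is 23 on J and 14 on N. Overlaps are
the pairwise intersections of gene position sets, reported regardless of
strand; a triple overlap would appear as all of its pairs. Intergenic
spacers are the maximal uncovered runs on the circle, and the control region
is identified *structurally* as the largest spacer (ties broken by smallest
start coordinate), so unannotated control regions are handled. Gene-order
signatures are signed circular sequences anchored at trnI (or the
lexicographically first PCG); two genomes are "identical" when one signature
is a rotation of the other with equal strand signs, and the breakpoint count
is the number of signed adjacencies of one order missing from the other
(an adjacency `a→b` is equated with its reverse reading `-b→-a`).

## Composition and skews

AT-skew = (fA − fT)/(fA + fT) and GC-skew = (fG − fC)/(fG + fC), with
frequencies computed over unambiguous bases only (ambiguity codes are
counted and excluded from denominators; a zero denominator yields NaN, never
0). Per-class rows concatenate the member genes' *sense-strand* sequences
(N-strand genes reverse-complemented first), while the whole-genome row uses
the J-strand. This sense-strand convention is the only one under which the
J- and N-strand PCG rows can show opposite skew signs, as insect mitogenomes
do. Genes contribute their full length to their class even where they
overlap another gene. Reporting precision follows the field's convention:
%A+T to 1 decimal, skews to 3.

## Codon analyses

Translation uses the invertebrate mitochondrial code (NCBI table 5: AGA/AGG
= Ser, ATA = Met, TGA = Trp; stops TAA/TAG). Incomplete stop codons — a
terminal T or TA completed to TAA by post-transcriptional polyadenylation —
are recognised from CDS length mod 3 plus the terminal residues when no
annotation says so. They are *excluded* from codon counts, RSCU and usage:
they are not codons. With that convention the 13 published PCG lengths and
stop codons of the *B. cockerelli* record imply exactly 3,595 encoded
residues, which the package recomputes from its shipped copy of the
published table. Start codons count as their table-5 amino acid (not forced
to Met), keeping the residue tally consistent for TTG/GTG starts in other
species. RSCU is the observed codon count divided by the mean count of its
synonymous family; family sums equal family size exactly, and a family with
zero observations is undefined (NaN), not zero. Amino-acid usage splits
leucine (UUR vs CUN) and serine (AGN vs UCN) because they are served by
different tRNAs.

## Alignment

One affine-gap Gotoh dynamic program serves sequence–sequence and
profile–profile alignment (a sequence is a one-row profile; profile columns
are scored as frequency-vector products). A gap of length k costs
`gap_open + k·gap_extend`. Traceback ties prefer substitution over a gap in
the second sequence over a gap in the first, making output deterministic.
Protein defaults use the Gonnet matrix with opening 35 / extension 0.75 for
pairs and 15 / 0.3 for multiple alignment — the Clustal-style settings used
for mitochondrial PCG work; DNA defaults are match 1 / mismatch −1 / open
5 / extend 0.5. The progressive MSA builds its guide tree by neighbour
joining on pairwise p-distances and merges profiles bottom-up ("once a gap,
always a gap"). Codon-aware alignment trims (possibly incomplete) stops,
aligns the translations, and expands each residue back to its source codon
and each gap to three columns, preserving frame in every row.

## Diversity, SNPs, haplotypes

Nucleotide diversity π is the average over row pairs of differences per
valid site, where a valid site for a pair has an unambiguous base in both
rows (pairwise deletion, approximating DnaSP's handling of ragged
alignments). Sliding windows are 250 bp advancing by 25 bp; only full
windows are evaluated by default (the trailing partial window is dropped),
and an alignment shorter than one window degrades to a single full-length
window with a warning. Both the mean of window values and the whole-region
π are reported; the windows-mean is the default comparator.

SNP calling reports columns with at least one unambiguous non-reference
state; any column containing a gap is an indel column, never a SNP. Given a
reading frame it annotates codon position and synonymy (an alternate is
synonymous when substituting it into the reference codon leaves the table-5
amino acid unchanged).

Haplotype classification works over a fixed 500 bp region of cox1 (the
segment used for potato-psyllid haplotyping). Profiles are built from
reference sequences at run time, not hard-coded; the variable positions
among them are the fingerprint columns. A query is globally aligned to the
region anchor and must cover ≥90 % of it. Distances are Hamming distances
over the *whole* region (query-covered, unambiguous positions): this way a
variant one SNP away from a named haplotype is called "novel at distance 1"
even when its SNP falls outside the fingerprint columns, which is exactly
the situation of the known M variant relative to the Northwestern
haplotype.

## In-silico PCR

Primer sites are found on both strands of the origin-doubled sequence with
uniform mismatch counting (default 0 mismatches; no 3'-end weighting, since
the designed primers are exact). A productive pair has the two primers on
opposite strands with facing 3' ends; the product length is the circular
distance from forward 5' end to reverse 5' end inclusive of both primers.
The reported product is the shorter arc; a wrapping product disappears when
the topology is set to linear, which is the circularity argument: the
package's default primer pair yields a 1,285 bp product spanning the origin.

## Phylogeny

The matrix concatenates the 13 PCGs in conventional table order (nad2, cox1,
cox2, atp8, atp6, cox3, nad3, nad5, nad4, nad4L, nad6, cob, nad1) from
codon-aware alignments. Third codon positions saturate at between-family
divergences, so the default matrix removes every third position (nt12); an
amino-acid matrix is also built. Distances are p-distances with pairwise
deletion; trees come from standard neighbour joining with lexicographic
tie-breaking and negative branch lengths clamped to zero with a warning.
NJ recovers additive matrices exactly (verified over hundreds of seeded
random trees). Topologies are compared by Robinson–Foulds distance over
non-trivial splits. Maximum-likelihood and Bayesian inference are out of
scope; the package exports relaxed PHYLIP/FASTA matrices for external
tools. One caveat found while testing: with a homogeneous substitution
process, iid third-position saturation inflates all pairwise distances
nearly equally, so all-position NJ is about as accurate as nt12 NJ on
simulated data — the nt12 matrix is kept as the default for its robustness
rationale, not because the simulation shows a gap.

## The synthetic-mitogenome generator

The generator's defaults are the study conditions of the psyllid system:

- 37 genes in the ancestral insect order, 23 J / 14 N; PCG and rRNA lengths
  and start/stop codons from the published *B. cockerelli* table (including
  incomplete T stops for cox1, cox2, nad5, nad4); tRNAs 54–75 bp; spacers
  3–31 bp; one 975 bp control region.
- 14 overlaps: four PCG–PCG (1–7 bp), seven tRNA–tRNA (1–12 bp), three
  PCG–tRNA (2–3 bp). Same-strand PCG–PCG overlaps of 7 bp use the
  biological `ATGATAA`-type junction (upstream frame ...ATA-TGA-STOP,
  downstream frame ATG-ATA-x), so both reading frames stay valid; 1 bp
  overlaps share the stop's last base with the downstream start's first.
- per-class base-composition targets (%A+T, AT-skew, GC-skew on the sense
  strand) for tRNA-J/N, the two rRNAs and noncoding DNA; PCG sequences are
  sampled codon-wise from a residue-usage profile (Ile 10.79 %, Phe 9.60 %,
  Leu-UUR 8.98 %, Arg 1.31 %, Cys 1.20 %, remainder a realistic insect
  spread) with within-family codon choice weighted by strand-specific base
  targets. Consequence: tRNA/rRNA/CR composition is directly dialable and
  recovered within binomial sampling error, while PCG skews *emerge* from
  the codon model and track the real values only qualitatively.
- the default primer pair is embedded so its amplicon (1,285 bp) wraps the
  origin.
- per-component random streams from one seed; identical seeds give
  byte-identical genomes.

Evolution along a star or tree mutates each site with probability
branch-length × per-gene rate × codon-position weight; start and stop
codons are invariant, and a substitution that would create an in-frame stop
resamples its alternate base among stop-free choices (skewing the alternate
distribution at stop-adjacent sites, not the rate). For a star with per-tip
site probability d and uniform alternates, two tips differ with probability
2d(1−d) + (2/3)d², which the package inverts to hit a target expected
pairwise diversity; the default per-gene profile follows the published
per-gene π values (cox1 0.21 … nad2/nad6 0.38) with a 250 bp hotspot in
nad5 at π = 0.46, and realistic levels (0.28–0.35) for the genes whose means
are not printed. A replayable truth log records every substitution.

What the generator does **not** emulate: tRNA/rRNA secondary structure,
tandem repeats and stem-loops of the control region, lineage-specific
compositional drift, indel-rich control-region evolution, and sequencing
artefacts. Closed-loop tests therefore demonstrate the *statistics and
bookkeeping* are correct on data with known truth — not that the pipeline
is robust to every pathology of real GenBank records.

## Problem sizes and tolerances

The test-suite and the acceptance script run entirely on generated data:
one ~15.5 kb genome, four-taxon and six-taxon panels, a 3,077 bp
partial-homolog comparison carrying exactly 31 substitutions (14 in nad1),
and property suites (brute-force alignment enumeration up to 8 bp, 200
seeded NJ additive-recovery trials, per-position occupancy oracles).
Sampling-based assertions use 3-standard-error binomial bounds derived from
the generator's own targets; diversity recovery is asserted at ±0.02 (gene
means) and ±0.03 (window peak), consistent with Monte-Carlo spread at these
sequence lengths.
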