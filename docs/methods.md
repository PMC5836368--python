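# Methods

## Coordinate and orientation conventions

All genomic intervals are 0-based, half-open. genePred is native in this
convention; GTF features (1-based, inclusive) are converted on read. All
transcript-relative quantities — junction phase, cumulative coding
offsets, boundary residues, peptide distances — are computed in
translation orientation; genomic blocks are stored in genomic order with
the transcript strand carrying orientation. Distances to splice sites
are measured in spliced coding-sequence space (introns collapsed), in
nucleotides; "1 nt downstream of a 3′ splice site" means the second
nucleotide of the acceptor exon.

## Coding transcripts and junctions

A transcript model contributes one coding transcript when its CDS length
is a multiple of 3 and its translation has no internal stop codon;
violations are dropped with a warning. The annotated stop codon is kept
in the spliced CDS but removed from the protein, so digestion operates
on the mature translation product (no further processing such as
N-terminal methionine removal is applied, since none is annotated).
Ambiguous bases translate to X; such transcripts are retained for
digestion but excluded from composition statistics so they cannot skew
background frequencies.

A splice junction is recorded only when coding sequence flanks it on
both sides (UTR-only exons never produce junctions). Its identity key is
(contig, strand, donor-exon last base, acceptor-exon first base);
isoform-shared junctions collapse to one record. The **phase** is the
cumulative count of coding nucleotides upstream of the junction mod 3;
the **boundary residue** is the amino acid whose codon contains the
donor exon's final coding nucleotide — the exon-ending residue at phase
0, the codon-crossing residue at phases 1 and 2. A junction that splits
the stop codon carries '*' as its boundary residue; it is excluded from
composition statistics and can never be a K/R junction. Where isoforms
assign a shared junction different phases, the first-encountered
occurrence defines the unique record; the per-occurrence composition
mode is unaffected.

## Composition statistics

Boundary-residue composition is reported in two countings, because the
two downstream uses differ: the fold-enrichment report counts one
residue per (transcript, junction) occurrence, while K/R-junction
fractions are computed over unique junctions. Background frequencies are
computed over all residues of all coding transcripts, redundantly across
isoforms. Fold change is boundary frequency / background frequency and
is undefined (omitted) when either side has no observations.

Splice-site position frequency matrices cover 10 nt of exon and 10 nt of
intron on each side, strand-corrected so canonical junctions read GT at
donor intron positions +1/+2 and AG at acceptor intron positions −2/−1.
No pseudocount is applied; positions with zero informative coverage are
NaN rather than smoothed. A ±4 trimmed view is provided for logo
rendering; rendering itself is out of scope.

The frame-adjusted K/R probability is the phase-usage-weighted mean of
per-phase K/R probabilities, which equals the overall K/R fraction of
unique junctions. Scenario 1 (phase 0 ∧ K/R; cleavage exactly at the
splice site, producing type 3/1 peptides) and scenario 2 (phase 2 ∧
K/R; cleavage 1 nt into the acceptor, producing type 4/2 peptides) are
joint probabilities; phase-1 K/R junctions (cleavage 2 nt into the
acceptor) are reported separately and folded into neither scenario,
since terminus enrichment is observed only at offsets 0 and 1.

The closed-form boundary-terminus rate 2/(L_exon − L_pep) takes its two
medians (amino acids) as inputs and does not recompute them from data;
the result is capped at 1 and the function refuses a non-positive
denominator. A Monte-Carlo check (uniform placement of windows in an
exon) agrees to within the discretization difference between
2/(L_exon − L_pep) and the exact 2/(L_exon − L_pep + 1).

## Digestion and projection

Cleavage sites are positions after (C-side) or before (N-side) a
recognition residue, suppressed when the neighbouring residue on the far
side of the scissile bond is in the enzyme's blocked set. Products with
0..m internal sites are enumerated; at zero missed cleavages the
products tile the protein exactly. Unknown residue letters are never
cleavable. Two preset families ship and the choice is an explicit
configuration: the `paper` family follows the source table of cleavage
rules literally (Glu-C after D; chymotrypsin F/Y/L/W/M with no proline
exception; trypsin K/R not before P), while `conventional` uses textbook
specificities (Glu-C after E; chymotrypsin not before P). The trypsin
proline exception is essential to the headline structural result: at
zero missed cleavages, the only K/R junctions a tryptic peptide can span
are those whose boundary K/R is immediately followed by proline.

Peptides project to the genome by concatenating their codons' genomic
blocks and merging contiguous runs; the sum of block lengths is always
3× the peptide length. Per spanned junction, donor- and acceptor-side
nucleotide coverage is recorded in translation orientation. A peptide
sequence is uniquely mapped iff all its occurrences across transcripts
share one identical genomic block set (isoform-shared locations merge);
sequences at two distinct loci are ambiguous and excluded downstream.
Gene labels play no role in uniqueness — only genomic identity does.

## Detectability and type classification

A junction is detectable under a digestion scheme when a uniquely mapped
filtered peptide spans it with acceptor coverage ≥ 3 nt and donor
coverage ≥ 1 nt. The acceptor threshold of 3 excludes both
single-nucleotide (type 4) and 2-nt acceptor-coverage peptides, whose
genomic mapping is too constrained to verify the acceptor exon. The
donor-side minimum of 1 nt is a symmetry default — no principled
donor-side rule exists — and both thresholds are configurable and
recorded in output metadata. CDS coverage is nucleotide-level over the
union of genomic CDS positions of all transcripts. Enzyme comparisons
operate on junction identity keys and refuse runs whose annotation
fingerprints differ.

Type calls: type 1 = peptide starts at an acceptor exon's first base;
type 2 = starts at its second base; type 3 = ends at a donor exon's
last base; type 4 = junction-spanning peptide ending on the acceptor
exon's first base. Acceptor exons are never the first coding exon and
donor exons never the last, so the required exclusions are implicit in
the definitions. A peptide can carry at most one start-side and one
end-side call. The boundary-distance histograms use the same exclusions
— starts are counted only within acceptor exons, ends only within donor
exons — which makes the type 1/2/3/4 counts equal the histogram cells at
offsets 0, 1, 0, and 1 respectively, an identity the tests assert
exactly.

The per-offset test is a one-sided one-proportion z-test of each
offset's count against a uniform multinomial over that category's window
(11 cells for start/end offsets 0–10, 10 cells for junction offsets
1–10), with σ = √(N·p₀(1−p₀)) and no multiple-testing correction; raw
p-values are reported. This is the simplest null consistent with asking
which locations carry excess termini. Null calibration is assessed on
the four boundary cells that define types 1–4; note that because
peptides start on codon boundaries, a single junction can only ever
contribute offsets congruent to −phase mod 3, so per-cell null
probabilities are exactly uniform only when aggregated over a balanced
phase mix — the calibration simulation therefore uses equal phase
weights.

## Synthetic genomes

The generator builds each gene in transcript orientation: junction
phases are drawn from `phase_weights`, and each junction's boundary
codon is a K/R codon with probability `p_boundary_kr` (otherwise a
non-K/R sense codon from the codon-usage background, renormalized — so
the planted probability is exact). Phase 0 plants the codon as the donor
exon's last triplet; phase 2 splits it 2+1 across the junction; phase 1
splits it 1+2. All other codons are drawn from the configured usage with
stop codons excluded, so proteins always translate cleanly; the first
codon is ATG and the last a stop. Exon coding lengths are drawn from
`exon_len_range_nt` and adjusted by ≤ 2 nt to realize the drawn phase;
the minimum exon length of 12 nt guarantees planted codons never
collide. Introns are GT..AG with probability `p_canonical_intron`.
Genes are placed with random-sequence spacers on one contig, on either
strand; an option emits duplicate isoforms to exercise junction
deduplication. Everything is reproducible from a single seed, and a
truth table records every planted phase and boundary residue.

Default conditions mirror the documented human biases: boundary K/R
probability 0.25 (the frame-adjusted rate for human coding transcripts,
about twice the ~11–13% proteome background), phase usage
(0.47, 0.30, 0.23) as typical for human coding genes, canonical introns,
exons 60–240 nt and introns 60–400 nt (compact but within the realistic
range for internal coding exons; introns are short to keep genomes
small, which affects no spliced-space statistic). Codon usage defaults
to uniform over the 61 sense codons so that fold-change tests can
compute their own background; note this puts the background K/R
frequency at 8/61 ≈ 13%, slightly above the human 11.4%.

What the generator does not emulate: real exon/intron length
distributions and codon-usage tables, alternative splicing beyond
duplicate isoforms, non-coding exons/UTRs, sequencing or identification
noise, and peptide abundance or spectral detectability beyond a
length-window detection model. Passing tests therefore demonstrate
correctness of the counting, projection and testing machinery and the
direction of enzyme effects under planted biases — not the exact
magnitudes expected on any particular real annotation, which depend on
that annotation's boundary composition and phase usage.

## Problem sizes and numerical choices

The test suite validates parameter recovery at ~20,000 junctions
(about 4,500 genes) against 3-binomial-SE bands, digestion equivalence
on 1,000 random proteins per preset against an independent
substring-acceptance oracle (plus pyteomics as an external cross-check
for trypsin), enzyme-direction effects over 100 seeded replicates of
30-gene genomes, and z-test calibration over 200 replicates of 2,000
uniformly placed within-exon peptides. Analysis drivers use 600-gene
genomes. Ties and degenerate inputs: empty junction sets yield empty
(not smoothed) reports; empty peptide sets yield zero coverages;
comparisons of fewer than two enzyme runs are errors.
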