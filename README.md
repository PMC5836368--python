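# splicepep

Why are exon–exon junction-spanning peptides so rare in shotgun proteomics
data? Junction-spanning peptides are the only direct mass-spectrometric
evidence that a specific splice isoform is translated, yet they are
under-represented in tryptic digests. The reason is genomic: coding exons
preferentially end in AG, and the triplets at and across splice junctions
are therefore enriched for lysine (K) and arginine (R) — exactly the
residues trypsin cleaves after. A protease cut at or next to a splice site
produces peptides that *end* at the junction instead of spanning it.

`splicepep` is an analysis pipeline that quantifies this effect end to
end, for anyone designing proteogenomics experiments or evaluating
protease choice for splice-isoform detection:

- parse gene models (UCSC genePred or GTF) plus genome FASTA into coding
  transcripts with a codon-resolved genome projection;
- enumerate unique coding splice junctions with their reading-frame
  **phase** (cumulative coding nt upstream mod 3) and **boundary
  residue** (the amino acid whose codon contains the donor exon's last
  coding nucleotide);
- compute boundary-residue enrichment over the proteome background,
  splice-site nucleotide consensus matrices, and the frame-adjusted
  probability that a junction is a K/R (trypsin) site, split into the two
  cleavage scenarios: phase 0 (cut exactly at the splice site) and
  phase 2 (cut 1 nt into the acceptor exon);
- digest proteomes in silico with six protease presets, project peptides
  to genomic block coordinates, and score per-enzyme CDS / junction /
  K-R-junction detectability (a junction counts as detectable when a
  uniquely mapped 8–25 aa peptide spans it with ≥ 3 nt on the acceptor
  side and ≥ 1 nt on the donor side);
- classify observed peptides (BED12) into boundary types 1–4 — start at
  a splice site, start 1 nt downstream, end at a splice site, junction
  peptide ending 1 nt into the acceptor — with per-offset z-tests;
- generate synthetic genomes with *planted* junction phases and boundary
  residues, so every statistic can be validated against known truth.

## The core quantities

For a junction with phase $p$ and boundary residue $b$, trypsin cleaves
at or adjacent to the splice site when $b \in \{K, R\}$. Over unique
junctions the pipeline reports

$$P_{K/R} = \sum_{p=0}^{2} P(\text{phase}=p)\; P(b \in \{K,R\} \mid p),$$

with scenario 1 $= P(p{=}0 \wedge b \in \{K,R\})$ and scenario 2
$= P(p{=}2 \wedge b \in \{K,R\})$. The expected background rate at which
within-exon peptides merely *touch* a boundary by chance is the closed
form $2/(L_{\text{exon}} - L_{\text{pep}})$ for median exon and peptide
lengths in amino acids — with the reference medians (66, 13) this is
$2/53 \approx 3.8\%$.

## Worked example

```bash
python analysis/01_simulate_genome.py      # synthetic annotations
python analysis/02_junction_composition.py # junction + composition stats
python analysis/03_insilico_digest.py      # six-protease detectability
python analysis/04_observed_peptides.py    # type 1-4 classification
```

Step 02, on the human-like annotation (600 genes, boundary K/R
probability 0.25, phase usage 0.47/0.30/0.23), prints:

```
721 coding transcripts, 2725 unique junctions
top-5 boundary-enriched residues: K (1.88x), R (1.84x), ...
K/R junctions: 670/2725 (24.6% of unique junctions; background K/R usage 13.2%)
scenario 1 (phase 0, cut at splice site): 0.110
scenario 2 (phase 2, cut 1 nt into acceptor): 0.051
```

i.e. K and R are the most boundary-enriched residues and a quarter of
junctions are trypsin sites, roughly double the 13% background usage.
Step 03 then shows the downstream cost and the remedy:

```
trypsin       CDS  59.1%  junctions  1305 ( 47.9%)  K/R   30 (  4.5%)
chymotrypsin  CDS  47.8%  junctions  1203 ( 44.1%)  K/R  373 ( 55.7%)
union of detectable junctions across six enzymes: 2294; common to all six: 6
```

trypsin's K/R-junction coverage collapses to 4.5% (the survivors are all
proline-suppressed sites), whereas chymotrypsin — whose cleavage residues
F/Y/L/W/M are not boundary-enriched — covers 55.7%, and the six enzymes'
detectable sets are largely complementary. Step 04 closes the loop on the
observed-peptide side: simulated tryptic peptides show a summed type 1–4
ratio of 8.9% versus 1.2% for chymotryptic peptides, with a massive
z-test spike for peptides starting exactly at splice sites (z = 15.2)
under trypsin and none under chymotrypsin.

Real annotations run through the same entry points, e.g.:

```bash
splicepep junctions --genome hg19.fa --annotation refGene.txt --outdir out/
splicepep digest --genome hg19.fa --annotation refGene.txt \
    --enzymes trypsin,chymotrypsin,asp-n --outdir out/
```

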