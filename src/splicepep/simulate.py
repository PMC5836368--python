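"""Synthetic genomes with controllable splice-boundary biases.

Generates multi-exon coding gene models in which each junction's reading
frame phase and boundary residue are planted from configurable
distributions: the phase is drawn from ``phase_weights`` and the boundary
codon (the triplet containing the donor exon's last coding nucleotide) is
a lysine/arginine codon with probability ``p_boundary_kr``. Phase 0
places the planted codon as the donor exon's last full triplet, phase 2
splits it 2+1 across the junction, and phase 1 splits it 1+2. All other
codons are drawn from a configurable codon-usage background with stop
codons excluded, so generated proteins always translate cleanly.

The generator emits standard genome FASTA and UCSC genePred plus a truth
table, and can simulate observed-peptide BED12 sets from enzyme digests
under a length-dependent detection model.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import GenomeSequence, TranscriptModel, revcomp
from .digestion import (
    Enzyme,
    PeptideRecord,
    collapse_unique,
    digest,
    project_to_genome,
    unique_representatives,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
KR_CODONS = ("AAA", "AAG", "CGT", "CGC", "CGA", "CGG", "AGA", "AGG")
_NONCANON_FIRST2 = ("CT", "AT", "CC", "TC")
_NONCANON_LAST2 = ("CT", "TC", "CC", "GC")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic annotation.

    Defaults mirror the biases documented for human coding genes: a
    quarter of junction boundary residues are K/R, phase usage ~
    (0.47, 0.30, 0.23), canonical GT..AG introns.
    """

    n_genes: int = 100
    exon_count_range: tuple[int, int] = (3, 8)
    exon_len_range_nt: tuple[int, int] = (60, 240)
    intron_len_range_nt: tuple[int, int] = (60, 400)
    codon_usage: dict | None = None  # per-sense-codon weights; None = uniform
    p_boundary_kr: float = 0.25
    phase_weights: tuple[float, float, float] = (0.47, 0.30, 0.23)
    p_canonical_intron: float = 1.0
    p_minus_strand: float = 0.5
    p_extra_isoform: float = 0.0
    kr_codons: tuple[str, ...] = KR_CODONS
    contig_name: str = "chrS"
    spacer_nt: int = 100
    seed: int = 0

    def validate(self) -> None:
        for p in (self.p_boundary_kr, self.p_canonical_intron,
                  self.p_minus_strand, self.p_extra_isoform):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if abs(sum(self.phase_weights) - 1.0) > 1e-9:
            raise ValueError("phase_weights must sum to 1")
        if self.exon_count_range[0] < 2 or self.exon_count_range[0] > self.exon_count_range[1]:
            raise ValueError("exon_count_range must be non-degenerate and >= 2")
        if self.exon_len_range_nt[0] < 12:
            raise ValueError("exons shorter than 12 nt cannot host planted "
                             "boundary codons")
        if self.exon_len_range_nt[0] > self.exon_len_range_nt[1]:
            raise ValueError("exon_len_range_nt degenerate")
        if self.intron_len_range_nt[0] < 8:
            raise ValueError("introns must be at least 8 nt")
        if not all(c in KR_CODONS for c in self.kr_codons) or not self.kr_codons:
            raise ValueError("kr_codons must be a non-empty subset of K/R codons")


@dataclass
class SyntheticGenome:
    """A generated genome, annotation and per-junction truth table."""

    genome: GenomeSequence
    models: list[TranscriptModel]
    truth: pd.DataFrame
    proteins: dict[str, str]
    config: SyntheticConfig

    def write(self, outdir) -> dict:
        """Write genome.fa, annotation.genePred, truth_junctions.tsv and a
        run manifest; returns the manifest dict."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        gp = outdir / "annotation.genePred"
        truth = outdir / "truth_junctions.tsv"
        write_fasta(self.genome, fasta)
        write_genepred(self.models, gp)
        self.truth.to_csv(truth, sep="\t", index=False)
        manifest = {
            "seed": self.config.seed,
            "n_genes": self.config.n_genes,
            "p_boundary_kr": self.config.p_boundary_kr,
            "phase_weights": list(self.config.phase_weights),
            "files": {
                "genome": fasta.name,
                "annotation": gp.name,
                "truth": truth.name,
            },
            "md5": {
                fasta.name: _md5(fasta),
                gp.name: _md5(gp),
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def _md5(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_genepred(models: Sequence[TranscriptModel], path) -> None:
    """15-column UCSC genePred (extended), exon lists comma-terminated."""
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            frames = "-1," * len(m.exons)
            fh.write(
                f"{m.transcript_id}\t{m.contig}\t{m.strand}\t"
                f"{m.exons[0][0]}\t{m.exons[-1][1]}\t{m.cds_start}\t{m.cds_end}\t"
                f"{len(m.exons)}\t{starts}\t{ends}\t0\t{m.gene_id}\t"
                f"cmpl\tcmpl\t{frames}\n"
            )


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _make_gene(cfg: SyntheticConfig, rng: np.random.Generator,
               usage_p: np.ndarray, nonkr: tuple, nonkr_p: np.ndarray):
    """Build one gene in transcript orientation.

    Returns (gene_seq, exon_local_intervals, junction_truths, protein)
    where intervals are gene-local half-open in transcript orientation.
    """
    n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
    phases = rng.choice(3, size=n_ex - 1, p=np.asarray(cfg.phase_weights))
    kr_flags = rng.random(n_ex - 1) < cfg.p_boundary_kr

    draws = rng.integers(cfg.exon_len_range_nt[0],
                         cfg.exon_len_range_nt[1] + 1, size=n_ex)
    lens, cum, cums = [], 0, []
    for e in range(n_ex - 1):
        needed = (int(phases[e]) - cum) % 3
        L = int(draws[e]) - ((int(draws[e]) - needed) % 3)
        lens.append(L)
        cum += L
        cums.append(cum)
    L_last = int(draws[-1]) - ((int(draws[-1]) + cum) % 3)
    lens.append(L_last)
    total = cum + L_last

    n_codons = total // 3
    codons = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS),
                                                  size=n_codons, p=usage_p)]
    codons[0] = "ATG"
    codons[-1] = STOP_CODONS[int(rng.integers(0, 3))]
    truths = []
    for e, c in enumerate(cums):
        b = (c - 1) // 3
        if kr_flags[e]:
            planted = cfg.kr_codons[int(rng.integers(0, len(cfg.kr_codons)))]
        else:
            planted = nonkr[int(rng.choice(len(nonkr), p=nonkr_p))]
        codons[b] = planted
        truths.append(
            {"phase": int(phases[e]),
             "boundary_residue": str(Seq(planted).translate()),
             "is_kr": bool(kr_flags[e])}
        )
    spliced = "".join(codons)
    protein = str(Seq(spliced).translate())[:-1]

    exon_seqs = []
    pos = 0
    for L in lens:
        exon_seqs.append(spliced[pos:pos + L])
        pos += L
    introns = []
    for _ in range(n_ex - 1):
        ilen = int(rng.integers(cfg.intron_len_range_nt[0],
                                cfg.intron_len_range_nt[1] + 1))
        iseq = _random_bases(rng, ilen)
        if rng.random() < cfg.p_canonical_intron:
            iseq = "GT" + iseq[2:-2] + "AG"
        else:
            iseq = (_NONCANON_FIRST2[int(rng.integers(0, 4))] + iseq[2:-2]
                    + _NONCANON_LAST2[int(rng.integers(0, 4))])
        introns.append(iseq)

    parts, intervals = [], []
    gpos = 0
    for e in range(n_ex):
        parts.append(exon_seqs[e])
        intervals.append((gpos, gpos + lens[e]))
        gpos += lens[e]
        if e < n_ex - 1:
            parts.append(introns[e])
            gpos += len(introns[e])
    return "".join(parts), intervals, truths, protein


def generate_genome(config: SyntheticConfig) -> SyntheticGenome:
    """Generate a genome FASTA + genePred annotation + truth table,
    fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.codon_usage is None:
        usage_p = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    else:
        usage_p = np.array([config.codon_usage.get(c, 0.0) for c in SENSE_CODONS])
        if usage_p.sum() <= 0:
            raise ValueError("codon_usage assigns no weight to sense codons")
        usage_p = usage_p / usage_p.sum()
    nonkr = tuple(c for c in SENSE_CODONS if c not in KR_CODONS)
    nonkr_p = np.array([usage_p[SENSE_CODONS.index(c)] for c in nonkr])
    if nonkr_p.sum() <= 0:
        raise ValueError("codon_usage leaves no non-K/R codons to sample")
    nonkr_p = nonkr_p / nonkr_p.sum()

    chunks = [_random_bases(rng, config.spacer_nt)]
    offset = config.spacer_nt
    models: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    proteins: dict[str, str] = {}
    for gi in range(config.n_genes):
        gene_seq, intervals, truths, protein = _make_gene(
            config, rng, usage_p, nonkr, nonkr_p
        )
        strand = "-" if rng.random() < config.p_minus_strand else "+"
        L = len(gene_seq)
        if strand == "+":
            gseq = gene_seq
            exons = [(offset + s, offset + e) for s, e in intervals]
        else:
            gseq = revcomp(gene_seq)
            exons = sorted(
                (offset + L - e, offset + L - s) for s, e in intervals
            )
        tid, gid = f"SYNT{gi:05d}", f"SYNG{gi:05d}"
        model = TranscriptModel(
            transcript_id=tid, gene_id=gid, contig=config.contig_name,
            strand=strand, exons=exons,
            cds_start=offset, cds_end=offset + L,
        )
        models.append(model)
        proteins[tid] = protein
        for ji, t in enumerate(truths):
            d_loc_last = intervals[ji][1] - 1
            a_loc_first = intervals[ji + 1][0]
            if strand == "+":
                d_end = offset + d_loc_last
                a_start = offset + a_loc_first
            else:
                d_end = offset + L - 1 - d_loc_last
                a_start = offset + L - 1 - a_loc_first
            truth_rows.append(
                {"gene_id": gid, "transcript_id": tid, "junction_index": ji,
                 "contig": config.contig_name, "strand": strand,
                 "donor_end": d_end, "acceptor_start": a_start, **t}
            )
        if rng.random() < config.p_extra_isoform:
            iso = replace(model, transcript_id=tid + "b")
            models.append(iso)
            proteins[iso.transcript_id] = protein
        chunks.append(gseq)
        chunks.append(_random_bases(rng, config.spacer_nt))
        offset += L + config.spacer_nt

    genome = GenomeSequence({config.contig_name: "".join(chunks)})
    truth = pd.DataFrame(truth_rows)
    return SyntheticGenome(genome=genome, models=models, truth=truth,
                           proteins=proteins, config=config)


def simulate_observed_peptides(
    transcripts,
    enzyme: Enzyme,
    detection_model: Callable[[int], float],
    seed: int,
    max_missed: int = 0,
) -> list[PeptideRecord]:
    """Digest every transcript protein and sample each uniquely mapped
    peptide independently with probability ``detection_model(length)``.

    Returns the detected unique peptide records (BED12-ready)."""
    rng = np.random.default_rng(seed)
    records: list[PeptideRecord] = []
    for ct in transcripts:
        if not ct.protein:
            continue
        for r in digest(ct.protein, enzyme, max_missed):
            records.append(project_to_genome(r, ct))
    collapse_unique(records)
    reps = unique_representatives(records)
    reps.sort(key=lambda r: (r.contig, r.blocks, r.sequence))
    out = []
    for r in reps:
        p = detection_model(len(r))
        if not 0.0 <= p <= 1.0:
            raise ValueError("detection probabilities must lie in [0,1]")
        if rng.random() < p:
            out.append(r)
    return out
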