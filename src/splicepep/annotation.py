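"""Gene models, coding transcripts, and splice-junction enumeration.

Parses genome FASTA plus gene models (UCSC genePred or GTF2.2) into
:class:`CodingTranscript` objects that carry the spliced coding sequence,
the translated protein, and a codon-resolved projection onto the genome.
Unique coding splice junctions are enumerated with their reading-frame
phase and boundary residue — the amino acid whose codon contains the last
coding nucleotide of the donor exon.

Coordinates are 0-based, half-open genomic intervals throughout. All
transcript-relative quantities (phase, cumulative coding offsets, boundary
residues) are computed in translation orientation; genomic blocks are
stored in genomic order with the transcript strand carrying orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Uppercase nucleotide sequences keyed by contig name."""

    contigs: dict[str, str]

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if start < 0 or end > len(seq):
            raise IndexError(f"{contig}:{start}-{end} outside contig bounds")
        return seq[start:end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


def read_genome(fasta_source) -> GenomeSequence:
    """Load a FASTA file into memory, uppercasing and mapping non-ACGT to N.

    Raises ``ValueError`` on duplicate contig names or an empty file.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(fasta_source, "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name: {rec.id}")
        seq = str(rec.seq).upper()
        # restrict alphabet to {A,C,G,T,N}
        if any(c not in "ACGTN" for c in set(seq)):
            seq = "".join(c if c in "ACGTN" else "N" for c in seq)
        if not seq:
            raise ValueError(f"empty sequence for contig {rec.id}")
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError("no FASTA records found")
    return GenomeSequence(contigs)


@dataclass
class TranscriptModel:
    """One transcript's exon structure and CDS bounds on the genome."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # sorted, non-overlapping, half-open
    cds_start: int
    cds_end: int

    def coding_segments(self) -> list[tuple[int, int]]:
        """Exon ∩ CDS intervals, in genomic order, empty pieces dropped."""
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return out

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.coding_segments())


def _parse_genepred_line(line: str) -> TranscriptModel | None:
    cols = line.rstrip("\n").split("\t")
    # UCSC tables may carry a leading `bin` column; detect by strand position
    if len(cols) >= 3 and cols[2] in "+-":
        pass
    elif len(cols) >= 4 and cols[3] in "+-":
        cols = cols[1:]
    else:
        raise ValueError(f"unparseable genePred line: {line[:80]!r}")
    name, chrom, strand = cols[0], cols[1], cols[2]
    cds_start, cds_end = int(cols[5]), int(cols[6])
    n_exons = int(cols[7])
    starts = [int(x) for x in cols[8].rstrip(",").split(",")]
    ends = [int(x) for x in cols[9].rstrip(",").split(",")]
    if len(starts) != n_exons or len(ends) != n_exons:
        raise ValueError(f"exon count mismatch in genePred record {name}")
    gene = cols[11] if len(cols) > 11 and cols[11] else name
    return TranscriptModel(
        transcript_id=name,
        gene_id=gene,
        contig=chrom,
        strand=strand,
        exons=list(zip(starts, ends)),
        cds_start=cds_start,
        cds_end=cds_end,
    )


def _read_genepred(source) -> list[TranscriptModel]:
    models = []
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        models.append(_parse_genepred_line(line))
    return models


def _read_gtf(source) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, contig, strand)
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            cds.setdefault(tid, []).append(iv)
    models = []
    for tid, (gid, contig, strand) in meta.items():
        if tid not in cds:
            continue  # non-coding transcript
        ex = sorted(exons.get(tid, cds[tid]))
        cds_start = min(s for s, _ in cds[tid])
        cds_end = max(e for _, e in cds[tid])
        models.append(
            TranscriptModel(tid, gid, contig, strand, ex, cds_start, cds_end)
        )
    return models


def read_gene_models(
    annotation_source,
    format: str = "genePred",
    genome: GenomeSequence | None = None,
) -> list[TranscriptModel]:
    """Parse gene models, keeping only well-formed coding transcripts.

    Non-coding transcripts are dropped silently; transcripts whose CDS
    length is not a multiple of 3, or whose exons fall outside contig
    bounds (when a genome is supplied), are dropped with a warning.
    """
    if format == "genePred":
        raw = _read_genepred(annotation_source)
    elif format in ("GTF", "gtf"):
        raw = _read_gtf(annotation_source)
    else:
        raise ValueError(f"unknown annotation format: {format!r}")

    models = []
    for m in raw:
        if m.cds_start >= m.cds_end:
            continue  # non-coding
        if genome is not None:
            if m.contig not in genome:
                logger.warning("%s: contig %s not in genome; rejected",
                               m.transcript_id, m.contig)
                continue
            clen = len(genome.contigs[m.contig])
            if any(s < 0 or e > clen for s, e in m.exons):
                logger.warning("%s: exon outside contig bounds; rejected",
                               m.transcript_id)
                continue
        if m.cds_len % 3 != 0:
            logger.warning("%s: CDS length %d not divisible by 3; dropped",
                           m.transcript_id, m.cds_len)
            continue
        models.append(m)
    return models


@dataclass
class CodingTranscript:
    """A transcript's spliced CDS, protein, and codon→genome projection.

    ``nt_pos[i]`` is the genomic coordinate of coding nucleotide ``i`` in
    translation order (descending for minus-strand transcripts).
    ``cds_nt`` includes the annotated stop codon when present; ``protein``
    never does.
    """

    model: TranscriptModel
    cds_nt: str
    protein: str
    nt_pos: np.ndarray = field(repr=False)
    has_ambiguous: bool = False

    @property
    def transcript_id(self) -> str:
        return self.model.transcript_id

    @property
    def strand(self) -> str:
        return self.model.strand

    @property
    def contig(self) -> str:
        return self.model.contig

    def segments(self) -> list[tuple[int, int]]:
        """Coding segments in translation order (genomic intervals)."""
        segs = self.model.coding_segments()
        return segs if self.strand == "+" else segs[::-1]

    def junction_offsets(self) -> list[int]:
        """Cumulative coding-nt position of each internal junction."""
        lens = [e - s for s, e in self.segments()]
        out, cum = [], 0
        for ln in lens[:-1]:
            cum += ln
            out.append(cum)
        return out

    def _runs(self, lo: int, hi: int) -> list[tuple[int, int]]:
        """Maximal genomically contiguous blocks of nt_pos[lo:hi],
        in translation order, each as a half-open genomic interval."""
        pos = self.nt_pos[lo:hi]
        if len(pos) == 0:
            return []
        step = 1 if self.strand == "+" else -1
        breaks = np.nonzero(np.diff(pos) != step)[0]
        bounds = np.concatenate(([0], breaks + 1, [len(pos)]))
        blocks = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            first, last = int(pos[a]), int(pos[b - 1])
            blocks.append((min(first, last), max(first, last) + 1))
        return blocks

    def codon_blocks(self, residue_index: int) -> list[tuple[int, int]]:
        """Genomic blocks (1–2) occupied by the codon of residue i."""
        return self._runs(3 * residue_index, 3 * residue_index + 3)

    @property
    def codon_map(self) -> list[list[tuple[int, int]]]:
        return [self.codon_blocks(i) for i in range(len(self.protein))]

    def blocks_for_span(self, start_res: int, end_res: int) -> list[tuple[int, int]]:
        """Genomic blocks covering residues [start_res, end_res),
        in translation order."""
        if not (0 <= start_res < end_res <= len(self.protein)):
            raise ValueError(
                f"residue span [{start_res},{end_res}) outside protein of "
                f"length {len(self.protein)}"
            )
        return self._runs(3 * start_res, 3 * end_res)


def build_coding_transcript(
    model: TranscriptModel, genome: GenomeSequence
) -> CodingTranscript | None:
    """Splice, orient and translate a transcript model.

    Returns ``None`` (with a warning) for transcripts containing an
    in-frame internal stop codon. Ambiguous bases translate to X and set
    ``has_ambiguous``.
    """
    segs = model.coding_segments()
    if model.strand == "+":
        parts = [genome.fetch(model.contig, s, e) for s, e in segs]
        pos_parts = [np.arange(s, e, dtype=np.int64) for s, e in segs]
    else:
        parts = [genome.fetch(model.contig, s, e) for s, e in segs[::-1]]
        parts = [revcomp(p) for p in parts]
        pos_parts = [np.arange(e - 1, s - 1, -1, dtype=np.int64)
                     for s, e in segs[::-1]]
    cds_nt = "".join(parts)
    nt_pos = (np.concatenate(pos_parts) if pos_parts
              else np.empty(0, dtype=np.int64))

    aa = str(Seq(cds_nt).translate())
    if aa.endswith("*"):
        protein = aa[:-1]
    else:
        protein = aa
    if "*" in protein:
        logger.warning("%s: in-frame internal stop; rejected",
                       model.transcript_id)
        return None
    has_ambiguous = "N" in cds_nt
    return CodingTranscript(
        model=model,
        cds_nt=cds_nt,
        protein=protein,
        nt_pos=nt_pos,
        has_ambiguous=has_ambiguous,
    )


def build_coding_transcripts(
    models: Iterable[TranscriptModel], genome: GenomeSequence
) -> list[CodingTranscript]:
    out = []
    for m in models:
        ct = build_coding_transcript(m, genome)
        if ct is not None:
            out.append(ct)
    return out


JunctionKey = tuple[str, str, int, int]  # contig, strand, donor_end, acceptor_start


@dataclass
class SpliceJunction:
    """A coding exon–exon junction on the genome.

    ``donor_end`` is the genomic coordinate of the last base of the donor
    exon; ``acceptor_start`` that of the first base of the acceptor exon,
    both in transcription orientation. ``phase`` is the cumulative count
    of coding nucleotides upstream of the junction modulo 3; phase 0 means
    the junction falls between codons. The boundary residue is the amino
    acid whose codon contains the donor exon's final coding nucleotide
    ('*' when that triplet is the stop codon).
    """

    contig: str
    strand: str
    donor_end: int
    acceptor_start: int
    phase: int
    boundary_residue: str
    donor_len: int = 0      # coding nt in the donor-side segment
    acceptor_len: int = 0   # coding nt in the acceptor-side segment
    transcript_id: str | None = None

    @property
    def key(self) -> JunctionKey:
        return (self.contig, self.strand, self.donor_end, self.acceptor_start)

    @property
    def splits_codon(self) -> bool:
        return self.phase != 0

    @property
    def is_kr(self) -> bool:
        return self.boundary_residue in ("K", "R")


def iter_junction_occurrences(
    transcripts: Iterable[CodingTranscript],
) -> Iterator[SpliceJunction]:
    """Yield one junction record per (transcript, junction) occurrence.

    Only junctions internal to the CDS (coding sequence on both sides)
    are yielded.
    """
    for ct in transcripts:
        segs = ct.segments()
        if len(segs) < 2:
            continue
        full = ct.cds_nt  # includes stop codon if annotated
        n_res_full = len(full) // 3
        cum = 0
        for i in range(len(segs) - 1):
            s, e = segs[i]
            cum += e - s
            phase = cum % 3
            bidx = (cum - 1) // 3
            if bidx < len(ct.protein):
                res = ct.protein[bidx]
            elif bidx < n_res_full:
                res = "*"  # junction splits the stop codon
            else:  # pragma: no cover - malformed annotation
                continue
            if ct.strand == "+":
                donor_end = segs[i][1] - 1
                acceptor_start = segs[i + 1][0]
            else:
                donor_end = segs[i][0]
                acceptor_start = segs[i + 1][1] - 1
            yield SpliceJunction(
                contig=ct.contig,
                strand=ct.strand,
                donor_end=donor_end,
                acceptor_start=acceptor_start,
                phase=phase,
                boundary_residue=res,
                donor_len=segs[i][1] - segs[i][0],
                acceptor_len=segs[i + 1][1] - segs[i + 1][0],
                transcript_id=ct.transcript_id,
            )


def enumerate_junctions(
    transcripts: Iterable[CodingTranscript],
) -> list[SpliceJunction]:
    """Unique coding splice junctions, deduplicated on
    (contig, strand, donor_end, acceptor_start). Junctions shared across
    isoforms collapse to the first-encountered record."""
    seen: dict[JunctionKey, SpliceJunction] = {}
    for jct in iter_junction_occurrences(transcripts):
        if jct.key not in seen:
            seen[jct.key] = jct
    return list(seen.values())


def write_junction_table(junctions: Sequence[SpliceJunction], path) -> None:
    """Write the junction table as TSV."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "contig": [j.contig for j in junctions],
            "strand": [j.strand for j in junctions],
            "donor_end": [j.donor_end for j in junctions],
            "acceptor_start": [j.acceptor_start for j in junctions],
            "phase": [j.phase for j in junctions],
            "boundary_residue": [j.boundary_residue for j in junctions],
            "is_KR": [j.is_kr for j in junctions],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_junction_bed(junctions: Sequence[SpliceJunction], path) -> None:
    """Write junction anchor intervals (donor last base, acceptor first
    base) as 6-column BED."""
    with open(path, "w") as fh:
        for j in junctions:
            lo = min(j.donor_end, j.acceptor_start)
            hi = max(j.donor_end, j.acceptor_start) + 1
            name = f"{j.boundary_residue}_phase{j.phase}"
            fh.write(f"{j.contig}\t{lo}\t{hi}\t{name}\t0\t{j.strand}\n")
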