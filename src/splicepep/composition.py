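"""Amino-acid composition and nucleotide patterns at splice junctions.

Quantifies how boundary residues — the amino acids encoded at exon ends
and across exon–exon junctions — differ from the proteome background,
how often they are lysine/arginine (trypsin cleavage sites), and how the
reading-frame phase of a junction converts that bias into cleavage
scenarios that place a protease cut exactly at (phase 0) or one
nucleotide past (phase 2) the splice site.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotation import (
    CodingTranscript,
    GenomeSequence,
    SpliceJunction,
    iter_junction_occurrences,
    revcomp,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


@dataclass
class CompositionReport:
    """Boundary-residue composition against the proteome background.

    ``mode`` records whether boundary residues were counted once per
    (transcript, junction) occurrence or once per unique junction.
    """

    boundary_counts: dict[str, int]
    background_freq: dict[str, float]
    n_boundary: int
    mode: str

    @property
    def boundary_freq(self) -> dict[str, float]:
        if self.n_boundary == 0:
            return {}
        return {aa: c / self.n_boundary for aa, c in self.boundary_counts.items()}

    @property
    def fold_change(self) -> dict[str, float]:
        if self.n_boundary == 0:
            return {}  # undefined without boundary observations
        bf = self.boundary_freq
        return {
            aa: bf.get(aa, 0.0) / self.background_freq[aa]
            for aa in self.background_freq
            if self.background_freq[aa] > 0
        }

    def top_share(self, k: int = 5) -> tuple[float, float, list[str]]:
        """Summed boundary and background frequency of the k most
        boundary-enriched amino acids (by fold change)."""
        fc = self.fold_change
        top = sorted(fc, key=fc.get, reverse=True)[:k]
        bshare = sum(self.boundary_freq.get(aa, 0.0) for aa in top)
        gshare = sum(self.background_freq[aa] for aa in top)
        return bshare, gshare, top

    def to_frame(self):
        import pandas as pd

        bf, fc = self.boundary_freq, self.fold_change
        return pd.DataFrame(
            {
                "residue": list(AMINO_ACIDS),
                "boundary_count": [self.boundary_counts.get(a, 0) for a in AMINO_ACIDS],
                "boundary_freq": [bf.get(a, 0.0) for a in AMINO_ACIDS],
                "background_freq": [self.background_freq.get(a, 0.0) for a in AMINO_ACIDS],
                "fold_change": [fc.get(a, np.nan) for a in AMINO_ACIDS],
            }
        )


def background_residue_freq(
    transcripts: Iterable[CodingTranscript],
) -> dict[str, float]:
    """Per-amino-acid frequency over all residues of all proteins,
    counted redundantly across isoforms. X (ambiguous) is excluded."""
    counts: Counter = Counter()
    for ct in transcripts:
        counts.update(ct.protein)
    total = sum(counts[aa] for aa in AMINO_ACIDS)
    if total == 0:
        return {aa: 0.0 for aa in AMINO_ACIDS}
    return {aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS}


def boundary_residue_composition(
    junctions: Sequence[SpliceJunction],
    transcripts: Sequence[CodingTranscript],
    mode: str = "occurrence",
) -> CompositionReport:
    """Boundary-residue composition report.

    mode='occurrence' counts one boundary residue per (transcript,
    junction) occurrence; mode='unique' counts once per unique junction
    (the input list). Residues outside the 20 standard letters ('X',
    '*') are excluded from both counts and background.
    """
    if mode == "occurrence":
        residues = [j.boundary_residue for j in iter_junction_occurrences(transcripts)]
    elif mode == "unique":
        residues = [j.boundary_residue for j in junctions]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    residues = [r for r in residues if r in AMINO_ACIDS]
    counts = dict(Counter(residues))
    return CompositionReport(
        boundary_counts=counts,
        background_freq=background_residue_freq(transcripts),
        n_boundary=len(residues),
        mode=mode,
    )


@dataclass
class KRPartition:
    """Unique junctions partitioned into K/R and other."""

    kr: list[SpliceJunction]
    other: list[SpliceJunction]

    @property
    def n_kr(self) -> int:
        return len(self.kr)

    @property
    def n_total(self) -> int:
        return len(self.kr) + len(self.other)

    @property
    def fraction_kr(self) -> float:
        return self.n_kr / self.n_total if self.n_total else float("nan")


def classify_kr_junctions(junctions: Iterable[SpliceJunction]) -> KRPartition:
    """A junction is K/R iff its boundary residue is lysine or arginine."""
    kr, other = [], []
    for j in junctions:
        (kr if j.is_kr else other).append(j)
    return KRPartition(kr=kr, other=other)


@dataclass
class PositionFrequencyMatrix:
    """Nucleotide frequencies around a splice site, strand-corrected.

    Offsets run -exon_flank..-1 on the exon side and +1..+intron_flank on
    the intron side for the donor, mirrored for the acceptor. Positions
    with zero informative coverage carry NaN rather than a smoothed value.
    """

    site_kind: str  # 'donor_5prime' or 'acceptor_3prime'
    offsets: list[int]
    counts: np.ndarray  # (n_positions, 4) in NUCLEOTIDES order

    @property
    def freq(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)

    def trimmed(self, k: int = 4) -> "PositionFrequencyMatrix":
        """±k view around the site, for logo rendering."""
        idx = [i for i, o in enumerate(self.offsets) if -k <= o <= k]
        return PositionFrequencyMatrix(
            self.site_kind, [self.offsets[i] for i in idx], self.counts[idx]
        )

    def prob(self, offset: int, base: str) -> float:
        i = self.offsets.index(offset)
        return float(self.freq[i, NUCLEOTIDES.index(base)])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.freq, columns=list(NUCLEOTIDES))
        df.insert(0, "offset", self.offsets)
        return df


def _count_window(mat: np.ndarray, seq: str, start_row: int) -> None:
    for i, base in enumerate(seq):
        j = NUCLEOTIDES.find(base)
        if j >= 0:
            mat[start_row + i, j] += 1


def splice_site_pfm(
    junctions: Sequence[SpliceJunction],
    genome: GenomeSequence,
    exon_flank: int = 10,
    intron_flank: int = 10,
) -> tuple[PositionFrequencyMatrix, PositionFrequencyMatrix]:
    """Donor and acceptor position-frequency matrices.

    Windows are strand-corrected so the intron side of the donor starts
    GT and the intron side of the acceptor ends AG for canonical
    junctions. Junctions whose flanks overrun the contig are skipped
    with a warning.
    """
    junctions = list(junctions)
    if not junctions:
        raise ValueError("junction set is empty")
    n_pos = exon_flank + intron_flank
    donor = np.zeros((n_pos, 4))
    acceptor = np.zeros((n_pos, 4))
    skipped = 0
    for j in junctions:
        contig_len = len(genome.contigs[j.contig])
        try:
            if j.strand == "+":
                d_exon = genome.fetch(j.contig, j.donor_end - exon_flank + 1,
                                      j.donor_end + 1)
                d_intron = genome.fetch(j.contig, j.donor_end + 1,
                                        j.donor_end + 1 + intron_flank)
                a_intron = genome.fetch(j.contig, j.acceptor_start - intron_flank,
                                        j.acceptor_start)
                a_exon = genome.fetch(j.contig, j.acceptor_start,
                                      j.acceptor_start + exon_flank)
            else:
                d_exon = revcomp(genome.fetch(j.contig, j.donor_end,
                                              j.donor_end + exon_flank))
                d_intron = revcomp(genome.fetch(j.contig,
                                                j.donor_end - intron_flank,
                                                j.donor_end))
                a_intron = revcomp(genome.fetch(j.contig, j.acceptor_start + 1,
                                                j.acceptor_start + 1 + intron_flank))
                a_exon = revcomp(genome.fetch(j.contig,
                                              j.acceptor_start - exon_flank + 1,
                                              j.acceptor_start + 1))
        except IndexError:
            skipped += 1
            continue
        _count_window(donor, d_exon, 0)
        _count_window(donor, d_intron, exon_flank)
        _count_window(acceptor, a_intron, 0)
        _count_window(acceptor, a_exon, intron_flank)
    if skipped:
        logger.warning("splice_site_pfm: skipped %d junctions with flanks "
                       "overrunning a contig", skipped)
    exon_off = list(range(-exon_flank, 0))
    intron_off = list(range(1, intron_flank + 1))
    donor_pfm = PositionFrequencyMatrix("donor_5prime", exon_off + intron_off, donor)
    acceptor_pfm = PositionFrequencyMatrix(
        "acceptor_3prime", [-o for o in intron_off[::-1]] + [o for o in range(1, exon_flank + 1)],
        acceptor,
    )
    return donor_pfm, acceptor_pfm


@dataclass
class CleavageScenarioStats:
    """Frame-adjusted probabilities that a junction is a protease site.

    Scenario 1: phase-0 junction with a K/R boundary residue — the cut
    falls exactly at the splice site. Scenario 2: phase-2 junction with a
    K/R boundary residue — the cut falls 1 nt into the acceptor exon.
    Phase-1 K/R junctions (cut 2 nt into the acceptor) are reported
    separately.
    """

    phase_usage: dict[int, float]
    p_kr_given_phase: dict[int, float]
    p_kr_adjusted: float
    p_scenario1: float
    p_scenario2: float
    p_phase1_kr: float
    n_junctions: int

    def to_dict(self) -> dict:
        return {
            "n_junctions": self.n_junctions,
            "phase_usage": {str(k): v for k, v in self.phase_usage.items()},
            "p_kr_given_phase": {str(k): v for k, v in self.p_kr_given_phase.items()},
            "p_kr_adjusted": self.p_kr_adjusted,
            "p_scenario1": self.p_scenario1,
            "p_scenario2": self.p_scenario2,
            "p_phase1_kr": self.p_phase1_kr,
        }


def cleavage_scenario_stats(
    junctions: Sequence[SpliceJunction],
    residue_set: frozenset[str] = frozenset("KR"),
) -> CleavageScenarioStats:
    """Phase usage, per-phase K/R probability, and scenario probabilities
    over unique junctions."""
    junctions = list(junctions)
    n = len(junctions)
    n_phase = Counter(j.phase for j in junctions)
    n_hit = Counter(j.phase for j in junctions if j.boundary_residue in residue_set)
    phase_usage = {p: (n_phase.get(p, 0) / n if n else 0.0) for p in (0, 1, 2)}
    p_given = {
        p: (n_hit.get(p, 0) / n_phase[p] if n_phase.get(p) else float("nan"))
        for p in (0, 1, 2)
    }
    p_adj = sum(
        phase_usage[p] * p_given[p]
        for p in (0, 1, 2)
        if n_phase.get(p)
    )
    return CleavageScenarioStats(
        phase_usage=phase_usage,
        p_kr_given_phase=p_given,
        p_kr_adjusted=p_adj,
        p_scenario1=n_hit.get(0, 0) / n if n else 0.0,
        p_scenario2=n_hit.get(2, 0) / n if n else 0.0,
        p_phase1_kr=n_hit.get(1, 0) / n if n else 0.0,
        n_junctions=n,
    )


def expected_boundary_terminus_rate(
    median_peptide_len_aa: float, median_exon_len_aa: float
) -> float:
    """Expected fraction of within-exon peptides whose terminus falls on
    an exon boundary: 2 / (median exon length − median peptide length),
    both in amino acids, capped at 1."""
    denom = median_exon_len_aa - median_peptide_len_aa
    if denom <= 0:
        raise ValueError(
            "median exon length must exceed median peptide length"
        )
    return min(2.0 / denom, 1.0)
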