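"""Junction detectability, peptide type classification, and enrichment.

A junction is *detectable* under a digestion scheme when at least one
uniquely mapped, length- and missed-cleavage-filtered peptide spans it
with sufficient nucleotide coverage on both sides. The acceptor-side
minimum defaults to 3 nt, which excludes both single-nucleotide (type 4)
and two-nucleotide acceptor-coverage peptides whose genomic mapping is
uncertain; the donor-side minimum defaults to 1 nt.

Observed peptide termini are classified against splice sites into four
types: (1) start at an acceptor exon's first base, (2) start one base
downstream of it, (3) end at a donor exon's last base, (4) a
junction-spanning peptide ending on the acceptor exon's first base —
the four signatures of a protease cut at or 1 nt past a splice site.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import CodingTranscript, JunctionKey, SpliceJunction
from .digestion import PeptideRecord, unique_representatives

logger = logging.getLogger(__name__)


def annotation_fingerprint(junctions: Iterable[SpliceJunction]) -> str:
    """Stable digest of the unique-junction set, used to refuse
    cross-annotation enzyme comparisons."""
    keys = sorted(f"{j.contig}:{j.strand}:{j.donor_end}:{j.acceptor_start}"
                  for j in junctions)
    return hashlib.md5("|".join(keys).encode()).hexdigest()


@dataclass
class CoverageReport:
    """Per-enzyme CDS / junction / K-R junction detectability."""

    enzyme: str
    cds_coverage: float
    n_junctions: int
    n_detectable_junctions: int
    n_kr_junctions: int
    n_detectable_kr: int
    detectable_keys: set = field(default_factory=set, repr=False)
    detectable_kr_keys: set = field(default_factory=set, repr=False)
    fingerprint: str = ""
    min_acceptor_nt: int = 3
    min_donor_nt: int = 1

    @property
    def junction_coverage(self) -> float:
        return (self.n_detectable_junctions / self.n_junctions
                if self.n_junctions else 0.0)

    @property
    def kr_coverage(self) -> float:
        return (self.n_detectable_kr / self.n_kr_junctions
                if self.n_kr_junctions else 0.0)

    def to_dict(self) -> dict:
        return {
            "enzyme": self.enzyme,
            "cds_coverage": self.cds_coverage,
            "n_junctions": self.n_junctions,
            "n_detectable_junctions": self.n_detectable_junctions,
            "junction_coverage": self.junction_coverage,
            "n_kr_junctions": self.n_kr_junctions,
            "n_detectable_kr": self.n_detectable_kr,
            "kr_coverage": self.kr_coverage,
            "min_acceptor_nt": self.min_acceptor_nt,
            "min_donor_nt": self.min_donor_nt,
        }


def coverage_report(
    peptides: Sequence[PeptideRecord],
    junctions: Sequence[SpliceJunction],
    transcripts: Sequence[CodingTranscript],
    enzyme_name: str = "",
    min_acceptor_nt: int = 3,
    min_donor_nt: int = 1,
    contig_lengths: Mapping[str, int] | None = None,
) -> CoverageReport:
    """Compute CDS and junction coverage from uniquely mapped peptides.

    ``peptides`` must be projected and uniqueness-flagged; only unique
    sequences count. CDS coverage is nucleotide-level over the union of
    genomic CDS positions of all transcripts.
    """
    reps = unique_representatives(peptides)
    jmap = {j.key: j for j in junctions}

    detectable: set[JunctionKey] = set()
    for r in reps:
        for key, (dcov, acov) in r.junction_coverage.items():
            if key in jmap and acov >= min_acceptor_nt and dcov >= min_donor_nt:
                detectable.add(key)
    detectable_kr = {k for k in detectable if jmap[k].is_kr}
    n_kr = sum(1 for j in junctions if j.is_kr)

    # nucleotide-level CDS coverage over genomic positions
    if contig_lengths is None:
        contig_lengths = {}
        for ct in transcripts:
            hi = max((e for _, e in ct.model.coding_segments()), default=0)
            contig_lengths[ct.contig] = max(contig_lengths.get(ct.contig, 0), hi)
    cds_mask = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    cov_mask = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    for ct in transcripts:
        m = cds_mask.get(ct.contig)
        if m is None:
            continue
        for s, e in ct.model.coding_segments():
            m[s:e] = True
    for r in reps:
        m = cov_mask.get(r.contig)
        if m is None:
            continue
        for s, e in r.blocks:
            m[s:e] = True
    n_cds = sum(int(m.sum()) for m in cds_mask.values())
    n_cov = sum(int((cds_mask[c] & cov_mask[c]).sum()) for c in cds_mask)

    return CoverageReport(
        enzyme=enzyme_name,
        cds_coverage=(n_cov / n_cds if n_cds else 0.0),
        n_junctions=len(junctions),
        n_detectable_junctions=len(detectable),
        n_kr_junctions=n_kr,
        n_detectable_kr=len(detectable_kr),
        detectable_keys=detectable,
        detectable_kr_keys=detectable_kr,
        fingerprint=annotation_fingerprint(junctions),
        min_acceptor_nt=min_acceptor_nt,
        min_donor_nt=min_donor_nt,
    )


def compare_enzymes(reports: Sequence[CoverageReport], kr_only: bool = False) -> dict:
    """Union / intersection / exclusive-region counts of detectable
    junction sets across enzyme runs on the same annotation.

    For 2–3 enzymes, per-subset (Venn region) counts are included.
    Raises ``ValueError`` when the runs' annotation fingerprints differ.
    """
    if len(reports) < 2:
        raise ValueError("need at least two enzyme runs to compare")
    fps = {r.fingerprint for r in reports}
    if len(fps) != 1:
        raise ValueError("annotation fingerprints differ across runs; "
                         "enzyme comparisons require one annotation")
    sets = {
        r.enzyme: (r.detectable_kr_keys if kr_only else r.detectable_keys)
        for r in reports
    }
    names = list(sets)
    union = set().union(*sets.values())
    inter = set.intersection(*sets.values())
    out = {
        "enzymes": names,
        "kr_only": kr_only,
        "per_enzyme": {n: len(s) for n, s in sets.items()},
        "union": len(union),
        "intersection": len(inter),
        "pairwise_intersection": {
            f"{a}&{b}": len(sets[a] & sets[b]) for a, b in combinations(names, 2)
        },
    }
    if len(names) in (2, 3):
        regions = {}
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                inside = set.intersection(*(sets[n] for n in combo))
                outside = set().union(*(sets[n] for n in names if n not in combo)) \
                    if len(combo) < len(names) else set()
                regions["&".join(combo)] = len(inside - outside)
        out["exclusive_regions"] = regions
    return out


class JunctionIndex:
    """Lookup structures over unique junctions for terminus classification."""

    def __init__(self, junctions: Iterable[SpliceJunction]):
        self.by_acceptor: dict[tuple[str, str, int], SpliceJunction] = {}
        self.by_donor: dict[tuple[str, str, int], SpliceJunction] = {}
        self.by_key: dict[JunctionKey, SpliceJunction] = {}
        for j in junctions:
            self.by_acceptor[(j.contig, j.strand, j.acceptor_start)] = j
            self.by_donor[(j.contig, j.strand, j.donor_end)] = j
            self.by_key[j.key] = j


def _termini(record: PeptideRecord) -> tuple[int, int, int]:
    """(5'-most base, 3'-most base, direction) in translation orientation."""
    if record.strand == "+":
        return record.blocks[0][0], record.blocks[-1][1] - 1, 1
    return record.blocks[-1][1] - 1, record.blocks[0][0], -1


@dataclass
class PeptideTypeCall:
    peptide: str
    type: int  # 1..4, or 0 for 'none'
    offset_nt: int


def classify_peptide_type(
    record: PeptideRecord, index: JunctionIndex
) -> list[PeptideTypeCall]:
    """Type calls for one uniquely mapped peptide (at most one start-side
    and one end-side call; a single type-0 call when neither matches).

    Acceptor exons are by construction never the first coding exon and
    donor exons never the last, so the required exclusions are implicit.
    """
    g5, g3, d = _termini(record)
    contig, strand = record.contig, record.strand
    calls = []
    j = index.by_acceptor.get((contig, strand, g5))
    if j is not None:
        calls.append(PeptideTypeCall(record.sequence, 1, 0))
    else:
        j = index.by_acceptor.get((contig, strand, g5 - d))
        if j is not None and j.acceptor_len >= 2:
            calls.append(PeptideTypeCall(record.sequence, 2, 1))
    j = index.by_donor.get((contig, strand, g3))
    if j is not None:
        calls.append(PeptideTypeCall(record.sequence, 3, 0))
    else:
        j = index.by_acceptor.get((contig, strand, g3))
        if j is not None and record.spans_junction and j.key in record.junction_coverage:
            calls.append(PeptideTypeCall(record.sequence, 4, 1))
    if not calls:
        calls.append(PeptideTypeCall(record.sequence, 0, -1))
    return calls


def classify_peptides(
    records: Iterable[PeptideRecord], index: JunctionIndex
) -> list[PeptideTypeCall]:
    """Classify every uniquely mapped peptide; ambiguous records are
    skipped with a warning."""
    calls = []
    skipped = 0
    for r in records:
        if r.unique_genomic is False:
            skipped += 1
            continue
        if not r.blocks:
            skipped += 1
            continue
        calls.extend(classify_peptide_type(r, index))
    if skipped:
        logger.warning("classify_peptides: skipped %d ambiguous/unmapped "
                       "peptides", skipped)
    return calls


def type_ratio_summary(calls: Sequence[PeptideTypeCall],
                       n_peptides: int | None = None) -> dict:
    """Per-type fractions over uniquely mapped peptide sequences.

    A peptide with both a start-side and an end-side call contributes to
    both types. ``summed_ratio`` is the sum of the four per-type
    fractions.
    """
    peptides = {c.peptide for c in calls}
    n = n_peptides if n_peptides is not None else len(peptides)
    per_type = {}
    for t in (1, 2, 3, 4):
        per_type[t] = len({c.peptide for c in calls if c.type == t})
    fractions = {t: (per_type[t] / n if n else 0.0) for t in per_type}
    return {
        "n_peptides": n,
        "counts": per_type,
        "fractions": fractions,
        "summed_ratio": sum(fractions.values()),
    }


CATEGORIES = (
    "starts_vs_acceptor",
    "ends_vs_donor",
    "junction_starts_vs_donor_end",
    "junction_ends_vs_acceptor_start",
)


@dataclass
class BoundaryDistanceHistogram:
    """Counts of peptide termini at small offsets from splice sites, with
    per-offset one-sided z-tests against a uniform null over the window."""

    category: str
    offsets: list[int]
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def z(self) -> np.ndarray:
        n, k = self.n, len(self.offsets)
        if n == 0:
            return np.zeros(k)
        p0 = 1.0 / k
        se = np.sqrt(n * p0 * (1 - p0))
        return (self.counts - n * p0) / se

    @property
    def p(self) -> np.ndarray:
        return stats.norm.sf(self.z)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"offset": self.offsets, "count": self.counts.astype(int),
             "z": self.z, "p": self.p}
        )


def boundary_distance_histogram(
    records: Iterable[PeptideRecord],
    index: JunctionIndex,
    max_offset: int = 10,
) -> dict[str, BoundaryDistanceHistogram]:
    """Four offset histograms of peptide termini relative to splice
    sites, measured in spliced coding coordinates.

    Start/end categories use offsets 0..max_offset within the acceptor /
    donor exon of a junction (so first / last coding exons never
    contribute); junction categories use donor/acceptor nucleotide
    coverage 1..max_offset of spanned junctions.
    """
    hists = {
        "starts_vs_acceptor": np.zeros(max_offset + 1),
        "ends_vs_donor": np.zeros(max_offset + 1),
        "junction_starts_vs_donor_end": np.zeros(max_offset),
        "junction_ends_vs_acceptor_start": np.zeros(max_offset),
    }
    for r in records:
        if r.unique_genomic is False or not r.blocks:
            continue
        g5, g3, d = _termini(r)
        contig, strand = r.contig, r.strand
        for off in range(max_offset + 1):
            j = index.by_acceptor.get((contig, strand, g5 - d * off))
            if j is not None and off < j.acceptor_len:
                hists["starts_vs_acceptor"][off] += 1
                break
        for off in range(max_offset + 1):
            j = index.by_donor.get((contig, strand, g3 + d * off))
            if j is not None and off < j.donor_len:
                hists["ends_vs_donor"][off] += 1
                break
        if r.spans_junction and r.junction_coverage:
            items = list(r.junction_coverage.items())
            dcov = items[0][1][0]       # donor coverage of first spanned junction
            acov = items[-1][1][1]      # acceptor coverage of last spanned junction
            if 1 <= dcov <= max_offset:
                hists["junction_starts_vs_donor_end"][dcov - 1] += 1
            if 1 <= acov <= max_offset:
                hists["junction_ends_vs_acceptor_start"][acov - 1] += 1
    return {
        "starts_vs_acceptor": BoundaryDistanceHistogram(
            "starts_vs_acceptor", list(range(max_offset + 1)),
            hists["starts_vs_acceptor"]),
        "ends_vs_donor": BoundaryDistanceHistogram(
            "ends_vs_donor", list(range(max_offset + 1)),
            hists["ends_vs_donor"]),
        "junction_starts_vs_donor_end": BoundaryDistanceHistogram(
            "junction_starts_vs_donor_end", list(range(1, max_offset + 1)),
            hists["junction_starts_vs_donor_end"]),
        "junction_ends_vs_acceptor_start": BoundaryDistanceHistogram(
            "junction_ends_vs_acceptor_start", list(range(1, max_offset + 1)),
            hists["junction_ends_vs_acceptor_start"]),
    }
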