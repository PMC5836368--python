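"""In-silico protease digestion and peptide-to-genome projection.

A cleavage rule is a residue set, a terminus side (cut C-terminal or
N-terminal of the recognition residue), and an optional set of
neighbouring residues that suppress cleavage (trypsin's "not before
proline"). Digestion products carry residue spans on the parent protein;
projection through a :class:`~splicepep.annotation.CodingTranscript`
attaches genomic blocks and per-junction nucleotide coverage.

Two preset families ship: ``paper`` follows the cleavage-site table of the
source analysis literally (Glu-C after D, chymotrypsin with no proline
exception), ``conventional`` uses textbook specificities (Glu-C after E,
chymotrypsin suppressed before P).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Enzyme:
    """A protease cleavage rule.

    ``blocked_next`` names residues on the far side of the scissile bond
    (C-terminal neighbour for C-side enzymes, N-terminal neighbour for
    N-side enzymes) that suppress cleavage.
    """

    name: str
    cleave_residues: frozenset[str]
    side: str  # 'C' or 'N'
    blocked_next: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.cleave_residues:
            raise ValueError("cleave_residues must be non-empty")
        if self.side not in ("C", "N"):
            raise ValueError(f"side must be 'C' or 'N', got {self.side!r}")

    def cleavage_sites(self, protein: str) -> list[int]:
        """Internal cut positions p (cut between residues p-1 and p)."""
        sites = []
        if self.side == "C":
            for p in range(1, len(protein)):
                if (protein[p - 1] in self.cleave_residues
                        and protein[p] not in self.blocked_next):
                    sites.append(p)
        else:
            for p in range(1, len(protein)):
                if (protein[p] in self.cleave_residues
                        and protein[p - 1] not in self.blocked_next):
                    sites.append(p)
        return sites


def _ez(name, residues, side, blocked=""):
    return Enzyme(name, frozenset(residues), side, frozenset(blocked))


#: Cleavage rules as printed in the source analysis's enzyme table.
PAPER_PRESETS: dict[str, Enzyme] = {
    "trypsin": _ez("trypsin", "KR", "C", "P"),
    "lys-c": _ez("lys-c", "K", "C"),
    "glu-c": _ez("glu-c", "D", "C"),
    "chymotrypsin": _ez("chymotrypsin", "FYLWM", "C"),
    "asp-n": _ez("asp-n", "D", "N"),
    "arg-c": _ez("arg-c", "R", "C"),
}

#: Textbook specificities for the same six proteases.
CONVENTIONAL_PRESETS: dict[str, Enzyme] = {
    "trypsin": _ez("trypsin", "KR", "C", "P"),
    "lys-c": _ez("lys-c", "K", "C"),
    "glu-c": _ez("glu-c", "E", "C"),
    "chymotrypsin": _ez("chymotrypsin", "FYLWM", "C", "P"),
    "asp-n": _ez("asp-n", "D", "N"),
    "arg-c": _ez("arg-c", "R", "C"),
}

PRESET_FAMILIES = {"paper": PAPER_PRESETS, "conventional": CONVENTIONAL_PRESETS}


def get_enzyme(name: str, family: str = "paper") -> Enzyme:
    try:
        presets = PRESET_FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown preset family {family!r}") from None
    try:
        return presets[name.lower()]
    except KeyError:
        raise ValueError(f"unknown enzyme {name!r} in family {family!r}") from None


@dataclass
class PeptideRecord:
    """A digestion product or observed peptide.

    Residue coordinates are 0-based half-open on the parent protein.
    ``blocks`` are genomic half-open intervals in genomic order;
    ``junction_coverage`` maps each spanned junction key to (donor_nt,
    acceptor_nt) coverage measured in translation orientation.
    """

    sequence: str
    transcript_id: str | None = None
    start_res: int = 0
    end_res: int = 0
    missed_cleavages: int = 0
    contig: str | None = None
    strand: str | None = None
    blocks: tuple[tuple[int, int], ...] = ()
    junction_coverage: dict = field(default_factory=dict)
    unique_genomic: bool | None = None

    @property
    def spans_junction(self) -> bool:
        return len(self.blocks) > 1

    @property
    def location_key(self):
        return (self.contig, self.strand, self.blocks)

    def __len__(self) -> int:
        return len(self.sequence)


def digest(protein: str, enzyme: Enzyme, max_missed: int = 0) -> list[PeptideRecord]:
    """All cleavage products of ``protein`` with 0..max_missed internal sites.

    At ``max_missed=0`` the products tile the protein exactly.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0] + enzyme.cleavage_sites(protein) + [len(protein)]
    n_frag = len(bounds) - 1
    records = []
    for m in range(min(max_missed, n_frag - 1) + 1):
        for i in range(n_frag - m):
            s, e = bounds[i], bounds[i + 1 + m]
            records.append(
                PeptideRecord(
                    sequence=protein[s:e],
                    start_res=s,
                    end_res=e,
                    missed_cleavages=m,
                )
            )
    return records


def filter_peptides(
    records: Iterable[PeptideRecord],
    min_len: int = 8,
    max_len: int = 25,
    max_missed: int = 0,
) -> list[PeptideRecord]:
    """Length bounds are inclusive on both ends."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [
        r for r in records
        if min_len <= len(r) <= max_len and r.missed_cleavages <= max_missed
    ]


def spanned_junctions(
    blocks: Sequence[tuple[int, int]], strand: str
) -> list[tuple[int, int, int, int]]:
    """For genomically ordered blocks, yield per spanned junction
    (donor_end, acceptor_start, donor_cov_nt, acceptor_cov_nt) in
    translation order."""
    if len(blocks) < 2:
        return []
    lens = [e - s for s, e in blocks]
    total = sum(lens)
    out = []
    if strand == "+":
        cum = 0
        for i in range(len(blocks) - 1):
            cum += lens[i]
            out.append((blocks[i][1] - 1, blocks[i + 1][0], cum, total - cum))
    else:
        # translation runs from the genomically last block downwards
        cum = 0
        for i in range(len(blocks) - 1, 0, -1):
            cum += lens[i]
            out.append((blocks[i][0], blocks[i - 1][1] - 1, cum, total - cum))
    return out


def project_to_genome(record: PeptideRecord, transcript) -> PeptideRecord:
    """Attach genomic blocks and junction coverage for a digestion product
    of ``transcript.protein``. Returns a new record."""
    tblocks = transcript.blocks_for_span(record.start_res, record.end_res)
    blocks = tuple(sorted(tblocks))
    cov = {}
    for d_end, a_start, dcov, acov in spanned_junctions(blocks, transcript.strand):
        key = (transcript.contig, transcript.strand, d_end, a_start)
        cov[key] = (dcov, acov)
    return replace(
        record,
        transcript_id=transcript.transcript_id,
        contig=transcript.contig,
        strand=transcript.strand,
        blocks=blocks,
        junction_coverage=cov,
    )


def digest_transcripts(
    transcripts,
    enzyme: Enzyme,
    min_len: int = 8,
    max_len: int = 25,
    max_missed: int = 0,
) -> list[PeptideRecord]:
    """Digest every transcript protein, filter, and project to the genome."""
    out = []
    for ct in transcripts:
        if not ct.protein:
            continue
        recs = digest(ct.protein, enzyme, max_missed)
        recs = filter_peptides(recs, min_len, max_len, max_missed)
        out.extend(project_to_genome(r, ct) for r in recs)
    return out


def collapse_unique(records: Iterable[PeptideRecord]) -> list[PeptideRecord]:
    """Flag genomic uniqueness per peptide sequence.

    A sequence is uniquely mapped iff every occurrence shares one
    identical genomic block set (isoform-shared locations merge); it is
    ambiguous (and flagged False) when it occurs at two distinct loci.
    Flags are set in place; the input records are returned.
    """
    records = list(records)
    locs: dict[str, set] = {}
    for r in records:
        locs.setdefault(r.sequence, set()).add(r.location_key)
    for r in records:
        r.unique_genomic = len(locs[r.sequence]) == 1
    return records


def unique_representatives(records: Iterable[PeptideRecord]) -> list[PeptideRecord]:
    """One record per uniquely mapped peptide sequence."""
    seen: dict[str, PeptideRecord] = {}
    for r in records:
        if r.unique_genomic and r.sequence not in seen:
            seen[r.sequence] = r
    return list(seen.values())


def write_peptide_table(records: Sequence[PeptideRecord], path) -> None:
    import pandas as pd

    rows = []
    for r in records:
        acov = max((a for _, a in r.junction_coverage.values()), default=0)
        rows.append(
            {
                "sequence": r.sequence,
                "transcript_id": r.transcript_id,
                "start_res": r.start_res,
                "missed_cleavages": r.missed_cleavages,
                "n_blocks": len(r.blocks),
                "spans_junction": r.spans_junction,
                "acceptor_nt_coverage": acov,
                "unique_genomic": r.unique_genomic,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
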