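"""BED12 interchange for observed / simulated peptide mappings.

One BED12 record per peptide: blocks are the peptide's exonic segments
in genome coordinates, the name column carries the peptide sequence.
This is the plain-text stand-in for proBAM-style peptide-to-genome
mappings.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .digestion import PeptideRecord, spanned_junctions

logger = logging.getLogger(__name__)


def write_bed12(records: Sequence[PeptideRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if not r.blocks:
                continue
            start = r.blocks[0][0]
            end = r.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in r.blocks) + ","
            starts = ",".join(str(s - start) for s, e in r.blocks) + ","
            fh.write(
                f"{r.contig}\t{start}\t{end}\t{r.sequence}\t0\t{r.strand}\t"
                f"{start}\t{end}\t0\t{len(r.blocks)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path) -> tuple[list[PeptideRecord], int]:
    """Parse BED12 peptide records.

    Returns (records, n_skipped); malformed lines are skipped with a
    warning. Junction coverage is recomputed from the block structure.
    """
    records: list[PeptideRecord] = []
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if len(cols) < 12:
                    raise ValueError("fewer than 12 columns")
                contig, start, name, strand = cols[0], int(cols[1]), cols[3], cols[5]
                if strand not in "+-":
                    raise ValueError(f"bad strand {strand!r}")
                n_blocks = int(cols[9])
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                offs = [int(x) for x in cols[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(offs) != n_blocks:
                    raise ValueError("block count mismatch")
                blocks = tuple(
                    (start + o, start + o + s) for o, s in zip(offs, sizes)
                )
                if any(e <= s for s, e in blocks):
                    raise ValueError("empty block")
            except ValueError as exc:
                logger.warning("skipping malformed BED line %d: %s", ln, exc)
                skipped += 1
                continue
            cov = {
                (contig, strand, d, a): (dc, ac)
                for d, a, dc, ac in spanned_junctions(blocks, strand)
            }
            records.append(
                PeptideRecord(
                    sequence=name,
                    contig=contig,
                    strand=strand,
                    blocks=blocks,
                    junction_coverage=cov,
                    unique_genomic=True,
                )
            )
    return records, skipped
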