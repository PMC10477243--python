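"""SAM and BED ingest/egress.

SAM parsing is delegated to pysam; CIGAR strings are reduced to aligned
reference blocks here with the conventions: M/=/X extend the current block,
D extends it too (a deletion does not interrupt contiguous reference
coverage), N closes the block and opens a new one after the skip, and
I/S/H/P do not consume reference. SAM POS is 1-based; everything downstream
is 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pysam

from .quant import AlignmentRecord, CassetteExonAnnotation, IntronAnnotation

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 10

_BAM_CMATCH = {0, 7, 8}  # M, =, X
_BAM_CDEL = 2
_BAM_CREF_SKIP = 3


def blocks_from_cigar(pos0: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Aligned reference blocks from a 0-based start and pysam cigartuples.

    Deletions are merged into the surrounding block; only N splits blocks.
    """
    blocks: list[tuple[int, int]] = []
    start = pos0
    cur = pos0
    for op, length in cigartuples:
        if op in _BAM_CMATCH or op == _BAM_CDEL:
            cur += length
        elif op == _BAM_CREF_SKIP:
            if cur > start:
                blocks.append((start, cur))
            cur += length
            start = cur
        # I, S, H, P: no reference consumption
    if cur > start:
        blocks.append((start, cur))
    return tuple(blocks)


def read_sam(path, min_mapq: int = DEFAULT_MIN_MAPQ) -> list[AlignmentRecord]:
    """Load mapped reads from a SAM file as AlignmentRecords.

    Unmapped reads and reads below ``min_mapq`` (multi-mapper proxy) are
    excluded.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            blocks = blocks_from_cigar(aln.reference_start, aln.cigartuples)
            if not blocks:
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    blocks=blocks,
                    mapq=aln.mapping_quality,
                )
            )
    return records


def write_sam(path, records, ref_lengths: dict[str, int] | None = None) -> None:
    """Write AlignmentRecords as minimal valid SAM (CIGAR with M and N only)."""
    records = list(records)
    if ref_lengths is None:
        ref_lengths = {}
        for rec in records:
            end = rec.blocks[-1][1] + 1
            ref_lengths[rec.chrom] = max(ref_lengths.get(rec.chrom, 0), end)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in sorted(ref_lengths.items()):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for rec in records:
            cigar_parts = []
            for i, (b0, b1) in enumerate(rec.blocks):
                if i > 0:
                    cigar_parts.append(f"{b0 - rec.blocks[i - 1][1]}N")
                cigar_parts.append(f"{b1 - b0}M")
            fh.write(
                "\t".join(
                    [
                        rec.read_id,
                        "0",
                        rec.chrom,
                        str(rec.blocks[0][0] + 1),
                        str(rec.mapq),
                        "".join(cigar_parts),
                        "*",
                        "0",
                        "0",
                        "*",
                        "*",
                    ]
                )
                + "\n"
            )


class BedFormatError(ValueError):
    pass


def read_intron_bed(path) -> list[IntronAnnotation]:
    """Parse a 6-column BED of introns (name column = event_id)."""
    introns: list[IntronAnnotation] = []
    for lineno, fields in _bed_rows(path):
        try:
            introns.append(
                IntronAnnotation(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    event_id=fields[3],
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            )
        except ValueError as exc:
            raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    introns.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return introns


def read_cassette_bed(path) -> list[CassetteExonAnnotation]:
    """Parse cassette exons from BED12-like rows.

    Expected columns: chrom, exon_start, exon_end, event_id, score, strand,
    upstream_end, downstream_start.
    """
    exons: list[CassetteExonAnnotation] = []
    for lineno, fields in _bed_rows(path):
        if len(fields) < 8:
            raise BedFormatError(
                f"{path}:{lineno}: cassette rows need 8 columns, got {len(fields)}"
            )
        try:
            exons.append(
                CassetteExonAnnotation(
                    chrom=fields[0],
                    exon_start=int(fields[1]),
                    exon_end=int(fields[2]),
                    event_id=fields[3],
                    strand=fields[5],
                    upstream_end=int(fields[6]),
                    downstream_start=int(fields[7]),
                )
            )
        except ValueError as exc:
            raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    exons.sort(key=lambda ex: (ex.chrom, ex.exon_start, ex.exon_end))
    return exons


def write_intron_bed(path, introns) -> None:
    with open(path, "w") as fh:
        for iv in introns:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.event_id}\t0\t{iv.strand}\n"
            )


def _bed_rows(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(
                    f"{path}:{lineno}: need at least 4 tab-separated columns"
                )
            yield lineno, fields
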