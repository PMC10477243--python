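"""Splice-aware read counting for intron retention and cassette exons.

Reads are abstracted to ordered, 0-based half-open aligned blocks; a gap
between consecutive blocks corresponds to a spliced-out region (CIGAR ``N``).
An intron-retention event is quantified as the number of reads splicing the
intron out exactly at its annotated boundaries (*spliced*) versus reads with
a contiguous alignment across an intron boundary or lying fully inside the
intron (*unspliced*), mirroring the spliced:unspliced ratio used to score
splicing efficiency. Cassette exons are quantified from the three junctions
(upstream-inclusion, downstream-inclusion, skipping) as percent spliced in.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "IntronAnnotation",
    "CassetteExonAnnotation",
    "AlignmentRecord",
    "count_intron_reads",
    "count_cassette_junctions",
    "splice_ratio",
    "psi",
    "UndefinedRatioError",
]

DEFAULT_MIN_OVERHANG = 6


class UndefinedRatioError(ValueError):
    """Raised when a ratio or PSI is requested from all-zero counts."""


@dataclass(frozen=True)
class IntronAnnotation:
    """One intron, 0-based half-open on ``chrom``: [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    gene_id: str = ""
    event_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid intron interval [{self.start}, {self.end}) for {self.event_id!r}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CassetteExonAnnotation:
    """A cassette exon with its flanking constitutive exons.

    The three junctions follow from the exon boundaries:
    upstream-inclusion (upstream_end, exon_start), downstream-inclusion
    (exon_end, downstream_start), and skipping (upstream_end, downstream_start).
    """

    chrom: str
    exon_start: int
    exon_end: int
    upstream_end: int
    downstream_start: int
    strand: str = "."
    gene_id: str = ""
    event_id: str = ""

    def __post_init__(self) -> None:
        if not self.upstream_end <= self.exon_start < self.exon_end <= self.downstream_start:
            raise ValueError(
                f"overlapping or out-of-order exon definition for {self.event_id!r}: "
                f"upstream_end={self.upstream_end}, exon=[{self.exon_start},{self.exon_end}), "
                f"downstream_start={self.downstream_start}"
            )

    @property
    def junctions(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        return (
            (self.upstream_end, self.exon_start),
            (self.exon_end, self.downstream_start),
            (self.upstream_end, self.downstream_start),
        )


@dataclass(frozen=True)
class AlignmentRecord:
    """A spliced alignment reduced to its aligned reference blocks.

    ``blocks`` are 0-based half-open intervals, strictly increasing and
    non-overlapping; a gap between consecutive blocks is a skipped region.
    """

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    mapq: int = 60

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id!r} has no aligned blocks")
        prev_end = None
        for start, end in self.blocks:
            if start >= end:
                raise ValueError(
                    f"read {self.read_id!r}: malformed block [{start}, {end})"
                )
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"read {self.read_id!r}: blocks not strictly increasing"
                )
            prev_end = end

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        """Skipped regions between consecutive aligned blocks."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )


def _gap_matches(read: AlignmentRecord, gap: tuple[int, int], min_overhang: int) -> bool:
    """True if the read has a block gap exactly at ``gap`` with sufficient
    aligned overhang on both flanking blocks."""
    for i in range(len(read.blocks) - 1):
        left = read.blocks[i]
        right = read.blocks[i + 1]
        if (left[1], right[0]) == gap:
            if left[1] - left[0] >= min_overhang and right[1] - right[0] >= min_overhang:
                return True
    return False


def _spans_boundary(read: AlignmentRecord, pos: int, min_overhang: int) -> bool:
    """True if some contiguous block covers ``pos`` with >= min_overhang
    aligned bases strictly on each side of the boundary."""
    for start, end in read.blocks:
        if start + min_overhang <= pos <= end - min_overhang:
            return True
    return False


def _within(read: AlignmentRecord, start: int, end: int) -> bool:
    return all(start <= b0 and b1 <= end for b0, b1 in read.blocks)


def count_intron_reads(
    alignments,
    intron: IntronAnnotation,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    *,
    count_boundary: bool = True,
    count_internal: bool = True,
) -> tuple[int, int]:
    """Count spliced and unspliced reads for one intron.

    A read is *spliced* when one of its block gaps coincides exactly with
    the intron and both flanking blocks align at least ``min_overhang``
    bases. It is *unspliced* when a contiguous block spans the intron start
    or end with ``min_overhang`` bases on each side (``count_boundary``) or
    when all its blocks lie inside the intron (``count_internal``). A read
    counts at most once per intron, with spliced taking precedence.

    Reads on other chromosomes are skipped silently.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    spliced = 0
    unspliced = 0
    for read in alignments:
        if read.chrom != intron.chrom:
            continue
        if _gap_matches(read, (intron.start, intron.end), min_overhang):
            spliced += 1
        elif count_boundary and (
            _spans_boundary(read, intron.start, min_overhang)
            or _spans_boundary(read, intron.end, min_overhang)
        ):
            unspliced += 1
        elif count_internal and _within(read, intron.start, intron.end):
            unspliced += 1
    return spliced, unspliced


def count_cassette_junctions(
    alignments,
    exon: CassetteExonAnnotation,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> tuple[int, int, int]:
    """Count (incl_up, incl_down, skip) junction reads for a cassette exon.

    Each junction is matched with the same exact-gap-plus-overhang rule used
    for introns; a read may support both inclusion junctions if it splices
    across the whole event.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    j_up, j_down, j_skip = exon.junctions
    incl_up = incl_down = skip = 0
    for read in alignments:
        if read.chrom != exon.chrom:
            continue
        if _gap_matches(read, j_up, min_overhang):
            incl_up += 1
        if _gap_matches(read, j_down, min_overhang):
            incl_down += 1
        if _gap_matches(read, j_skip, min_overhang):
            skip += 1
    return incl_up, incl_down, skip


def splice_ratio(spliced: float, unspliced: float, pseudocount: float = 0.0) -> float:
    """Spliced:unspliced ratio, (spliced + c) / (unspliced + c).

    A positive pseudocount is required when ``unspliced`` is zero.
    """
    if spliced < 0 or unspliced < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if unspliced + pseudocount == 0:
        raise UndefinedRatioError(
            "splice ratio undefined: unspliced + pseudocount is zero"
        )
    return (spliced + pseudocount) / (unspliced + pseudocount)


def psi(incl_up: float, incl_down: float, skip: float) -> float:
    """Percent spliced in: 100 * mean(inclusion) / (mean(inclusion) + skip)."""
    if min(incl_up, incl_down, skip) < 0:
        raise ValueError("counts must be non-negative")
    incl = 0.5 * (incl_up + incl_down)
    if incl + skip == 0:
        raise UndefinedRatioError("PSI undefined: all junction counts are zero")
    return 100.0 * incl / (incl + skip)
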