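"""Strand-aware genomic intervals and multi-block feature annotations.

All coordinates are 0-based, half-open ``[start, end)``. External formats
that use other conventions (GFF3) are converted at the I/O boundary, never
here. CLIP libraries are stranded, so every interval carries a strand and
overlap arithmetic is strand-aware by default.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-")

#: Recognised functional classes for annotations.
FEATURE_CLASSES = (
    "lncRNA",
    "three_prime_utr",
    "cds",
    "exon",
    "intron",
    "mirna_locus",
    "rrna_repeat",
    "other",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", ignore_strand: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if not ignore_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval", ignore_strand: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if not ignore_strand and self.strand != other.strand:
            return False
        return self.start <= other.start and other.end <= self.end


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals per (chrom, strand)."""
    out: list[GenomicInterval] = []
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    for (chrom, strand), ivs in sorted(by_key.items()):
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e, strand))
    return out


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Strand-aware interval subtraction ``a \\ b``.

    Output intervals are disjoint and sorted; the total length identity
    ``len(a \\ b) + len(a ∩ b) = len(a)`` holds for merged ``a``. Intervals
    of ``b`` on the opposite strand or another chromosome never subtract.
    """
    b_merged = merge_intervals(b)
    b_by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in b_merged:
        b_by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    out: list[GenomicInterval] = []
    for iv in sorted(a, key=lambda x: (x.chrom, x.strand, x.start, x.end)):
        cuts = b_by_key.get((iv.chrom, iv.strand), [])
        starts = [c.start for c in cuts]
        pos = iv.start
        # first cut that could touch iv
        i = bisect.bisect_left(starts, iv.start)
        if i > 0 and cuts[i - 1].end > iv.start:
            i -= 1
        while pos < iv.end and i < len(cuts) and cuts[i].start < iv.end:
            c = cuts[i]
            if c.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, c.start, iv.strand))
            pos = max(pos, c.end)
            i += 1
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end, iv.strand))
    out.sort(key=lambda x: (x.chrom, x.strand, x.start, x.end))
    return out


@dataclass
class FeatureAnnotation:
    """A (possibly multi-block) annotated feature such as a 3'UTR or lncRNA.

    Blocks are same-chromosome, same-strand, sorted, non-overlapping
    intervals. Transcript coordinates run 5'->3' along the feature: for a
    minus-strand feature, transcript position 0 is the rightmost genomic
    base of the last block.
    """

    feature_id: str
    gene_id: str
    feature_class: str
    blocks: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class {self.feature_class!r}")
        if not self.blocks:
            raise ValueError(f"feature {self.feature_id} has no blocks")
        self.blocks = tuple(sorted(self.blocks, key=lambda b: b.start))
        chroms = {b.chrom for b in self.blocks}
        strands = {b.strand for b in self.blocks}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"feature {self.feature_id}: blocks mix chrom/strand")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"feature {self.feature_id}: overlapping blocks")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def length(self) -> int:
        return total_length(self.blocks)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.blocks[0].start, self.blocks[-1].end, self.strand
        )

    def with_blocks(self, blocks: Sequence[GenomicInterval]) -> "FeatureAnnotation":
        return FeatureAnnotation(self.feature_id, self.gene_id, self.feature_class, tuple(blocks))

    def tx_to_genome(self, tx_start: int, tx_end: int) -> list[GenomicInterval]:
        """Project transcript coordinates ``[tx_start, tx_end)`` onto the genome.

        Returns one interval per spanned block (several when the region
        straddles a block junction), sorted by genomic position.
        """
        if not (0 <= tx_start < tx_end <= self.length):
            raise ValueError(
                f"transcript coords [{tx_start},{tx_end}) outside feature of "
                f"length {self.length}"
            )
        # walk blocks in transcript (5'->3') order
        blocks = self.blocks if self.strand == "+" else self.blocks[::-1]
        out: list[GenomicInterval] = []
        offset = 0
        for b in blocks:
            blen = len(b)
            lo = max(tx_start - offset, 0)
            hi = min(tx_end - offset, blen)
            if lo < hi:
                if self.strand == "+":
                    out.append(GenomicInterval(b.chrom, b.start + lo, b.start + hi, "+"))
                else:
                    out.append(GenomicInterval(b.chrom, b.end - hi, b.end - lo, "-"))
            offset += blen
            if offset >= tx_end:
                break
        out.sort(key=lambda iv: iv.start)
        return out
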