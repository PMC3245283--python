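"""Core genomic data types.

All coordinates inside the package are 0-based half-open (BED-native).
Report writers convert to 1-based inclusive at the very last step; see
:mod:`methcapdmr.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")


class FeatureCategory(str, enum.Enum):
    """Genomic feature class of a region, one per DMR under the precedence rule
    promoter > exon > intron > repeat > intergenic."""

    PROMOTER = "promoter"
    EXON = "exon"
    INTRON = "intron"
    REPEAT = "repeat"
    INTERGENIC = "intergenic"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded). ``start < end`` is
    enforced: zero-length intervals have no place in this pipeline.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def to_1based(self) -> tuple[str, int, int]:
        """(chrom, start, end) in 1-based inclusive coordinates, as printed in
        report tables."""
        return (self.chrom, self.start + 1, self.end)

    @classmethod
    def from_1based(
        cls, chrom: str, start1: int, end1: int, strand: str = "."
    ) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (the involution partner of
        :meth:`to_1based`)."""
        return cls(chrom, start1 - 1, end1, strand)


@dataclass
class GeneModel:
    """A gene with strand-aware TSS, transcript span and exon blocks.

    The TSS is the 0-based coordinate of the first transcribed base: ``span.start``
    on '+', ``span.end - 1`` on '-'. Exons must be sorted, disjoint and inside
    the span.
    """

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.span.chrom != self.chrom:
            raise ValueError(f"gene {self.gene_id}: span chrom mismatch")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id}: exon chrom mismatch")
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    def promoter(self, flank: int = 5000) -> GenomicInterval | None:
        """The ``flank`` bp immediately upstream of the TSS, strand-aware,
        clipped to the chromosome origin. ``None`` if clipping empties it."""
        if self.strand == "+":
            start, end = max(0, self.tss - flank), self.tss
        else:
            start, end = self.tss + 1, self.tss + 1 + flank
        if start >= end:
            return None
        return GenomicInterval(self.chrom, start, end, self.strand)
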