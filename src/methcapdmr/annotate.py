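"""Genomic-feature annotation of DMRs and CpG observed/expected profiling.

Each DMR receives exactly one feature category under the precedence
promoter > exon > intron > repeat > intergenic (any-overlap); the promoter is
the 5 kb immediately upstream of a TSS, strand-aware. Gene association lists
every gene whose TSS lies within ±5 kb of the DMR, labelled
``overlapStart`` / ``upstream`` / ``downstream`` with a signed, strand-aware
distance (negative = DMR upstream of the TSS on the gene's strand).

CpG o/e is the observed CpG dinucleotide count scaled by the count expected
from the C and G mononucleotide frequencies: ``n_CpG * L / (n_C * n_G)``.
``N`` bases are excluded from all counts and break dinucleotides. Values
above ~0.6 characterize CpG islands; the 0.6 threshold is only reported
descriptively, never used as a filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import FeatureCategory, GeneModel, GenomicInterval

PROMOTER_FLANK = 5000

REL_OVERLAP_START = "overlapStart"
REL_UPSTREAM = "upstream"
REL_DOWNSTREAM = "downstream"


@dataclass
class GeneAssociation:
    gene_id: str
    relation: str
    distance_to_tss: int


@dataclass
class CpGOEResult:
    """CpG o/e over one sequence; ``defined`` is False when the sequence has
    no C or no G (the ratio is then reported as 0 and excluded from
    distributions)."""

    n_cpg: int
    n_c: int
    n_g: int
    length: int
    oe: float
    defined: bool


# ---------------------------------------------------------------------------
# Feature assignment
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Interval trees over promoters, exons, gene spans and repeats for
    repeated category lookups."""

    def __init__(
        self,
        genes: list[GeneModel],
        repeat_track: list[GenomicInterval],
        promoter_flank: int = PROMOTER_FLANK,
    ) -> None:
        self.promoters: dict[str, IntervalTree] = {}
        self.exons: dict[str, IntervalTree] = {}
        self.spans: dict[str, IntervalTree] = {}
        self.repeats: dict[str, IntervalTree] = {}
        self.genes = genes
        for g in genes:
            prom = g.promoter(promoter_flank)
            if prom is not None:
                self.promoters.setdefault(g.chrom, IntervalTree()).addi(
                    prom.start, prom.end
                )
            for ex in g.exons:
                self.exons.setdefault(g.chrom, IntervalTree()).addi(ex.start, ex.end)
            self.spans.setdefault(g.chrom, IntervalTree()).addi(
                g.span.start, g.span.end
            )
        for r in repeat_track:
            self.repeats.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)

    def _hits(self, trees: dict[str, IntervalTree], iv: GenomicInterval) -> bool:
        tree = trees.get(iv.chrom)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))

    def category(self, iv: GenomicInterval) -> FeatureCategory:
        if self._hits(self.promoters, iv):
            return FeatureCategory.PROMOTER
        if self._hits(self.exons, iv):
            return FeatureCategory.EXON
        if self._hits(self.spans, iv):
            return FeatureCategory.INTRON
        if self._hits(self.repeats, iv):
            return FeatureCategory.REPEAT
        return FeatureCategory.INTERGENIC


def assign_feature(
    dmr: GenomicInterval,
    genes: list[GeneModel],
    repeat_track: list[GenomicInterval],
    promoter_flank: int = PROMOTER_FLANK,
) -> FeatureCategory:
    """One-shot feature category (see :class:`FeatureIndex` for batch use)."""
    return FeatureIndex(genes, repeat_track, promoter_flank).category(dmr)


def associate_genes(
    dmr: GenomicInterval,
    genes: list[GeneModel],
    flank: int = PROMOTER_FLANK,
) -> list[GeneAssociation]:
    """Genes whose TSS is inside the DMR (``overlapStart``) or within
    ``flank`` bp of it, with signed strand-aware distance."""
    out: list[GeneAssociation] = []
    for g in genes:
        if g.chrom != dmr.chrom:
            continue
        tss = g.tss
        if dmr.start <= tss < dmr.end:
            out.append(GeneAssociation(g.gene_id, REL_OVERLAP_START, 0))
            continue
        # signed genomic gap from the DMR's nearest edge to the TSS
        if dmr.end <= tss:
            genomic_d = (dmr.end - 1) - tss  # DMR left of TSS -> negative
        else:
            genomic_d = dmr.start - tss  # DMR right of TSS -> positive
        d = genomic_d if g.strand == "+" else -genomic_d
        if abs(d) <= flank:
            rel = REL_UPSTREAM if d < 0 else REL_DOWNSTREAM
            out.append(GeneAssociation(g.gene_id, rel, d))
    return out


# ---------------------------------------------------------------------------
# CpG observed / expected
# ---------------------------------------------------------------------------

def cpg_oe(sequence: str) -> CpGOEResult:
    """CpG o/e of one sequence. ``N`` positions do not count toward C/G or
    length and break CG dinucleotides."""
    if len(sequence) < 2:
        raise ValueError("sequence must be at least 2 bp")
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    if not np.all(valid | (arr == ord("N"))):
        raise ValueError("sequence contains characters outside A/C/G/T/N")
    n_c = int((arr == ord("C")).sum())
    n_g = int((arr == ord("G")).sum())
    n_cpg = int(((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).sum())
    length = int(valid.sum())
    if n_c == 0 or n_g == 0:
        return CpGOEResult(n_cpg, n_c, n_g, length, 0.0, False)
    return CpGOEResult(n_cpg, n_c, n_g, length, n_cpg * length / (n_c * n_g), True)


def centered_window(
    iv: GenomicInterval, chrom_length: int, window: int = 500
) -> GenomicInterval:
    """``window`` bp centered on the interval midpoint, clipped to the
    chromosome."""
    mid = iv.midpoint
    start = max(0, mid - window // 2)
    end = min(chrom_length, start + window)
    start = max(0, end - window)
    return GenomicInterval(iv.chrom, start, end)


# ---------------------------------------------------------------------------
# DMR annotation and o/e stratification
# ---------------------------------------------------------------------------

def annotate_dmrs(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    repeat_track: list[GenomicInterval],
    genome: dict[str, str],
    flank: int = PROMOTER_FLANK,
    oe_window: int = 500,
) -> pd.DataFrame:
    """Add category, gene association and CpG o/e columns to a DMR frame.

    Gene association columns are comma-joined over all associated genes;
    ``cpg_oe`` is computed on the ``oe_window`` bp centered on the DMR
    midpoint and is NaN where undefined (no C or no G).
    """
    index = FeatureIndex(genes, repeat_track, flank)
    categories, gene_ids, relations, distances, oes = [], [], [], [], []
    for row in dmrs.itertuples(index=False):
        iv = GenomicInterval(row.chrom, row.start, row.end)
        categories.append(index.category(iv).value)
        assoc = associate_genes(iv, genes, flank)
        gene_ids.append(",".join(a.gene_id for a in assoc) or ".")
        relations.append(",".join(a.relation for a in assoc) or ".")
        distances.append(",".join(str(a.distance_to_tss) for a in assoc) or ".")
        win = centered_window(iv, len(genome[row.chrom]), oe_window)
        res = cpg_oe(genome[row.chrom][win.start : win.end])
        oes.append(res.oe if res.defined else np.nan)
    out = dmrs.copy()
    out["category"] = categories
    out["gene_ids"] = gene_ids
    out["relations"] = relations
    out["tss_distances"] = distances
    out["cpg_oe"] = oes
    return out


def stratify_oe(
    annotated: pd.DataFrame, oe_threshold: float = 0.6
) -> pd.DataFrame:
    """Per-category CpG o/e summary: count, median o/e and fraction above
    ``oe_threshold``. Undefined o/e values are excluded."""
    rows = []
    for category in FeatureCategory:
        sub = annotated[annotated["category"] == category.value]
        vals = sub["cpg_oe"].dropna() if len(sub) else pd.Series(dtype=float)
        if len(vals):
            rows.append(
                (category.value, len(sub), float(vals.median()),
                 float((vals > oe_threshold).mean()))
            )
        else:
            rows.append((category.value, len(sub), np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["category", "n", "median_oe", "fraction_above"]
    )
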