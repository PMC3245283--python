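"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Internal coordinates are 0-based half-open. Report tables (DMRs, truth,
  genes) are printed 1-based inclusive, matching the convention of published
  500 bp windows that start at ``...001``.
* TSV writers emit a single ``#``-prefixed header line naming the columns.
  BED files are written header-free, per the BED convention.
* Infinite rpm ratios are printed literally as ``Inf``.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .core import GeneModel, GenomicInterval


class ParseError(ValueError):
    """A malformed input file; the message names the file and line number."""


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(
    path: str | os.PathLike,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into 0-based half-open intervals.

    Lines starting with ``#``, ``track`` or ``browser`` and blank lines are
    skipped. Malformed lines raise :class:`ParseError` naming the line number.
    If ``chrom_lengths`` is given, intervals on unknown chromosomes or beyond
    the chromosome end are rejected; otherwise chromosome names are taken on
    trust. Reads without a strand column are treated as '+'.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if not 3 <= len(fields) <= 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3-6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start < 0:
                raise ParseError(f"{path}: line {lineno}: negative start {start}")
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) == 6 else "+"
            if strand == ".":
                strand = "+"
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: invalid strand {strand!r}"
                )
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise ParseError(
                        f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                    )
                if end > chrom_lengths[chrom]:
                    raise ParseError(
                        f"{path}: line {lineno}: interval end {end} beyond "
                        f"chromosome length {chrom_lengths[chrom]}"
                    )
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write BED6 (name ``r<i>``, score 0), header-free, 0-based half-open."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals, start=1):
            strand = iv.strand if iv.strand in ("+", "-") else "+"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tr{i}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into ``{name: uppercased sequence}``, insertion-ordered.

    Names are truncated at the first whitespace; duplicates are an error.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in genome:
            raise ParseError(f"{path}: duplicate sequence name {name!r}")
        genome[name] = str(rec.seq).upper()
    return genome


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    """Write sequences wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

GENES_HEADER = (
    "#gene_id\tchrom\tstrand\ttss\ttx_start\ttx_end\texon_starts\texon_ends"
)


def write_genes(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write the gene table; coordinates 1-based inclusive, exon lists
    comma-separated."""
    with open(path, "w") as fh:
        fh.write(GENES_HEADER + "\n")
        for g in genes:
            ex_starts = ",".join(str(e.start + 1) for e in g.exons)
            ex_ends = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss + 1}\t"
                f"{g.span.start + 1}\t{g.span.end}\t{ex_starts}\t{ex_ends}\n"
            )


def read_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read the gene table written by :func:`write_genes`."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(
                    f"{path}: line {lineno}: expected 8 columns, got {len(fields)}"
                )
            gene_id, chrom, strand = fields[0], fields[1], fields[2]
            try:
                tx_start1, tx_end1 = int(fields[4]), int(fields[5])
                ex_starts = [int(x) for x in fields[6].split(",") if x]
                ex_ends = [int(x) for x in fields[7].split(",") if x]
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if len(ex_starts) != len(ex_ends):
                raise ParseError(
                    f"{path}: line {lineno}: exon start/end count mismatch"
                )
            span = GenomicInterval.from_1based(chrom, tx_start1, tx_end1, strand)
            exons = [
                GenomicInterval.from_1based(chrom, s, e, strand)
                for s, e in zip(ex_starts, ex_ends)
            ]
            genes.append(GeneModel(gene_id, chrom, strand, span, exons))
    return genes


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

TRUTH_HEADER = "#chrom\tstart\tend\tmeth_A\tmeth_B\tis_dmr\tdirection"


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the simulator ground truth; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write(TRUTH_HEADER + "\n")
        for row in truth.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start + 1}\t{row.end}\t"
                f"{row.meth_A:.4f}\t{row.meth_B:.4f}\t"
                f"{int(row.is_dmr)}\t{row.direction}\n"
            )


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    """Read a truth table back into 0-based half-open coordinates."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "meth_A", "meth_B", "is_dmr", "direction"],
        comment="#",
        dtype={"chrom": str},
    )
    df["start"] = df["start"] - 1
    df["is_dmr"] = df["is_dmr"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Window counts
# ---------------------------------------------------------------------------

COUNTS_COLUMNS = ["chrom", "start", "end", "count_A", "count_B", "rpm_A", "rpm_B"]


def write_counts(
    stats: pd.DataFrame,
    path: str | os.PathLike,
    library_size_a: int,
    library_size_b: int,
    unplaced_a: int = 0,
    unplaced_b: int = 0,
) -> None:
    """Write per-window counts/rpm. Library sizes and unplaced-read counts are
    recorded in header comments so downstream stages can reuse them."""
    with open(path, "w") as fh:
        fh.write(f"#library_size_A={library_size_a}\tlibrary_size_B={library_size_b}\n")
        fh.write(f"#unplaced_A={unplaced_a}\tunplaced_B={unplaced_b}\n")
        fh.write("#" + "\t".join(COUNTS_COLUMNS) + "\n")
        for row in stats.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start + 1}\t{row.end}\t"
                f"{row.count_A}\t{row.count_B}\t{row.rpm_A:.4f}\t{row.rpm_B:.4f}\n"
            )


def read_counts(path: str | os.PathLike) -> tuple[pd.DataFrame, int, int]:
    """Read a counts table; returns (frame with 0-based starts, lib_A, lib_B)."""
    lib_a = lib_b = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("#library_size_A="):
                parts = dict(
                    kv.split("=") for kv in line[1:].strip().split("\t")
                )
                lib_a = int(parts["library_size_A"])
                lib_b = int(parts["library_size_B"])
    if lib_a is None or lib_b is None:
        raise ParseError(f"{path}: missing #library_size header")
    df = pd.read_csv(path, sep="\t", names=COUNTS_COLUMNS, comment="#",
                     dtype={"chrom": str})
    df["start"] = df["start"] - 1
    return df, lib_a, lib_b


# ---------------------------------------------------------------------------
# DMR report
# ---------------------------------------------------------------------------

DMR_COLUMNS = [
    "chrom", "start", "end", "rpm_A", "rpm_B", "ratio",
    "p_value", "fdr", "direction",
]


def _format_ratio(ratio: float) -> str:
    return "Inf" if math.isinf(ratio) else f"{ratio:.2f}"


def write_dmr_table(records: pd.DataFrame, path: str | os.PathLike,
                    extra_columns: list[str] | None = None) -> None:
    """Write the DMR report: 1-based inclusive coordinates, rpm to two
    decimals, infinite ratios as ``Inf``. ``extra_columns`` (e.g. annotation
    fields) are appended verbatim."""
    extra_columns = extra_columns or []
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DMR_COLUMNS + extra_columns) + "\n")
        for row in records.itertuples(index=False):
            cells = [
                row.chrom,
                str(row.start + 1),
                str(row.end),
                f"{row.rpm_A:.2f}",
                f"{row.rpm_B:.2f}",
                _format_ratio(row.ratio),
                f"{row.p_value:.3e}",
                f"{row.fdr:.3e}",
                row.direction,
            ]
            for col in extra_columns:
                cells.append(str(getattr(row, col)))
            fh.write("\t".join(cells) + "\n")


def read_dmr_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a DMR report back into 0-based half-open coordinates; ``Inf``
    ratio cells become ``math.inf``."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.startswith("#"):
        raise ParseError(f"{path}: missing header line")
    columns = header[1:].split("\t")
    df = pd.read_csv(path, sep="\t", names=columns, comment="#",
                     dtype={"chrom": str})
    if len(df) == 0:
        df = pd.DataFrame(columns=columns)
        return df
    df["start"] = df["start"].astype(int) - 1
    df["ratio"] = df["ratio"].map(
        lambda x: math.inf if str(x) == "Inf" else float(x)
    )
    return df


# ---------------------------------------------------------------------------
# Gene lists and term maps (enrichment inputs)
# ---------------------------------------------------------------------------

def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments skipped."""
    genes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def read_term_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Two-column TSV gene<TAB>term -> ``{term: set of genes}`` (genes
    uppercased for case-insensitive matching)."""
    term_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            gene, term = fields
            term_map.setdefault(term, set()).add(gene.upper())
    return term_map
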