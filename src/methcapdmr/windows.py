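"""Fixed-window tiling, per-window read counting and rpm normalization,
plus CpG-island coverage summaries.

Reads are attributed to exactly one window — the tile containing the read's
leftmost (start) coordinate — so per-window counts are integral and sum to
the number of placeable reads (conservation). Reads on chromosomes absent
from the tiling are tallied in an ``unplaced`` bucket, never dropped
silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval


def tile_genome(
    chrom_lengths: Mapping[str, int], window_size: int = 500
) -> list[GenomicInterval]:
    """Non-overlapping tiles of ``window_size`` bp from coordinate 0; the
    final partial tile is kept if it is at least 1 bp."""
    if window_size <= 0:
        raise ValueError(f"window_size must be > 0, got {window_size}")
    tiles = []
    for chrom, length in chrom_lengths.items():
        for s in range(0, length, window_size):
            tiles.append(GenomicInterval(chrom, s, min(s + window_size, length)))
    return tiles


def count_reads(
    chrom_lengths: Mapping[str, int],
    reads: Sequence[GenomicInterval],
    window_size: int = 500,
) -> tuple[pd.DataFrame, int]:
    """Count reads per tile by start position.

    Returns ``(frame with chrom/start/end/count, n_unplaced)``. A read is
    assigned to the tile containing its start; reads on unknown chromosomes
    go to the unplaced bucket.
    """
    counts: dict[str, np.ndarray] = {
        chrom: np.zeros(-(-length // window_size), dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }
    by_chrom: dict[str, list[int]] = {}
    for read in reads:
        by_chrom.setdefault(read.chrom, []).append(read.start)
    unplaced = 0
    for chrom, starts in by_chrom.items():
        arr = counts.get(chrom)
        if arr is None:
            unplaced += len(starts)
            continue
        pos = np.asarray(starts, dtype=np.int64)
        ok = pos < chrom_lengths[chrom]
        unplaced += int((~ok).sum())
        np.add.at(arr, pos[ok] // window_size, 1)
    rows = []
    for chrom, length in chrom_lengths.items():
        arr = counts[chrom]
        for i, c in enumerate(arr):
            s = i * window_size
            rows.append((chrom, s, min(s + window_size, length), int(c)))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    return frame, unplaced


def rpm_normalize(counts: Iterable[int] | np.ndarray, library_size: int) -> np.ndarray:
    """reads-per-million: ``count * 1e6 / library_size``."""
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    return np.asarray(counts, dtype=float) * 1e6 / library_size


def window_stats(
    chrom_lengths: Mapping[str, int],
    reads_a: Sequence[GenomicInterval],
    reads_b: Sequence[GenomicInterval],
    window_size: int = 500,
    library_size_a: int | None = None,
    library_size_b: int | None = None,
    dedup: bool = False,
) -> tuple[pd.DataFrame, int, int, int, int]:
    """Joint per-window statistics for two libraries.

    Library size defaults to the number of reads supplied (mapped-read
    totals). With ``dedup=True`` exact-coordinate duplicate reads are removed
    first. Returns ``(stats, lib_a, lib_b, unplaced_a, unplaced_b)`` where
    ``stats`` has columns chrom, start, end, count_A, count_B, rpm_A, rpm_B.
    """
    if dedup:
        reads_a = _dedup(reads_a)
        reads_b = _dedup(reads_b)
    lib_a = library_size_a if library_size_a is not None else len(reads_a)
    lib_b = library_size_b if library_size_b is not None else len(reads_b)
    ca, unplaced_a = count_reads(chrom_lengths, reads_a, window_size)
    cb, unplaced_b = count_reads(chrom_lengths, reads_b, window_size)
    stats = ca.rename(columns={"count": "count_A"})
    stats["count_B"] = cb["count"]
    stats["rpm_A"] = rpm_normalize(stats["count_A"], lib_a) if lib_a > 0 else 0.0
    stats["rpm_B"] = rpm_normalize(stats["count_B"], lib_b) if lib_b > 0 else 0.0
    return stats, lib_a, lib_b, unplaced_a, unplaced_b


def _dedup(reads: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    seen = set()
    out = []
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# CpG-island coverage (Table 1-style summary)
# ---------------------------------------------------------------------------

@dataclass
class LibraryStats:
    """Per-library CpG-island coverage summary.

    ``cgi_fraction_of_reads`` is a percentage of ``total_reads``;
    ``per_cgi_depth`` is reads-in-CGI per covered CGI. When no CGI is covered
    the depth is reported as 0 with ``depth_defined=False``.
    """

    total_reads: int
    reads_in_cgi: int
    cgis_covered: int
    n_cgis: int
    cgi_fraction_of_reads: float
    cgi_covered_fraction: float
    per_cgi_depth: float
    depth_defined: bool = True

    @classmethod
    def from_counts(
        cls, total_reads: int, reads_in_cgi: int, cgis_covered: int,
        n_cgis: int | None = None,
    ) -> "LibraryStats":
        if reads_in_cgi > total_reads:
            raise ValueError("reads_in_cgi exceeds total_reads")
        frac = 100.0 * reads_in_cgi / total_reads if total_reads else 0.0
        covered_frac = (
            100.0 * cgis_covered / n_cgis if n_cgis else 0.0
        )
        if cgis_covered > 0:
            depth, defined = reads_in_cgi / cgis_covered, True
        else:
            depth, defined = 0.0, False
        return cls(total_reads, reads_in_cgi, cgis_covered,
                   n_cgis or 0, frac, covered_frac, depth, defined)


def cgi_stats(
    reads: Sequence[GenomicInterval],
    cgi_track: Sequence[GenomicInterval],
    total_reads: int | None = None,
) -> LibraryStats:
    """CGI coverage statistics: a read is in a CGI if its assigned (start)
    position falls inside one; a CGI is covered if at least one read is
    assigned to it."""
    if not cgi_track:
        raise ValueError("CGI track is empty")
    total = total_reads if total_reads is not None else len(reads)
    # sorted, per-chrom CGI boundary arrays for point lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {c.chrom for c in cgi_track}:
        ivs = sorted((c for c in cgi_track if c.chrom == chrom),
                     key=lambda c: c.start)
        starts = np.array([c.start for c in ivs])
        ends = np.array([c.end for c in ivs])
        ids = np.arange(len(ivs))
        by_chrom[chrom] = (starts, ends, ids)
    offsets = {}
    off = 0
    for chrom, (starts, _e, _i) in by_chrom.items():
        offsets[chrom] = off
        off += len(starts)
    hit_cgis: set[int] = set()
    in_cgi = 0
    for read in reads:
        entry = by_chrom.get(read.chrom)
        if entry is None:
            continue
        starts, ends, ids = entry
        j = int(np.searchsorted(starts, read.start, side="right")) - 1
        if j >= 0 and read.start < ends[j]:
            in_cgi += 1
            hit_cgis.add(offsets[read.chrom] + j)
    return LibraryStats.from_counts(total, in_cgi, len(hit_cgis), len(cgi_track))
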