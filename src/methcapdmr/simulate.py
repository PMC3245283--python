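"""Synthetic MBD/MethylCap-seq data generator.

Produces a toy genome containing CpG islands (high CpG observed/expected
ratio), genes and repeats; two isogenic methylomes that differ only at planted
differentially methylated regions; and single-end 36 bp capture reads whose
sampling probability is proportional to the methylated-CpG content of the
source fragment — the statistical structure an MBD capture experiment is
assumed to produce.

Model summary
-------------
* Base composition is a two-state first-order process: bases are drawn from a
  background distribution except that the base following a ``C`` is ``G`` with
  probability ``t = oe_target * gc/2``. Asymptotically the realized CpG
  observed/expected ratio equals ``oe_target`` and the GC content equals
  ``gc``; CGI intervals use a high-``oe`` parameter set, everything else the
  background set.
* Methylation is regional: the genome is tiled into fixed regions
  (``region_size``) and each region carries one methylation level per
  condition. Non-DMR regions share a level drawn around ``meth_background``;
  planted DMRs get ``meth_high`` in the hyper condition and ``meth_low`` in
  the other, split approximately evenly between directions.
* A fragment starting at position ``s`` has capture weight
  ``sum(meth at each CpG in [s, s+fragment_length)) + eps * max_weight``;
  the floor ``eps`` models residual capture of unmethylated DNA. Fragment
  starts are sampled proportional to weight; each read is the 5' or 3'
  ``read_length`` bp of its fragment on a random strand.

One master seed drives everything through named child streams (genome,
methylomes, reads per condition), so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval

_BASES = np.array(list("ACGT"))

DIRECTION_A = "A_hyper"
DIRECTION_B = "B_hyper"
DIRECTION_NONE = "none"

PLACEMENTS = ("uniform", "cgi", "background")


class SimSizingError(ValueError):
    """Requested features exceed genome capacity."""


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults are the package's reference conditions: a 1 Mb diploid-free toy
    genome (2 x 500 kb), promoter CpG islands, a 0.9-vs-0.05 methylation
    contrast at planted DMRs over a 0.4 background, 36 bp single-end reads
    from ~400 bp fragments, and libraries of 1e5 reads.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 20
    n_cgis: int = 20
    n_repeats: int = 60
    cgi_target_oe: float = 0.9
    background_oe: float = 0.3
    cgi_gc: float = 0.55
    background_gc: float = 0.42
    cgi_length: int = 2000
    gene_length_range: tuple[int, int] = (5000, 15000)
    repeat_length_range: tuple[int, int] = (300, 1000)
    region_size: int = 4000
    n_dmrs: int = 30
    dmr_placement: str = "uniform"
    meth_high: float = 0.9
    meth_low: float = 0.05
    meth_background: float = 0.4
    meth_background_sd: float = 0.07
    min_effect: float = 0.2
    reads_per_library: int = 100_000
    fragment_length: int = 400
    read_length: int = 36
    weight_floor: float = 1e-3

    def validate(self) -> None:
        counts = {
            "n_chroms": self.n_chroms, "chrom_length": self.chrom_length,
            "n_genes": self.n_genes, "n_cgis": self.n_cgis,
            "n_repeats": self.n_repeats, "n_dmrs": self.n_dmrs,
            "reads_per_library": self.reads_per_library,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_chroms == 0 or self.chrom_length <= 0:
            raise ValueError("genome must have at least one non-empty chromosome")
        for name in ("meth_high", "meth_low", "meth_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fragment_length < self.read_length:
            raise ValueError(
                f"fragment_length {self.fragment_length} < read_length "
                f"{self.read_length}"
            )
        if self.dmr_placement not in PLACEMENTS:
            raise ValueError(
                f"dmr_placement must be one of {PLACEMENTS}, got "
                f"{self.dmr_placement!r}"
            )
        if self.weight_floor < 0:
            raise ValueError("weight_floor must be >= 0")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_lengths(self) -> dict[str, int]:
        return {name: self.chrom_length for name in self.chrom_names()}


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    """Documented stream order: genome, methylomes, reads_A, reads_B."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(4)
    names = ["genome", "methylomes", "reads_A", "reads_B"]
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Sequence composition
# ---------------------------------------------------------------------------

def _composition_params(gc: float, oe_target: float) -> tuple[np.ndarray, float]:
    """Base distribution ``q`` and post-C G-probability ``t`` whose stationary
    GC content is ``gc`` and stationary CpG o/e is ``oe_target``.

    After a C the next base is G with probability ``t``, otherwise drawn from
    ``q`` restricted to {A, C, T}; after any other base it is drawn from ``q``.
    Solving the stationary equations for P(G) = P(C) = gc/2 gives the q
    entries below, and the realized o/e is ``t / P(G) = oe_target``.
    """
    pg = gc / 2.0
    t = oe_target * pg
    if not 0.0 <= t < 1.0:
        raise ValueError(f"infeasible composition: gc={gc}, oe={oe_target}")
    q_g = pg * (1.0 - t) / (1.0 - pg)
    # P(C) balance: pg = pg*(1-t)*q_c/(1-q_g) + (1-pg)*q_c
    q_c = pg / (pg * (1.0 - t) / (1.0 - q_g) + (1.0 - pg))
    q_a = q_t = (1.0 - q_g - q_c) / 2.0
    if min(q_a, q_c, q_g) < 0:
        raise ValueError(f"infeasible composition: gc={gc}, oe={oe_target}")
    return np.array([q_a, q_c, q_g, q_t]), t


def _sample_segment(
    n: int, q: np.ndarray, t: float, rng: np.random.Generator, prev: str
) -> str:
    """Sample ``n`` bases of the two-state dinucleotide process, continuing
    from previous base ``prev``."""
    # Pre-draw uniforms; the chain itself is inherently sequential.
    u = rng.random(n)
    v = rng.random(n)
    cum_q = np.cumsum(q)
    # distribution after a C, G excluded and renormalized
    q_nc = q.copy()
    q_nc[2] = 0.0
    q_nc /= q_nc.sum()
    cum_nc = np.cumsum(q_nc)
    out = []
    for i in range(n):
        if prev == "C":
            if u[i] < t:
                base = "G"
            else:
                base = "ACGT"[int(np.searchsorted(cum_nc, v[i], side="right"))]
        else:
            base = "ACGT"[int(np.searchsorted(cum_q, u[i], side="right"))]
        out.append(base)
        prev = base
    return "".join(out)


# ---------------------------------------------------------------------------
# Feature placement
# ---------------------------------------------------------------------------

def _place_nonoverlapping(
    n: int, lengths: list[int], chrom_len: int, rng: np.random.Generator,
    margin: int,
) -> list[tuple[int, int]]:
    """Place ``n`` intervals of the given lengths uniformly without overlap,
    keeping ``margin`` bp between neighbours (stars-and-bars)."""
    if n == 0:
        return []
    occupied = sum(lengths) + margin * (n + 1)
    slack = chrom_len - occupied
    if slack < 0:
        raise SimSizingError(
            f"cannot place {n} features totalling {sum(lengths)} bp with "
            f"{margin} bp margins on a {chrom_len} bp chromosome"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    spans = []
    base = margin
    for i in range(n):
        start = base + int(cuts[i])
        spans.append((start, start + lengths[i]))
        base += lengths[i] + margin
    return spans


def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], list[GenomicInterval], list[GenomicInterval]]:
    """Generate (genome, gene models, CGI track, repeat track).

    Genes are placed uniformly per chromosome with random strands; the first
    ``min(n_cgis, n_genes)`` CGIs sit immediately upstream of gene TSSs
    (promoter CGIs), the remainder in intergenic space; repeats go in leftover
    intergenic, non-CGI space. Sequence composition follows the CGI parameter
    set inside CGI intervals and the background set elsewhere.
    """
    config.validate()
    rng = _streams(config)["genome"]
    chroms = config.chrom_names()
    L = config.chrom_length

    # Round-robin feature counts per chromosome.
    def split(total: int) -> list[int]:
        base, extra = divmod(total, len(chroms))
        return [base + (1 if i < extra else 0) for i in range(len(chroms))]

    genes_per = split(config.n_genes)
    cgis_per_gene_budget = config.n_cgis
    repeats_per = split(config.n_repeats)

    genes: list[GeneModel] = []
    cgis: list[GenomicInterval] = []
    repeats: list[GenomicInterval] = []
    promoter_margin = config.cgi_length + 1000

    for ci, chrom in enumerate(chroms):
        n_g = genes_per[ci]
        glens = [
            int(rng.integers(config.gene_length_range[0],
                             config.gene_length_range[1] + 1))
            for _ in range(n_g)
        ]
        spans = _place_nonoverlapping(n_g, glens, L, rng, promoter_margin)
        for gi, (s, e) in enumerate(spans):
            strand = "+" if rng.random() < 0.5 else "-"
            span = GenomicInterval(chrom, s, e, strand)
            # exons: first at the TSS, the rest spread over the span
            n_ex = int(rng.integers(2, 7))
            edges = np.sort(rng.choice(np.arange(s + 200, e - 200), size=2 * n_ex - 2,
                                       replace=False))
            bounds = [s] + [int(x) for x in edges] + [e]
            exons = []
            for k in range(0, len(bounds) - 1, 2):
                ex_s, ex_e = bounds[k], bounds[k + 1]
                if ex_e > ex_s:
                    exons.append(GenomicInterval(chrom, ex_s, ex_e, strand))
            gene = GeneModel(f"G{ci + 1:02d}{gi + 1:03d}", chrom, strand, span, exons)
            genes.append(gene)

    # Promoter CGIs, in gene order, until the budget runs out.
    for gene in genes:
        if len(cgis) >= cgis_per_gene_budget:
            break
        if gene.strand == "+":
            s, e = gene.tss - config.cgi_length, gene.tss
        else:
            s, e = gene.tss + 1, gene.tss + 1 + config.cgi_length
        if s < 0 or e > L:
            continue
        cgis.append(GenomicInterval(gene.chrom, s, e))

    # Remaining CGIs and repeats: rejection-sample intergenic space.
    def conflicts(iv: GenomicInterval, tracks) -> bool:
        return any(iv.overlaps(o) for track in tracks for o in track)

    gene_spans = [g.span for g in genes]
    n_extra_cgi = config.n_cgis - len(cgis)
    for _ in range(n_extra_cgi):
        placed = False
        for _try in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            s = int(rng.integers(0, L - config.cgi_length + 1))
            iv = GenomicInterval(chrom, s, s + config.cgi_length)
            if not conflicts(iv, [gene_spans, cgis]):
                cgis.append(iv)
                placed = True
                break
        if not placed:
            raise SimSizingError(
                f"cannot place {config.n_cgis} CGIs of {config.cgi_length} bp: "
                "intergenic space exhausted"
            )

    for ci, chrom in enumerate(chroms):
        for _ in range(repeats_per[ci]):
            rl = int(rng.integers(config.repeat_length_range[0],
                                  config.repeat_length_range[1] + 1))
            placed = False
            for _try in range(2000):
                s = int(rng.integers(0, L - rl + 1))
                iv = GenomicInterval(chrom, s, s + rl)
                if not conflicts(iv, [gene_spans, cgis, repeats]):
                    repeats.append(iv)
                    placed = True
                    break
            if not placed:
                raise SimSizingError(
                    f"cannot place {config.n_repeats} repeats: space exhausted"
                )

    cgis.sort()
    repeats.sort()

    # Sequence: background process with CGI-process segments spliced in.
    q_bg, t_bg = _composition_params(config.background_gc, config.background_oe)
    q_cgi, t_cgi = _composition_params(config.cgi_gc, config.cgi_target_oe)
    genome: dict[str, str] = {}
    for chrom in chroms:
        chrom_cgis = [c for c in cgis if c.chrom == chrom]
        parts: list[str] = []
        prev = "A"
        pos = 0
        for cgi in chrom_cgis:
            if cgi.start > pos:
                seg = _sample_segment(cgi.start - pos, q_bg, t_bg, rng, prev)
                parts.append(seg)
                prev = seg[-1]
            seg = _sample_segment(cgi.length, q_cgi, t_cgi, rng, prev)
            parts.append(seg)
            prev = seg[-1]
            pos = cgi.end
        if pos < L:
            parts.append(_sample_segment(L - pos, q_bg, t_bg, rng, prev))
        genome[chrom] = "".join(parts)

    return genome, genes, cgis, repeats


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------

def tile_regions(config: SimConfig) -> pd.DataFrame:
    """Fixed methylation regions tiling the genome (``region_size`` bp)."""
    rows = []
    for chrom in config.chrom_names():
        for s in range(0, config.chrom_length, config.region_size):
            rows.append((chrom, s, min(s + config.region_size, config.chrom_length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_methylomes(
    config: SimConfig,
    regions: pd.DataFrame,
    cgi_track: list[GenomicInterval] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Assign methylation levels per region for both conditions and return
    (methylome_A, methylome_B, truth_table).

    Non-DMR regions share one level per region in both conditions, drawn from
    a Beta distribution with mean ``meth_background``. Exactly ``n_dmrs``
    regions are planted as DMRs (``meth_high`` vs ``meth_low``), directions
    split as evenly as possible. ``dmr_placement`` selects candidate regions:
    ``uniform`` (any region), ``cgi`` (regions overlapping the CGI track by at
    least half a CGI), ``background`` (regions not overlapping any CGI).
    """
    config.validate()
    rng = _streams(config)["methylomes"]
    n_regions = len(regions)
    if config.n_dmrs > n_regions:
        raise ValueError(
            f"n_dmrs={config.n_dmrs} exceeds the {n_regions} available regions"
        )

    # background levels, shared between conditions so the null is exact
    m = config.meth_background
    sd = config.meth_background_sd
    if sd > 0:
        k = m * (1 - m) / sd**2 - 1
        a, b = max(m * k, 1e-3), max((1 - m) * k, 1e-3)
        base = rng.beta(a, b, size=n_regions)
    else:
        base = np.full(n_regions, m)

    meth_a = base.copy()
    meth_b = base.copy()
    is_dmr = np.zeros(n_regions, dtype=bool)
    direction = np.array([DIRECTION_NONE] * n_regions, dtype=object)

    if config.n_dmrs > 0:
        candidates = _placement_candidates(config, regions, cgi_track)
        if len(candidates) < config.n_dmrs:
            raise ValueError(
                f"n_dmrs={config.n_dmrs} exceeds the {len(candidates)} regions "
                f"eligible under placement {config.dmr_placement!r}"
            )
        chosen = rng.choice(candidates, size=config.n_dmrs, replace=False)
        # split directions as evenly as possible
        n_a = (config.n_dmrs + 1) // 2
        perm = rng.permutation(config.n_dmrs)
        a_side = set(np.asarray(chosen)[perm[:n_a]].tolist())
        for idx in chosen:
            is_dmr[idx] = True
            if idx in a_side:
                meth_a[idx], meth_b[idx] = config.meth_high, config.meth_low
                direction[idx] = DIRECTION_A
            else:
                meth_a[idx], meth_b[idx] = config.meth_low, config.meth_high
                direction[idx] = DIRECTION_B

    truth = regions.copy()
    truth["meth_A"] = meth_a
    truth["meth_B"] = meth_b
    truth["is_dmr"] = is_dmr
    truth["direction"] = direction

    methylome_a = regions.copy()
    methylome_a["meth"] = meth_a
    methylome_b = regions.copy()
    methylome_b["meth"] = meth_b
    return methylome_a, methylome_b, truth


def _placement_candidates(
    config: SimConfig,
    regions: pd.DataFrame,
    cgi_track: list[GenomicInterval] | None,
) -> np.ndarray:
    if config.dmr_placement == "uniform":
        return np.arange(len(regions))
    if cgi_track is None:
        raise ValueError(
            f"dmr_placement={config.dmr_placement!r} requires a CGI track"
        )
    overlap_bp = np.zeros(len(regions))
    for i, row in enumerate(regions.itertuples(index=False)):
        for cgi in cgi_track:
            if cgi.chrom == row.chrom:
                ov = min(cgi.end, row.end) - max(cgi.start, row.start)
                if ov > 0:
                    overlap_bp[i] += ov
    if config.dmr_placement == "cgi":
        return np.where(overlap_bp >= config.cgi_length / 2)[0]
    return np.where(overlap_bp == 0)[0]  # "background"


# ---------------------------------------------------------------------------
# Capture reads
# ---------------------------------------------------------------------------

def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.where((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]


def simulate_capture_reads(
    genome: dict[str, str],
    methylome: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[GenomicInterval]:
    """Sample ``reads_per_library`` single-end reads for one methylome.

    Fragment-start weight = sum of the regional methylation level at each CpG
    inside the fragment, plus ``weight_floor * max_weight``. Reads are the
    ``read_length`` 5' or 3' bp of the fragment (random strand). Raises if the
    genome holds no CpGs and the floor is zero (degenerate weights).
    """
    config.validate()
    if rng is None:
        rng = _streams(config)["reads_A"]
    Lf, Lr = config.fragment_length, config.read_length

    chrom_names = []
    weights = []
    for chrom, seq in genome.items():
        if len(seq) < Lf:
            continue
        n_pos = len(seq) - Lf + 1
        cpg = _cpg_positions(seq)
        regs = methylome[methylome["chrom"] == chrom]
        starts = regs["start"].to_numpy()
        meths = regs["meth"].to_numpy()
        contrib = np.zeros(len(seq) + 1)
        if len(cpg) > 0:
            reg_idx = np.searchsorted(starts, cpg, side="right") - 1
            reg_idx = np.clip(reg_idx, 0, len(meths) - 1)
            np.add.at(contrib, cpg, meths[reg_idx])
        cum = np.concatenate([[0.0], np.cumsum(contrib)])
        w = cum[Lf : Lf + n_pos] - cum[:n_pos]
        chrom_names.append(chrom)
        weights.append(w)

    if not chrom_names:
        raise ValueError("no chromosome is at least one fragment long")
    wmax = max(float(w.max()) for w in weights)
    if wmax == 0.0 and config.weight_floor == 0.0:
        raise ValueError(
            "degenerate fragment weights: genome has no methylated CpGs and "
            "weight_floor is 0"
        )
    if wmax == 0.0:
        wmax = 1.0  # floor-only sampling: uniform
    weights = [w + config.weight_floor * wmax for w in weights]

    totals = np.array([w.sum() for w in weights])
    n_per_chrom = rng.multinomial(config.reads_per_library, totals / totals.sum())

    reads: list[GenomicInterval] = []
    for chrom, w, n in zip(chrom_names, weights, n_per_chrom):
        if n == 0:
            continue
        frag_starts = rng.choice(len(w), size=n, replace=True, p=w / w.sum())
        minus = rng.random(n) < 0.5
        read_starts = np.where(minus, frag_starts + Lf - Lr, frag_starts)
        for rs, mi in zip(read_starts, minus):
            reads.append(
                GenomicInterval(chrom, int(rs), int(rs) + Lr, "-" if mi else "+")
            )
    reads.sort()
    return reads


# ---------------------------------------------------------------------------
# One-call simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    genome: dict[str, str]
    genes: list[GeneModel]
    cgis: list[GenomicInterval]
    repeats: list[GenomicInterval]
    methylome_a: pd.DataFrame
    methylome_b: pd.DataFrame
    truth: pd.DataFrame
    reads_a: list[GenomicInterval]
    reads_b: list[GenomicInterval]


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: genome, methylomes, and both read libraries."""
    config.validate()
    streams = _streams(config)
    genome, genes, cgis, repeats = simulate_genome(config)
    regions = tile_regions(config)
    meth_a, meth_b, truth = simulate_methylomes(config, regions, cgi_track=cgis)
    reads_a = simulate_capture_reads(genome, meth_a, config, rng=streams["reads_A"])
    reads_b = simulate_capture_reads(genome, meth_b, config, rng=streams["reads_B"])
    return SimResult(genome, genes, cgis, repeats, meth_a, meth_b, truth,
                     reads_a, reads_b)
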