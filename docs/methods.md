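# Methods

This note documents the models, defaults and numerical choices behind
`methcap-dmr`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## The differential test

MBD-capture read counts per fixed window are compared between two libraries
with a two-sided Fisher's exact test on window-vs-rest-of-library counts
(`[[c_A, N_A − c_A], [c_B, N_B − c_B]]`). The capture-analysis tools this
package replaces do not publish the model behind their window p-values, so
the test here is a deliberate, documented definition rather than a
re-implementation: exact, assumption-light and reproducible. Consequences to
be aware of:

* The test conditions on library totals and assumes reads are exchangeable
  across windows; it does not model biological replicate dispersion (there
  are no replicates in the two-library design) or CpG-density coupling.
* Counts are integral by construction because each read is attributed to
  exactly one window — the tile containing its leftmost (start) coordinate.
  This start-based rule, rather than fractional overlap, is the one place
  window counts can differ from coupling-aware capture pipelines.
* No multiple-testing correction gates the calls: the published filter uses
  the raw p < 0.001, and the package mirrors that. A Benjamini–Hochberg FDR
  column is emitted for information only.

The triple filter is strict everywhere: rpm > 20, rpm ratio > 20, p < 0.001.
The ratio is `max(rpm)/min(rpm)`; a zero denominator gives an infinite ratio
that *passes* the filter (real capture tables report such windows as `Inf`),
and a 0/0 window has an undefined ratio and never passes. Adjacent passing
windows are reported as separate 500 bp records, never merged, matching the
convention of published DMR tables where consecutive tiles appear as
individual rows. Partial terminal tiles (chromosome length not divisible by
the window size) are counted — so read conservation holds — but excluded
from calling, since published DMRs are all exactly one window long.

## Coordinates

Internally everything is 0-based half-open (BED-native). Report tables print
1-based inclusive coordinates; published 500 bp windows start at `...001`,
which is exactly this tiling printed 1-based. The conversion lives in one
place (`GenomicInterval.to_1based` / `from_1based`) and is an involution.

## Annotation

* Promoter: the 5 kb immediately upstream of the TSS, strand-aware
  ([TSS−5000, TSS) on `+`, mirrored on `-`), clipped at the chromosome
  origin.
* Category precedence promoter > exon > intron > repeat > intergenic, with
  any-overlap semantics. The precedence order is a package choice (published
  feature breakdowns do not state one); it favors the regulatory
  interpretation and is configurable in the library API.
* Gene association: every gene whose TSS lies inside the DMR
  (`overlapStart`) or within ±5 kb of it; distances are signed and
  strand-aware, negative meaning the DMR is upstream of the TSS on the
  gene's strand, measured from the DMR edge nearest the TSS.
* CpG o/e is `n_CpG · L / (n_C · n_G)` with `N` bases excluded from all
  counts (including the effective length `L`) and breaking dinucleotides.
  "The 500 bp region surrounding a DMR" is implemented as the 500 bp window
  centered on the DMR midpoint — identical to the DMR window itself for
  standard tiles. The 0.6 island threshold is only ever reported
  descriptively (fraction of windows above), never used as a filter.

## Enrichment and overlap

Term enrichment and the two-list overlap test are explicit upper-tail
hypergeometric computations (`scipy.stats.hypergeom.sf`). Live GO/KEGG
services are deliberately out of scope — they are version-unstable — so the
caller supplies gene→term tables and gene lists. Identifier matching is
case-insensitive with set semantics: a gene hit by several DMRs counts once.
The overlap test's population defaults to 12,000, the promoter count of the
comparison array platform this analysis is usually run against. Raw p < 0.01
flags significance; BH-FDR is informational.

## The simulator

The simulator exists to give the pipeline data whose generating process
matches the analysis assumptions, plus ground truth. What it emulates:

* **Genome.** Chromosomes are generated by a two-state first-order base
  process: after a `C` the next base is `G` with probability
  `t = oe_target · gc/2`; otherwise bases follow a background distribution
  solved so the stationary GC content is `gc`. This makes the realized CpG
  o/e equal `oe_target` asymptotically, independently of GC — an i.i.d. base
  model cannot do that. CGI intervals use (gc = 0.55, o/e = 0.9), everything
  else (gc = 0.42, o/e = 0.3), so islands separate cleanly from background
  (realized mean difference > 0.3). The first `min(n_cgis, n_genes)` CGIs
  sit immediately upstream of gene TSSs, as promoter islands do.
* **Methylomes.** Methylation is regional: one level per fixed 4,000 bp
  region, because the analysis operates at 500 bp window resolution and
  per-CpG states would add cost without testable benefit. Non-DMR regions
  share (between conditions) a level drawn from a Beta distribution with
  mean 0.4 and s.d. 0.07 — sharing makes the no-DMR configuration an exact
  null for the window test. Planted DMRs get 0.9 vs 0.05, directions split
  evenly. A DMR region spans 8 windows: regional methylation differences in
  real capture data extend over kilobases, and a single 500 bp window is, at
  realistic depth, right at the edge of what an 18-fold density contrast can
  push past a strict 20-fold ratio filter — multi-window regions are both
  the realistic and the recoverable condition.
* **Reads.** A fragment starting at `s` has capture weight
  `Σ (methylation at each CpG in [s, s+400)) + ε · max_weight`, with
  ε = 10⁻³: the floor models residual low-salt carryover of unmethylated
  DNA, so no position has zero mass. Fragment starts are sampled
  proportional to weight; each read is the 5′ or 3′ 36 bp of its fragment on
  a random strand (36 bp single-end matches the trimmed read length of the
  motivating experiment; 400 bp is its selected fragment size). Libraries
  are 100,000 reads by default — inside the 10⁴–10⁶ band such experiments
  produce per chromosome-scale target, and enough to give planted DMR
  windows ≥ 30 expected reads in the hyper library on the default 1 Mb
  genome (2 × 500 kb).

What it does **not** emulate: sequencing errors and quality strings, PCR
duplicates, paired-end structure, mappability and GC bias, copy-number
variation, and any capture-efficiency noise beyond the proportional-weight
model (no published noise model exists for the capture step; the
proportional model is an explicit assumption). Passing recovery tests
therefore show that the caller is correct *under the stated capture model*,
not that it is robust to alignment artifacts or library chemistry.

Determinism: one master seed feeds named child streams (genome, methylomes,
reads per condition) via `numpy` `SeedSequence.spawn`, in that documented
order; identical configurations give byte-identical FASTA/BED/TSV outputs.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `window_size` | 500 bp | DMR window length |
| `rpm_min`, `ratio_min` | 20, 20 | strict rpm and ratio thresholds |
| `p_max` | 0.001 | strict raw Fisher p threshold |
| `flank` | 5,000 bp | promoter length and TSS-association flank |
| `enrich_p` | 0.01 | enrichment significance (raw) |
| `population` | 12,000 | overlap-test population |
| `n_chroms × chrom_length` | 2 × 500 kb | toy genome (2,000 full windows) |
| `region_size` | 4,000 bp | methylome region (8 windows) |
| `n_dmrs` | 30 | planted DMRs, placed uniformly over regions |
| `meth_high/low/background` | 0.9 / 0.05 / 0.4 | methylation levels |
| `reads_per_library` | 100,000 | single-end 36 bp reads |
| `fragment_length` | 400 bp | capture fragment |
| `weight_floor` | 10⁻³ | unmethylated-capture floor (× max weight) |

DMR placement is uniform over regions by default — most planted DMRs land in
non-island sequence, matching the observed feature distribution of capture
peaks, which is mostly intronic/intergenic. `dmr_placement: cgi` and
`background` restrict planting to island-overlapping or island-free regions
for the CpG-o/e stratification checks.

## Numerical choices and degenerate inputs

* Fisher p-values come from `scipy.stats.fisher_exact`; the test suite
  cross-checks them against exact rational-arithmetic enumeration of all
  tables with the observed margins (≤ 10⁻¹⁰ absolute for margins ≤ 50), and
  hypergeometric tails likewise against exact summation for populations
  ≤ 200.
* rpm values are plain floats; report writers fix the printed precision
  (2 decimals for rpm, scientific notation for p) so reruns are
  byte-stable.
* Library size for rpm is the number of reads supplied (i.e. mapped reads),
  and duplicate reads are kept by default — the upstream protocol is silent
  on deduplication — with an opt-in `dedup` flag for exact-coordinate
  duplicates.
* A CGI counts as "covered" with ≥ 1 assigned read; zero-read summaries
  report depth 0 with an explicit undefined flag rather than NaN.
* Vacuous recovery (no planted DMRs and/or no calls) reports
  sensitivity/precision 1.0 with a `defined=False` flag.
* Degenerate capture weights (a genome with no CpGs and a zero floor) are a
  hard error, as is planting more DMRs than there are eligible regions.
* Sequence composition parameters are solved in closed form; infeasible
  (gc, o/e) combinations raise before any sampling.

## Problem sizes

The shipped tests and the acceptance script run the full chain at the
reference conditions above (1 Mb genome, 2 × 10⁵ reads per simulated
contrast); the null-calibration check repeats the no-DMR configuration over
20 seeds. These sizes were chosen so the whole suite completes in a few
minutes on a single CPU while keeping ≥ 10³ full windows and ≥ 10⁵ reads
per library in every statistical check, i.e. the regime the thresholds are
meant for.

## Known limitations

* The Fisher window test is a defined replacement, not a reproduction, of
  the capture-analysis software used in the motivating study; published DMR
  counts from that study are not expected to be reproduced exactly.
* Ratio cells in some published DMR tables disagree with the quotient of
  their own printed rpm columns; this package always defines the ratio as
  the rpm quotient.
* Feature percentages depend on the (configurable) precedence order when a
  window overlaps several features.
* The overlap test's result depends strongly on the chosen population size;
  the 12,000 default is the array-platform convention, not a biological
  constant.
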