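"""End-to-end pipeline: simulate -> count -> call -> annotate -> enrich.

A run is driven by a flat YAML config validated up front (unknown keys are
rejected to catch typos; the published filter thresholds are the defaults). Every
stage writes a self-describing table; a ``manifest.json`` records the seed,
parameters, input checksums and per-stage row counts. Identical configs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as ann
from . import dmr as dmrmod
from . import enrichment as enr
from . import io as mio
from . import simulate as sim
from . import windows as win


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI)."""


_SIM_FIELDS = {f.name for f in dataclasses.fields(sim.SimConfig)}


@dataclass
class PipelineConfig:
    """All knobs of one reproducible run. Defaults are the published filter
    values: 500 bp windows, rpm > 20, ratio > 20, p < 0.001, ±5 kb TSS flank,
    enrichment p < 0.01, overlap population 12,000."""

    outdir: str = "run"
    seed: int = 0
    window: int = 500
    rpm_min: float = 20.0
    ratio_min: float = 20.0
    p_max: float = 0.001
    flank: int = 5000
    enrich_p: float = 0.01
    population: int = enr.DEFAULT_POPULATION
    dedup: bool = False
    # optional external inputs; when absent, the simulator supplies them
    genome: str | None = None
    reads_a: str | None = None
    reads_b: str | None = None
    genes: str | None = None
    cgi: str | None = None
    repeats: str | None = None
    term_map: str | None = None
    sim: dict = field(default_factory=dict)

    def filter_config(self) -> dmrmod.DMRFilterConfig:
        return dmrmod.DMRFilterConfig(self.window, self.rpm_min,
                                      self.ratio_min, self.p_max)

    def sim_config(self) -> sim.SimConfig:
        return sim.SimConfig(seed=self.seed, **self.sim)


def validate_config(path: str | os.PathLike | None = None,
                    data: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys and type mismatches are
    rejected by name, referenced input files must exist."""
    if data is None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping of keys to values")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sim_keys = data.get("sim") or {}
    if not isinstance(sim_keys, dict):
        raise ConfigError("'sim' must be a mapping")
    bad_sim = set(sim_keys) - (_SIM_FIELDS - {"seed"})
    if bad_sim:
        raise ConfigError(f"unknown sim keys: {sorted(bad_sim)}")
    cfg = PipelineConfig(**data)
    for name, caster in (
        ("seed", int), ("window", int), ("flank", int), ("population", int),
    ):
        value = getattr(cfg, name)
        if not isinstance(value, int) or isinstance(value, bool):
            raise ConfigError(f"config key {name!r} must be an integer, got "
                              f"{value!r}")
    for name in ("rpm_min", "ratio_min", "p_max", "enrich_p"):
        value = getattr(cfg, name)
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"config key {name!r} must be a number, got {value!r}")
        if value <= 0:
            raise ConfigError(f"config key {name!r} must be > 0, got {value}")
    if cfg.window <= 0:
        raise ConfigError("window must be > 0")
    try:
        cfg.sim_config().validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    for name in ("genome", "reads_a", "reads_b", "genes", "cgi", "repeats",
                 "term_map"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"input file for {name!r} does not exist: {p}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, log=print) -> Path:
    """Execute all stages in order inside ``config.outdir``; returns the run
    directory. Any stage failure raises :class:`StageError` naming the
    stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "window": config.window, "rpm_min": config.rpm_min,
            "ratio_min": config.ratio_min, "p_max": config.p_max,
            "flank": config.flank, "enrich_p": config.enrich_p,
            "population": config.population, "dedup": config.dedup,
        },
        "inputs": {},
        "stages": {},
    }
    stage = "simulate"
    try:
        external = config.genome is not None
        if external:
            genome = mio.read_fasta(config.genome)
            manifest["inputs"]["genome"] = _sha256(Path(config.genome))
            reads_a = mio.read_bed(config.reads_a)
            reads_b = mio.read_bed(config.reads_b)
            genes = mio.read_genes(config.genes) if config.genes else []
            cgis = mio.read_bed(config.cgi) if config.cgi else []
            repeats = mio.read_bed(config.repeats) if config.repeats else []
            truth = None
        else:
            result = sim.simulate_dataset(config.sim_config())
            genome = result.genome
            genes, cgis, repeats = result.genes, result.cgis, result.repeats
            reads_a, reads_b = result.reads_a, result.reads_b
            truth = result.truth
            mio.write_fasta(genome, outdir / "genome.fa")
            mio.write_genes(genes, outdir / "genes.tsv")
            mio.write_bed(cgis, outdir / "cgi.bed")
            mio.write_bed(repeats, outdir / "repeats.bed")
            mio.write_bed(reads_a, outdir / "reads_A.bed")
            mio.write_bed(reads_b, outdir / "reads_B.bed")
            mio.write_truth(truth, outdir / "truth.tsv")
        manifest["stages"]["simulate"] = {
            "reads_A": len(reads_a), "reads_B": len(reads_b),
            "genes": len(genes), "cgis": len(cgis), "repeats": len(repeats),
        }
        log(f"[simulate] reads_A={len(reads_a)} reads_B={len(reads_b)} "
            f"genes={len(genes)} cgis={len(cgis)} repeats={len(repeats)}")

        stage = "count"
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        stats, lib_a, lib_b, un_a, un_b = win.window_stats(
            chrom_lengths, reads_a, reads_b, config.window, dedup=config.dedup
        )
        mio.write_counts(stats, outdir / "counts.tsv", lib_a, lib_b, un_a, un_b)
        if cgis:
            stats_a = win.cgi_stats(reads_a, cgis)
            stats_b = win.cgi_stats(reads_b, cgis)
            manifest["stages"]["cgi_coverage"] = {
                "A": dataclasses.asdict(stats_a), "B": dataclasses.asdict(stats_b),
            }
            log(f"[count] CGI coverage A: {stats_a.cgi_fraction_of_reads:.2f}% of "
                f"reads, {stats_a.cgis_covered}/{stats_a.n_cgis} CGIs, depth "
                f"{stats_a.per_cgi_depth:.1f}")
        manifest["stages"]["count"] = {
            "windows": len(stats), "library_A": lib_a, "library_B": lib_b,
            "unplaced_A": un_a, "unplaced_B": un_b,
        }
        log(f"[count] windows={len(stats)} lib_A={lib_a} lib_B={lib_b}")

        stage = "call"
        dmrs = dmrmod.call_dmrs(stats, config.filter_config(), lib_a, lib_b)
        mio.write_dmr_table(dmrs, outdir / "dmrs.tsv")
        manifest["stages"]["call"] = {"dmrs": len(dmrs)}
        log(f"[call] dmrs={len(dmrs)}")
        if truth is not None and len(dmrs) >= 0:
            sens, prec, defined = dmrmod.recover_truth(dmrs, truth)
            manifest["stages"]["recovery"] = {
                "sensitivity": sens, "precision": prec, "defined": defined,
            }
            log(f"[call] recovery sensitivity={sens:.3f} precision={prec:.3f}")

        stage = "annotate"
        annotated = ann.annotate_dmrs(dmrs, genes, repeats, genome,
                                      flank=config.flank, oe_window=config.window)
        mio.write_dmr_table(
            annotated, outdir / "annotated.tsv",
            extra_columns=["category", "gene_ids", "relations",
                           "tss_distances", "cpg_oe"],
        )
        strat = ann.stratify_oe(annotated)
        strat.to_csv(outdir / "oe_by_category.tsv", sep="\t", index=False)
        manifest["stages"]["annotate"] = {"annotated": len(annotated)}
        log(f"[annotate] annotated={len(annotated)}")

        if config.term_map is not None:
            stage = "enrich"
            term_map = mio.read_term_map(config.term_map)
            manifest["inputs"]["term_map"] = _sha256(Path(config.term_map))
            study = sorted(
                {g for ids in annotated["gene_ids"] for g in ids.split(",")
                 if g and g != "."}
            )
            background = sorted(g.gene_id for g in genes)
            table = enr.enrich_terms(study, term_map, background,
                                     p_threshold=config.enrich_p)
            enr.write_enrichment(table, str(outdir / "enrichment.tsv"))
            manifest["stages"]["enrich"] = {
                "study_genes": len(study), "terms": len(table),
            }
            log(f"[enrich] study_genes={len(study)} terms={len(table)}")
    except (ConfigError,):
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def dump_default_config(path: str | os.PathLike) -> None:
    """Write a demo config with every default spelled out."""
    cfg = PipelineConfig()
    data = {k: v for k, v in dataclasses.asdict(cfg).items() if v is not None}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
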