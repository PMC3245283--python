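"""Simulator contracts: determinism, composition targets, planted truth and
the capture-weight read model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import methcapdmr.io as mio
import methcapdmr.simulate as sim
from methcapdmr.annotate import cpg_oe

from conftest import small_config


def _uniform_genome(length: int) -> dict[str, str]:
    # CpG at every 4th position: perfectly even CpG density
    return {"chr1": "ACGT" * (length // 4)}


def _flat_methylome(length: int, meth: float) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": ["chr1"], "start": [0], "end": [length], "meth": [meth]}
    )


class TestGenome:
    def test_same_seed_is_byte_identical(self, tmp_path):
        config = small_config()
        a = sim.simulate_dataset(config)
        b = sim.simulate_dataset(config)
        fa_a, fa_b = tmp_path / "a.fa", tmp_path / "b.fa"
        mio.write_fasta(a.genome, fa_a)
        mio.write_fasta(b.genome, fa_b)
        assert fa_a.read_bytes() == fa_b.read_bytes()
        bed_a, bed_b = tmp_path / "a.bed", tmp_path / "b.bed"
        mio.write_bed(a.reads_a, bed_a)
        mio.write_bed(b.reads_a, bed_b)
        assert bed_a.read_bytes() == bed_b.read_bytes()

    def test_no_cgis_still_valid(self):
        config = small_config(n_cgis=0)
        genome, genes, cgis, repeats = sim.simulate_genome(config)
        assert cgis == []
        assert len(genome["chr1"]) == config.chrom_length

    def test_cgi_oe_hits_target(self):
        config = sim.SimConfig(
            seed=1, n_chroms=1, chrom_length=200_000, n_genes=0, n_cgis=10,
            cgi_length=1000, n_repeats=0, cgi_target_oe=0.9,
        )
        genome, _genes, cgis, _ = sim.simulate_genome(config)
        assert len(cgis) == 10
        oes = [cpg_oe(genome[c.chrom][c.start : c.end]).oe for c in cgis]
        assert 0.75 <= np.mean(oes) <= 1.05

    def test_cgi_separates_from_background(self):
        config = small_config(chrom_length=120_000, n_cgis=6)
        genome, _genes, cgis, _ = sim.simulate_genome(config)
        cgi_oe = np.mean(
            [cpg_oe(genome[c.chrom][c.start : c.end]).oe for c in cgis]
        )
        mask = np.zeros(config.chrom_length, dtype=bool)
        for c in cgis:
            mask[c.start : c.end] = True
        bg_seq = "".join(
            ch for ch, m in zip(genome["chr1"], mask) if not m
        )
        assert cgi_oe - cpg_oe(bg_seq).oe > 0.3

    def test_features_within_bounds_and_strand_aware_tss(self):
        config = small_config()
        _genome, genes, cgis, repeats = sim.simulate_genome(config)
        for iv in cgis + repeats + [g.span for g in genes]:
            assert 0 <= iv.start < iv.end <= config.chrom_length
        for g in genes:
            assert g.tss == (g.span.start if g.strand == "+" else g.span.end - 1)

    def test_oversized_request_raises_sizing_error(self):
        config = small_config(n_genes=40, gene_length_range=(5000, 5001))
        with pytest.raises(sim.SimSizingError):
            sim.simulate_genome(config)


class TestMethylomes:
    def test_null_contrast_has_equal_methylomes(self):
        config = small_config(n_dmrs=0)
        regions = sim.tile_regions(config)
        ma, mb, truth = sim.simulate_methylomes(config, regions)
        assert np.array_equal(ma["meth"], mb["meth"])
        assert truth["is_dmr"].sum() == 0
        assert (truth["direction"] == "none").all()

    def test_planted_dmrs_have_full_effect(self):
        config = small_config(chrom_length=100_000, n_dmrs=20)
        regions = sim.tile_regions(config)
        _ma, _mb, truth = sim.simulate_methylomes(config, regions)
        planted = truth[truth["is_dmr"]]
        assert len(planted) == 20
        diffs = (planted["meth_A"] - planted["meth_B"]).abs()
        assert np.allclose(diffs, config.meth_high - config.meth_low)
        # directions split evenly
        counts = planted["direction"].value_counts()
        assert abs(counts.get("A_hyper", 0) - counts.get("B_hyper", 0)) <= 1

    def test_background_mean_near_target(self):
        config = sim.SimConfig(seed=3, n_chroms=1, chrom_length=500_000,
                               region_size=4000, n_dmrs=0)
        regions = sim.tile_regions(config)
        ma, _mb, _truth = sim.simulate_methylomes(config, regions)
        assert len(regions) >= 100
        assert abs(ma["meth"].mean() - config.meth_background) <= 0.1

    def test_too_many_dmrs_rejected(self):
        config = small_config(n_dmrs=10_000)
        regions = sim.tile_regions(config)
        with pytest.raises(ValueError, match="n_dmrs"):
            sim.simulate_methylomes(config, regions)

    def test_truth_effect_flag_consistency(self):
        config = small_config()
        regions = sim.tile_regions(config)
        _ma, _mb, truth = sim.simulate_methylomes(config, regions)
        effect = (truth["meth_A"] - truth["meth_B"]).abs()
        assert ((effect >= config.min_effect) == truth["is_dmr"]).all()


class TestCaptureReads:
    def test_emits_exact_read_count_within_bounds(self):
        config = small_config()
        result = sim.simulate_dataset(config)
        assert len(result.reads_a) == config.reads_per_library
        assert len(result.reads_b) == config.reads_per_library
        for r in result.reads_a:
            assert r.length == config.read_length
            assert 0 <= r.start and r.end <= config.chrom_length

    def test_zero_reads_gives_empty_bed(self, tmp_path):
        config = small_config(reads_per_library=0)
        result = sim.simulate_dataset(config)
        assert result.reads_a == []
        p = tmp_path / "reads.bed"
        mio.write_bed(result.reads_a, p)
        assert p.read_text() == ""

    def test_degenerate_weights_raise(self):
        config = small_config(weight_floor=0.0)
        genome = {"chr1": "AT" * 30_000}  # no CpG anywhere
        methylome = _flat_methylome(60_000, 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            sim.simulate_capture_reads(genome, methylome, config)

    def test_uniform_weights_give_uniform_starts(self):
        L = 50_000
        config = small_config(
            reads_per_library=100_000, fragment_length=36, read_length=36,
        )
        rng = np.random.default_rng(0)
        reads = sim.simulate_capture_reads(
            _uniform_genome(L), _flat_methylome(L, 1.0), config, rng=rng
        )
        starts = np.array([r.start for r in reads])
        starts = starts[starts < 48_000]
        observed, _ = np.histogram(starts, bins=24, range=(0, 48_000))
        chi2 = sps.chisquare(observed)
        assert chi2.pvalue > 0.01

    def test_hot_region_enrichment_matches_weight_ratio(self):
        L = 200_000
        config = small_config(reads_per_library=100_000)
        methylome = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 100_000, 102_000],
                "end": [100_000, 102_000, L],
                "meth": [0.05, 0.9, 0.05],
            }
        )
        rng = np.random.default_rng(1)
        reads = sim.simulate_capture_reads(
            _uniform_genome(L), methylome, config, rng=rng
        )
        starts = np.array([r.start for r in reads])
        # measure away from region boundaries (fragment-length smoothing)
        hot = ((starts >= 100_400) & (starts < 101_600)).sum() / 1200
        bg = ((starts >= 10_000) & (starts < 90_000)).sum() / 80_000
        ratio = hot / bg
        assert 18 / 1.5 <= ratio <= 18 * 1.5
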