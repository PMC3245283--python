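"""Shared fixtures: one full-size reference simulation (reused across tests
because it is the expensive object) and a small fast configuration for
structural checks."""

from __future__ import annotations

import pytest
from hypothesis import settings

import methcapdmr.dmr as dmr
import methcapdmr.simulate as sim
import methcapdmr.windows as win

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def small_config(**overrides) -> sim.SimConfig:
    """A cheap configuration for structural (non-statistical) tests."""
    kwargs = dict(
        seed=7,
        n_chroms=1,
        chrom_length=60_000,
        n_genes=3,
        gene_length_range=(2000, 4000),
        n_cgis=3,
        cgi_length=1000,
        n_repeats=5,
        repeat_length_range=(200, 400),
        region_size=2000,
        n_dmrs=5,
        reads_per_library=5000,
    )
    kwargs.update(overrides)
    return sim.SimConfig(**kwargs)


@pytest.fixture(scope="session")
def default_sim():
    """The reference study conditions at seed 42."""
    config = sim.SimConfig(seed=42)
    return config, sim.simulate_dataset(config)


@pytest.fixture(scope="session")
def default_windows(default_sim):
    config, result = default_sim
    stats, lib_a, lib_b, un_a, un_b = win.window_stats(
        config.chrom_lengths(), result.reads_a, result.reads_b
    )
    return stats, lib_a, lib_b


@pytest.fixture(scope="session")
def default_calls(default_sim, default_windows):
    stats, lib_a, lib_b = default_windows
    return dmr.call_dmrs(stats, dmr.DMRFilterConfig(), lib_a, lib_b)
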