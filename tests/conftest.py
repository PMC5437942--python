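"""Shared fixtures: small deterministic simulations reused across tests."""

from __future__ import annotations

import pytest

import megareads as mr
from megareads.simulate import ERROR_FREE


@pytest.fixture(scope="session")
def small_genome():
    """Repeat-free 20-kb genome."""
    return mr.generate_genome(20_000, [], seed=101)


@pytest.fixture(scope="session")
def error_free_assembly():
    """Error-free short+long reads of a repeat-free 50-kb genome pushed
    through super-reads, mega-reads and contig assembly."""
    genome = mr.generate_genome(50_000, [], seed=7)
    short = mr.simulate_short_reads(genome, 20, 100, (300, 500),
                                    ERROR_FREE, seed=8)
    spectrum = mr.build_kmer_spectrum(short, 25, 1)
    supers = mr.build_super_reads(short, spectrum)
    longs = mr.simulate_long_reads(genome, 12, 4000, 1500, ERROR_FREE,
                                   0.0, seed=9)
    run = mr.run_megareads(longs, supers)
    contigs = mr.assemble({m.id: m.sequence for m in run.mega_reads})
    return {
        "genome": genome,
        "super_reads": supers,
        "long_reads": longs,
        "run": run,
        "contigs": contigs,
    }


@pytest.fixture(scope="session")
def benchmark_replicates():
    """Three replicates of the documented correction benchmark (200-kb
    genome with a diverged repeat family, 30x short reads at 1% error,
    12x long reads at ~15% error)."""
    from megareads.benchmark import run_correction_benchmark

    return [run_correction_benchmark(seed) for seed in (1, 2, 3)]
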