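"""Reference benchmark for mega-read correction accuracy.

One benchmark run simulates the pipeline's documented operating point —
a 200-kb genome carrying one 2-kb repeat family (5 copies, 2%
divergence), 30x paired short reads at 1% substitution error, and 12x
long reads at ~15% insertion-dominated error — builds super-reads and
mega-reads at default parameters, and measures every mega-read against
the recorded true origin of its source long read with an edit-distance
aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

from .megaread import MegaReadParams, megaread_identity, run_megareads
from .simulate import (LONG_READ_PROFILE, SHORT_READ_PROFILE,
                       generate_genome, simulate_long_reads,
                       simulate_short_reads)
from .superread import build_kmer_spectrum, build_super_reads
from .util import derive_seed


@dataclass
class BenchmarkResult:
    seed: int
    n_long_reads: int
    n_mega_reads: int
    mega_reads_per_long_read: float
    mean_identity: float  # fraction in [0, 1]
    n_super_reads: int


def run_correction_benchmark(
    seed: int,
    genome_length: int = 200_000,
    repeat_spec=((1, 2000, 5, 0.02),),
    short_coverage: float = 30.0,
    read_length: int = 100,
    long_coverage: float = 12.0,
    long_length_mean: float = 9665.0,
    long_length_spread: float = 5000.0,
    params: MegaReadParams | None = None,
) -> BenchmarkResult:
    """Simulate, correct, and score one benchmark replicate."""
    genome = generate_genome(genome_length, list(repeat_spec), seed=seed)
    short = simulate_short_reads(
        genome, short_coverage, read_length, (300, 500),
        SHORT_READ_PROFILE, seed=derive_seed(seed, 2),
    )
    long_reads = simulate_long_reads(
        genome, long_coverage, long_length_mean, long_length_spread,
        LONG_READ_PROFILE, 0.0, seed=derive_seed(seed, 4),
    )
    spectrum = build_kmer_spectrum(short)
    super_reads = build_super_reads(short, spectrum)
    run = run_megareads(long_reads, super_reads, params)
    truth = {r.id: r for r in long_reads}
    identities = [
        megaread_identity(m, genome.sequence,
                          truth[m.source_long_read].true_origin)
        for m in run.mega_reads
    ]
    return BenchmarkResult(
        seed=seed,
        n_long_reads=len(long_reads),
        n_mega_reads=len(run.mega_reads),
        mega_reads_per_long_read=run.report["mega_reads_per_long_read"],
        mean_identity=(sum(identities) / len(identities)
                       if identities else 0.0),
        n_super_reads=len(super_reads),
    )
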