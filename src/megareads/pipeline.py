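"""End-to-end pipeline orchestration on a simulated genome.

``run_pipeline`` wires the stages together — simulate, super-reads,
mega-reads, contigs, scaffolds, statistics and feature containment — with
one master seed, a manifest log of parameters and counters, per-stage
artifact files, and simple stage resumption (a stage whose outputs exist
is skipped when ``resume`` is set).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .assemble import assemble
from .evaluate import containment_summary, write_report
from .io import SeqEntry, write_fasta
from .megaread import (MegaReadParams, megaread_identity,
                       placed_superread_ids, run_megareads)
from .metrics import assembly_stats
from .scaffold import (build_links, make_scaffolds, map_pairs, write_agp,
                       write_links_tsv)
from .simulate import (LONG_READ_PROFILE, SHORT_READ_PROFILE, ErrorProfile,
                       generate_genome, sample_features,
                       simulate_long_reads, simulate_short_reads,
                       write_truth)
from .superread import build_kmer_spectrum, build_super_reads
from .util import derive_seed

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, seeded and overridable.

    The matching word size is fixed at 15 throughout; the remaining
    defaults are the pipeline's documented operating point for a
    repeat-bearing 200-kb benchmark genome with 30x short reads and 12x
    noisy long reads.
    """

    seed: int = 1
    # genome
    genome_length: int = 200_000
    repeat_spec: list = field(
        default_factory=lambda: [(1, 2000, 5, 0.02)]
    )
    # short reads (shotgun library)
    short_coverage: float = 30.0
    read_length: int = 100
    fragment_range: tuple[int, int] = (300, 500)
    short_profile: ErrorProfile = field(
        default_factory=lambda: SHORT_READ_PROFILE
    )
    # long-fragment jumping library (for scaffolding)
    jump_coverage: float = 4.0
    jump_fragment_range: tuple[int, int] = (5000, 10000)
    # long reads
    long_coverage: float = 12.0
    long_length_mean: float = 9665.0
    long_length_spread: float = 5000.0
    long_profile: ErrorProfile = field(
        default_factory=lambda: LONG_READ_PROFILE
    )
    chimera_rate: float = 0.0
    # super-reads
    k: int = 25
    min_count: int = 2
    # mega-reads
    k_match: int = 15
    min_hits: int = 3
    diagonal_tolerance: float = 0.2
    min_overlap_agreement: float = 0.95
    # assembly
    min_overlap: int = 200
    max_error: float = 0.02
    assemble_min_support: int = 1
    # scaffolding
    min_support: int = 2
    gap_floor: int = 10
    # evaluation
    n_features: int = 50
    feature_length: int = 2000
    thresholds: tuple[int, ...] = (200, 500, 20000)
    # control
    skip_scaffold: bool = False
    skip_evaluate: bool = False

    def __post_init__(self):
        if self.k_match != 15:
            raise ValueError("the matching word size is fixed at 15")


@dataclass
class PipelineResult:
    genome: object
    super_reads: list
    mega_reads: list
    synthetic_pairs: list
    contigs: list
    scaffolds: list
    report: dict


def run_pipeline(
    config: PipelineConfig, outdir=None, resume: bool = False
) -> PipelineResult:
    """Execute all stages in order; artifacts are written under *outdir*
    when given.  Deterministic for a fixed config."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__,
                    "config": _config_dict(config)}
    if resume and out is not None:
        cached = _try_resume(out, report["config"])
        if cached is not None:
            log.info("resuming from %s (matching manifest)", out)
            return cached

    genome = generate_genome(config.genome_length, config.repeat_spec,
                             seed=derive_seed(config.seed, 1))
    short = simulate_short_reads(
        genome, config.short_coverage, config.read_length,
        config.fragment_range, config.short_profile,
        seed=derive_seed(config.seed, 2),
    )
    jump = simulate_short_reads(
        genome, config.jump_coverage, config.read_length,
        config.jump_fragment_range, config.short_profile,
        seed=derive_seed(config.seed, 3),
    ) if not config.skip_scaffold else []
    long_reads = simulate_long_reads(
        genome, config.long_coverage, config.long_length_mean,
        config.long_length_spread, config.long_profile,
        config.chimera_rate, seed=derive_seed(config.seed, 4),
    )
    report["reads"] = {
        "n_short": len(short), "n_jump": len(jump),
        "n_long": len(long_reads),
    }

    spectrum = build_kmer_spectrum(short, config.k, config.min_count)
    super_reads = build_super_reads(short, spectrum)
    report["super_reads"] = {
        "n": len(super_reads),
        "total_bases": sum(len(s.sequence) for s in super_reads),
        "compression_ratio": (len(short) / len(super_reads)
                              if super_reads else 0.0),
    }

    params = MegaReadParams(
        min_hits=config.min_hits,
        diagonal_tolerance=config.diagonal_tolerance,
        min_overlap_agreement=config.min_overlap_agreement,
    )
    mr = run_megareads(long_reads, super_reads, params)
    truth = {r.id: r for r in long_reads}
    identities = [
        megaread_identity(m, genome.sequence,
                          truth[m.source_long_read].true_origin)
        for m in mr.mega_reads
        if not truth[m.source_long_read].chimeric
    ]
    mr.report["mean_identity"] = (
        sum(identities) / len(identities) if identities else 0.0
    )
    report["mega_reads"] = mr.report

    placed = placed_superread_ids(mr.mega_reads)
    inputs = {m.id: m.sequence for m in mr.mega_reads}
    for sr in super_reads:
        if sr.id not in placed and len(sr.sequence) >= config.min_overlap:
            inputs[sr.id] = sr.sequence
    contigs = assemble(inputs, config.min_overlap, config.max_error,
                       config.assemble_min_support)
    contig_stats = assembly_stats((c.sequence for c in contigs),
                                  config.thresholds)
    report["contigs"] = dataclasses.asdict(contig_stats)

    scaffolds = []
    if not config.skip_scaffold:
        jump_pairs = [(jump[i], jump[i + 1]) for i in range(0, len(jump), 2)]
        mapped = map_pairs(list(mr.synthetic_pairs) + jump_pairs, contigs)
        fragment_mean = sum(config.jump_fragment_range) / 2
        links = build_links(mapped, contigs, fragment_mean=fragment_mean)
        scaffolds = make_scaffolds(contigs, links, config.min_support,
                                   config.gap_floor)
        scf_stats = assembly_stats((s.sequence for s in scaffolds),
                                   config.thresholds)
        report["scaffolds"] = dataclasses.asdict(scf_stats)
        if out is not None:
            write_links_tsv(links, out / "links.tsv")

    if not config.skip_evaluate:
        features = sample_features(genome, config.n_features,
                                   config.feature_length,
                                   seed=derive_seed(config.seed, 5))
        cr = containment_summary(
            [(fid, seq) for fid, seq, _ in features],
            contigs,
            scaffolds if scaffolds else None,
        )
        report["containment"] = cr.summary
        if out is not None:
            write_report(cr, out / "containment.tsv",
                         out / "containment.json")

    if out is not None:
        write_fasta([SeqEntry(id="genome", sequence=genome.sequence)],
                    out / "genome.fasta")
        write_truth(long_reads, out / "long_reads.truth.tsv")
        write_fasta(
            [SeqEntry(id=s.id, sequence=s.sequence,
                      description=f"n_reads={s.n_constituent_reads}")
             for s in super_reads],
            out / "super_reads.fasta",
        )
        write_fasta(
            [SeqEntry(id=m.id, sequence=m.sequence,
                      description=(f"src={m.source_long_read} interval="
                                   f"{m.long_read_interval[0]}-"
                                   f"{m.long_read_interval[1]}"))
             for m in mr.mega_reads],
            out / "mega_reads.fasta",
        )
        with open(out / "synthetic_pairs.tsv", "w") as fh:
            fh.write("left\tright\tgap\tsource\n")
            for p in mr.synthetic_pairs:
                fh.write(f"{p.left_megaread_id}\t{p.right_megaread_id}\t"
                         f"{p.gap_estimate}\t{p.source_long_read}\n")
        write_fasta(
            [SeqEntry(id=c.id, sequence=c.sequence) for c in contigs],
            out / "contigs.fasta",
        )
        if scaffolds:
            write_fasta(
                [SeqEntry(id=s.id, sequence=s.sequence)
                 for s in scaffolds],
                out / "scaffolds.fasta",
            )
            write_agp(scaffolds, contigs, out / "scaffolds.agp")
        with open(out / "manifest.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return PipelineResult(
        genome=genome, super_reads=super_reads, mega_reads=mr.mega_reads,
        synthetic_pairs=mr.synthetic_pairs, contigs=contigs,
        scaffolds=scaffolds, report=report,
    )


def _try_resume(out: Path, config_dict: dict) -> PipelineResult | None:
    """Reload a completed run whose manifest matches the config.

    Resumption is at whole-run granularity: the manifest carries the full
    configuration, and a run is reused only when every parameter matches.
    Reloaded objects carry sequences and ids; in-memory-only detail
    (tilings, layout records) is not reconstructed.
    """
    manifest = out / "manifest.json"
    if not manifest.exists():
        return None
    try:
        cached = json.loads(manifest.read_text())
    except json.JSONDecodeError:
        return None
    if json.loads(json.dumps(config_dict, default=str)) != cached.get(
        "config"
    ):
        return None
    from .io import read_fasta

    def entries(name):
        p = out / name
        return read_fasta(p) if p.exists() else []

    return PipelineResult(
        genome=None,
        super_reads=entries("super_reads.fasta"),
        mega_reads=entries("mega_reads.fasta"),
        synthetic_pairs=[],
        contigs=entries("contigs.fasta"),
        scaffolds=entries("scaffolds.fasta"),
        report=cached,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("short_profile", "long_profile"):
        d[key] = dataclasses.asdict(getattr(config, key))
    return d
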