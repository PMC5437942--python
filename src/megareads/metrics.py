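"""Assembly contiguity and coverage statistics.

N50 is the smallest length L such that sequences of length >= L together
hold at least half of the total bases; threshold counts use a strict
"longer than" comparison.  Sequence coverage is total bases over genome
size; clone coverage counts whole sequencing fragments rather than only
their sequenced ends, so for fragments of length F sequenced R bases from
each end it exceeds sequence coverage by F/(2R) — e.g. 10 000/200 = 50.

Fold coverages are displayed with one decimal below 10x and to the
nearest integer at 10x and above; the raw quotients remain available.
"""

from __future__ import annotations

from dataclasses import dataclass


def n50(lengths) -> int:
    """Smallest L with sum(lengths >= L) >= half the total (exact integer
    comparison, no floating point)."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    if min(lengths) <= 0:
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for L in lengths:
        acc += L
        if 2 * acc >= total:
            return L
    return lengths[-1]  # unreachable


def threshold_counts(lengths, thresholds) -> dict[int, int]:
    """Number of sequences strictly longer than each threshold."""
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    return {t: sum(1 for L in lengths if L > t) for t in thresholds}


def format_fold(x: float) -> float:
    """Display convention for fold coverage: one decimal below 10, nearest
    integer at 10 and above."""
    return round(x, 1) if x < 10 else float(round(x))


@dataclass
class CoverageModel:
    total_bases: int
    n_reads: int
    genome_size: int
    n_pairs: int = 0
    fragment_length: int = 0  # F
    read_length_per_end: int = 0  # R

    def __post_init__(self):
        if self.genome_size <= 0:
            raise ValueError("genome size must be positive")
        if self.total_bases < self.n_reads:
            raise ValueError("total bases below read count")
        if self.n_pairs and self.fragment_length < 2 * self.read_length_per_end:
            raise ValueError("fragment shorter than its sequenced ends")


def sequence_coverage(model: CoverageModel, raw: bool = False) -> float:
    cov = model.total_bases / model.genome_size
    return cov if raw else format_fold(cov)


def clone_coverage_ratio(F: int, R: int) -> float:
    """Factor by which clone coverage exceeds sequence coverage: F / 2R."""
    if R <= 0 or F < 2 * R:
        raise ValueError("need F >= 2R > 0 (fragment at least both ends)")
    return F / (2 * R)


def clone_coverage(model: CoverageModel, raw: bool = False) -> float:
    """Depth of coverage counting whole fragments: n_pairs * F / G."""
    if model.fragment_length < 2 * model.read_length_per_end:
        raise ValueError("fragment shorter than its sequenced ends")
    cov = model.n_pairs * model.fragment_length / model.genome_size
    return cov if raw else format_fold(cov)


def mean_read_length(total_bases: int, n_reads: int) -> int:
    if n_reads <= 0:
        raise ValueError("mean read length of zero reads is undefined")
    return int(round(total_bases / n_reads))


@dataclass
class AssemblyStats:
    n_sequences: int
    total_length: int  # non-N bases
    span_with_gaps: int  # including estimated gaps (N runs)
    n50: int
    counts_over: dict[int, int]


def assembly_stats(
    sequences, thresholds=(200, 500, 20000)
) -> AssemblyStats:
    """Table-style summary of a sequence set.  ``total_length`` counts
    non-N bases; ``span_with_gaps`` is the full span including N-run
    gaps, so their difference is the total estimated gap length."""
    seqs = list(sequences)
    lengths = [len(s) for s in seqs]
    n_bases = [len(s) - s.count("N") for s in seqs]
    return AssemblyStats(
        n_sequences=len(seqs),
        total_length=sum(n_bases),
        span_with_gaps=sum(lengths),
        n50=n50(lengths) if lengths else 0,
        counts_over=threshold_counts(lengths, thresholds),
    )
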