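"""Synthetic genomes and reads with recorded ground truth.

The simulator emulates the data regime the hybrid pipeline was designed
for: a genome with planted, slightly diverged repeat families; accurate
paired short reads from two fragment scales (a 300–500 bp shotgun library
and a 5–10 kb jumping library); and long, noisy single-molecule reads with
~15% error dominated by insertions, optionally chimeric.  Every read
carries its true origin interval on the forward strand of the genome so
that downstream accuracy claims are testable.

All coordinates are 0-based, half-open, on the genome's forward strand;
reverse-complement reads store strand '-' with the origin unchanged.
Every operation takes one explicit integer seed and is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .util import BASES, revcomp

log = logging.getLogger(__name__)

_B = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ErrorProfile:
    """Per-base error rates applied independently at each position."""

    mismatch_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0

    def __post_init__(self):
        if min(self.mismatch_rate, self.insertion_rate, self.deletion_rate) < 0:
            raise ValueError("error rates must be non-negative")
        if self.total > 0.5:
            raise ValueError(f"total error rate {self.total} exceeds 0.5")

    @property
    def total(self) -> float:
        return self.mismatch_rate + self.insertion_rate + self.deletion_rate


#: Shotgun short reads: substitution-only 1% error.
SHORT_READ_PROFILE = ErrorProfile(mismatch_rate=0.01)

#: Single-molecule long reads: ~15% total error, insertion-dominated.
LONG_READ_PROFILE = ErrorProfile(
    mismatch_rate=0.01, insertion_rate=0.10, deletion_rate=0.04
)

ERROR_FREE = ErrorProfile()


@dataclass
class SyntheticGenome:
    sequence: str
    length: int
    repeat_annotations: list[tuple[str, int, int, float]] = field(
        default_factory=list
    )
    seed: int = 0

    def __post_init__(self):
        if len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with declared length")
        for fam, start, end, ident in self.repeat_annotations:
            if not (0 <= start < end <= self.length):
                raise ValueError(f"repeat {fam} outside genome bounds")
            if not (0.5 <= ident <= 1.0):
                raise ValueError(f"repeat {fam} identity {ident} outside [0.5, 1]")


@dataclass
class SimulatedRead:
    id: str
    sequence: str
    true_origin: tuple[int, int, str]  # (start, end, strand) on the genome
    mate_id: str | None = None
    fragment_length: int | None = None
    chimeric: bool = False
    second_origin: tuple[int, int, str] | None = None


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _B[rng.integers(0, 4, n)].tobytes().decode()


def _mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability *rate*."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit):
        # shift by 1..3 within ACGT so the new base always differs
        idx = np.searchsorted(_B, arr[hit])
        arr[hit] = _B[(idx + rng.integers(1, 4, len(hit))) % 4]
    return arr.tobytes().decode()


def apply_errors(seq: str, profile: ErrorProfile, rng: np.random.Generator) -> str:
    """Inject mismatches, insertions and deletions per the profile."""
    if profile.total == 0:
        return seq
    if profile.insertion_rate == 0 and profile.deletion_rate == 0:
        return _mutate_substitutions(seq, profile.mismatch_rate, rng)
    n = len(seq)
    u = rng.random(n)
    ins = rng.random(n + 1) < profile.insertion_rate
    rand_ins = rng.integers(0, 4, n + 1)
    rand_sub = rng.integers(1, 4, n)
    p_del = profile.deletion_rate
    p_del_mis = p_del + profile.mismatch_rate
    out: list[str] = []
    for i, ch in enumerate(seq):
        if ins[i]:
            out.append(BASES[rand_ins[i]])
        if u[i] < p_del:
            continue
        if u[i] < p_del_mis and ch in BASES:
            out.append(BASES[(BASES.index(ch) + rand_sub[i]) % 4])
        else:
            out.append(ch)
    if ins[n]:
        out.append(BASES[rand_ins[n]])
    return "".join(out)


def generate_genome(
    length: int,
    repeat_spec: list[tuple[int, int, int, float]] | tuple = (),
    seed: int | None = None,
) -> SyntheticGenome:
    """Random genome with planted repeat families.

    ``repeat_spec`` entries are ``(n_families, unit_length, copy_number,
    divergence)``: for each family a master unit is drawn and each planted
    copy is independently mutated at divergence/2 substitutions per base,
    giving ~``divergence`` pairwise divergence between copies.  Copies are
    planted at non-overlapping positions recorded in
    ``repeat_annotations``.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if length < 1000:
        raise ValueError("genome length must be at least 1000")
    span = sum(nf * ul * cn for nf, ul, cn, _ in repeat_spec)
    if span > length:
        raise ValueError(
            f"total repeat span {span} exceeds genome length {length}"
        )
    rng = np.random.default_rng(seed)
    genome = bytearray(_random_seq(rng, length).encode())
    annotations: list[tuple[str, int, int, float]] = []
    occupied: list[tuple[int, int]] = []
    fam_index = 0
    for n_families, unit_len, copies, divergence in repeat_spec:
        if not (0.0 <= divergence <= 0.5):
            raise ValueError("divergence must be in [0, 0.5]")
        for _ in range(n_families):
            fam_id = f"fam{fam_index}"
            fam_index += 1
            master = _random_seq(rng, unit_len)
            for _ in range(copies):
                placed = False
                for _attempt in range(1000):
                    start = int(rng.integers(0, length - unit_len + 1))
                    end = start + unit_len
                    if all(end <= s or start >= e for s, e in occupied):
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        "could not place repeat copies without overlap; "
                        "genome too small for the requested repeat span"
                    )
                copy_seq = _mutate_substitutions(master, divergence / 2, rng)
                genome[start:end] = copy_seq.encode()
                occupied.append((start, end))
                annotations.append((fam_id, start, end, 1.0 - divergence))
    annotations.sort(key=lambda a: (a[1], a[0]))
    return SyntheticGenome(
        sequence=genome.decode(),
        length=length,
        repeat_annotations=annotations,
        seed=seed,
    )


def simulate_short_reads(
    genome: SyntheticGenome,
    coverage: float,
    read_length: int,
    fragment_range: tuple[int, int],
    profile: ErrorProfile = SHORT_READ_PROFILE,
    seed: int | None = None,
) -> list[SimulatedRead]:
    """Paired short reads: mates face inward from opposite fragment ends.

    The number of pairs is chosen so total bases match ``coverage x
    genome length`` within rounding.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_length > genome.length:
        raise ValueError("read length exceeds genome length")
    fmin, fmax = fragment_range
    if fmin < 2 * read_length:
        raise ValueError(
            "fragment_range.min must be at least twice the read length"
        )
    if fmax > genome.length:
        raise ValueError("fragments longer than the genome")
    rng = np.random.default_rng(seed)
    g = genome.sequence
    G = genome.length
    n_pairs = int(round(coverage * G / (2 * read_length)))
    frags = rng.integers(fmin, fmax + 1, n_pairs)
    starts = rng.integers(0, G - frags + 1, n_pairs)
    flips = rng.random(n_pairs) < 0.5
    reads: list[SimulatedRead] = []
    R = read_length
    for i in range(n_pairs):
        start, frag = int(starts[i]), int(frags[i])
        end = start + frag
        fwd = SimulatedRead(
            id=f"sr{i}/1",
            sequence=apply_errors(g[start : start + R], profile, rng),
            true_origin=(start, start + R, "+"),
            mate_id=f"sr{i}/2",
            fragment_length=frag,
        )
        rev = SimulatedRead(
            id=f"sr{i}/2",
            sequence=apply_errors(revcomp(g[end - R : end]), profile, rng),
            true_origin=(end - R, end, "-"),
            mate_id=f"sr{i}/1",
            fragment_length=frag,
        )
        if flips[i]:
            fwd.id, rev.id = rev.id, fwd.id
            fwd.mate_id, rev.mate_id = rev.mate_id, fwd.mate_id
            reads.extend([rev, fwd])
        else:
            reads.extend([fwd, rev])
    return reads


def simulate_long_reads(
    genome: SyntheticGenome,
    coverage: float,
    length_mean: float = 9665.0,
    length_spread: float = 5000.0,
    profile: ErrorProfile = LONG_READ_PROFILE,
    chimera_rate: float = 0.0,
    seed: int | None = None,
    min_length: int | None = None,
) -> list[SimulatedRead]:
    """Noisy long reads with log-normal lengths.

    A ``chimera_rate`` fraction of reads are head-to-tail fusions of two
    uniformly chosen loci at a uniform breakpoint; the second segment's
    strand is random and its origin is recorded in ``second_origin``.
    ``min_length``, when given, emulates a size-selection floor by
    resampling lengths below it.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if length_mean < 500:
        raise ValueError("length_mean must be at least 500")
    if not (0.0 <= chimera_rate <= 0.2):
        raise ValueError("chimera_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    g = genome.sequence
    G = genome.length
    target = coverage * G
    sigma2 = np.log1p((length_spread / length_mean) ** 2)
    mu = np.log(length_mean) - sigma2 / 2
    sigma = np.sqrt(sigma2)

    def draw_length() -> int:
        for _ in range(100):
            L = int(rng.lognormal(mu, sigma))
            if min_length is not None and L < min_length:
                continue
            return max(200, min(L, G))
        return max(200, min(min_length or 200, G))

    # insertions lengthen and deletions shorten the emitted sequence;
    # budget on emitted bases so realized coverage matches the request
    stretch = 1.0 + profile.insertion_rate - profile.deletion_rate
    reads: list[SimulatedRead] = []
    total = 0
    i = 0
    while total < target:
        L = draw_length()
        if total + L * stretch > target:
            # trim the final read so emitted coverage matches the request
            L = max(200, int((target - total) / stretch))
        if rng.random() < chimera_rate:
            cut = int(L * rng.uniform(0.2, 0.8))
            s1 = int(rng.integers(0, G - cut + 1))
            st1 = "+" if rng.random() < 0.5 else "-"
            seg1 = g[s1 : s1 + cut]
            if st1 == "-":
                seg1 = revcomp(seg1)
            L2 = L - cut
            s2 = int(rng.integers(0, G - L2 + 1))
            st2 = "+" if rng.random() < 0.5 else "-"
            seg2 = g[s2 : s2 + L2]
            if st2 == "-":
                seg2 = revcomp(seg2)
            reads.append(
                SimulatedRead(
                    id=f"lr{i}",
                    sequence=apply_errors(seg1 + seg2, profile, rng),
                    true_origin=(s1, s1 + cut, st1),
                    chimeric=True,
                    second_origin=(s2, s2 + L2, st2),
                )
            )
        else:
            start = int(rng.integers(0, G - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seg = g[start : start + L]
            if strand == "-":
                seg = revcomp(seg)
            reads.append(
                SimulatedRead(
                    id=f"lr{i}",
                    sequence=apply_errors(seg, profile, rng),
                    true_origin=(start, start + L, strand),
                )
            )
        total += len(reads[-1].sequence)
        i += 1
    log.info("simulated %d long reads, %d bases", len(reads), total)
    return reads


def sample_features(
    genome: SyntheticGenome,
    n_features: int,
    feature_length: int,
    seed: int | None = None,
) -> list[tuple[str, str, tuple[int, int]]]:
    """Sample feature intervals ("genes"/"fosmids") from the genome to
    serve as an evaluation truth set; returns (id, sequence, interval)."""
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if feature_length > genome.length:
        raise ValueError("feature longer than the genome")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_features):
        start = int(rng.integers(0, genome.length - feature_length + 1))
        out.append(
            (
                f"feat{i}",
                genome.sequence[start : start + feature_length],
                (start, start + feature_length),
            )
        )
    return out


def write_truth(reads: list[SimulatedRead], path) -> None:
    """Ground-truth TSV sidecar: read id, start, end, strand, chimeric."""
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tend\tstrand\tchimeric\n")
        for r in reads:
            s, e, st = r.true_origin
            fh.write(f"{r.id}\t{s}\t{e}\t{st}\t{int(r.chimeric)}\n")
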