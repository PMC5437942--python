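"""Super-read construction: unique de Bruijn extension plus deduplication.

Short reads are first screened against a canonical k-mer spectrum (k-mers
seen fewer than ``min_count`` times are treated as sequencing errors).  A
read whose k-mers all survive is extended base by base at both ends for as
long as exactly one continuation k-mer exists in the spectrum; extension
halts at a junction (two or more continuations), a dead end, or a length
cap.  Extended reads are then deduplicated: any super-read contained in
another (either strand) is merged into it, so a deep short-read set
collapses into a far smaller set of accurate, longer sequences.

This is a compact re-statement of the super-read principle; the production
machinery (quality-aware error correction, jumping-library handling) is
intentionally out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .simulate import SimulatedRead
from .util import BASES, canonical, revcomp

log = logging.getLogger(__name__)

DEFAULT_K = 25
MAX_SUPER_READ_LENGTH = 2_000_000


@dataclass
class KmerSpectrum:
    k: int
    counts: dict[str, int]
    min_count: int
    n_reads_skipped: int = 0  # reads shorter than k

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.counts


@dataclass
class SuperRead:
    id: str
    sequence: str
    n_constituent_reads: int
    seed_read_ids: list[str] = field(default_factory=list)
    flagged: bool = False  # read contained a k-mer absent from the spectrum


def build_kmer_spectrum(
    reads: list[SimulatedRead], k: int = DEFAULT_K, min_count: int = 2
) -> KmerSpectrum:
    """Count canonical k-mers across all reads, dropping those below
    ``min_count`` (error filtering).  Reads shorter than k are skipped and
    counted, not rejected."""
    if not (11 <= k <= 63) or k % 2 == 0:
        raise ValueError("k must be odd and in [11, 63]")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    skipped = 0
    for read in reads:
        seq = read.sequence
        if len(seq) < k:
            skipped += 1
            continue
        for i in range(len(seq) - k + 1):
            c = canonical(seq[i : i + k])
            counts[c] = counts.get(c, 0) + 1
    if min_count > 1:
        counts = {km: n for km, n in counts.items() if n >= min_count}
    if skipped:
        log.info("spectrum: skipped %d reads shorter than k=%d", skipped, k)
    return KmerSpectrum(k=k, counts=counts, min_count=min_count,
                        n_reads_skipped=skipped)


def _screen(seq: str, spectrum: KmerSpectrum) -> bool:
    """True when every k-mer of *seq* is present in the spectrum at
    credible depth.

    Besides outright absence, a k-mer far below the read's median k-mer
    depth marks a residual error (an error k-mer that happened to recur
    above ``min_count``); such reads are flagged rather than allowed to
    seed extensions that would embed the error."""
    k = spectrum.k
    counts = spectrum.counts
    observed = []
    for i in range(len(seq) - k + 1):
        c = counts.get(canonical(seq[i : i + k]), 0)
        if c == 0:
            return False
        observed.append(c)
    observed.sort()
    med = observed[len(observed) // 2]
    return observed[0] >= BRANCH_RATIO * med


#: A continuation whose count is below this fraction of the dominant
#: continuation's count is treated as residual sequencing error, not as a
#: genuine junction branch.
BRANCH_RATIO = 0.2


def _continuations(tail: str, spectrum: KmerSpectrum) -> list[str]:
    """Spectrum continuations of a (k-1)-mer, discarding low-abundance
    side branches: surviving error k-mers sit at counts near the spectrum
    floor while the true path carries full read depth, whereas the
    branches of a real (repeat) junction have comparable depth."""
    cands = [
        (b, spectrum.counts.get(canonical(tail + b), 0)) for b in BASES
    ]
    cands = [(b, c) for b, c in cands if c > 0]
    if not cands:
        return []
    cmax = max(c for _, c in cands)
    return [b for b, c in cands if c >= BRANCH_RATIO * cmax]


def _extend(seq: str, spectrum: KmerSpectrum, max_length: int) -> str:
    """Unique extension of *seq* at both ends through the spectrum."""
    k = spectrum.k
    # rightward
    out = list(seq)
    while len(out) < max_length:
        nxt = _continuations("".join(out[-(k - 1):]), spectrum)
        if len(nxt) != 1:
            break
        out.append(nxt[0])
    # leftward (extend the reverse complement rightward)
    rc = list(revcomp("".join(out)))
    while len(rc) < max_length:
        nxt = _continuations("".join(rc[-(k - 1):]), spectrum)
        if len(nxt) != 1:
            break
        rc.append(nxt[0])
    return revcomp("".join(rc))


def extend_to_super_read(
    read: SimulatedRead,
    spectrum: KmerSpectrum,
    max_length: int = MAX_SUPER_READ_LENGTH,
) -> SuperRead:
    """Extend one read through the spectrum; reads carrying a k-mer absent
    from the spectrum (error reads) are returned unextended and flagged."""
    seq = read.sequence.upper()
    if len(seq) < spectrum.k or not _screen(seq, spectrum):
        return SuperRead(
            id=read.id, sequence=seq, n_constituent_reads=1,
            seed_read_ids=[read.id], flagged=True,
        )
    extended = _extend(seq, spectrum, max_length)
    return SuperRead(
        id=read.id, sequence=extended, n_constituent_reads=1,
        seed_read_ids=[read.id],
    )


def build_super_reads(
    reads: list[SimulatedRead],
    spectrum: KmerSpectrum,
    max_length: int = MAX_SUPER_READ_LENGTH,
) -> list[SuperRead]:
    """Extend every screened read and deduplicate by containment.

    A read whose first k-mer already belongs to a built super-read and that
    is fully contained in it (either strand) is absorbed without
    re-walking the graph, which keeps construction linear in total bases.
    Output ids are stable: sorted by descending length, then sequence.
    """
    k = spectrum.k
    drafts: list[SuperRead] = []
    kmer_owner: dict[str, int] = {}
    n_flagged = 0
    n_short = 0
    for read in sorted(reads, key=lambda r: r.id):
        seq = read.sequence.upper()
        if len(seq) < k:
            n_short += 1
            continue
        if not _screen(seq, spectrum):
            n_flagged += 1
            continue
        owner = kmer_owner.get(canonical(seq[:k]))
        if owner is not None:
            sr = drafts[owner]
            if seq in sr.sequence or revcomp(seq) in sr.sequence:
                sr.n_constituent_reads += 1
                sr.seed_read_ids.append(read.id)
                continue
        extended = _extend(seq, spectrum, max_length)
        idx = len(drafts)
        drafts.append(
            SuperRead(
                id=f"draft{idx}", sequence=extended,
                n_constituent_reads=1, seed_read_ids=[read.id],
            )
        )
        for i in range(len(extended) - k + 1):
            kmer_owner.setdefault(canonical(extended[i : i + k]), idx)
    merged = _deduplicate(drafts)
    merged.sort(key=lambda s: (-len(s.sequence), s.sequence))
    for i, sr in enumerate(merged):
        sr.id = f"SR{i:06d}"
    log.info(
        "super-reads: %d reads in (%d flagged, %d short), %d super-reads out",
        len(reads), n_flagged, n_short, len(merged),
    )
    return merged


def _deduplicate(drafts: list[SuperRead]) -> list[SuperRead]:
    """Merge any super-read contained in another (either strand); ties
    between identical sequences keep the lexicographically smaller id."""
    order = sorted(drafts, key=lambda s: (-len(s.sequence), s.id))
    kept: list[SuperRead] = []
    kept_index: dict[str, int] = {}  # k-mer -> kept idx, for candidate lookup
    for sr in order:
        seq = sr.sequence
        container = None
        for cand in _containment_candidates(seq, kept, kept_index):
            if seq in cand.sequence or revcomp(seq) in cand.sequence:
                container = cand
                break
        if container is not None:
            container.n_constituent_reads += sr.n_constituent_reads
            container.seed_read_ids.extend(sr.seed_read_ids)
        else:
            idx = len(kept)
            kept.append(sr)
            probe = canonical(seq[: min(len(seq), 25)])
            kept_index.setdefault(probe, idx)
    return kept


def _containment_candidates(seq, kept, kept_index):
    # cheap path: probe by leading k-mer, else scan all kept (desk scale)
    probe = canonical(seq[: min(len(seq), 25)])
    idx = kept_index.get(probe)
    if idx is not None:
        yield kept[idx]
    yield from kept
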