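"""Mega-read construction: correct noisy long reads by tiling them with
super-reads.

Each long read is scanned against a database of all 15-mers of the
super-reads.  Exact 15-mer hits are chained per (super-read, strand) into
placements; inconsistent placements (those that cannot belong to one
consistent walk along the read) are discarded by a maximum-weight
compatible-chain selection; the survivors are spliced into mega-reads
whose bases come exclusively from super-reads — the noisy read serves only
as the template that orders and orients them.  Uncovered stretches between
consecutive mega-reads of one read yield synthetic mate pairs used later
in scaffolding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .chaining import K_MATCH, Chain, KmerIndex, collect_hits, extract_chains
from .simulate import SimulatedRead
from .superread import SuperRead
from .util import revcomp

log = logging.getLogger(__name__)


@dataclass
class MegaReadParams:
    """Tiling parameters.

    min_hits
        minimum chained 15-mer hits for a placement (default 3).
    diagonal_tolerance
        allowed diagonal drift as a fraction of distance covered; 0.2
        covers 15% indel error with margin.
    min_overlap_agreement
        identity required between the two super-read sequences across a
        splice overlap longer than 15 bases; shorter overlaps must match
        exactly.
    """

    min_hits: int = 3
    diagonal_tolerance: float = 0.2
    min_overlap_agreement: float = 0.95


@dataclass
class Placement:
    """A super-read's chained 15-mer match to an interval of one long read.

    ``superread_interval`` is in the coordinates of the super-read oriented
    to the read (for strand '-', positions count along the reverse
    complement)."""

    superread_id: str
    long_read_interval: tuple[int, int]
    superread_interval: tuple[int, int]
    strand: str
    n_hits: int
    diagonal: int
    chain: Chain = field(repr=False, default=None)
    superread_length: int = 0

    def map_read_pos(self, pos: int) -> int:
        t = self.chain.map_query_pos(pos, self.superread_length)
        return max(self.superread_interval[0],
                   min(self.superread_interval[1], t))


@dataclass
class MegaRead:
    id: str
    sequence: str
    source_long_read: str
    long_read_interval: tuple[int, int]
    tiling: list[Placement] = field(default_factory=list)


@dataclass
class SyntheticMatePair:
    left_megaread_id: str
    right_megaread_id: str
    gap_estimate: int
    source_long_read: str


def build_match_index(super_reads: list[SuperRead]) -> KmerIndex:
    """Database of all 15-mers of the super-reads (canonical, with strand
    flags); super-reads shorter than 15 are skipped with a log entry."""
    if not super_reads:
        raise ValueError("super-read set is empty")
    index = KmerIndex({sr.id: sr.sequence for sr in super_reads}, k=K_MATCH)
    if index.n_skipped:
        log.info("match index: skipped %d super-reads shorter than %d",
                 index.n_skipped, K_MATCH)
    return index


def find_placements(
    long_read: SimulatedRead,
    index: KmerIndex,
    min_hits: int = 3,
    diagonal_tolerance_fraction: float = 0.2,
) -> list[Placement]:
    """Chain 15-mer hits of the super-read database along one long read.

    Each chained locus is extended from the matched core to the full
    extent of the super-read (clamped to the read): exact-word chains
    systematically stop a few bases short of the true boundary on noisy
    reads, and the overhang bases are still super-read bases, so the
    extension recovers the abutments between adjacent super-reads without
    touching read sequence.
    """
    if len(long_read.sequence) < K_MATCH:
        return []
    groups = collect_hits(long_read.sequence, index)
    read_len = len(long_read.sequence)
    placements: list[Placement] = []
    for (sid, rel), hits in sorted(groups.items()):
        if len(hits) < min_hits:
            continue
        sr_len = index.lengths[sid]
        for chain in extract_chains(hits, diagonal_tolerance_fraction,
                                    min_hits):
            chain.strand = rel
            q0, q1 = chain.query_interval
            t0, t1 = chain.target_interval
            ext_left = min(t0, q0)
            ext_right = min(sr_len - t1, read_len - q1)
            placements.append(
                Placement(
                    superread_id=sid,
                    long_read_interval=(q0 - ext_left, q1 + ext_right),
                    superread_interval=(t0 - ext_left, t1 + ext_right),
                    strand=rel,
                    n_hits=chain.n_hits,
                    diagonal=chain.diagonal,
                    chain=chain,
                    superread_length=sr_len,
                )
            )
    placements.sort(key=lambda p: (p.long_read_interval, p.superread_id,
                                   p.strand))
    return placements


def _oriented(sr: SuperRead, strand: str) -> str:
    return sr.sequence if strand == "+" else revcomp(sr.sequence)


def _overlap_splice(
    p: Placement,
    q: Placement,
    super_reads: dict[str, SuperRead],
    min_agreement: float,
) -> tuple[int, int] | None:
    """Verify the implied super-read overlap of two read-overlapping
    placements and locate a splice point.

    The two placements map read positions through different chains, so
    their segment coordinates can disagree by the read's indel jitter;
    the shorter segment is aligned as an infix of the other's padded
    window, which tolerates the jitter while still rejecting overlaps
    from divergent loci (identity below ``min_agreement``; overlaps of
    15 bp or less must match exactly).  On success returns the cut
    positions ``(a_mid, b_mid)`` in the two oriented super-reads,
    derived from the alignment location so the splice is coordinate
    exact; on failure returns None.
    """
    overlap = p.long_read_interval[1] - q.long_read_interval[0]
    if overlap <= 0:
        return p.superread_interval[1], q.superread_interval[0]
    a = _oriented(super_reads[p.superread_id], p.strand)
    b = _oriented(super_reads[q.superread_id], q.strand)
    a1 = p.map_read_pos(q.long_read_interval[0])
    a2 = p.superread_interval[1]
    b1 = q.superread_interval[0]
    b2 = q.map_read_pos(p.long_read_interval[1])
    seg_a, seg_b = a[a1:a2], b[b1:b2]
    if not seg_a or not seg_b:
        return None
    pad = 10 + overlap // 10
    a_is_query = len(seg_a) <= len(seg_b)
    if a_is_query:
        query = seg_a
        ws = max(0, b1 - pad)
        window = b[ws: b2 + pad]
    else:
        query = seg_b
        ws = max(0, a1 - pad)
        window = a[ws: a2 + pad]
    if overlap <= K_MATCH:
        at = window.find(query)
        if at < 0:
            return None
        dist, loc = 0, (at, at + len(query) - 1)
    else:
        res = edlib.align(query, window, mode="HW", task="locations")
        dist = res["editDistance"]
        if 1.0 - dist / len(query) < min_agreement:
            return None
        loc = res["locations"][0]
    if a_is_query:
        # A position a1 corresponds to B position ws + loc[0]
        a_mid = (a1 + a2) // 2
        b_mid = ws + loc[0] + (a_mid - a1)
        return a_mid, max(0, min(len(b), b_mid))
    b_mid = (b1 + b2) // 2
    a_mid = ws + loc[0] + (b_mid - b1)
    return max(0, min(len(a), a_mid)), b_mid


def _overlap_agrees(
    p: Placement,
    q: Placement,
    super_reads: dict[str, SuperRead],
    min_agreement: float,
) -> bool:
    return _overlap_splice(p, q, super_reads, min_agreement) is not None


def _compatible(
    p: Placement,
    q: Placement,
    super_reads: dict[str, SuperRead] | None,
    min_agreement: float,
) -> bool:
    """Can q directly follow p in one consistent tiling?  Requires strict
    forward progress on the read and, when the two placements overlap,
    agreement of the implied super-read overlap."""
    if q.long_read_interval[0] < p.long_read_interval[0]:
        return False
    if q.long_read_interval[1] <= p.long_read_interval[1]:
        return False  # containment or no progress
    if super_reads is None:
        return True
    return _overlap_agrees(p, q, super_reads, min_agreement)


def filter_inconsistent(
    placements: list[Placement],
    super_reads: dict[str, SuperRead] | None = None,
    min_overlap_agreement: float = 0.95,
) -> tuple[list[Placement], list[Placement]]:
    """Maximum-weight consistent tiling by weighted chain selection.

    Placements are sorted along the read; a subset is consistent when
    every consecutive pair is compatible (forward progress + overlap
    agreement).  The kept set maximises total hit weight; ties prefer the
    lexicographically smallest placement tuple (interval, then super-read
    id), matching the exhaustive-search oracle.  Returns (kept,
    discarded).
    """
    if not placements:
        return [], []
    order = sorted(
        placements,
        key=lambda p: (p.long_read_interval, p.superread_id, p.strand),
    )
    n = len(order)
    best: list[tuple[int, tuple]] = [None] * n  # (weight, index tuple)
    for i in range(n):
        w, key = order[i].n_hits, (i,)
        for j in range(i):
            if best[j][0] + order[i].n_hits > w or (
                best[j][0] + order[i].n_hits == w
                and best[j][1] + (i,) < key
            ):
                if _compatible(order[j], order[i], super_reads,
                               min_overlap_agreement):
                    w = best[j][0] + order[i].n_hits
                    key = best[j][1] + (i,)
        best[i] = (w, key)
    w_max = max(b[0] for b in best)
    winner = min(b[1] for b in best if b[0] == w_max)
    kept = [order[i] for i in winner]
    dropped = [order[i] for i in range(n) if i not in set(winner)]
    return kept, dropped


def rescue_gaps(
    kept: list[Placement],
    discarded: list[Placement],
    super_reads: dict[str, SuperRead],
    min_overlap_agreement: float = 0.95,
) -> list[Placement]:
    """Patch tiling gaps with discarded placements.

    The maximum-weight chain can leave a read stretch uncovered when the
    only spanning placement conflicts with a heavier, coverage-redundant
    one (typical inside diverged repeats).  For each gap between
    consecutive kept placements, the best-supported discarded placement
    that bridges the gap and whose super-read sequence agrees with both
    flanks is re-inserted; a bridge that also covers a flank supersedes
    it.  Only genuine gaps are touched, so the consistent chain is
    otherwise unchanged.
    """
    if not discarded:
        return kept
    order = list(kept)
    used: set[int] = set()
    changed = True
    while changed:
        changed = False
        for i in range(len(order) - 1):
            p, q = order[i], order[i + 1]
            gap = q.long_read_interval[0] - p.long_read_interval[1]
            if gap <= 0:
                continue
            bridges = [
                b for b in discarded
                if id(b) not in used
                and b.long_read_interval[0] <= p.long_read_interval[1]
                and b.long_read_interval[1] >= q.long_read_interval[0]
                and _overlap_agrees(p, b, super_reads,
                                    min_overlap_agreement)
                and _overlap_agrees(b, q, super_reads,
                                    min_overlap_agreement)
            ]
            if not bridges:
                continue
            bridges.sort(key=lambda b: (-b.n_hits, b.long_read_interval,
                                        b.superread_id))
            b = bridges[0]
            used.add(id(b))
            repl = order[: i + 1] + [b] + order[i + 1:]
            # a bridge spanning past a flank supersedes it
            if b.long_read_interval[1] >= q.long_read_interval[1]:
                repl.remove(q)
            if b.long_read_interval[0] <= p.long_read_interval[0]:
                repl.remove(p)
            order = repl
            changed = True
            break
    return order


def merge_to_mega_reads(
    long_read: SimulatedRead,
    placements: list[Placement],
    super_reads: dict[str, SuperRead],
    min_overlap_agreement: float = 0.95,
) -> tuple[list[MegaRead], list[SyntheticMatePair]]:
    """Splice consistent placements into mega-reads.

    Consecutive placements that overlap or abut on the read are joined at
    the midpoint of their overlap after verifying the implied super-read
    overlap; a gap or a failed verification closes the current mega-read.
    One synthetic mate pair is emitted per adjacent mega-read pair, with
    the read-gap length as the gap estimate.  Mega-read bases are copied
    from super-reads only, never from the long read.
    """
    megas: list[MegaRead] = []
    pairs: list[SyntheticMatePair] = []
    if not placements:
        return megas, pairs
    order = sorted(placements, key=lambda p: (p.long_read_interval,
                                              p.superread_id))
    segments: list[str] = []
    tiling: list[Placement] = []
    cur = order[0]
    cur_seq = _oriented(super_reads[cur.superread_id], cur.strand)
    cursor = cur.superread_interval[0]
    mega_start = cur.long_read_interval[0]

    def close(end_read_pos: int):
        segments.append(cur_seq[cursor:cur.superread_interval[1]])
        seq = "".join(segments)
        if seq:
            megas.append(
                MegaRead(
                    id=f"{long_read.id}.mr{len(megas)}",
                    sequence=seq,
                    source_long_read=long_read.id,
                    long_read_interval=(mega_start, end_read_pos),
                    tiling=list(tiling),
                )
            )

    tiling.append(cur)
    for q in order[1:]:
        if q.long_read_interval[1] <= cur.long_read_interval[1]:
            continue  # contained placement adds nothing
        gap = q.long_read_interval[0] - cur.long_read_interval[1]
        splice = (
            _overlap_splice(cur, q, super_reads, min_overlap_agreement)
            if gap <= 0 else None
        )
        if splice is not None:
            a_mid, b_mid = splice
            segments.append(cur_seq[cursor:max(cursor, a_mid)])
            cur = q
            cur_seq = _oriented(super_reads[cur.superread_id], cur.strand)
            cursor = b_mid
            tiling.append(q)
        else:
            if gap <= 0:
                log.debug("%s: splice verification failed at %d",
                          long_read.id, q.long_read_interval[0])
            close(cur.long_read_interval[1])
            segments.clear()
            tiling.clear()
            prev_end = cur.long_read_interval[1]
            cur = q
            cur_seq = _oriented(super_reads[cur.superread_id], cur.strand)
            if gap > 0:
                mega_start = q.long_read_interval[0]
                cursor = q.superread_interval[0]
            else:
                # failed agreement inside an overlap: trim the new
                # mega-read so read intervals stay disjoint
                mega_start = prev_end
                cursor = q.map_read_pos(prev_end)
            tiling.append(cur)
    close(cur.long_read_interval[1])
    for left, right in zip(megas, megas[1:]):
        pairs.append(
            SyntheticMatePair(
                left_megaread_id=left.id,
                right_megaread_id=right.id,
                gap_estimate=max(
                    0,
                    right.long_read_interval[0] - left.long_read_interval[1],
                ),
                source_long_read=long_read.id,
            )
        )
    return megas, pairs


@dataclass
class MegaReadRun:
    mega_reads: list[MegaRead]
    synthetic_pairs: list[SyntheticMatePair]
    report: dict


def run_megareads(
    long_reads: list[SimulatedRead],
    super_reads: list[SuperRead],
    params: MegaReadParams | None = None,
) -> MegaReadRun:
    """Tile, filter and merge every long read; returns all mega-reads,
    all synthetic pairs, and a per-run report."""
    params = params or MegaReadParams()
    index = build_match_index(super_reads)
    by_id = {sr.id: sr for sr in super_reads}
    megas: list[MegaRead] = []
    pairs: list[SyntheticMatePair] = []
    n_kept = n_dropped = n_tiled = 0
    for lr in sorted(long_reads, key=lambda r: r.id):
        placements = find_placements(
            lr, index, params.min_hits, params.diagonal_tolerance
        )
        kept, dropped = filter_inconsistent(
            placements, by_id, params.min_overlap_agreement
        )
        kept = rescue_gaps(kept, dropped, by_id,
                           params.min_overlap_agreement)
        n_kept += len(kept)
        n_dropped += len(dropped)
        m, p = merge_to_mega_reads(lr, kept, by_id,
                                   params.min_overlap_agreement)
        if m:
            n_tiled += 1
        megas.extend(m)
        pairs.extend(p)
    report = {
        "n_long_reads": len(long_reads),
        "n_long_reads_tiled": n_tiled,
        "n_mega_reads": len(megas),
        "n_synthetic_pairs": len(pairs),
        "placements_kept": n_kept,
        "placements_discarded": n_dropped,
        "mega_reads_per_long_read": (
            len(megas) / len(long_reads) if long_reads else 0.0
        ),
    }
    log.info("mega-reads: %s", report)
    return MegaReadRun(mega_reads=megas, synthetic_pairs=pairs, report=report)


def megaread_identity(
    mega: MegaRead, genome_sequence: str, origin: tuple[int, int, str]
) -> float:
    """Identity of one mega-read against the true origin segment of its
    source long read (infix edit-distance alignment)."""
    s, e, strand = origin
    segment = genome_sequence[s:e]
    if strand == "-":
        segment = revcomp(segment)
    if not mega.sequence or not segment:
        return 0.0
    dist = edlib.align(mega.sequence, segment, mode="HW",
                       task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / len(mega.sequence))


def placed_superread_ids(megas: list[MegaRead]) -> set[str]:
    """Super-reads absorbed into at least one mega-read tiling."""
    return {p.superread_id for m in megas for p in m.tiling}
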