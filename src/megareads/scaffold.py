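"""Mate-pair scaffolding with a minimum-support rule.

Contigs are joined into scaffolds using two kinds of evidence: genomic
read pairs from long (5–10 kb) DNA fragments, and synthetic mate pairs
created from the two mega-reads flanking an uncovered stretch of one long
read.  A join between two contig ends requires at least ``min_support``
(default 2) independent mates spanning the junction with consistent gap
estimates — the rule that keeps a single chimeric long read from welding
unrelated loci together, since a lone synthetic pair can never force a
join on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

from .assemble import Contig
from .chaining import KmerIndex, collect_hits, extract_chains
from .megaread import SyntheticMatePair
from .simulate import SimulatedRead
from .util import revcomp

log = logging.getLogger(__name__)


@dataclass
class MappedMate:
    contig: str
    interval: tuple[int, int]
    strand: str


@dataclass
class MappedPair:
    pair_id: str
    kind: str  # "synthetic" or "long_fragment"
    mates: tuple[MappedMate, MappedMate]
    gap_estimate: int | None = None  # carried by synthetic pairs


@dataclass
class Link:
    contig_a: str
    contig_b: str
    end_a: str  # which end of contig_a faces the gap: "L" or "R"
    end_b: str
    orientation: str  # FF/FR/RF/RR
    gap_estimates: list[int] = field(default_factory=list)
    sources: list[tuple[str, str]] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.gap_estimates)

    @property
    def gap(self) -> int:
        return int(median(self.gap_estimates))

    @property
    def gap_mad(self) -> float:
        m = self.gap
        return float(median(abs(g - m) for g in self.gap_estimates))


@dataclass
class Scaffold:
    id: str
    parts: list[tuple[str, str, int]]  # (contig id, strand, gap_after)
    sequence: str

    @property
    def span(self) -> int:
        return len(self.sequence)


def _place_mate(
    seq: str, index: KmerIndex, min_anchor: int, tolerance: float = 0.1
) -> MappedMate | None:
    """Unique best placement of one mate on the contigs; ambiguous mates
    (two near-equal placements at different loci) are dropped."""
    groups = collect_hits(seq, index)
    candidates = []
    for (cid, rel), hits in sorted(groups.items()):
        for chain in extract_chains(hits, tolerance, min_hits=2,
                                    max_loci=2):
            q0, q1 = chain.query_interval
            if q1 - q0 < min_anchor:
                continue
            t0, t1 = chain.target_interval
            if rel == "-":
                clen = index.lengths[cid]
                t0, t1 = clen - t1, clen - t0
            candidates.append((chain.n_hits, cid, (t0, t1), rel))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    best = candidates[0]
    if len(candidates) > 1:
        second = candidates[1]
        same_locus = (
            second[1] == best[1]
            and min(second[2][1], best[2][1]) - max(second[2][0], best[2][0])
            > 0
        )
        if not same_locus and second[0] >= 0.8 * best[0]:
            return None  # ambiguous
    return MappedMate(contig=best[1], interval=best[2], strand=best[3])


def map_pairs(
    pairs,
    contigs: list[Contig],
    min_anchor: int = 50,
) -> list[MappedPair]:
    """Anchor mate pairs on contigs.

    Genomic pairs (tuples of reads) are placed by 15-mer chaining; each
    mate must have a unique best placement of at least ``min_anchor``
    matched span.  Synthetic pairs are located through the contig layout
    records of their flanking mega-reads.  Pairs whose two mates land on
    the same contig are classified internal and produce no link.
    """
    mapped: list[MappedPair] = []
    index = None
    constituents: dict[str, tuple[str, tuple[int, int], str]] = {}
    for c in contigs:
        for sid, interval, strand in c.constituents:
            constituents.setdefault(sid, (c.id, interval, strand))
    n_unmapped = 0
    for pair in pairs:
        if isinstance(pair, SyntheticMatePair):
            left = constituents.get(pair.left_megaread_id)
            right = constituents.get(pair.right_megaread_id)
            if left is None or right is None:
                n_unmapped += 1
                continue
            mapped.append(
                MappedPair(
                    pair_id=(f"{pair.source_long_read}:"
                             f"{pair.left_megaread_id}-"
                             f"{pair.right_megaread_id}"),
                    kind="synthetic",
                    mates=(
                        MappedMate(contig=left[0], interval=left[1],
                                   strand=left[2]),
                        MappedMate(contig=right[0], interval=right[1],
                                   strand=right[2]),
                    ),
                    gap_estimate=pair.gap_estimate,
                )
            )
        else:
            r1, r2 = pair
            if index is None:
                index = KmerIndex({c.id: c.sequence for c in contigs})
            m1 = _place_mate(r1.sequence, index, min_anchor)
            m2 = _place_mate(r2.sequence, index, min_anchor)
            if m1 is None or m2 is None:
                n_unmapped += 1
                continue
            mapped.append(
                MappedPair(pair_id=r1.id.rsplit("/", 1)[0],
                           kind="long_fragment", mates=(m1, m2))
            )
    if n_unmapped:
        log.info("map_pairs: %d pairs unmapped or ambiguous", n_unmapped)
    return mapped


def _junction_side(mate: MappedMate, kind: str, which: str,
                   contig_len: int) -> tuple[str, int]:
    """Which end of the contig faces the junction, and the distance from
    the mate to that end.

    Genomic mates point 3'-ward into the fragment; the left mega-read of a
    synthetic pair points forward along the long read (away from its end)
    while the right one points backward (away from its start)."""
    s, e = mate.interval
    if kind == "long_fragment" or which == "left":
        if mate.strand == "+":
            return "R", contig_len - s if kind == "long_fragment" else \
                contig_len - e
        return "L", e if kind == "long_fragment" else s
    # right mega-read of a synthetic pair
    if mate.strand == "+":
        return "L", s
    return "R", contig_len - e


def build_links(
    mapped: list[MappedPair],
    contigs: list[Contig],
    fragment_mean: float | None = None,
) -> list[Link]:
    """Bucket inter-contig pairs by (contig pair, junction ends) into
    links; the per-hit gap estimate is the fragment mean minus the
    distances to the contig ends (or the synthetic pair's own gap)."""
    lengths = {c.id: len(c.sequence) for c in contigs}
    buckets: dict[tuple, Link] = {}
    for mp in mapped:
        a, b = mp.mates
        if a.contig == b.contig:
            continue  # internal
        ea, da = _junction_side(a, mp.kind, "left", lengths[a.contig])
        eb, db = _junction_side(b, mp.kind, "right", lengths[b.contig])
        if mp.kind == "synthetic":
            gap = mp.gap_estimate - da - db
        else:
            if fragment_mean is None:
                raise ValueError(
                    "fragment_mean required for long-fragment pairs"
                )
            gap = int(fragment_mean - da - db)
        ca, cb = a.contig, b.contig
        if (cb, eb) < (ca, ea):
            ca, ea, cb, eb = cb, eb, ca, ea
        key = (ca, ea, cb, eb)
        link = buckets.get(key)
        if link is None:
            orient = ("F" if ea == "R" else "R") + ("F" if eb == "L" else "R")
            link = Link(contig_a=ca, contig_b=cb, end_a=ea, end_b=eb,
                        orientation=orient)
            buckets[key] = link
        link.gap_estimates.append(int(gap))
        link.sources.append((mp.pair_id, mp.kind))
    return sorted(buckets.values(),
                  key=lambda l: (-l.support, l.contig_a, l.contig_b))


def make_scaffolds(
    contigs: list[Contig],
    links: list[Link],
    min_support: int = 2,
    gap_floor: int = 10,
    gap_consistency_tol: float = 2000.0,
) -> list[Scaffold]:
    """Greedy scaffold graph construction under the >= ``min_support``
    mate rule.

    Links failing the support or gap-consistency thresholds are dropped;
    surviving links are taken in order of support then consistency, each
    contig end is used at most once, and cycles are refused.  Linear paths
    become scaffolds with N-runs of ``max(gap_floor, median gap)``;
    negative median gaps (implied overlap) are floored to ``gap_floor``.
    Singleton contigs become single-contig scaffolds.
    """
    usable = [
        l for l in links
        if l.support >= min_support and l.gap_mad <= gap_consistency_tol
    ]
    used_ends: set[tuple[str, str]] = set()
    parent = {c.id: c.id for c in contigs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen: list[Link] = []
    for link in sorted(usable, key=lambda l: (-l.support, l.gap_mad,
                                              l.contig_a, l.contig_b,
                                              l.orientation)):
        ea = (link.contig_a, link.end_a)
        eb = (link.contig_b, link.end_b)
        if ea in used_ends or eb in used_ends:
            continue
        if find(link.contig_a) == find(link.contig_b):
            log.info("cycle refused at link %s-%s", link.contig_a,
                     link.contig_b)
            continue
        used_ends.update([ea, eb])
        parent[find(link.contig_a)] = find(link.contig_b)
        chosen.append(link)
    by_end = {}
    incident: dict[str, list[Link]] = {}
    for l in chosen:
        by_end[(l.contig_a, l.end_a)] = l
        by_end[(l.contig_b, l.end_b)] = l
        incident.setdefault(l.contig_a, []).append(l)
        incident.setdefault(l.contig_b, []).append(l)
    seq_by_id = {c.id: c.sequence for c in contigs}
    visited: set[str] = set()
    scaffolds: list[Scaffold] = []
    for c in sorted(contigs, key=lambda c: c.id):
        if c.id in visited:
            continue
        edges = incident.get(c.id, [])
        if len(edges) == 2:
            continue  # interior of a path
        visited.add(c.id)
        if not edges:
            scaffolds.append(Scaffold(id="", parts=[(c.id, "+", 0)],
                                      sequence=c.sequence))
            continue
        # orient the first contig so its linked end trails
        link = edges[0]
        my_end = link.end_a if link.contig_a == c.id else link.end_b
        strand = "+" if my_end == "R" else "-"
        parts: list[tuple[str, str, int]] = []
        pieces: list[str] = []
        cur, cur_strand = c.id, strand
        while True:
            exit_end = "R" if cur_strand == "+" else "L"
            nxt = by_end.get((cur, exit_end))
            if nxt is not None and (len(parts) == 0
                                    or nxt is not prev_link):
                gap = max(gap_floor, nxt.gap)
            else:
                nxt, gap = None, 0
            parts.append((cur, cur_strand, gap))
            s = seq_by_id[cur]
            pieces.append(s if cur_strand == "+" else revcomp(s))
            if nxt is None:
                break
            pieces.append("N" * gap)
            prev_link = nxt
            if nxt.contig_a == cur:
                cur = nxt.contig_b
                entered = nxt.end_b
            else:
                cur = nxt.contig_a
                entered = nxt.end_a
            cur_strand = "+" if entered == "L" else "-"
            visited.add(cur)
        scaffolds.append(Scaffold(id="", parts=parts,
                                  sequence="".join(pieces)))
    scaffolds.sort(key=lambda s: (-s.span, s.sequence))
    for i, s in enumerate(scaffolds):
        s.id = f"scf{i:05d}"
    return scaffolds


def write_agp(scaffolds: list[Scaffold], contigs: list[Contig],
              path) -> None:
    """AGP v2.1 description of scaffold parts and gaps (component type W,
    scaffold gaps with paired-ends evidence)."""
    lengths = {c.id: len(c.sequence) for c in contigs}
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for scf in scaffolds:
            pos = 0
            part = 0
            for i, (cid, strand, gap) in enumerate(scf.parts):
                part += 1
                clen = lengths[cid]
                fh.write(
                    f"{scf.id}\t{pos + 1}\t{pos + clen}\t{part}\tW\t"
                    f"{cid}\t1\t{clen}\t{strand}\n"
                )
                pos += clen
                if gap > 0 and i < len(scf.parts) - 1:
                    part += 1
                    fh.write(
                        f"{scf.id}\t{pos + 1}\t{pos + gap}\t{part}\tN\t"
                        f"{gap}\tscaffold\tyes\tpaired-ends\n"
                    )
                    pos += gap


def write_links_tsv(links: list[Link], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_a\tend_a\tcontig_b\tend_b\torientation\t"
                 "support\tgap\tkinds\n")
        for l in links:
            kinds = ",".join(sorted({k for _, k in l.sources}))
            fh.write(f"{l.contig_a}\t{l.end_a}\t{l.contig_b}\t{l.end_b}\t"
                     f"{l.orientation}\t{l.support}\t{l.gap}\t{kinds}\n")
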