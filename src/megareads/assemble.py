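"""Greedy overlap-layout contig assembly of mega-reads and unplaced
super-reads.

Suffix–prefix overlaps are found by k-mer anchoring and verified by
edit-distance alignment; contained sequences are absorbed into their
containers; transitively implied overlaps are reduced; and any junction
still claimed by two or more conflicting candidates is refused, so no
contig crosses a repeat boundary whose resolution is not forced.  The
input sequences are accurate (>99% identity mega-reads and exact
super-reads), so a deterministic greedy layout suffices at desk scale —
no string-graph cleaning is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .util import revcomp

log = logging.getLogger(__name__)

_FUZZ = 25  # positional slack (bp) for transitive-overlap consistency


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


@dataclass
class Overlap:
    """Suffix–prefix overlap in the layout [left oriented][right oriented]."""

    left: str
    left_strand: str
    right: str
    right_strand: str
    suffix_len: int  # bases of the oriented left sequence in the overlap
    prefix_len: int  # bases of the oriented right sequence consumed
    identity: float
    support: int = 1

    @property
    def tail(self) -> tuple[str, str]:
        return self.left, "R" if self.left_strand == "+" else "L"

    @property
    def head(self) -> tuple[str, str]:
        return self.right, "L" if self.right_strand == "+" else "R"

    def key(self):
        return tuple(sorted([self.tail, self.head]))

    def view(self, node: str):
        """Present the overlap with *node* as the left element."""
        if node == self.left:
            return (self.left, self.left_strand, self.right,
                    self.right_strand, self.suffix_len, self.prefix_len)
        return (self.right, _flip(self.right_strand), self.left,
                _flip(self.left_strand), self.prefix_len, self.suffix_len)


@dataclass
class Containment:
    inner: str
    outer: str
    strand: str  # inner relative to outer forward
    location: tuple[int, int]  # on outer forward
    identity: float


@dataclass
class Contig:
    id: str
    sequence: str
    constituents: list[tuple[str, tuple[int, int], str]] = field(
        default_factory=list
    )


def _as_dict(sequences) -> dict[str, str]:
    if isinstance(sequences, dict):
        return dict(sequences)
    return {sid: seq for sid, seq in sequences}


def compute_overlaps(
    sequences, min_overlap: int = 200, max_error: float = 0.02
) -> tuple[list[Overlap], list[Containment]]:
    """All suffix–prefix overlaps >= ``min_overlap`` at identity
    >= 1 - ``max_error``, found by k-mer anchoring then edit-distance
    verification; containments are reported separately."""
    seqs = _as_dict(sequences)
    if min_overlap < 1:
        raise ValueError("min_overlap must be positive")
    k = max(3, min(15, min_overlap))
    oriented = {}
    for sid, seq in seqs.items():
        oriented[(sid, "+")] = seq
        oriented[(sid, "-")] = revcomp(seq)
    index: dict[str, list[tuple[str, str, int]]] = {}
    for (sid, strand), seq in oriented.items():
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append(
                (sid, strand, pos)
            )
    # candidate diagonals per (a forward, b oriented); anchors are sampled
    # every few bases, which keeps enumeration cheap without losing any
    # overlap >= min_overlap
    stride = 1 if min_overlap < 60 else 4
    cands: dict[tuple[str, str, str], dict[int, int]] = {}
    for a, seq in seqs.items():
        for pa in range(0, len(seq) - k + 1, stride):
            for b, sb, pb in index.get(seq[pa : pa + k], ()):
                if b == a:
                    continue
                diags = cands.setdefault((a, b, sb), {})
                d = pa - pb
                diags[d] = diags.get(d, 0) + 1
    best_overlaps: dict[tuple, Overlap] = {}
    best_containments: dict[str, Containment] = {}
    for (a, b, sb), diags in sorted(cands.items()):
        top = sorted(diags.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
        for d, _count in top:
            if d >= 0:
                left, lstr, right, rstr, off = a, "+", b, sb, d
            else:
                left, lstr, right, rstr, off = b, sb, a, "+", -d
            lseq = oriented[(left, lstr)]
            rseq = oriented[(right, rstr)]
            ov = len(lseq) - off
            if ov < min_overlap:
                continue
            # near-full coverage of the right sequence is containment,
            # not extension; the fuzz only applies to sequences long
            # enough for it to be meaningful
            fuzz = _FUZZ if len(rseq) >= 4 * _FUZZ else 0
            if ov >= len(rseq) - fuzz:
                _try_containment(right, rstr, left, lstr, seqs, max_error,
                                 best_containments)
                continue
            query = lseq[off:]
            res = edlib.align(query, rseq, mode="SHW", task="locations")
            dist = res["editDistance"]
            if dist > max_error * len(query):
                continue
            prefix_len = res["locations"][0][1] + 1
            overlap = Overlap(
                left=left, left_strand=lstr, right=right, right_strand=rstr,
                suffix_len=ov, prefix_len=prefix_len,
                identity=1.0 - dist / len(query),
            )
            prev = best_overlaps.get(overlap.key())
            if prev is None or (overlap.identity, overlap.suffix_len) > (
                prev.identity, prev.suffix_len
            ):
                best_overlaps[overlap.key()] = overlap
    overlaps = sorted(
        best_overlaps.values(),
        key=lambda o: (-o.identity, -o.suffix_len, o.left, o.right),
    )
    # mutual containment (identical-length sequences): keep one record,
    # with the lexicographically smaller id as the container
    for inner in sorted(best_containments):
        c = best_containments.get(inner)
        if (c is not None and c.outer in best_containments
                and best_containments[c.outer].outer == inner
                and inner < c.outer):
            del best_containments[inner]
    return overlaps, sorted(
        best_containments.values(), key=lambda c: (c.inner, c.outer)
    )


def _try_containment(inner, inner_str, outer, outer_str, seqs, max_error,
                     out: dict):
    """Verify containment of *inner* in *outer*, expressed on the outer's
    forward strand."""
    rel = "+" if inner_str == outer_str else "-"
    q = seqs[inner] if rel == "+" else revcomp(seqs[inner])
    res = edlib.align(q, seqs[outer], mode="HW", task="locations")
    dist = res["editDistance"]
    if dist > max_error * len(q):
        return
    loc = res["locations"][0]
    cont = Containment(
        inner=inner, outer=outer, strand=rel,
        location=(loc[0], loc[1] + 1),
        identity=1.0 - dist / len(q),
    )
    prev = out.get(inner)
    if prev is None or (cont.identity, prev.outer) > (prev.identity,
                                                      cont.outer):
        out[inner] = cont


def _resolve_containments(
    containments: list[Containment], seqs: dict[str, str]
) -> dict[str, Containment]:
    """Assign each contained sequence to an ultimate (non-contained)
    container, composing locations; mutual containments (identical
    sequences) keep one representative."""
    by_inner: dict[str, Containment] = {}
    for c in sorted(containments, key=lambda c: (-c.identity, c.inner,
                                                 c.outer)):
        if c.inner in by_inner:
            continue
        # refuse cycles: the proposed outer must not resolve back to inner
        seen = {c.inner}
        outer = c.outer
        ok = True
        while outer in by_inner:
            outer = by_inner[outer].outer
            if outer in seen:
                ok = False
                break
            seen.add(outer)
        if ok:
            by_inner[c.inner] = c
    resolved: dict[str, Containment] = {}
    for inner, c in by_inner.items():
        cur = c
        while cur.outer in by_inner:
            nxt = by_inner[cur.outer]
            outer_len = len(seqs[cur.outer])
            s, e = cur.location
            if nxt.strand == "+":
                loc = (nxt.location[0] + s, nxt.location[0] + e)
                strand = cur.strand
            else:
                loc = (nxt.location[0] + outer_len - e,
                       nxt.location[0] + outer_len - s)
                strand = _flip(cur.strand)
            loc = (max(loc[0], 0), min(loc[1], len(seqs[nxt.outer])))
            cur = Containment(inner=inner, outer=nxt.outer, strand=strand,
                              location=loc, identity=cur.identity)
        resolved[inner] = cur
    return resolved


def _transitive_reduction(
    overlaps: list[Overlap], lengths: dict[str, int]
) -> list[Overlap]:
    """Remove overlaps implied by a two-step path, crediting the surviving
    pair's support."""
    by_key = {o.key(): o for o in overlaps}
    by_tail: dict[tuple[str, str], list[Overlap]] = {}
    for o in overlaps:
        by_tail.setdefault(o.tail, []).append(o)
        by_tail.setdefault(o.head, []).append(o)
    # single marking pass: every edge (marked or not) may serve as a
    # witness, so reductions cascade independent of processing order
    removed: set = set()
    for endpoint, edges in sorted(by_tail.items()):
        node = endpoint[0]
        views = []
        for o in edges:
            v = o.view(node)
            # only edges leaving through this endpoint
            t_end = "R" if v[1] == "+" else "L"
            if (node, t_end) == endpoint:
                views.append((o, v))
        views.sort(key=lambda ov: -ov[1][4])  # by overlap length desc
        for i, (e1, v1) in enumerate(views):
            _, _, bid, bstr, ov1, _ = v1
            for e2, v2 in views[i + 1:]:
                if e2.key() in removed:
                    continue
                _, _, cid, cstr, ov2, _ = v2
                if cid == bid:
                    continue
                expected = lengths[bid] - ov1 + ov2
                if expected < 1:
                    continue
                far = (bid, "R" if bstr == "+" else "L")
                for f in by_tail.get(far, []):
                    if f is e2 or f is e1:
                        continue
                    vf = f.view(bid)
                    f_tail_end = "R" if vf[1] == "+" else "L"
                    if (bid, f_tail_end) != far or vf[1] != bstr:
                        continue
                    if vf[2] != cid or vf[3] != cstr:
                        continue
                    if abs(vf[4] - expected) <= _FUZZ:
                        removed.add(e2.key())
                        e1.support += 1
                        f.support += 1
                        break
    return [o for o in overlaps if o.key() not in removed]


def greedy_merge(
    sequences,
    overlaps: list[Overlap],
    containments: list[Containment] | None = None,
    min_support: int = 1,
) -> list[Contig]:
    """Merge along unambiguous overlaps into contigs.

    After containment absorption and transitive reduction, any sequence
    end claimed by two or more candidate overlaps is a junction and all
    its joins are refused; circular components are broken at their
    lowest-identity overlap.  With ``min_support > 1`` a join must be
    confirmed by at least that many independent overlap witnesses.
    """
    seqs = _as_dict(sequences)
    containments = containments or []
    resolved = _resolve_containments(containments, seqs)
    nodes = [sid for sid in seqs if sid not in resolved]
    lengths = {sid: len(seqs[sid]) for sid in seqs}
    live = [
        o for o in overlaps
        if o.left not in resolved and o.right not in resolved
    ]
    live = _transitive_reduction(live, lengths)
    # refuse joins at ambiguous junctions
    degree: dict[tuple[str, str], int] = {}
    for o in live:
        degree[o.tail] = degree.get(o.tail, 0) + 1
        degree[o.head] = degree.get(o.head, 0) + 1
    ambiguous = {ep for ep, n in degree.items() if n > 1}
    refused = [o for o in live
               if o.tail in ambiguous or o.head in ambiguous]
    if refused:
        log.info("refused %d joins at %d ambiguous junctions",
                 len(refused), len(ambiguous))
    live = [o for o in live if o not in refused]
    if min_support > 1:
        live = [o for o in live if o.support >= min_support]
    # break cycles: components where every endpoint is used
    live = _break_cycles(live, nodes)
    by_end = {}
    for o in live:
        by_end[o.tail] = o
        by_end[o.head] = o
    contigs = _walk_paths(nodes, live, by_end, seqs)
    _attach_contained(contigs, resolved, seqs)
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    for i, c in enumerate(contigs):
        c.id = f"ctg{i:05d}"
    return contigs


def _break_cycles(live: list[Overlap], nodes: list[str]) -> list[Overlap]:
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kept = []
    for o in sorted(live, key=lambda o: (-o.identity, -o.suffix_len,
                                         o.left, o.right)):
        ra, rb = find(o.left), find(o.right)
        if ra == rb:
            log.info("cycle broken at overlap %s-%s (identity %.3f)",
                     o.left, o.right, o.identity)
            continue
        parent[ra] = rb
        kept.append(o)
    return kept


def _walk_paths(nodes, live, by_end, seqs) -> list[Contig]:
    incident: dict[str, list[Overlap]] = {}
    for o in live:
        incident.setdefault(o.left, []).append(o)
        incident.setdefault(o.right, []).append(o)
    visited: set[str] = set()
    contigs: list[Contig] = []
    for start in sorted(nodes):
        if start in visited:
            continue
        edges = incident.get(start, [])
        if not edges:
            visited.add(start)
            contigs.append(
                Contig(id="", sequence=seqs[start],
                       constituents=[(start, (0, len(seqs[start])), "+")])
            )
            continue
        if len(edges) == 2:
            continue  # interior node; reached from a path end
        # path endpoint: walk
        visited.add(start)
        o = edges[0]
        _, lstr, *_ = o.view(start)
        strand = lstr
        seq = seqs[start] if strand == "+" else revcomp(seqs[start])
        contig_seq = seq
        constituents = [(start, (0, len(seq)), strand)]
        cur, cur_strand, edge = start, strand, o
        while edge is not None:
            _, lstr, rid, rstr, _suf, pre = edge.view(cur)
            rseq = seqs[rid] if rstr == "+" else revcomp(seqs[rid])
            offset = len(contig_seq) - pre
            contig_seq += rseq[pre:]
            constituents.append((rid, (offset, offset + len(rseq)), rstr))
            visited.add(rid)
            cur, cur_strand = rid, rstr
            exit_end = (cur, "R" if cur_strand == "+" else "L")
            nxt = by_end.get(exit_end)
            edge = None
            if nxt is not None and nxt.key() != o.key():
                # only continue through the end we did not enter by
                v = nxt.view(cur)
                if v[1] == cur_strand:
                    edge = nxt
                    o = nxt
        contigs.append(Contig(id="", sequence=contig_seq,
                              constituents=constituents))
    # any untouched interior nodes (isolated cycles already broken) emit
    for n in sorted(nodes):
        if n not in visited:
            visited.add(n)
            contigs.append(
                Contig(id="", sequence=seqs[n],
                       constituents=[(n, (0, len(seqs[n])), "+")])
            )
    return contigs


def _attach_contained(contigs, resolved, seqs):
    pos = {}
    for c in contigs:
        for sid, interval, strand in c.constituents:
            pos[sid] = (c, interval, strand)
    for inner, cont in sorted(resolved.items()):
        if cont.outer not in pos:
            continue
        contig, (os_, oe_), ostr = pos[cont.outer]
        outer_len = len(seqs[cont.outer])
        s, e = cont.location
        if ostr == "+":
            interval = (os_ + s, os_ + e)
            strand = cont.strand
        else:
            interval = (os_ + outer_len - e, os_ + outer_len - s)
            strand = _flip(cont.strand)
        interval = (max(0, interval[0]), min(len(contig.sequence),
                                             interval[1]))
        contig.constituents.append((inner, interval, strand))


def assemble(
    sequences,
    min_overlap: int = 200,
    max_error: float = 0.02,
    min_support: int = 1,
) -> list[Contig]:
    """Convenience wrapper: overlaps then greedy merge."""
    overlaps, containments = compute_overlaps(sequences, min_overlap,
                                              max_error)
    return greedy_merge(sequences, overlaps, containments, min_support)
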