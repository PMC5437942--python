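"""Seed-and-chain machinery shared by the tiling, scaffolding and
evaluation stages.

A :class:`KmerIndex` stores every occurrence of every 15-mer of a set of
target sequences under its canonical form.  Queries collect exact 15-mer
hits and group them per (target, relative strand); within a group, hits are
chained into maximal collinear runs whose diagonal (query position minus
target position) drifts by at most a tolerance fraction of the distance
covered — the drift budget absorbs the indel-dominated error of noisy long
reads.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .util import canonical, iter_kmers

#: Matching word size used throughout the pipeline (the 15-mer database).
K_MATCH = 15

#: Hard cap on hits per (target, strand) group, guarding against
#: low-complexity blowups on adversarial input.
_MAX_GROUP_HITS = 4000

#: Hit sets larger than this are subsampled before the quadratic
#: chaining DP; subsampling a dense collinear run loses no locus.
_MAX_DP_HITS = 500


class KmerIndex:
    """Index of all k-mer occurrences of a set of named sequences.

    Entries map a canonical k-mer to a list of ``(seq_id, offset, strand)``
    where *strand* is '+' if the k-mer at *offset* equals the canonical
    form and '-' if it equals its reverse complement.
    """

    def __init__(self, seqs: dict[str, str], k: int = K_MATCH):
        self.k = k
        self.lengths = {sid: len(s) for sid, s in seqs.items()}
        self.n_skipped = 0
        entries: dict[str, list[tuple[str, int, str]]] = {}
        for sid, seq in seqs.items():
            if len(seq) < k:
                self.n_skipped += 1
                continue
            for off, kmer in iter_kmers(seq, k):
                c = canonical(kmer)
                entries.setdefault(c, []).append(
                    (sid, off, "+" if kmer == c else "-")
                )
        self.entries = entries

    def n_positions(self) -> int:
        return sum(len(v) for v in self.entries.values())


def collect_hits(
    query: str, index: KmerIndex
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Exact k-mer hits of *query* against the index.

    Returns per ``(target_id, relative_strand)`` a list of ``(qpos, tpos)``
    where *tpos* is expressed in the coordinates of the target oriented to
    the query: for relative strand '-' the offset is mirrored so that
    chains are increasing in both coordinates.
    """
    k = index.k
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for qpos, kmer in iter_kmers(query, k):
        c = canonical(kmer)
        entry = index.entries.get(c)
        if not entry:
            continue
        qstrand = "+" if kmer == c else "-"
        for sid, off, tstrand in entry:
            rel = "+" if qstrand == tstrand else "-"
            t = off if rel == "+" else index.lengths[sid] - k - off
            bucket = groups.setdefault((sid, rel), [])
            if len(bucket) < _MAX_GROUP_HITS:
                bucket.append((qpos, t))
    return groups


@dataclass
class Chain:
    """A collinear run of k-mer hits of one query against one target."""

    hits: list[tuple[int, int]]  # (qpos, tpos), strictly increasing in both
    strand: str = "+"
    weight: int = 0  # estimated hit count (corrects for subsampling)

    def __post_init__(self):
        if not self.weight:
            self.weight = len(self.hits)

    @property
    def n_hits(self) -> int:
        return self.weight

    @property
    def query_interval(self) -> tuple[int, int]:
        return self.hits[0][0], self.hits[-1][0] + K_MATCH

    @property
    def target_interval(self) -> tuple[int, int]:
        return self.hits[0][1], self.hits[-1][1] + K_MATCH

    @property
    def diagonal(self) -> int:
        return self.hits[0][0] - self.hits[0][1]

    def map_query_pos(self, qpos: int, t_len: int) -> int:
        """Map a query position to target coordinates by offsetting from
        the nearest chain hit (clamped to the target)."""
        qs = [q for q, _ in self.hits]
        i = bisect.bisect_left(qs, qpos)
        if i == len(qs):
            i -= 1
        elif i > 0 and qpos - qs[i - 1] < qs[i] - qpos:
            i -= 1
        q, t = self.hits[i]
        return max(0, min(t_len, t + (qpos - q)))


def best_chain(
    hits: list[tuple[int, int]], tolerance: float, slack: int = 4
) -> list[tuple[int, int]]:
    """Longest collinear chain (most hits) under the diagonal-drift rule.

    Consecutive chain hits must increase strictly in both coordinates and
    their diagonals may differ by at most ``tolerance * dq + slack``.
    Ties are broken toward the chain whose hits are lexicographically
    smallest, which makes the result deterministic.
    """
    if not hits:
        return []
    hits = sorted(set(hits))
    n = len(hits)
    score = [1] * n
    parent = [-1] * n
    for i in range(n):
        qi, ti = hits[i]
        di = qi - ti
        best = 1
        arg = -1
        for j in range(i):
            qj, tj = hits[j]
            if qj >= qi or tj >= ti:
                continue
            if abs(di - (qj - tj)) > tolerance * (qi - qj) + slack:
                continue
            cand = score[j] + 1
            if cand > best:
                best, arg = cand, j
        score[i] = best
        parent[i] = arg
    end = max(range(n), key=lambda i: (score[i], -hits[i][0], -hits[i][1]))
    chain = []
    while end != -1:
        chain.append(hits[end])
        end = parent[end]
    chain.reverse()
    return chain


def extract_chains(
    hits: list[tuple[int, int]],
    tolerance: float,
    min_hits: int,
    max_loci: int = 5,
) -> list[Chain]:
    """Iteratively peel off the best chain, masking its footprint, until no
    chain of ``min_hits`` hits remains.  Each surviving chain corresponds
    to one placement locus of the target on the query."""
    remaining = sorted(set(hits))
    chains: list[Chain] = []
    while remaining and len(chains) < max_loci:
        # the chaining DP is quadratic; dense hit sets (near-exact
        # matches) are subsampled and the chain weight rescaled
        if len(remaining) > _MAX_DP_HITS:
            step = -(-len(remaining) // _MAX_DP_HITS)
            sample = remaining[::step]
            if sample[-1] != remaining[-1]:
                sample.append(remaining[-1])
            factor = len(remaining) / len(sample)
        else:
            sample, factor = remaining, 1.0
        chain = best_chain(sample, tolerance)
        if len(chain) < min_hits:
            break
        chains.append(Chain(hits=chain, weight=round(len(chain) * factor)))
        q0, q1 = chain[0][0], chain[-1][0] + K_MATCH
        t0, t1 = chain[0][1], chain[-1][1] + K_MATCH
        remaining = [
            (q, t)
            for q, t in remaining
            if not (q0 <= q < q1) and not (t0 <= t < t1)
        ]
    return chains
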