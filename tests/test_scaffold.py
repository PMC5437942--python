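"""Scaffolding: mate mapping, link building, the minimum-support rule
and its chimera resistance, and contig conservation."""

import numpy as np
import pytest

import megareads as mr
from megareads.assemble import Contig
from megareads.megaread import SyntheticMatePair
from megareads.scaffold import (MappedMate, MappedPair, build_links,
                                make_scaffolds, map_pairs)
from megareads.simulate import ERROR_FREE
from megareads.util import revcomp


def _rand(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _contig(cid, seq, mega_ids=()):
    cons = [(cid, (0, len(seq)), "+")]
    for mid, interval, strand in mega_ids:
        cons.append((mid, interval, strand))
    return Contig(id=cid, sequence=seq, constituents=cons)


def test_same_contig_pair_is_internal():
    genome = _rand(5000, 1)
    c = _contig("c0", genome)
    r1 = mr.SimulatedRead("p0/1", genome[100:250], (100, 250, "+"),
                          mate_id="p0/2", fragment_length=2000)
    r2 = mr.SimulatedRead("p0/2", revcomp(genome[1950:2100]),
                          (1950, 2100, "-"), mate_id="p0/1",
                          fragment_length=2000)
    mapped = map_pairs([(r1, r2)], [c])
    assert len(mapped) == 1
    links = build_links(mapped, [c], fragment_mean=2000)
    assert links == []


def test_ambiguous_repeat_mate_is_dropped():
    block = _rand(3000, 2)
    c1 = _contig("c1", _rand(2000, 3) + block)
    c2 = _contig("c2", block + _rand(2000, 4))
    inside = block[1000:1150]
    r1 = mr.SimulatedRead("p0/1", inside, (0, 150, "+"), mate_id="p0/2")
    r2 = mr.SimulatedRead("p0/2", c1.sequence[100:250], (100, 250, "+"),
                          mate_id="p0/1")
    mapped = map_pairs([(r1, r2)], [c1, c2])
    assert mapped == []  # the repeat mate cannot be placed uniquely


def test_adjacent_contigs_joined_with_estimated_gap():
    """Paired reads from long fragments spanning a 1-kb break join the
    two contigs; the resulting scaffold improves N50 and its gap run
    approximates the true gap."""
    genome = mr.generate_genome(30_000, [], seed=5)
    c1 = _contig("c1", genome.sequence[0:14_000])
    c2 = _contig("c2", genome.sequence[15_000:30_000])
    reads = mr.simulate_short_reads(genome, 5, 100, (4000, 5000),
                                    ERROR_FREE, seed=6)
    pairs = [(reads[i], reads[i + 1]) for i in range(0, len(reads), 2)]
    mapped = map_pairs(pairs, [c1, c2])
    links = build_links(mapped, [c1, c2], fragment_mean=4500)
    inter = [l for l in links if {l.contig_a, l.contig_b} == {"c1", "c2"}]
    assert len(inter) == 1
    link = inter[0]
    assert link.support >= 2
    assert abs(link.gap - 1000) < 800
    scaffolds = make_scaffolds([c1, c2], links, min_support=2)
    assert len(scaffolds) == 1
    scf = scaffolds[0]
    assert [p[0] for p in scf.parts] in (["c1", "c2"], ["c2", "c1"])
    n_gap = scf.sequence.count("N")
    assert n_gap == max(10, link.gap)
    assert mr.n50([s.span for s in scaffolds]) > \
        mr.n50([len(c1.sequence), len(c2.sequence)])


def _synthetic(lid, rid, gap, src="lr0"):
    return SyntheticMatePair(left_megaread_id=lid, right_megaread_id=rid,
                             gap_estimate=gap, source_long_read=src)


def _two_contig_setup():
    c1 = _contig("c1", _rand(4000, 7),
                 [("m1", (3000, 4000), "+")])
    c2 = _contig("c2", _rand(4000, 8),
                 [("m2", (0, 1000), "+")])
    return c1, c2


def test_confirmed_synthetic_pairs_create_one_link_with_support():
    c1, c2 = _two_contig_setup()
    pairs = [_synthetic("m1", "m2", 500, "lr0"),
             _synthetic("m1", "m2", 520, "lr1")]
    mapped = map_pairs(pairs, [c1, c2])
    links = build_links(mapped, [c1, c2])
    assert len(links) == 1
    assert links[0].support == 2
    assert links[0].gap == 510


def test_lone_synthetic_pair_never_joins_at_default_support():
    c1, c2 = _two_contig_setup()
    mapped = map_pairs([_synthetic("m1", "m2", 500)], [c1, c2])
    links = build_links(mapped, [c1, c2])
    assert links[0].support == 1
    scaffolds = make_scaffolds([c1, c2], links)  # min_support=2 default
    assert len(scaffolds) == 2


def test_chimeric_join_appears_only_at_min_support_one():
    """A chimeric long read yields a lone synthetic pair between
    unrelated loci: the false join must appear at min_support=1 but
    never at the default min_support=2."""
    c1, c2 = _two_contig_setup()
    c2.constituents.append(("m2b", (3000, 4000), "+"))
    c3 = _contig("c3", _rand(4000, 9), [("m3", (0, 1000), "+")])
    # two mates confirm c1-c2; the chimera links c2's far end to the
    # unrelated c3 once
    pairs = [
        _synthetic("m1", "m2", 500, "lr0"),
        _synthetic("m1", "m2", 450, "lr1"),
        _synthetic("m2b", "m3", 300, "lr_chimera"),
    ]
    contigs = [c1, c2, c3]
    links = build_links(map_pairs(pairs, contigs), contigs)
    strict = make_scaffolds(contigs, links, min_support=2)
    joined_strict = {
        frozenset(p[0] for p in s.parts) for s in strict if len(s.parts) > 1
    }
    assert joined_strict == {frozenset({"c1", "c2"})}
    loose = make_scaffolds(contigs, links, min_support=1)
    parts = {p[0] for s in loose for p in s.parts if len(s.parts) > 1}
    assert "c3" in parts  # the false join now appears


def test_gap_estimate_is_median_of_hits():
    c1, c2 = _two_contig_setup()
    gaps = [100, 400, 200, 900, 300]
    pairs = [_synthetic("m1", "m2", g, f"lr{i}")
             for i, g in enumerate(gaps)]
    links = build_links(map_pairs(pairs, [c1, c2]), [c1, c2])
    assert links[0].gap == sorted(gaps)[2]


def test_no_usable_links_leaves_contigs_unchanged():
    c1, c2 = _two_contig_setup()
    scaffolds = make_scaffolds([c1, c2], [])
    assert len(scaffolds) == 2
    assert sorted(s.sequence for s in scaffolds) == \
        sorted([c1.sequence, c2.sequence])


def test_every_contig_in_exactly_one_scaffold():
    c1, c2 = _two_contig_setup()
    c3 = _contig("c3", _rand(3000, 10))
    pairs = [_synthetic("m1", "m2", 500, "lr0"),
             _synthetic("m1", "m2", 520, "lr1")]
    links = build_links(map_pairs(pairs, [c1, c2, c3]), [c1, c2, c3])
    scaffolds = make_scaffolds([c1, c2, c3], links)
    placed = [p[0] for s in scaffolds for p in s.parts]
    assert sorted(placed) == ["c1", "c2", "c3"]


def test_multi_contig_joins_are_backed_by_support_two_links():
    c1, c2 = _two_contig_setup()
    pairs = [_synthetic("m1", "m2", 500, "lr0"),
             _synthetic("m1", "m2", 520, "lr1")]
    links = build_links(map_pairs(pairs, [c1, c2]), [c1, c2])
    scaffolds = make_scaffolds([c1, c2], links)
    by_pair = {frozenset((l.contig_a, l.contig_b)): l for l in links}
    for s in scaffolds:
        for (a, _, _), (b, _, _) in zip(s.parts, s.parts[1:]):
            assert by_pair[frozenset((a, b))].support >= 2


def test_scaffold_span_accounts_for_gaps():
    c1, c2 = _two_contig_setup()
    pairs = [_synthetic("m1", "m2", 500, "lr0"),
             _synthetic("m1", "m2", 500, "lr1")]
    links = build_links(map_pairs(pairs, [c1, c2]), [c1, c2])
    (scf,) = make_scaffolds([c1, c2], links)
    total_contig = len(c1.sequence) + len(c2.sequence)
    gaps = sum(g for _, _, g in scf.parts)
    assert scf.span == total_contig + gaps
    assert scf.sequence.count("N") == gaps
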