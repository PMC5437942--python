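"""Mega-read construction: 15-mer index, placement chaining, consistency
filtering (vs an exhaustive oracle), splicing and provenance."""

import itertools

import numpy as np
import pytest

import megareads as mr
from megareads.chaining import Chain
from megareads.megaread import (Placement, _compatible, build_match_index,
                                filter_inconsistent, find_placements,
                                merge_to_mega_reads)
from megareads.simulate import ERROR_FREE, LONG_READ_PROFILE, SimulatedRead
from megareads.superread import SuperRead
from megareads.util import revcomp


def _sr(sid, seq):
    return SuperRead(id=sid, sequence=seq, n_constituent_reads=1)


def _lr(seq, rid="lr0"):
    return SimulatedRead(id=rid, sequence=seq,
                         true_origin=(0, len(seq), "+"))


def _rand(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestMatchIndex:
    def test_single_15mer_super_read(self):
        idx = build_match_index([_sr("a", "ACGTACGTACGTACG")])
        assert idx.n_positions() == 1

    def test_tandem_repeat_positions(self):
        idx = build_match_index([_sr("a", "ACGT" * 10)])
        assert idx.n_positions() == 26  # 40 - 15 + 1

    def test_reverse_complement_lookup_symmetry(self):
        seq = _rand(100, 71)
        idx = build_match_index([_sr("a", seq)])
        from megareads.chaining import collect_hits

        fwd = collect_hits(seq, idx)
        rev = collect_hits(revcomp(seq), idx)
        assert sum(len(h) for h in fwd.values()) == \
            sum(len(h) for h in rev.values()) == 86

    def test_short_super_reads_skipped(self):
        idx = build_match_index([_sr("a", "ACGTACGTACGTACG"),
                                 _sr("b", "ACGT")])
        assert idx.n_skipped == 1
        with pytest.raises(ValueError):
            build_match_index([])


class TestFindPlacements:
    def test_identical_read_and_super_read(self):
        seq = _rand(300, 72)
        idx = build_match_index([_sr("a", seq)])
        pls = find_placements(_lr(seq), idx)
        assert len(pls) == 1
        p = pls[0]
        assert p.long_read_interval == (0, 300)
        assert p.superread_interval == (0, 300)
        assert p.n_hits == 300 - 14
        assert p.strand == "+"

    def test_unrelated_super_read_never_places(self):
        idx = build_match_index([_sr("a", _rand(1000, 73))])
        pls = find_placements(_lr(_rand(1000, 74)), idx, min_hits=3)
        assert pls == []

    def test_noisy_read_placements_reflect_true_layout(self):
        genome = _rand(20_000, 75)
        supers = [_sr("s0", genome[0:8000]), _sr("s1", genome[7000:15000]),
                  _sr("s2", genome[14000:20000])]
        rng = np.random.default_rng(76)
        from megareads.simulate import apply_errors

        read_seq = apply_errors(genome[2000:18000], LONG_READ_PROFILE, rng)
        idx = build_match_index(supers)
        pls = find_placements(_lr(read_seq), idx)
        kept, _ = filter_inconsistent(pls, {s.id: s for s in supers})
        assert [p.superread_id for p in kept] == ["s0", "s1", "s2"]
        for p, q in zip(kept, kept[1:]):
            overlap = p.long_read_interval[1] - q.long_read_interval[0]
            assert overlap > 0  # true overlaps are 1000 bp

    def test_raising_min_hits_never_adds_placements(self):
        genome = _rand(5000, 77)
        rng = np.random.default_rng(78)
        from megareads.simulate import apply_errors

        read_seq = apply_errors(genome[500:4500], LONG_READ_PROFILE, rng)
        idx = build_match_index(
            [_sr(f"s{i}", genome[i * 1000:(i + 1) * 1000 + 200])
             for i in range(4)]
        )
        counts = [
            len(find_placements(_lr(read_seq), idx, min_hits=h))
            for h in (3, 6, 12, 24)
        ]
        assert counts == sorted(counts, reverse=True)


def _fake_placement(start, end, hits, sid):
    chain = Chain(hits=[(start, 0), (end - 15, end - 15 - start)],
                  weight=hits)
    return Placement(
        superread_id=sid, long_read_interval=(start, end),
        superread_interval=(0, end - start), strand="+", n_hits=hits,
        diagonal=start, chain=chain, superread_length=end - start,
    )


def _oracle_max_weight(placements):
    """Exhaustive maximum-weight consistent subset: every consecutive
    pair (in canonical order) must be compatible; ties prefer the
    lexicographically smallest index tuple."""
    order = sorted(
        placements,
        key=lambda p: (p.long_read_interval, p.superread_id, p.strand),
    )
    best = (0, ())
    for r in range(1, len(order) + 1):
        for combo in itertools.combinations(range(len(order)), r):
            sub = [order[i] for i in combo]
            if all(_compatible(a, b, None, 0.95)
                   for a, b in zip(sub, sub[1:])):
                w = sum(p.n_hits for p in sub)
                if w > best[0] or (w == best[0] and combo < best[1]):
                    best = (w, combo)
    return [order[i] for i in best[1]]


class TestFilterInconsistent:
    def test_disjoint_placements_all_kept(self):
        pls = [_fake_placement(0, 100, 10, "a"),
               _fake_placement(200, 300, 5, "b")]
        kept, dropped = filter_inconsistent(pls)
        assert len(kept) == 2 and dropped == []

    def test_duplicate_span_keeps_smaller_id(self):
        pls = [_fake_placement(0, 100, 10, "b"),
               _fake_placement(0, 100, 10, "a")]
        kept, dropped = filter_inconsistent(pls)
        assert [p.superread_id for p in kept] == ["a"]
        assert [p.superread_id for p in dropped] == ["b"]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(900 + seed)
        n = int(rng.integers(2, 9))
        pls = []
        for i in range(n):
            start = int(rng.integers(0, 500))
            end = start + int(rng.integers(30, 400))
            pls.append(_fake_placement(start, end,
                                       int(rng.integers(1, 40)),
                                       f"s{i}"))
        kept, _ = filter_inconsistent(pls)
        oracle = _oracle_max_weight(pls)
        assert [(p.long_read_interval, p.superread_id) for p in kept] == \
            [(p.long_read_interval, p.superread_id) for p in oracle]


class TestMerge:
    def test_single_placement_yields_super_read_sequence(self):
        seq = _rand(400, 80)
        supers = {"a": _sr("a", seq)}
        idx = build_match_index(list(supers.values()))
        lr = _lr(seq)
        pls = find_placements(lr, idx)
        megas, pairs = merge_to_mega_reads(lr, pls, supers)
        assert len(megas) == 1 and pairs == []
        assert megas[0].sequence == seq

    def test_splice_recovers_exact_concatenation_despite_insertions(self):
        genome = _rand(60, 81)
        supers = {"a": _sr("a", genome[0:40]), "b": _sr("b", genome[20:60])}
        # two bases inserted inside the 20-bp overlap region
        read_seq = genome[:30] + "AC" + genome[30:]
        idx = build_match_index(list(supers.values()))
        lr = _lr(read_seq)
        pls = find_placements(lr, idx, min_hits=3)
        kept, _ = filter_inconsistent(pls, supers)
        megas, pairs = merge_to_mega_reads(lr, kept, supers)
        assert len(megas) == 1 and pairs == []
        assert megas[0].sequence == genome

    def test_coverage_hole_yields_two_megas_and_synthetic_pair(self):
        genome = _rand(2000, 82)
        supers = {"a": _sr("a", genome[0:700]),
                  "b": _sr("b", genome[1200:2000])}
        idx = build_match_index(list(supers.values()))
        lr = _lr(genome)
        pls = find_placements(lr, idx)
        kept, _ = filter_inconsistent(pls, supers)
        megas, pairs = merge_to_mega_reads(lr, kept, supers)
        assert len(megas) == 2 and len(pairs) == 1
        assert pairs[0].gap_estimate == 500
        assert megas[0].sequence == genome[0:700]
        assert megas[1].sequence == genome[1200:2000]

    def test_mega_bases_never_copied_from_long_read(self):
        """Marked alphabet: long-read-only bases are 'X'; since mega-read
        sequence is spliced purely from super-reads, no X may appear."""
        genome = _rand(3000, 83)
        supers = {"a": _sr("a", genome[0:1600]),
                  "b": _sr("b", genome[1400:3000])}
        read = list(genome)
        for pos in range(25, 3000, 50):
            read.insert(pos, "X")
        lr = _lr("".join(read))
        idx = build_match_index(list(supers.values()))
        pls = find_placements(lr, idx)
        kept, _ = filter_inconsistent(pls, supers)
        megas, _ = merge_to_mega_reads(lr, kept, supers)
        assert megas
        joined = "".join(m.sequence for m in megas)
        assert "X" not in joined
        assert sum(len(m.sequence) for m in megas) > 2500


class TestRunMegaReads:
    def test_error_free_megas_are_exact_genome_substrings(
        self, error_free_assembly
    ):
        genome = error_free_assembly["genome"].sequence
        for m in error_free_assembly["run"].mega_reads:
            assert (m.sequence in genome or revcomp(m.sequence) in genome)

    def test_mega_intervals_disjoint_and_increasing(self):
        genome = mr.generate_genome(30_000, [], seed=84)
        short = mr.simulate_short_reads(genome, 25, 100, (300, 500),
                                        seed=85)
        supers = mr.build_super_reads(
            short, mr.build_kmer_spectrum(short, 25, 2)
        )
        longs = mr.simulate_long_reads(genome, 6, 4000, 1500,
                                       LONG_READ_PROFILE, seed=86)
        run = mr.run_megareads(longs, supers)
        by_read = {}
        for m in run.mega_reads:
            by_read.setdefault(m.source_long_read, []).append(m)
        for megas in by_read.values():
            megas.sort(key=lambda m: m.long_read_interval)
            for a, b in zip(megas, megas[1:]):
                assert a.long_read_interval[1] <= b.long_read_interval[0]

    def test_synthetic_pairs_order_and_nonnegative_gap(self):
        genome = _rand(2000, 87)
        supers = [_sr("a", genome[0:600]), _sr("b", genome[900:1300]),
                  _sr("c", genome[1600:2000])]
        run = mr.run_megareads([_lr(genome)], supers)
        assert len(run.mega_reads) == 3
        assert len(run.synthetic_pairs) == 2
        megas = {m.id: m for m in run.mega_reads}
        for p in run.synthetic_pairs:
            assert p.gap_estimate >= 0
            left = megas[p.left_megaread_id]
            right = megas[p.right_megaread_id]
            assert left.long_read_interval[1] <= \
                right.long_read_interval[0]
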