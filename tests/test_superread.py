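"""Super-read construction: spectrum counting, unique extension,
deduplication and conservation."""

import pytest

import megareads as mr
from megareads.simulate import ERROR_FREE, SimulatedRead
from megareads.superread import _screen, extend_to_super_read
from megareads.util import canonical, revcomp


def _read(seq, rid="r0"):
    return SimulatedRead(id=rid, sequence=seq,
                         true_origin=(0, len(seq), "+"))


def test_spectrum_counts_canonical_kmers_by_hand():
    # enumerate the four 11-mers of a 14-mer by hand, canonicalized with
    # an independently written reverse complement
    seq = "ACGTACGTACGTAC"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def rc(s):
        return "".join(comp[c] for c in reversed(s))

    expected = {}
    for i in range(4):
        kmer = seq[i : i + 11]
        c = min(kmer, rc(kmer))
        expected[c] = expected.get(c, 0) + 1
    spectrum = mr.build_kmer_spectrum([_read(seq)], k=11, min_count=1)
    assert spectrum.counts == expected


def test_spectrum_of_empty_read_list_is_empty():
    spectrum = mr.build_kmer_spectrum([], k=25, min_count=1)
    assert spectrum.counts == {}


def test_spectrum_validates_k_and_skips_short_reads():
    with pytest.raises(ValueError):
        mr.build_kmer_spectrum([], k=24, min_count=1)  # even
    with pytest.raises(ValueError):
        mr.build_kmer_spectrum([], k=9, min_count=1)  # too small
    spectrum = mr.build_kmer_spectrum([_read("ACGT")], k=25, min_count=1)
    assert spectrum.n_reads_skipped == 1


def test_spectrum_recovers_genome_kmers_at_depth():
    genome = mr.generate_genome(10_000, [], seed=51)
    reads = mr.simulate_short_reads(genome, 30, 100, (300, 500),
                                    ERROR_FREE, seed=52)
    spectrum = mr.build_kmer_spectrum(reads, 25, min_count=2)
    genome_kmers = {
        canonical(genome.sequence[i : i + 25])
        for i in range(genome.length - 24)
    }
    # no spurious k-mers; interior k-mers all present (the extreme ends
    # of the genome are sampled by very few fragments)
    assert set(spectrum.counts) <= genome_kmers
    interior = {
        canonical(genome.sequence[i : i + 25])
        for i in range(200, genome.length - 224)
    }
    assert interior <= set(spectrum.counts)


def test_unique_extension_recovers_repeat_free_sequence():
    genome = mr.generate_genome(5000, [], seed=53)
    spectrum = mr.build_kmer_spectrum([_read(genome.sequence)], k=25,
                                      min_count=1)
    read = _read(genome.sequence[2000:2100])
    sr = extend_to_super_read(read, spectrum)
    assert not sr.flagged
    assert sr.sequence == genome.sequence


def test_extension_halts_at_repeat_junction():
    import numpy as np

    rng = np.random.default_rng(54)
    bases = "ACGT"

    def rand(n):
        return "".join(bases[i] for i in rng.integers(0, 4, n))

    repeat = rand(30)
    genome = rand(150) + repeat + rand(150) + repeat + rand(150)
    spectrum = mr.build_kmer_spectrum([_read(genome)], k=11, min_count=1)
    sr = extend_to_super_read(_read(genome[:60], "seed"), spectrum)
    # extension cannot resolve which copy follows the repeat
    assert len(sr.sequence) < len(genome)
    assert sr.sequence in genome


def test_extension_with_only_own_kmers_returns_read():
    read = _read("ACGTTGCAGGCTAAACGTACGTCGATTGCA")
    spectrum = mr.build_kmer_spectrum([read], k=25, min_count=1)
    sr = extend_to_super_read(read, spectrum)
    assert sr.sequence == read.sequence


def test_error_read_is_flagged_not_extended():
    genome = mr.generate_genome(5000, [], seed=55)
    clean = [_read(genome.sequence[i : i + 100], f"r{i}")
             for i in range(0, 4900, 50)]
    spectrum = mr.build_kmer_spectrum(clean, k=25, min_count=1)
    bad_seq = list(genome.sequence[1000:1100])
    bad_seq[50] = "A" if bad_seq[50] != "A" else "C"
    sr = extend_to_super_read(_read("".join(bad_seq), "bad"), spectrum)
    assert sr.flagged
    assert sr.sequence == "".join(bad_seq)


def test_two_identical_reads_collapse():
    seq = mr.generate_genome(1000, [], seed=56).sequence[:80]
    reads = [_read(seq, "a"), _read(seq, "b")]
    spectrum = mr.build_kmer_spectrum(reads, k=25, min_count=1)
    supers = mr.build_super_reads(reads, spectrum)
    assert len(supers) == 1
    assert supers[0].n_constituent_reads == 2


@pytest.mark.parametrize("seed", [61, 62])
def test_error_free_coverage_collapses_and_conserves(seed):
    """Error-free 20x coverage of a repeat-free genome collapses to a
    handful of super-reads that are exact genome substrings, conserving
    read counts and compressing total bases."""
    genome = mr.generate_genome(30_000, [], seed=seed)
    reads = mr.simulate_short_reads(genome, 20, 100, (300, 500),
                                    ERROR_FREE, seed=seed + 1)
    spectrum = mr.build_kmer_spectrum(reads, 25, min_count=2)
    supers = mr.build_super_reads(reads, spectrum)
    assert 1 <= len(supers) <= 8
    for sr in supers:
        assert (sr.sequence in genome.sequence
                or revcomp(sr.sequence) in genome.sequence)
    n_pass = sum(
        1 for r in reads
        if len(r.sequence) >= 25 and _screen(r.sequence, spectrum)
    )
    assert sum(s.n_constituent_reads for s in supers) == n_pass
    # compression: far fewer super-reads than reads, fewer total bases
    assert len(reads) / len(supers) > 1
    assert sum(len(s.sequence) for s in supers) <= \
        sum(len(r.sequence) for r in reads)


def test_super_read_ids_stable_and_sorted():
    genome = mr.generate_genome(10_000, [], seed=63)
    reads = mr.simulate_short_reads(genome, 10, 100, (300, 500),
                                    ERROR_FREE, seed=64)
    supers = mr.build_super_reads(
        reads, mr.build_kmer_spectrum(reads, 25, min_count=1)
    )
    lengths = [len(s.sequence) for s in supers]
    assert lengths == sorted(lengths, reverse=True)
    assert [s.id for s in supers] == \
        [f"SR{i:06d}" for i in range(len(supers))]
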