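"""Small sequence utilities shared across the pipeline."""

from __future__ import annotations

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

#: The four DNA bases, in the fixed order used by all simulators.
BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement; characters outside ACGT (N, marked test
    alphabets) are reversed but left unchanged."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Canonical form of a k-mer: the lexicographic minimum of the k-mer
    and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int):
    """Yield ``(position, kmer)`` for every k-mer of *seq* consisting only
    of A/C/G/T (k-mers touching an N or other mark are skipped)."""
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if _is_acgt(kmer):
            yield i, kmer


def _is_acgt(s: str) -> bool:
    return all(c in "ACGT" for c in s)


def derive_seed(seed: int, stage: int) -> int:
    """Derive a per-stage child seed (< 2**31) from one master seed."""
    return (seed * 1_000_003 + stage * 7_919 + 1) % (2**31)
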