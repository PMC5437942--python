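"""FASTA/FASTQ I/O (gzip-transparent) and record containers.

Thin wrappers over Bio.SeqIO that normalise FASTA sequence to upper case,
preserve FASTQ qualities verbatim, and guarantee round-trip identity of
ids and sequences.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class SeqEntry:
    id: str
    sequence: str
    description: str = ""
    quality: str | None = None


def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path) -> list[SeqEntry]:
    """Parse FASTA; sequence is upper-cased, wraps removed; empty file
    yields an empty list; records without sequence raise."""
    entries = []
    with _open(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise ValueError(f"{path}: record without an id")
            entries.append(
                SeqEntry(id=rec.id, sequence=seq,
                         description=rec.description[len(rec.id):].strip())
            )
    return entries


def read_fastq(path) -> list[SeqEntry]:
    entries = []
    with _open(path, "r") as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                entries.append(
                    SeqEntry(
                        id=rec.id,
                        sequence=str(rec.seq).upper(),
                        description=rec.description[len(rec.id):].strip(),
                        quality="".join(
                            chr(q + 33)
                            for q in rec.letter_annotations["phred_quality"]
                        ),
                    )
                )
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed FASTQ near record {len(entries) + 1}: "
                f"{exc}"
            ) from exc
    return entries


def write_fasta(entries, path, wrap: int = 60) -> None:
    with _open(path, "w") as fh:
        for e in entries:
            header = f">{e.id}"
            if e.description:
                header += f" {e.description}"
            fh.write(header + "\n")
            seq = e.sequence
            if wrap:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


def write_fastq(entries, path, default_quality: str = "I") -> None:
    with _open(path, "w") as fh:
        for e in entries:
            qual = e.quality or default_quality * len(e.sequence)
            rec = SeqRecord(Seq(e.sequence), id=e.id,
                            description=e.description)
            rec.letter_annotations["phred_quality"] = [
                ord(c) - 33 for c in qual
            ]
            SeqIO.write(rec, fh, "fastq")


def reads_to_entries(reads) -> list[SeqEntry]:
    """SimulatedRead list -> SeqEntry list (quality constant)."""
    return [SeqEntry(id=r.id, sequence=r.sequence) for r in reads]
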