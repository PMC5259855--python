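"""FASTA/FASTQ readers and writers shared by the CLI and the library.

Readers accept wrapped FASTA, gzip-compressed files and CRLF line endings
(Biopython handles the records; gzip detection is by magic bytes, not file
extension).
"""

from __future__ import annotations

import gzip
from typing import IO, Iterable, Iterator, List, Tuple

from Bio import SeqIO

from .index import ReferenceSet
from .mapper import ReadRecord


def open_text_auto(path: str) -> IO[str]:
    """Open a possibly gzip-compressed text file for reading."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "r", newline=None)


def read_fasta(path: str) -> ReferenceSet:
    with open_text_auto(path) as fh:
        seqs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    if not seqs:
        raise ValueError(f"no FASTA records in {path!r}")
    return ReferenceSet(seqs)


def write_fasta(ref: ReferenceSet, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(ref.names):
            fh.write(f">{name}\n")
            seq = ref.sequence(i)
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width] + "\n")


def read_fastq(path: str, mate_index: int = 0) -> Iterator[ReadRecord]:
    with open_text_auto(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                name=rec.id,
                bases=str(rec.seq).upper(),
                qualities="".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                ),
                mate_index=mate_index,
            )


def write_fastq(reads: Iterable[ReadRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qualities or "I" * len(r.bases)
            fh.write(f"@{r.name}\n{r.bases}\n+\n{qual}\n")
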