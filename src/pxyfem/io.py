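"""FASTQ/FASTA readers and writers used across the pipeline.

Reading goes through Biopython; writing is plain text so that a fixed seed
yields byte-identical files.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .preprocess import PHRED_OFFSET, FastqParseError, ReadRecord

__all__ = ["read_fastq", "write_fastq", "read_fasta", "write_fasta"]


def read_fastq(path: str | os.PathLike) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` from a Phred+33 FASTQ file.

    Malformed records (e.g. sequence/quality length mismatch) raise
    :class:`FastqParseError` naming the record when identifiable.
    """
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield ReadRecord(
                rec.id,
                str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:  # Biopython's parse error
        raise FastqParseError(str(exc)) from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality_string}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Return ``{id: sequence}`` (uppercased) from a FASTA file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            out[title.split()[0]] = seq.upper()
    return out


def write_fasta(records: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def phred_string(qualities: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in qualities)
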