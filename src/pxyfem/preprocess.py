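"""Small-RNA read preprocessing: adapter trimming, quality and size filters.

Reproduces the standard small-RNA library cleanup: locate the 3' sequencing
adapter and truncate the read before it, strip any 5'-adapter carry-over at
the read start, drop poor-quality reads (mean Phred < 20 by default) and
keep only inserts in the single-stranded small-RNA size window (20-40 nt).
Adapter matching allows one mismatch per 8 nt of overlap with a minimum
overlap of 8 nt, mimicking common trimmer behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "ReadRecord",
    "PreprocessStats",
    "FastqParseError",
    "preprocess_reads",
    "DEFAULT_ADAPTER3",
    "DEFAULT_ADAPTER5",
]

# TruSeq small-RNA adapters (RA3 / RA5), stored as DNA.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

PHRED_OFFSET = 33
_ALPHABET = frozenset("ACGTN")


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records (names the offending record)."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read: id, DNA sequence and per-base Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FastqParseError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if not set(self.sequence) <= _ALPHABET:
            bad = sorted(set(self.sequence) - _ALPHABET)
            raise FastqParseError(f"record {self.id!r}: non-ACGTN characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def quality_string(self) -> str:
        return "".join(chr(q + PHRED_OFFSET) for q in self.qualities)


@dataclass
class PreprocessStats:
    """Read-count bookkeeping; input = output + dropped_quality + dropped_size."""

    input_count: int = 0
    trimmed_count: int = 0
    dropped_quality: int = 0
    dropped_size: int = 0
    output_count: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input_count": self.input_count,
            "trimmed_count": self.trimmed_count,
            "dropped_quality": self.dropped_quality,
            "dropped_size": self.dropped_size,
            "output_count": self.output_count,
        }


def _find_adapter3(seq: str, adapter: str, min_overlap: int = 8) -> int | None:
    """Left-most position at which a prefix of ``adapter`` matches ``seq``.

    A match at position i requires some overlap length o >= min_overlap with
    at most o // 8 mismatches between seq[i:i+o] and adapter[:o].  Checking
    every overlap length (not just the maximal one) makes trimming
    idempotent: a window that passes on a shortened read would also have
    passed on the original.
    """
    n = len(seq)
    max_allowed = len(adapter) // 8
    for i in range(0, n - min_overlap + 1):
        o_max = min(len(adapter), n - i)
        mm = 0
        for o in range(1, o_max + 1):
            if seq[i + o - 1] != adapter[o - 1]:
                mm += 1
                if mm > max_allowed:
                    break
            if o >= min_overlap and mm <= o // 8:
                return i
    return None


def _find_adapter5(seq: str, adapter: str, min_overlap: int = 8) -> int:
    """Length of the longest suffix of ``adapter`` matching the read start."""
    for o in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
        mm = sum(1 for a, b in zip(seq[:o], adapter[-o:]) if a != b)
        if mm <= o // 8:
            return o
    return 0


def _trim_read(read: ReadRecord, adapter3: str, adapter5: str) -> tuple[ReadRecord, bool]:
    seq, qual = read.sequence, read.qualities
    trimmed = False
    cut = _find_adapter3(seq, adapter3)
    if cut is not None:
        seq, qual = seq[:cut], qual[:cut]
        trimmed = True
    # 5'-adapter carry-over is removed to a fixpoint so a second pass is a no-op.
    while seq:
        o = _find_adapter5(seq, adapter5)
        if o == 0:
            break
        seq, qual = seq[o:], qual[o:]
        trimmed = True
    if not trimmed:
        return read, False
    return ReadRecord(read.id, seq, qual), True


def preprocess_reads(
    reads: Iterable[ReadRecord],
    adapter3: str = DEFAULT_ADAPTER3,
    adapter5: str = DEFAULT_ADAPTER5,
    qmin: float = 20.0,
    lmin: int = 20,
    lmax: int = 40,
    quality_mode: str = "mean",
) -> tuple[list[ReadRecord], PreprocessStats]:
    """Trim adapters, then drop low-quality and out-of-size reads.

    Parameters
    ----------
    qmin
        Phred threshold. With ``quality_mode="mean"`` a read is dropped when
        its mean Phred score is below ``qmin``; with ``"min"`` when any base
        is below it.
    lmin, lmax
        Inclusive post-trim insert-length window (nt).

    Returns the surviving reads and a :class:`PreprocessStats` whose counters
    are conserved (input = output + dropped_quality + dropped_size).
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    if not (0 < lmin <= lmax):
        raise ValueError(f"invalid size window [{lmin}, {lmax}]")
    if quality_mode not in ("mean", "min"):
        raise ValueError(f"unknown quality_mode {quality_mode!r}")

    stats = PreprocessStats()
    out: list[ReadRecord] = []
    for read in reads:
        stats.input_count += 1
        read, was_trimmed = _trim_read(read, adapter3, adapter5)
        if was_trimmed:
            stats.trimmed_count += 1
        if len(read) == 0:
            stats.dropped_size += 1
            continue
        if quality_mode == "mean":
            ok = sum(read.qualities) / len(read.qualities) >= qmin
        else:
            ok = min(read.qualities) >= qmin
        if not ok:
            stats.dropped_quality += 1
            continue
        if not (lmin <= len(read) <= lmax):
            stats.dropped_size += 1
            continue
        out.append(read)
        stats.output_count += 1
    return out, stats


def iter_preprocess(
    reads: Iterable[ReadRecord], **kwargs
) -> Iterator[ReadRecord]:
    """Streaming wrapper around :func:`preprocess_reads` (stats discarded)."""
    out, _ = preprocess_reads(reads, **kwargs)
    yield from out
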