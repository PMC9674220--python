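"""Bespoke exact/k-mismatch short-read mapper against a single transcript.

Maps each preprocessed small-RNA read to both strands of a target sequence
allowing up to ``max_mismatch`` substitutions (no indels).  A read maps
"sense" when it matches the target directly and "antisense" when its reverse
complement does; coordinates are always reported on the target's forward
coordinate system (1-based inclusive).  Among equally-best hits the
left-most is reported (sense preferred on an exact positional tie) and
``n_hits`` records the tie count.  N never matches any base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocess import ReadRecord
from .synthetic_data import TranscriptModel, revcomp

__all__ = ["AlignmentRecord", "map_reads", "alignments_to_sam", "alignments_to_table"]

_LUT = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _LUT[ord(_b)] = _i
_N_CODE = 4


def _encode(seq: str) -> np.ndarray:
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 5).any():
        raise ValueError(f"sequence contains non-ACGTN characters: {seq!r}")
    return arr


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read on the target's forward coordinate system."""

    read_id: str
    target_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "sense" | "antisense"
    mismatches: int
    n_hits: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _coerce_target(target) -> tuple[str, str]:
    if isinstance(target, TranscriptModel):
        return target.id, target.sequence.upper()
    if isinstance(target, tuple) and len(target) == 2:
        return target[0], target[1].upper()
    if isinstance(target, str):
        return "target", target.upper()
    raise TypeError(f"unsupported target type {type(target)!r}")


def map_reads(
    reads: Iterable[ReadRecord | tuple[str, str]],
    target,
    max_mismatch: int = 0,
) -> tuple[list[AlignmentRecord], list[str]]:
    """Map reads to the target on both strands.

    Parameters
    ----------
    reads
        :class:`ReadRecord` objects or plain ``(id, sequence)`` tuples,
        15-50 nt each.
    target
        A :class:`TranscriptModel`, an ``(id, sequence)`` tuple, or a bare
        sequence string.
    max_mismatch
        Maximum substitution count (default 0); indels are not modelled.

    Returns the alignments plus the ids of unmapped reads.  Results for a
    repeated read sequence are cached, so libraries with duplicated inserts
    map in sub-linear time.
    """
    target_id, tseq = _coerce_target(target)
    if not tseq:
        raise ValueError("empty target")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    tarr = _encode(tseq)
    t_is_n = tarr == _N_CODE
    L = len(tseq)

    window_cache: dict[int, np.ndarray] = {}
    winn_cache: dict[int, np.ndarray] = {}
    result_cache: dict[str, tuple | None] = {}

    alignments: list[AlignmentRecord] = []
    unmapped: list[str] = []

    for read in reads:
        if isinstance(read, ReadRecord):
            rid, seq = read.id, read.sequence
        else:
            rid, seq = read
        seq = seq.upper()
        k = len(seq)
        if not (15 <= k <= 50):
            raise ValueError(f"read {rid!r}: length {k} outside the 15-50 nt contract")

        hit = result_cache.get(seq, "miss")
        if hit == "miss":
            hit = None
            if k <= L:
                if k not in window_cache:
                    window_cache[k] = np.lib.stride_tricks.sliding_window_view(tarr, k)
                    winn_cache[k] = np.lib.stride_tricks.sliding_window_view(t_is_n, k)
                windows, win_n = window_cache[k], winn_cache[k]
                best_mm = max_mismatch + 1
                cands: list[tuple[int, int, str]] = []  # (start0, mm, strand)
                for strand, s in (("sense", seq), ("antisense", revcomp(seq))):
                    rarr = _encode(s)
                    r_is_n = rarr == _N_CODE
                    mm = ((windows != rarr) | win_n | r_is_n).sum(axis=1)
                    ok = np.nonzero(mm <= max_mismatch)[0]
                    for p in ok:
                        cands.append((int(p), int(mm[p]), strand))
                if cands:
                    best_mm = min(c[1] for c in cands)
                    best = [c for c in cands if c[1] == best_mm]
                    # left-most position; sense wins a positional tie
                    best.sort(key=lambda c: (c[0], c[2] != "sense"))
                    p0, mm0, strand0 = best[0]
                    hit = (p0 + 1, p0 + k, strand0, mm0, len(best))
            result_cache[seq] = hit

        if hit is None:
            unmapped.append(rid)
        else:
            start, end, strand, mm, n_hits = hit
            alignments.append(
                AlignmentRecord(rid, target_id, start, end, strand, mm, n_hits)
            )
    return alignments, unmapped


def alignments_to_table(alignments: Sequence[AlignmentRecord]):
    """Alignments as a pandas DataFrame (native TSV representation)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "target_id": a.target_id,
                "start": a.start,
                "end": a.end,
                "strand": a.strand,
                "mismatches": a.mismatches,
                "n_hits": a.n_hits,
            }
            for a in alignments
        ],
        columns=["read_id", "target_id", "start", "end", "strand", "mismatches", "n_hits"],
    )


def alignments_to_sam(
    alignments: Sequence[AlignmentRecord],
    target_id: str,
    target_len: int,
    reads: dict[str, str] | None = None,
) -> str:
    """Minimal SAM rendering: flag 0 for sense, 16 for antisense, 1-based POS.

    Sequences (when provided) are written in reference orientation, as SAM
    requires for reverse-strand alignments.
    """
    lines = [f"@SQ\tSN:{target_id}\tLN:{target_len}"]
    for a in alignments:
        flag = 0 if a.strand == "sense" else 16
        seq = "*"
        if reads and a.read_id in reads:
            seq = reads[a.read_id]
            if a.strand == "antisense":
                seq = revcomp(seq)
        lines.append(
            f"{a.read_id}\t{flag}\t{a.target_id}\t{a.start}\t255\t{a.length}M\t*\t0\t0\t{seq}\t*\tNM:i:{a.mismatches}"
        )
    return "\n".join(lines) + "\n"
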