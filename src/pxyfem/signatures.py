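"""Small-RNA signature statistics over transcript alignments.

All the read-level signatures used to characterise a silencing-RNA
population: strand-by-size histograms, per-position strand-split coverage,
base-frequency (sequence-logo) matrices, the 1U/10A nucleotide biases, the
ping-pong 5'-overlap spectrum with a z-score for the 10-nt bin, the phasing
(head-to-tail distance) spectrum, and reads-per-million normalisation.

Coordinate conventions: alignments are 1-based inclusive intervals on the
target's forward strand.  An antisense read's 5' end is its ``end``
coordinate.  The ping-pong overlap between a sense read s and an antisense
read a is ``a.end - s.start + 1`` — the number of bases shared between the
two 5' ends; guide-directed slicing across from nucleotides 10/11 of the
guide makes 10 the hallmark value.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ReadRecord
from .srna_map import AlignmentRecord

__all__ = [
    "SignatureProfile",
    "PingPongResult",
    "strand_size_histogram",
    "positional_density",
    "base_frequency_matrix",
    "bias_1U_10A",
    "pingpong_spectrum",
    "phasing_spectrum",
    "normalize_rpm",
    "compute_profile",
    "reads_as_dict",
]

STRANDS = ("sense", "antisense")


def reads_as_dict(reads: Iterable[ReadRecord | tuple[str, str]]) -> dict[str, str]:
    """``{read_id: sequence}`` helper for the read-sequence-based statistics."""
    out = {}
    for r in reads:
        if isinstance(r, ReadRecord):
            out[r.id] = r.sequence
        else:
            out[r[0]] = r[1]
    return out


def strand_size_histogram(alignments: Sequence[AlignmentRecord]) -> pd.DataFrame:
    """Read counts indexed by length, one column per strand.

    The histogram total equals the number of alignments; lengths outside the
    usual 20-40 nt window are still counted under their own row.
    """
    counts: dict[str, Counter] = {s: Counter() for s in STRANDS}
    for a in alignments:
        counts[a.strand][a.length] += 1
    lengths = sorted(set(counts["sense"]) | set(counts["antisense"])) or [0]
    return pd.DataFrame(
        {s: [counts[s].get(l, 0) for l in lengths] for s in STRANDS},
        index=pd.Index(lengths, name="length"),
    )


def positional_density(
    alignments: Sequence[AlignmentRecord], target_len: int
) -> pd.DataFrame:
    """Per-position coverage split by strand (positions 1..target_len)."""
    dens = {s: np.zeros(target_len, dtype=np.int64) for s in STRANDS}
    for a in alignments:
        if not (1 <= a.start <= a.end <= target_len):
            raise ValueError(
                f"alignment {a.read_id!r} [{a.start},{a.end}] outside target of length {target_len}"
            )
        dens[a.strand][a.start - 1 : a.end] += 1
    return pd.DataFrame(
        {s: dens[s] for s in STRANDS},
        index=pd.RangeIndex(1, target_len + 1, name="position"),
    )


def base_frequency_matrix(
    alignments: Sequence[AlignmentRecord],
    reads: Mapping[str, str],
    strand: str,
    length: int,
) -> pd.DataFrame | None:
    """Base frequencies by read position for one strand and read length.

    Frequencies are computed on the read sequence in its own 5'->3'
    orientation (the natural orientation for a sequence logo).  Returns
    ``None`` when no alignment matches — an empty-result signal rather than
    an exception.  Each column sums to 1.  The internal alphabet is DNA;
    writers may display U for T.
    """
    seqs = [
        reads[a.read_id]
        for a in alignments
        if a.strand == strand and a.length == length and a.read_id in reads
    ]
    if not seqs:
        return None
    mat = np.zeros((4, length), dtype=float)
    order = {b: i for i, b in enumerate("ACGT")}
    for s in seqs:
        for j, b in enumerate(s[:length]):
            if b in order:
                mat[order[b], j] += 1
    colsum = mat.sum(axis=0)
    colsum[colsum == 0] = 1.0
    mat /= colsum
    return pd.DataFrame(
        mat, index=pd.Index(list("ACGT"), name="base"),
        columns=pd.RangeIndex(1, length + 1, name="position"),
    )


def bias_1U_10A(
    alignments: Sequence[AlignmentRecord], reads: Mapping[str, str]
) -> tuple[float | None, float | None]:
    """(1U fraction over antisense reads, 10A fraction over sense reads).

    1U: fraction of antisense reads whose own 5' base is T (U on the RNA);
    10A: fraction of sense reads (>= 10 nt) whose 10th base is A.  A strand
    with no reads yields ``None``.
    """
    n_anti = u1 = 0
    n_sense = a10 = 0
    for a in alignments:
        seq = reads.get(a.read_id)
        if seq is None:
            continue
        if a.strand == "antisense":
            n_anti += 1
            u1 += seq[0] == "T"
        else:
            if len(seq) >= 10:
                n_sense += 1
                a10 += seq[9] == "A"
    return (
        u1 / n_anti if n_anti else None,
        a10 / n_sense if n_sense else None,
    )


@dataclass
class PingPongResult:
    """Ping-pong 5'-overlap spectrum with the overlap-10 z-score."""

    spectrum: dict[int, int]
    z10: float | None
    n_pairs: int

    def modal_overlap(self) -> int | None:
        if self.n_pairs == 0:
            return None
        return max(self.spectrum, key=lambda k: (self.spectrum[k], -k))


def pingpong_spectrum(
    alignments: Sequence[AlignmentRecord], max_overlap: int = 25
) -> PingPongResult:
    """Count sense/antisense pairs by 5'-overlap, per target.

    Every (sense, antisense) pair on the same target with overlap
    ``a.end - s.start + 1`` in [1, max_overlap] increments that bin; each
    pair counts once (multimap ``n_hits`` ignored).  ``z10`` standardises
    the overlap-10 bin against the remaining bins; it is ``None`` when fewer
    than 2 background bins are nonzero or their spread is zero.
    """
    spectrum = {k: 0 for k in range(1, max_overlap + 1)}
    by_target: dict[str, tuple[Counter, Counter]] = defaultdict(
        lambda: (Counter(), Counter())
    )
    for a in alignments:
        s_starts, a_ends = by_target[a.target_id]
        if a.strand == "sense":
            s_starts[a.start] += 1
        else:
            a_ends[a.end] += 1
    n_pairs = 0
    for s_starts, a_ends in by_target.values():
        for end, n_a in a_ends.items():
            for k in range(1, max_overlap + 1):
                n_s = s_starts.get(end - k + 1, 0)
                if n_s:
                    spectrum[k] += n_a * n_s
                    n_pairs += n_a * n_s
    background = [spectrum[k] for k in spectrum if k != 10]
    nonzero = sum(1 for b in background if b > 0)
    z10: float | None = None
    if nonzero >= 2:
        sd = float(np.std(background, ddof=1))
        if sd > 0:
            z10 = (spectrum[10] - float(np.mean(background))) / sd
    return PingPongResult(spectrum=spectrum, z10=z10, n_pairs=n_pairs)


def phasing_spectrum(
    alignments: Sequence[AlignmentRecord], strand: str, max_gap: int = 30
) -> dict[int, int]:
    """Distance spectrum between consecutive same-strand reads.

    Reads are ordered by their 5' position along their own strand; for each
    consecutive pair the distance is the gap between the upstream read's 3'
    end and the downstream read's 5' end (0 for perfectly head-to-tail
    phased reads).  Distances are counted over [-10, max_gap], per target.
    """
    if strand not in STRANDS:
        raise ValueError(f"unknown strand {strand!r}")
    counts: dict[int, int] = {d: 0 for d in range(-10, max_gap + 1)}
    by_target: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        if a.strand == strand:
            by_target[a.target_id].append(a)
    for aligns in by_target.values():
        if strand == "sense":
            aligns.sort(key=lambda a: (a.start, a.end))
            dists = (
                nxt.start - prev.end - 1 for prev, nxt in zip(aligns, aligns[1:])
            )
        else:
            aligns.sort(key=lambda a: (-a.end, -a.start))
            dists = (
                prev.start - nxt.end - 1 for prev, nxt in zip(aligns, aligns[1:])
            )
        for d in dists:
            if -10 <= d <= max_gap:
                counts[d] += 1
    return counts


def normalize_rpm(count: float, library_total: int) -> float:
    """Reads per million: count x 10^6 / library_total."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return count * 1_000_000 / library_total


@dataclass
class SignatureProfile:
    """Bundle of the per-library signature statistics."""

    size_hist: pd.DataFrame
    pos_density: pd.DataFrame
    base_matrices: dict[tuple[str, int], pd.DataFrame]
    bias_1U: float | None
    bias_10A: float | None
    pingpong: PingPongResult
    rpm_factor: float | None
    n_alignments: int


def compute_profile(
    alignments: Sequence[AlignmentRecord],
    reads: Mapping[str, str] | Iterable[ReadRecord],
    target_len: int,
    library_total: int | None = None,
) -> SignatureProfile:
    """Compute the full signature profile of one mapped library.

    Base-frequency matrices are produced for the most common read length on
    each strand (the size class a sequence logo would display).
    """
    if not isinstance(reads, Mapping):
        reads = reads_as_dict(reads)
    hist = strand_size_histogram(alignments)
    matrices: dict[tuple[str, int], pd.DataFrame] = {}
    for strand in STRANDS:
        if hist[strand].sum() > 0:
            top_len = int(hist[strand].idxmax())
            m = base_frequency_matrix(alignments, reads, strand, top_len)
            if m is not None:
                matrices[(strand, top_len)] = m
    b1u, b10a = bias_1U_10A(alignments, reads)
    return SignatureProfile(
        size_hist=hist,
        pos_density=positional_density(alignments, target_len),
        base_matrices=matrices,
        bias_1U=b1u,
        bias_10A=b10a,
        pingpong=pingpong_spectrum(alignments),
        rpm_factor=(1_000_000 / library_total) if library_total else None,
        n_alignments=len(alignments),
    )
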