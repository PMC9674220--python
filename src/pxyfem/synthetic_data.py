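"""Synthetic inputs for the whole pipeline, with truth records.

This module generates every input the analysis consumes:

* a transcript model of a male-determining mRNA (exon structure, UTRs and a
  motif window straddling an exon junction, standing in for the
  cysteine-cysteine domain of *Masculinizer* homologs);
* adapter-ligated small-RNA FASTQ libraries in which sense/antisense read
  pairs are produced by PIWI slicer geometry (the responder's 5' end is set
  by cleavage across from the guide's 10th/11th nucleotides), with a 1U bias
  on antisense reads, optional phased downstream trails, and
  transcript-uniform background;
* a developmental time course in which target-derived reads scale per
  timepoint over a constant off-target pool;
* genome scaffolds with planted spliced retrocopies (reverse-complemented,
  diverged, flanked by LTR-fragment motifs and target-site duplications);
* reporter-assay tables of per-embryo nanoluciferase/firefly readings.

Every emitted read and planted locus carries exactly one truth record so
parameter recovery can be tested downstream.  All randomness flows through
one seeded ``numpy`` generator per call: identical inputs and seed give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import motifs
from .preprocess import ReadRecord

__all__ = [
    "TranscriptModel",
    "LibrarySpec",
    "RetrocopyPlant",
    "make_transcript_model",
    "default_transcript_model",
    "simulate_small_rna_library",
    "simulate_time_course",
    "DEFAULT_TIMEPOINTS",
    "plant_retrocopy_scaffold",
    "default_retrocopy_plants",
    "simulate_assay_table",
    "revcomp",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Transcript model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced target mRNA with exon boundaries, UTRs and a motif window.

    Coordinates are 1-based inclusive on the spliced transcript.  The motif
    window marks the region coding for the conserved cysteine-cysteine
    domain analogue; in the default preset it straddles the exon 5-6
    junction, where silencing reads concentrate.
    """

    id: str
    sequence: str
    exon_lengths: tuple[int, ...]
    utr5_len: int
    utr3_len: int
    motif_window: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.exon_lengths) < 2:
            raise ValueError("a transcript model needs at least 2 exons")
        if any(l < 1 for l in self.exon_lengths):
            raise ValueError("exon lengths must be >= 1")
        if sum(self.exon_lengths) != len(self.sequence):
            raise ValueError("sum(exon_lengths) must equal sequence length")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError("UTR lengths must be non-negative")
        if self.utr5_len + self.utr3_len >= len(self.sequence):
            raise ValueError("UTRs cannot cover the whole transcript")
        lo, hi = self.motif_window
        if not (1 <= lo <= hi <= len(self.sequence)):
            raise ValueError("motif window must lie within the transcript")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def junctions(self) -> tuple[int, ...]:
        """Exon-exon junction positions: the last base of each internal exon."""
        acc, out = 0, []
        for l in self.exon_lengths[:-1]:
            acc += l
            out.append(acc)
        return tuple(out)

    def exon_bounds(self, index: int) -> tuple[int, int]:
        """1-based inclusive transcript interval of exon ``index`` (1-based)."""
        if not (1 <= index <= len(self.exon_lengths)):
            raise ValueError(f"exon index {index} out of range")
        start = 1 + sum(self.exon_lengths[: index - 1])
        return start, start + self.exon_lengths[index - 1] - 1

    def exon_of(self, pos: int) -> int:
        """1-based exon index containing transcript position ``pos``."""
        if not (1 <= pos <= self.length):
            raise ValueError(f"position {pos} outside transcript")
        acc = 0
        for i, l in enumerate(self.exon_lengths, start=1):
            acc += l
            if pos <= acc:
                return i
        raise AssertionError("unreachable")


def make_transcript_model(
    exon_lengths: Sequence[int],
    utr5_len: int,
    utr3_len: int,
    motif_window: tuple[int, int],
    seed: int,
    id: str = "target_mRNA",
) -> TranscriptModel:
    """Random (seeded) transcript with the requested exon architecture."""
    exon_lengths = tuple(int(l) for l in exon_lengths)
    if any(l < 1 for l in exon_lengths):
        raise ValueError("exon lengths must be >= 1")
    rng = np.random.default_rng(seed)
    total = sum(exon_lengths)
    seq = "".join(rng.choice(list(_BASES), size=total))
    return TranscriptModel(
        id=id,
        sequence=seq,
        exon_lengths=exon_lengths,
        utr5_len=utr5_len,
        utr3_len=utr3_len,
        motif_window=(int(motif_window[0]), int(motif_window[1])),
    )


#: Exon architecture of the default Masc-like preset (7 exons, 1250 nt).
#: The motif window (815, 850) straddles the exon 5-6 junction at 830, and
#: the exon sizes are chosen so a 326-nt copy starting in exon 4 reaches
#: into exon 7 ("long") while a 192-nt copy ends within exon 6 ("short").
DEFAULT_EXON_LENGTHS = (200, 150, 180, 160, 140, 120, 300)
DEFAULT_MOTIF_WINDOW = (815, 850)


def default_transcript_model(seed: int = 0) -> TranscriptModel:
    """The Masc-like preset: 7 exons, motif window over the exon 5-6 junction."""
    return make_transcript_model(
        DEFAULT_EXON_LENGTHS,
        utr5_len=120,
        utr3_len=200,
        motif_window=DEFAULT_MOTIF_WINDOW,
        seed=seed,
        id="masc_like",
    )


# ---------------------------------------------------------------------------
# Small-RNA library simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one simulated small-RNA library.

    ``bias_1U`` is the probability that a ping-pong guide starts with U; in
    slicer mode the sense 10A follows from the same base pair (the
    responder's 10th nucleotide is the partner of the guide's first), so
    ``bias_10A`` only takes effect when ``slicer`` is False and sense reads
    are placed independently.  ``n_decoy`` reads are off-target (random
    sequence) and anchor the library size in time-course simulations.
    """

    n_pingpong_pairs: int = 500
    n_background: int = 200
    n_decoy: int = 0
    bias_1U: float = 0.9
    bias_10A: float = 0.9
    pirna_size_range: tuple[int, int] = (25, 30)
    sirna_size_range: tuple[int, int] = (21, 24)
    frac_pirna: float = 0.7
    hotspot: tuple[int, int] | None = None
    phased_trail_prob: float = 0.3
    slicer: bool = True
    adapters: tuple[str, str] = (
        "GTTCAGAGTTCTACAGTCCGACGATC",  # 5' adapter
        "TGGAATTCTCGGGTGCCAAGG",  # 3' adapter
    )
    read_length: int = 50
    qual_mean: int = 35
    low_quality_frac: float = 0.0
    low_quality_mean: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bias_1U", "bias_10A", "frac_pirna", "phased_trail_prob", "low_quality_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        for name in ("pirna_size_range", "sirna_size_range"):
            lo, hi = getattr(self, name)
            if not (20 <= lo <= hi <= 40):
                raise ValueError(f"{name}=({lo},{hi}) must lie within 20-40 nt")
        if min(self.n_pingpong_pairs, self.n_background, self.n_decoy) < 0:
            raise ValueError("read counts must be non-negative")
        if not self.adapters[0] or not self.adapters[1]:
            raise ValueError("adapters must be non-empty")


TRUTH_COLUMNS = ["read_id", "origin", "start", "end", "strand", "length"]


def _ligate(rng: np.random.Generator, insert: str, spec: LibrarySpec) -> str:
    """Insert + 3' adapter + random filler, truncated to the read length."""
    raw = insert + spec.adapters[1]
    if len(raw) < spec.read_length:
        pad = "".join(rng.choice(list(_BASES), size=spec.read_length - len(raw)))
        raw += pad
    return raw[: spec.read_length]


def _qualities(rng: np.random.Generator, n: int, spec: LibrarySpec) -> tuple[int, ...]:
    if spec.low_quality_frac > 0 and rng.random() < spec.low_quality_frac:
        q = rng.normal(spec.low_quality_mean, 3.0, size=n)
        return tuple(int(v) for v in np.clip(np.rint(q), 2, 40))
    return (spec.qual_mean,) * n


def _sample_length(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def simulate_small_rna_library(
    model: TranscriptModel, spec: LibrarySpec
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one adapter-ligated small-RNA library with truth labels.

    Ping-pong pairs follow slicer geometry: an antisense guide whose 5' end
    sits at forward coordinate e directs cleavage of the sense strand across
    from its 10th/11th nucleotides, so the sense responder starts at e - 9
    and the emergent 5'-overlap statistic is 10 by mechanism, not by
    construction of the statistic.  Each responder spawns a downstream
    head-to-tail phased read with probability ``phased_trail_prob``.
    Background reads are uniform over transcript and strand; decoy reads are
    random off-target sequence.  Read order is shuffled (seeded) and ids are
    positionally uninformative.

    Returns the reads and a truth table (one row per read) with columns
    ``read_id, origin, start, end, strand, length``; decoys have start/end 0.
    """
    rng = np.random.default_rng(spec.seed)
    seq = model.sequence
    L = model.length
    hotspot = spec.hotspot if spec.hotspot is not None else model.motif_window
    if not (1 <= hotspot[0] <= hotspot[1] <= L):
        raise ValueError(f"hotspot {hotspot} outside transcript of length {L}")

    pir_lo, pir_hi = spec.pirna_size_range
    sir_lo, sir_hi = spec.sirna_size_range

    # Guide 5' ends must leave room for the guide on the left and the
    # responder (+ phased trail) on the right.
    e_min = max(hotspot[0], pir_hi)
    e_max = min(hotspot[1], L - (pir_hi - 9) - pir_hi - 1)
    if spec.n_pingpong_pairs > 0 and e_min > e_max:
        raise ValueError("hotspot leaves no room for ping-pong geometry")
    candidates = np.arange(e_min, e_max + 1)
    pos_A = candidates[[seq[p - 1] == "A" for p in candidates]]
    pos_other = candidates[[seq[p - 1] != "A" for p in candidates]]

    entries: list[tuple[str, str, int, int, str]] = []  # origin, insert, start, end, strand

    def add(origin: str, start: int, end: int, strand: str) -> None:
        insert = seq[start - 1 : end]
        if strand == "antisense":
            insert = revcomp(insert)
        entries.append((origin, insert, start, end, strand))

    for _ in range(spec.n_pingpong_pairs):
        want_u = rng.random() < spec.bias_1U
        pool = pos_A if want_u else pos_other
        if pool.size == 0:
            pool = candidates
        e = int(rng.choice(pool))
        lg = _sample_length(rng, pir_lo, pir_hi)
        add("pingpong_guide", e - lg + 1, e, "antisense")
        if spec.slicer:
            s_r = e - 9
        else:
            s_r = int(rng.integers(1, L - pir_hi))
            # decoupled mode: impose the 10A independently by resampling the
            # start until position 10 matches the coin flip (bounded tries)
            want_a = rng.random() < spec.bias_10A
            for _try in range(200):
                if (seq[s_r + 8] == "A") == want_a:
                    break
                s_r = int(rng.integers(1, L - pir_hi))
        lr = _sample_length(rng, pir_lo, pir_hi)
        e_r = min(s_r + lr - 1, L)
        add("pingpong_responder", s_r, e_r, "sense")
        if rng.random() < spec.phased_trail_prob:
            s_p = e_r + 1
            lp = _sample_length(rng, pir_lo, pir_hi)
            if s_p + lp - 1 <= L:
                add("phased", s_p, s_p + lp - 1, "sense")

    for _ in range(spec.n_background):
        if rng.random() < spec.frac_pirna:
            lb = _sample_length(rng, pir_lo, pir_hi)
        else:
            lb = _sample_length(rng, sir_lo, sir_hi)
        s = int(rng.integers(1, L - lb + 2))
        strand = "sense" if rng.random() < 0.5 else "antisense"
        add("background", s, s + lb - 1, strand)

    decoys: list[tuple[str, str]] = []
    for _ in range(spec.n_decoy):
        if rng.random() < spec.frac_pirna:
            ld = _sample_length(rng, pir_lo, pir_hi)
        else:
            ld = _sample_length(rng, sir_lo, sir_hi)
        decoys.append(("decoy", "".join(rng.choice(list(_BASES), size=ld))))

    # Emit in shuffled order with opaque ids.
    order = rng.permutation(len(entries) + len(decoys))
    reads: list[ReadRecord] = []
    truth_rows: list[dict] = []
    for new_idx, old_idx in enumerate(order):
        rid = f"r{new_idx:06d}"
        if old_idx < len(entries):
            origin, insert, start, end, strand = entries[old_idx]
        else:
            origin, insert = decoys[old_idx - len(entries)]
            start = end = 0
            strand = "."
        raw = _ligate(rng, insert, spec)
        reads.append(ReadRecord(rid, raw, _qualities(rng, len(raw), spec)))
        truth_rows.append(
            {
                "read_id": rid,
                "origin": origin,
                "start": start,
                "end": end,
                "strand": strand,
                "length": len(insert),
            }
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


#: Default time-course abundance scales: absent at 3 h, rising through
#: 6/9 h, peaking at 12 h, reduced by 24 h.
DEFAULT_TIMEPOINTS: tuple[tuple[str, float], ...] = (
    ("3h", 0.0),
    ("6h", 0.25),
    ("9h", 0.5),
    ("12h", 1.0),
    ("24h", 0.3),
)


def simulate_time_course(
    model: TranscriptModel,
    base_spec: LibrarySpec,
    timepoints: Sequence[tuple[str, float]] = DEFAULT_TIMEPOINTS,
    seed: int = 0,
    n_decoy: int | None = None,
) -> list[tuple[str, list[ReadRecord], pd.DataFrame]]:
    """A developmental time course of libraries.

    Target-derived read counts (pairs and transcript background) scale with
    each timepoint's abundance scale; the off-target decoy pool is held
    constant so reads-per-million tracks target abundance.
    """
    decoy = n_decoy if n_decoy is not None else (base_spec.n_decoy or 2000)
    out = []
    rng = np.random.default_rng(seed)
    for label, scale in timepoints:
        if scale < 0:
            raise ValueError(f"abundance scale for {label!r} must be >= 0")
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base_spec,
            n_pingpong_pairs=int(round(scale * base_spec.n_pingpong_pairs)),
            n_background=int(round(scale * base_spec.n_background)),
            n_decoy=decoy,
            seed=sub_seed,
        )
        reads, truth = simulate_small_rna_library(model, spec)
        out.append((label, reads, truth))
    return out


# ---------------------------------------------------------------------------
# Retrocopy scaffolds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RetrocopyPlant:
    """One retrocopy to plant: a spliced transcript sub-sequence.

    ``transcript_start``/``transcript_end`` are 1-based inclusive on the
    spliced transcript (partial terminal exons allowed).  ``strand`` is the
    genomic orientation; minus-strand copies are reverse-complemented.
    ``divergence`` is the per-base substitution rate (substitutions never
    touch the 2 nt flanking an exon-exon junction so junction evidence stays
    intact).  ``tsd``, when given, is written immediately outside both
    flanking motifs, emulating a target-site duplication.
    """

    transcript_start: int
    transcript_end: int
    strand: str = "+"
    flank5_motif: str = ""
    flank3_motif: str = ""
    tsd: str | None = None
    divergence: float = 0.0
    genome_start: int | None = None  # 1-based start of the full insert; auto if None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        if self.transcript_start > self.transcript_end:
            raise ValueError("transcript_start must be <= transcript_end")


LOCUS_TRUTH_COLUMNS = [
    "locus_id",
    "scaffold_id",
    "start",
    "end",
    "insert_start",
    "insert_end",
    "strand",
    "transcript_start",
    "transcript_end",
    "exons_covered",
    "copy_class",
    "tsd",
    "n_substitutions",
]


def _classify(model: TranscriptModel, t_start: int, t_end: int) -> str:
    last = model.exon_of(t_end)
    if last >= 7:
        return "long"
    if last == 6:
        return "short"
    return "other"


def _exons_covered(model: TranscriptModel, t_start: int, t_end: int) -> str:
    """Compact 'exon list with partial flags' string, e.g. '4*,5,6*'."""
    first, last = model.exon_of(t_start), model.exon_of(t_end)
    parts = []
    for i in range(first, last + 1):
        lo, hi = model.exon_bounds(i)
        partial = (i == first and t_start > lo) or (i == last and t_end < hi)
        parts.append(f"{i}*" if partial else str(i))
    return ",".join(parts)


def _diverge(
    rng: np.random.Generator, sub: str, t_start: int, model: TranscriptModel, rate: float
) -> tuple[str, int]:
    """Seeded substitutions, sparing 2 nt on either side of each junction and
    the terminal 4 nt of the copy (keeps junction evidence and copy
    boundaries recoverable at default scanner thresholds)."""
    if rate <= 0:
        return sub, 0
    protected = set()
    for j in model.junctions:
        for p in range(j - 1, j + 3):  # transcript positions j-1 .. j+2
            protected.add(p)
    chars = list(sub)
    n_sub = 0
    for i in range(len(chars)):
        tpos = t_start + i
        if tpos in protected or i < 4 or i >= len(chars) - 4:
            continue
        if rng.random() < rate:
            alt = [b for b in _BASES if b != chars[i]]
            chars[i] = alt[int(rng.integers(0, 3))]
            n_sub += 1
    return "".join(chars), n_sub


def plant_retrocopy_scaffold(
    genome_len: int,
    model: TranscriptModel,
    copies: Sequence[RetrocopyPlant],
    seed: int,
    scaffold_id: str = "scaffold_W",
    min_spacing: int = 100,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random scaffold with planted spliced retrocopies and a truth table.

    Each planted insert is ``[tsd] flank5 copy flank3 [tsd]`` written over
    the random background; the copy part is the (diverged) spliced transcript
    sub-sequence, reverse-complemented for minus-strand plants.  Raises if
    planted intervals overlap or do not fit with ``min_spacing``.

    Returns ``({scaffold_id: sequence}, truth)`` where truth has one row per
    copy with the genomic interval of the transcript-homologous part
    (``start``/``end``) and of the whole insert (``insert_start``/``insert_end``).
    """
    # Salted stream: keeps the scaffold background independent of a
    # transcript model built from the same seed.
    rng = np.random.default_rng([seed, 0x5CAFF])
    genome = list("".join(rng.choice(list(_BASES), size=genome_len)))

    # Build insert sequences first so placement can be validated.
    built = []
    for idx, cp in enumerate(copies):
        if not (1 <= cp.transcript_start <= cp.transcript_end <= model.length):
            raise ValueError(f"copy {idx}: transcript interval outside the transcript")
        sub = model.sequence[cp.transcript_start - 1 : cp.transcript_end]
        sub, n_sub = _diverge(rng, sub, cp.transcript_start, model, cp.divergence)
        if cp.strand == "-":
            sub = revcomp(sub)
        tsd = cp.tsd or ""
        insert = tsd + cp.flank5_motif + sub + cp.flank3_motif + tsd
        built.append((cp, insert, len(sub), n_sub))

    # Placement: honour explicit genome_start, else spread evenly.
    total = sum(len(ins) for _, ins, _, _ in built)
    auto = [i for i, (cp, _, _, _) in enumerate(built) if cp.genome_start is None]
    if total + (len(built) + 1) * min_spacing > genome_len and built:
        raise ValueError("copies do not fit in the scaffold with required spacing")
    placements: list[tuple[int, int, int]] = []  # (insert_start0, insert_end0, idx)
    if auto:
        free = genome_len - total
        gap = free // (len(built) + 1)
        cursor = gap
        for i, (cp, ins, _, _) in enumerate(built):
            if cp.genome_start is not None:
                cursor = cp.genome_start - 1
            placements.append((cursor, cursor + len(ins), i))
            cursor += len(ins) + gap
    else:
        for i, (cp, ins, _, _) in enumerate(built):
            start0 = cp.genome_start - 1
            placements.append((start0, start0 + len(ins), i))
    placements.sort()
    prev_end = -min_spacing
    for s0, e0, _ in placements:
        if s0 < prev_end + min_spacing:
            raise ValueError("planted inserts overlap or violate minimum spacing")
        if e0 > genome_len:
            raise ValueError("planted insert extends past the scaffold end")
        prev_end = e0

    rows = []
    for s0, e0, i in placements:
        cp, insert, copy_len, n_sub = built[i]
        genome[s0:e0] = insert
        tsd_len = len(cp.tsd or "")
        copy_start0 = s0 + tsd_len + len(cp.flank5_motif)
        rows.append(
            {
                "locus_id": f"copy_{i + 1}",
                "scaffold_id": scaffold_id,
                "start": copy_start0 + 1,
                "end": copy_start0 + copy_len,
                # element bounds exclude the TSD copies, which sit
                # immediately outside the insert as in a real integration
                "insert_start": s0 + tsd_len + 1,
                "insert_end": e0 - tsd_len,
                "strand": cp.strand,
                "transcript_start": cp.transcript_start,
                "transcript_end": cp.transcript_end,
                "exons_covered": _exons_covered(model, cp.transcript_start, cp.transcript_end),
                "copy_class": _classify(model, cp.transcript_start, cp.transcript_end),
                "tsd": cp.tsd or "",
                "n_substitutions": n_sub,
            }
        )
    truth = pd.DataFrame(rows, columns=LOCUS_TRUTH_COLUMNS)
    return {scaffold_id: "".join(genome)}, truth


# Synthetic LTR gag-fragment flank motifs for the scaffold preset.  These are
# fixture sequences standing in for the conserved retrotransposon fragments
# that flank the real copies; only the conserved 34-bp element and the TSD
# are published motifs.
SYNTHETIC_LTR1_FRAGMENT = "GATTACCGCTAGGTTCAGCCAATGACGTTGAA"
SYNTHETIC_LTR2_FRAGMENT = "CCTAGTTGACAAGGCTTCAGTAACGGATTCGA"

#: Transcript interval of the long copies in the default model: 326 nt from
#: partial exon 4 into exon 7.
DEFAULT_LONG_SPAN = (660, 985)
#: Short copies share the same 5' end and stop within exon 6 (192 nt core).
DEFAULT_SHORT_SPAN = (660, 851)


def default_retrocopy_plants(divergence: float = 0.02) -> list[RetrocopyPlant]:
    """The two-cluster preset: 4 short minus-strand + 7 long plus-strand copies.

    Mirrors the published arrangement: eleven tandemly arranged copies in two
    divergently oriented clusters, each flanked by LTR-fragment motifs, with
    the 10-bp target-site duplication outside the flanks.
    """
    short = [
        RetrocopyPlant(
            *DEFAULT_SHORT_SPAN,
            strand="-",
            flank5_motif=SYNTHETIC_LTR2_FRAGMENT,
            flank3_motif=SYNTHETIC_LTR1_FRAGMENT,
            tsd=motifs.TSD_10BP,
            divergence=divergence,
        )
        for _ in range(4)
    ]
    long = [
        RetrocopyPlant(
            *DEFAULT_LONG_SPAN,
            strand="+",
            flank5_motif=motifs.CONSERVED_34BP,
            flank3_motif=SYNTHETIC_LTR1_FRAGMENT,
            tsd=motifs.TSD_10BP,
            divergence=divergence,
        )
        for _ in range(7)
    ]
    return short + long


# ---------------------------------------------------------------------------
# Reporter assay
# ---------------------------------------------------------------------------


def simulate_assay_table(
    n_f: int,
    n_m: int,
    effect: float = 1.5,
    cv: float = 0.6,
    seed: int = 0,
    nanoluc_mean: float = 500.0,
    firefly_mean: float = 1000.0,
) -> pd.DataFrame:
    """Per-embryo dual-reporter readings with a female nanoluc shift.

    Firefly (normalisation control) and nanoluciferase readings are drawn
    log-normally with coefficient of variation ``cv``; the female nanoluc
    mean is multiplied by ``effect`` (cleavage of the tagged transcript in
    females increases translation).  ``effect=1.0`` simulates the null.
    """
    if n_f < 2 or n_m < 2:
        raise ValueError("need at least 2 embryos per group")
    if cv <= 0:
        raise ValueError("cv must be positive")
    if effect <= 0:
        raise ValueError("effect must be positive")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2))

    def draw(mean: float, n: int) -> np.ndarray:
        mu = math.log(mean) - sigma**2 / 2.0
        return rng.lognormal(mu, sigma, size=n)

    rows = []
    for group, n, nl_mean in (("F", n_f, nanoluc_mean * effect), ("M", n_m, nanoluc_mean)):
        nano = draw(nl_mean, n)
        fire = draw(firefly_mean, n)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}{i + 1:03d}",
                    "group": group,
                    "nanoluc": float(nano[i]),
                    "firefly": float(fire[i]),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "group", "nanoluc", "firefly"])
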