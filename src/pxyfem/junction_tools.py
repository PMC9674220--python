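"""Junction archaeology: repeats, switch-point microhomology, TSD search.

Three sequence primitives used to reconstruct how a retroelement insertion
arose: the longest repeated substring (tandem-duplication detector), the
microhomology shared by two donor templates at a reverse-transcriptase
switch point, and the direct repeat (target-site duplication) flanking an
insertion.  All searches are case-insensitive and N never matches anything,
including another N.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "JunctionReport",
    "longest_repeated_substring",
    "switch_point_microhomology",
    "find_target_site_duplication",
]


@dataclass(frozen=True)
class JunctionReport:
    """A motif found by one of the junction analyses.

    ``positions`` are 1-based start positions within the searched sequence.
    The donor mismatch counts are populated in microhomology mode only.
    """

    motif: str
    length: int
    positions: tuple[int, ...]
    mismatches_to_donorA: int | None = None
    mismatches_to_donorB: int | None = None

    def as_dict(self) -> dict:
        d = {
            "motif": self.motif,
            "length": self.length,
            "positions": list(self.positions),
        }
        if self.mismatches_to_donorA is not None:
            d["mismatches_to_donorA"] = self.mismatches_to_donorA
            d["mismatches_to_donorB"] = self.mismatches_to_donorB
        return d


def _mask_n(seq: str) -> str:
    """Give each N a unique sentinel so it matches nothing, itself included."""
    out = []
    for i, c in enumerate(seq):
        out.append(chr(0x100 + i) if c == "N" else c)
    return "".join(out)


def longest_repeated_substring(seq: str) -> tuple[str, int, tuple[int, ...]]:
    """Longest substring occurring at >= 2 distinct start positions.

    Overlapping occurrences count (standard LRS); ties between equally long
    repeats are broken by the left-most first occurrence.  Returns
    ``(unit, length, positions)`` with 1-based start positions of every
    (possibly overlapping) occurrence, or ``("", 0, ())`` when the sequence
    has no repeated substring.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = _mask_n(seq.upper())
    n = len(s)
    # Suffix array by plain sort (n <= a few kb in practice), then adjacent LCP.
    order = sorted(range(n), key=lambda i: s[i:])
    lcps = []
    best_len = 0
    for a, b in zip(order, order[1:]):
        sa, sb = s[a:], s[b:]
        lcp = 0
        m = min(len(sa), len(sb))
        while lcp < m and sa[lcp] == sb[lcp]:
            lcp += 1
        lcps.append((lcp, a, b))
        best_len = max(best_len, lcp)
    if best_len == 0:
        return "", 0, ()
    # Among maximal repeats, prefer the one whose first occurrence is left-most.
    best_start = min(
        s.find(s[a : a + best_len]) for lcp, a, b in lcps if lcp == best_len
    )
    unit_masked = s[best_start : best_start + best_len]
    unit = seq.upper()[best_start : best_start + best_len]
    positions = []
    i = s.find(unit_masked)
    while i != -1:
        positions.append(i + 1)
        i = s.find(unit_masked, i + 1)
    return unit, best_len, tuple(positions)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _longest_exact_core(w: str, da: str, db: str) -> int:
    """Longest stretch of the window matching both donor windows exactly."""
    best = run = 0
    for x, y, z in zip(w, da, db):
        if x == y == z:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def switch_point_microhomology(
    chimera: str,
    junction: int,
    donorA_end: str,
    donorB_start: str,
    max_len: int = 20,
    max_mismatch_per_donor: int = 0,
) -> JunctionReport:
    """Microhomology between two donors at the switch point of a chimera.

    ``junction`` is the 1-based position of the last donor-A-derived base of
    the chimera.  The search considers every window of length <= ``max_len``
    that touches the junction boundary (a microhomology makes the exact
    switch position ambiguous, so windows ending at the junction or starting
    just after it qualify) and requires the window to match both the 3' end
    of donor A and the 5' start of donor B with at most
    ``max_mismatch_per_donor`` substitutions each.  The longest window wins;
    ties prefer a longer exact core, then fewer total mismatches, then the
    left-most window.  A zero-length report means no microhomology.
    """
    if not donorA_end or not donorB_start:
        raise ValueError("donors must be non-empty")
    chim = _mask_n(chimera.upper())
    da = _mask_n(donorA_end.upper())
    db = _mask_n(donorB_start.upper())
    n = len(chim)
    if not (1 <= junction < n):
        raise ValueError(f"junction {junction} must lie strictly inside the chimera")

    best: tuple[int, int, int, int] | None = None  # (k, exact_core, -total_mm, -a) maximised
    best_report: JunctionReport | None = None
    k_cap = min(max_len, len(da), len(db))
    for k in range(1, k_cap + 1):
        # 1-based window [a, a+k-1]; touching the boundary between
        # junction and junction+1 means a <= junction + 1 and a+k-1 >= junction.
        for a in range(max(1, junction - k + 1), min(junction + 1, n - k + 1) + 1):
            w = chim[a - 1 : a + k - 1]
            mm_a = _hamming(w, da[-k:])
            if mm_a > max_mismatch_per_donor:
                continue
            mm_b = _hamming(w, db[:k])
            if mm_b > max_mismatch_per_donor:
                continue
            core = _longest_exact_core(w, da[-k:], db[:k])
            key = (k, core, -(mm_a + mm_b), -a)
            if best is None or key > best:
                best = key
                best_report = JunctionReport(
                    motif=chimera.upper()[a - 1 : a + k - 1],
                    length=k,
                    positions=(a,),
                    mismatches_to_donorA=mm_a,
                    mismatches_to_donorB=mm_b,
                )
    if best_report is None:
        return JunctionReport(motif="", length=0, positions=(),
                              mismatches_to_donorA=None, mismatches_to_donorB=None)
    return best_report


def find_target_site_duplication(
    scaffold: str,
    insert_start: int,
    insert_end: int,
    k_min: int = 6,
    k_max: int = 20,
) -> JunctionReport | None:
    """Direct repeat immediately flanking an insertion.

    Looks for the longest k in [k_min, k_max] such that the k-mer ending
    immediately 5' of ``insert_start`` equals the k-mer beginning immediately
    3' of ``insert_end`` (both 1-based inclusive).  Returns ``None`` when no
    such repeat exists.  Requires at least ``k_max`` flanking bases on each
    side.
    """
    if not (1 <= insert_start <= insert_end <= len(scaffold)):
        raise ValueError("insert interval outside the scaffold")
    if insert_start - 1 < k_max or len(scaffold) - insert_end < k_max:
        raise ValueError(f"need at least k_max={k_max} flanking bases on each side")
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    s = _mask_n(scaffold.upper())
    for k in range(k_max, k_min - 1, -1):
        left = s[insert_start - 1 - k : insert_start - 1]
        right = s[insert_end : insert_end + k]
        if left == right:
            return JunctionReport(
                motif=scaffold.upper()[insert_start - 1 - k : insert_start - 1],
                length=k,
                positions=(insert_start - k, insert_end + 1),
            )
    return None
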