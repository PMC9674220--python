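# Methods

This note documents the models and conventions implemented in `pxyfem`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Coordinate and strand conventions

All intervals are 1-based inclusive. Alignments are always reported on the
target's forward coordinate system; a read is *sense* if it matches the
target directly and *antisense* if its reverse complement does. An
antisense read's 5' end is therefore its `end` coordinate. Exon–exon
junction positions are the cumulative sums of exon lengths, i.e. the last
base of each internal exon. BED output converts to the standard 0-based
half-open convention. The internal alphabet is DNA; logo writers may render
U for T.

## Transcript model

The default "Masc-like" preset is a seeded random transcript of 1250 nt in
7 exons (200, 150, 180, 160, 140, 120, 300), with a 120-nt 5' UTR, a 200-nt
3' UTR, and a motif window (815–850) straddling the exon 5–6 junction at
position 830 — the analogue of the conserved cysteine–cysteine domain over
which silencing reads concentrate. The exon sizes were chosen so that a
326-nt copy starting in exon 4 reaches into exon 7 (the "long" copy class)
while a 192-nt copy with the same 5' end stops inside exon 6 ("short"),
matching the published copy architecture.

## Small-RNA library generator

Each ping-pong pair is produced by slicer geometry: an antisense guide
whose 5' end sits at forward coordinate *e* (sampled inside the hotspot,
default = motif window) directs cleavage of the sense strand across from
its 10th/11th nucleotides, so the sense responder starts at *e* − 9. The
10-nt 5'-overlap and the sense 10A are consequences of the mechanism, not
planted values: the responder's 10th base is the base-pairing partner of
the guide's first. Because of that physical linkage, in slicer mode one
Bernoulli draw per pair (probability `bias_1U`, default 0.9) decides
whether the guide 5' base is U — which simultaneously fixes the responder's
position-10 A. The separate `bias_10A` knob only acts in the decoupled
(`slicer=False`) mode where sense reads are placed independently.

Each responder spawns a head-to-tail phased read immediately downstream
with probability `phased_trail_prob` (default 0.3). Background reads are
uniform over transcript and strand; their sizes mix the piRNA (25–30 nt)
and siRNA (21–24 nt) classes with `frac_pirna` = 0.7. *Decoy* reads are
random off-target sequence; they are zero by default and serve as the
constant library-size anchor in the time course (a library with no
target-derived reads must still have a defined RPM denominator). Reads are
emitted adapter-ligated — insert + 3' adapter + random filler, truncated to
a 50-nt read — with constant Q=35 qualities (a `low_quality_frac` knob
injects reads with mean Q≈10 for preprocessing tests), in seeded shuffled
order with opaque ids. Identical spec + seed gives byte-identical FASTQ.

Default pair and background counts (500 / 100) put the library in the
regime where the overlap spectrum, biases and density peak are stable; the
time-course preset scales target-derived reads by (0, 0.25, 0.5, 1.0, 0.3)
at 3/6/9/12/24 h over 2000 constant decoys.

What the generator does *not* emulate: sequencing errors, instrument
artifacts, PCR duplicates, multi-chromosome genomes, or a realistic
off-target transcriptome (backgrounds are uniform by design). Passing tests
therefore demonstrate correctness of the statistics and recovery logic
under clean composition, not robustness to real library noise.

## Preprocessing

The 3' adapter is located as the left-most position where a prefix of the
adapter matches with minimum overlap 8 nt and at most one mismatch per 8 nt
of overlap; every overlap length is checked at each position, which makes
trimming idempotent. Any 5'-adapter suffix at the read start is removed the
same way, to a fixpoint. The quality rule is mean Phred < 20 by default
(per-base-minimum mode available); the size window defaults to 20–40 nt.
Counters satisfy input = output + dropped_quality + dropped_size on every
input.

## Mapper

A read maps where it (or its reverse complement) matches the target with at
most `max_mismatch` substitutions (default 0); indels are not modelled, and
N never matches any base. Among equally-best hits the left-most is
reported, sense preferred on an exact positional tie, with `n_hits`
recording the tie count. The implementation compares encoded reads against
sliding windows of the target and caches results per distinct read
sequence; it is verified against an exhaustive O(L·n) scan in the tests.

## Signature statistics

The ping-pong overlap between sense read *s* and antisense read *a* is
`a.end − s.start + 1` — the number of bases shared between the two 5' ends
measured in forward coordinates (equivalently, the "3' overlap" of the
reads drawn on opposite strands). Every sense×antisense pair on the same
target with overlap in [1, 25] is counted once. z10 standardises the
overlap-10 bin against the other 24 bins of the same spectrum (no
resampling); it is reported as absent when fewer than two background bins
are nonzero or their spread is zero. z10 is a z-score only asymptotically:
with few reads the bin counts are small and the statistic is overdispersed
(empirically sd ≈ 1.1 at a few hundred reads), so null-calibration checks
are run on 2000-read uniform libraries, where each bin holds ~250 pairs and
|z10| < 2 in ≥95% of seeds.

Phasing is the gap between consecutive same-strand reads ordered by 5'
position along their own strand (0 = perfectly head-to-tail), counted over
[−10, 30]. The biases are the fraction of antisense reads whose own first
base is T (1U) and of sense reads whose tenth base is A (10A). RPM is
count × 10⁶ / library total.

## Retrocopy scanner

Exact 12-mers of the spliced transcript (both orientations) are hashed;
genome hits are grouped by diagonal, chained (max seed gap 60 nt) and
extended gap-free with an X-drop rule (match +1, mismatch −3, drop 6,
trimmed to the maximum score). A candidate becomes a locus only if it spans
at least one exon–exon junction with ≥15 aligned nt on each side — the
defining evidence that the copy derives from spliced mRNA — and its overall
identity is ≥85%. Overlapping same-strand candidates keep the best score.
With ≤5% divergence this recovers planted copies with correct strand and
class and no false positives on a megabase of random sequence
(12-mer seeding plus the junction-arm requirement makes chance acceptance
vanishingly rare).

Boundary precision is statistical: a flanking base that coincidentally
continues the transcript is indistinguishable from a longer copy, so
reported coordinates are typically within ±2 nt of the planted truth with a
small tail (~2% per end) of larger deviations. Mirroring that, the
generator never mutates the terminal 4 nt of a planted copy (nor 2 nt
around each junction), the same recoverability rationale in both cases.

Classification follows the copy architecture: *long* if coverage extends
into exon 7, *short* if it ends within exon 6, *other* otherwise. Clusters
merge same-strand loci within 50 kb; a strand flip always splits. Pairwise
identity is computed gap-free over a shared core region anchored on
transcript coordinates (positions a locus does not cover are padded and
count as mismatches, so a trimmed boundary costs a few columns instead of
shifting the frame); the summary is mean ± SE against the reference core
and the mean over all locus pairs.

## Junction tools

The longest-repeated-substring finder uses a suffix sort with adjacent-LCP
(overlapping occurrences allowed; ties broken by left-most first
occurrence) and is property-tested against an O(n²) dynamic-programming
oracle. Switch-point microhomology searches every window (≤20 nt) touching
the junction boundary for a match to both the 3' end of donor A and the 5'
start of donor B within the per-donor mismatch budget; ties prefer the
longer window, then a longer exact core, then fewer total mismatches. The
TSD finder returns the longest k in [6, 20] with identical k-mers
immediately outside the insertion. All three are case-insensitive and give
each N a unique sentinel so it matches nothing, itself included.

## Reporter statistics

Per-embryo nanoluciferase is normalised by the firefly reading of the same
embryo; rows with non-positive firefly readings cannot be normalised and
are excluded with an explicit log. The default test is the pooled-variance
Student t (two-tailed, df = n₁ + n₂ − 2, matching the published degrees of
freedom); Welch is available behind a flag. The assay simulator draws both
reporters log-normally with a common coefficient of variation and
multiplies the female nanoluciferase mean by `effect` (default 1.5,
cv = 0.6 — noise typical of single-embryo readouts). Under the null the
test is exactly calibrated for near-normal ratios (empirical type-I 0.048
at cv = 0.4 over 2000 replicates); under strongly skewed ratio noise the
Student t is conservative (≈0.04 at cv = 0.6), a known property of the
statistic rather than of this implementation.

## Numerical and degenerate-input choices

Empty alignment sets yield all-zero histograms and spectra rather than
errors; an absent strand yields an absent bias; `base_frequency_matrix`
returns an empty-result signal (None) when nothing matches. Zero pooled
variance, empty targets, malformed FASTQ records, out-of-range hotspots and
overlapping planted inserts raise with messages naming the offending input.
Scaffold backgrounds use a salted seed stream so a scaffold and a
transcript built from the same integer seed are independent.

## Limitations

The mapper is transcript-scale (no indexing suitable for whole genomes) and
ungapped, as is the retrocopy extension — indel-bearing copies would be
truncated at the indel. The scanner's identity is measured over its own
gap-free alignment, so it is not comparable to gapped-aligner identities on
diverged copies. Downstream-processing (Zucchini-pathway) modelling, miRNA
annotation, genome-wide piRNA cluster calling and phylogenies of the copies
are out of scope.
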