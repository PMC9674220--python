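"""Signature statistics: histograms, biases, ping-pong, phasing, RPM."""

import numpy as np
import pytest

from pxyfem import (
    LibrarySpec,
    bias_1U_10A,
    default_transcript_model,
    normalize_rpm,
    phasing_spectrum,
    pingpong_spectrum,
    positional_density,
    simulate_small_rna_library,
    strand_size_histogram,
    revcomp,
)
from pxyfem.preprocess import preprocess_reads
from pxyfem.signatures import base_frequency_matrix, reads_as_dict
from pxyfem.srna_map import AlignmentRecord, map_reads


def aln(rid, start, end, strand, target="t"):
    return AlignmentRecord(rid, target, start, end, strand, 0)


class TestHistogram:
    def test_sense_antisense_totals(self):
        """Strand split mirrors the female L1 library: 12 sense, 26 antisense."""
        rng = np.random.default_rng(0)
        records = []
        for i in range(12):
            k = int(rng.integers(21, 31))
            records.append(aln(f"s{i}", 100, 99 + k, "sense"))
        for i in range(26):
            k = int(rng.integers(21, 31))
            records.append(aln(f"a{i}", 200, 199 + k, "antisense"))
        h = strand_size_histogram(records)
        assert h["sense"].sum() == 12
        assert h["antisense"].sum() == 26

    def test_empty_input(self):
        h = strand_size_histogram([])
        assert h.values.sum() == 0

    def test_total_conservation(self):
        rng = np.random.default_rng(3)
        records = [
            aln(f"r{i}", 1, int(rng.integers(20, 41)), "sense" if rng.random() < 0.5 else "antisense")
            for i in range(157)
        ]
        assert strand_size_histogram(records).values.sum() == 157


class TestPositionalDensity:
    def test_single_alignment_block(self):
        d = positional_density([aln("r", 100, 127, "sense")], 200)
        assert d["sense"].loc[100:127].eq(1).all()
        assert d["sense"].sum() == 28
        assert d["antisense"].sum() == 0

    def test_total_equals_sum_of_read_lengths(self):
        rng = np.random.default_rng(5)
        records = []
        for i in range(60):
            s = int(rng.integers(1, 150))
            records.append(aln(f"r{i}", s, s + int(rng.integers(19, 40)), "antisense"))
        d = positional_density(records, 200)
        assert d.values.sum() == sum(a.length for a in records)

    def test_out_of_range_alignment_raises(self):
        with pytest.raises(ValueError):
            positional_density([aln("r", 190, 215, "sense")], 200)

    def test_hotspot_library_peaks_in_motif_window(self, model, pingpong_library):
        d = positional_density(pingpong_library["alignments"], model.length)
        peak = int(d["antisense"].idxmax())
        lo, hi = model.motif_window
        assert lo <= peak <= hi


class TestBaseMatrix:
    def test_antisense_all_start_with_t(self):
        reads = {"a": "TGCAGGTACGTACGTACGTAC", "b": "TTTACGTACGTACGTACGTAC"}
        records = [aln("a", 10, 30, "antisense"), aln("b", 50, 70, "antisense")]
        m = base_frequency_matrix(records, reads, "antisense", 21)
        assert m.loc["T", 1] == 1.0

    def test_columns_sum_to_one(self, pingpong_library):
        reads = reads_as_dict(pingpong_library["preprocessed"])
        m = base_frequency_matrix(pingpong_library["alignments"], reads, "sense", 27)
        if m is not None:
            np.testing.assert_allclose(m.sum(axis=0), 1.0)

    def test_no_matching_alignments_returns_none(self):
        assert base_frequency_matrix([], {}, "sense", 25) is None

    def test_bias_parameter_recovered_in_logo(self, model):
        spec = LibrarySpec(n_pingpong_pairs=2000, n_background=0, bias_1U=0.9, seed=31)
        reads, truth = simulate_small_rna_library(model, spec)
        pre, _ = preprocess_reads(reads)
        alignments, _ = map_reads(pre, model)
        rd = reads_as_dict(pre)
        u_freq = []
        for length in range(25, 31):
            m = base_frequency_matrix(alignments, rd, "antisense", length)
            if m is not None:
                n = sum(
                    1 for a in alignments if a.strand == "antisense" and a.length == length
                )
                u_freq.append((m.loc["T", 1], n))
        pooled = sum(f * n for f, n in u_freq) / sum(n for _, n in u_freq)
        assert pooled == pytest.approx(0.9, abs=0.05)


class TestBias:
    def test_all_antisense_start_t(self):
        reads = {"a": "TGCAGGTACGTACGTACGTAC", "b": "TTTACCGTACGTACGTACGTA"}
        records = [aln("a", 1, 21, "antisense"), aln("b", 30, 50, "antisense")]
        b1u, b10a = bias_1U_10A(records, reads)
        assert b1u == 1.0 and b10a is None

    def test_sense_10a_fraction(self):
        reads, records = {}, []
        for i in range(10):
            base = "A" if i < 7 else "G"
            seq = "CCCCCCCCC" + base + "C" * 15
            reads[f"r{i}"] = seq
            records.append(aln(f"r{i}", 1, 25, "sense"))
        _, b10a = bias_1U_10A(records, reads)
        assert b10a == pytest.approx(0.7)

    def test_pingpong_library_biases_exceed_background(self, pingpong_library):
        rd = reads_as_dict(pingpong_library["preprocessed"])
        b1u, b10a = bias_1U_10A(pingpong_library["alignments"], rd)
        assert b1u > 0.25 and b10a > 0.25


class TestPingPong:
    def test_constructed_overlap_of_ten(self):
        records = [aln("s", 100, 127, "sense"), aln("a", 81, 109, "antisense")]
        res = pingpong_spectrum(records)
        assert res.spectrum[10] == 1
        assert sum(res.spectrum.values()) == 1
        assert res.z10 is None  # no nonzero background bins

    def test_no_antisense_reads(self):
        res = pingpong_spectrum([aln("s", 100, 127, "sense")])
        assert all(v == 0 for v in res.spectrum.values())
        assert res.z10 is None and res.n_pairs == 0

    def test_all_pairs_oracle(self):
        """Spectrum equals the exhaustive double loop over sense x antisense."""
        rng = np.random.default_rng(13)
        records = []
        for i in range(200):
            s = int(rng.integers(1, 400))
            records.append(
                aln(f"r{i}", s, s + int(rng.integers(19, 31)),
                    "sense" if rng.random() < 0.5 else "antisense")
            )
        res = pingpong_spectrum(records)
        expected = {k: 0 for k in range(1, 26)}
        for a in records:
            for b in records:
                if a.strand == "sense" and b.strand == "antisense":
                    ov = b.end - a.start + 1
                    if 1 <= ov <= 25:
                        expected[ov] += 1
        assert res.spectrum == expected

    def test_slicer_library_modal_overlap_and_z(self, pingpong_library):
        res = pingpong_spectrum(pingpong_library["alignments"])
        assert res.modal_overlap() == 10
        assert res.z10 > 3


class TestPhasing:
    def test_head_to_tail_distance_zero(self):
        records = [aln("a", 100, 127, "sense"), aln("b", 128, 155, "sense")]
        assert phasing_spectrum(records, "sense")[0] == 1

    def test_single_read_empty_spectrum(self):
        counts = phasing_spectrum([aln("a", 100, 127, "sense")], "sense")
        assert all(v == 0 for v in counts.values())

    def test_antisense_mirrored(self):
        records = [aln("a", 100, 127, "antisense"), aln("b", 72, 99, "antisense")]
        assert phasing_spectrum(records, "antisense")[0] == 1

    def test_phased_trail_modal_distance_zero(self, model):
        # sparse library: pairs spread widely so each responder's phased
        # trail is its nearest downstream sense neighbour
        spec = LibrarySpec(
            n_pingpong_pairs=25, n_background=0, phased_trail_prob=0.9,
            hotspot=(40, 1180), seed=2,
        )
        reads, _ = simulate_small_rna_library(model, spec)
        pre, _ = preprocess_reads(reads)
        alignments, _ = map_reads(pre, model)
        counts = phasing_spectrum(alignments, "sense")
        assert max(counts, key=counts.get) == 0


class TestRPM:
    def test_zero_count(self):
        assert normalize_rpm(0, 1000) == 0.0

    def test_worked_example(self):
        # 38 target-mapping reads out of 3,328,300 total
        assert normalize_rpm(38, 3_328_300) == pytest.approx(11.4172, abs=5e-5)

    def test_linearity(self):
        assert normalize_rpm(24, 7919) == pytest.approx(2 * normalize_rpm(12, 7919))

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_rpm(5, 0)


def test_revcomp_equivariance(model):
    """Re-mapping against the reverse-complemented target swaps every
    strand label: the size histogram columns exchange, the density mirrors,
    and the ping-pong spectrum is unchanged."""
    spec = LibrarySpec(n_pingpong_pairs=120, n_background=60, seed=23)
    reads, _ = simulate_small_rna_library(model, spec)
    pre, _ = preprocess_reads(reads)
    fwd, _ = map_reads(pre, model)
    rev, _ = map_reads(pre, ("flipped", revcomp(model.sequence)))
    h_fwd, h_rev = strand_size_histogram(fwd), strand_size_histogram(rev)
    assert h_fwd["sense"].equals(h_rev["antisense"])
    assert h_fwd["antisense"].equals(h_rev["sense"])
    d_fwd = positional_density(fwd, model.length)
    d_rev = positional_density(rev, model.length)
    assert list(d_fwd["sense"]) == list(d_rev["antisense"][::-1])
    assert pingpong_spectrum(fwd).spectrum == pingpong_spectrum(rev).spectrum
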