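"""Generator contracts: architecture arithmetic, determinism, truth labels."""

import numpy as np
import pandas as pd
import pytest

from pxyfem import (
    LibrarySpec,
    RetrocopyPlant,
    default_retrocopy_plants,
    default_transcript_model,
    make_transcript_model,
    plant_retrocopy_scaffold,
    simulate_assay_table,
    simulate_small_rna_library,
    simulate_time_course,
    revcomp,
)
from pxyfem.io import write_fastq
from pxyfem.synthetic_data import DEFAULT_SHORT_SPAN, TranscriptModel


class TestTranscriptModel:
    def test_junctions_are_cumulative_exon_sums(self):
        m = make_transcript_model(
            [200, 150, 180, 160, 140, 170, 300], 100, 200, (700, 900), seed=0
        )
        assert m.length == 1300
        assert m.junctions == (200, 350, 530, 690, 830, 1000)

    def test_default_preset_motif_straddles_exon5_6_junction(self, model):
        assert len(model.exon_lengths) == 7
        j56 = model.junctions[4]
        lo, hi = model.motif_window
        assert lo <= j56 <= hi

    @pytest.mark.parametrize("lengths", [[0, 100], [100, -5], [100]])
    def test_degenerate_exon_architecture_rejected(self, lengths):
        with pytest.raises(ValueError):
            make_transcript_model(lengths, 10, 10, (1, 50), seed=0)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):  # exon sum mismatch
            TranscriptModel("x", "ACGT" * 10, (10, 20), 0, 0, (1, 10))
        with pytest.raises(ValueError):  # UTRs cover everything
            TranscriptModel("x", "ACGT" * 10, (20, 20), 30, 30, (1, 10))
        with pytest.raises(ValueError):  # motif window outside
            TranscriptModel("x", "ACGT" * 10, (20, 20), 0, 0, (35, 45))

    def test_exon_lookup(self, model):
        start5, end5 = model.exon_bounds(5)
        assert model.exon_of(start5) == 5
        assert model.exon_of(end5) == 5
        assert end5 == model.junctions[4]


class TestLibrary:
    def test_empty_spec_gives_empty_library(self, model):
        reads, truth = simulate_small_rna_library(
            model, LibrarySpec(n_pingpong_pairs=0, n_background=0, seed=0)
        )
        assert reads == [] and truth.empty

    def test_fixed_seed_is_byte_identical(self, model, tmp_path):
        spec = LibrarySpec(n_pingpong_pairs=50, n_background=20, seed=9)
        paths = []
        for i in range(2):
            reads, truth = simulate_small_rna_library(model, spec)
            p = tmp_path / f"lib{i}.fastq"
            write_fastq(reads, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_truth_completeness_and_composition(self, model):
        spec = LibrarySpec(n_pingpong_pairs=80, n_background=30, n_decoy=40, seed=4)
        reads, truth = simulate_small_rna_library(model, spec)
        assert len(truth) == len(reads)
        assert set(truth.read_id) == {r.id for r in reads}
        counts = truth.origin.value_counts()
        assert counts["pingpong_guide"] == 80
        assert counts["pingpong_responder"] == 80
        assert counts["background"] == 30
        assert counts["decoy"] == 40

    def test_slicer_geometry_links_guide_and_responder(self, model):
        reads, truth = simulate_small_rna_library(
            model, LibrarySpec(n_pingpong_pairs=30, n_background=0, seed=2)
        )
        guides = truth[truth.origin == "pingpong_guide"].reset_index()
        resp = truth[truth.origin == "pingpong_responder"].reset_index()
        # emission order is shuffled; recover pairing via the geometry itself
        assert sorted(resp.start) == sorted(g - 9 for g in guides.end)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            LibrarySpec(bias_1U=1.5)
        with pytest.raises(ValueError):
            LibrarySpec(pirna_size_range=(25, 45))

    def test_hotspot_outside_transcript_raises(self, model):
        spec = LibrarySpec(hotspot=(1200, 1400), seed=0)
        with pytest.raises(ValueError):
            simulate_small_rna_library(model, spec)

    def test_low_quality_knob_produces_droppable_reads(self, model):
        from pxyfem.preprocess import preprocess_reads

        spec = LibrarySpec(
            n_pingpong_pairs=20, n_background=0, low_quality_frac=1.0, seed=3
        )
        reads, _ = simulate_small_rna_library(model, spec)
        _, stats = preprocess_reads(reads)
        assert stats.dropped_quality == stats.input_count
        assert stats.output_count == 0


class TestTimeCourse:
    def test_zero_scale_has_no_target_reads(self, model):
        base = LibrarySpec(n_pingpong_pairs=100, n_background=50, seed=0)
        out = simulate_time_course(model, base, [("3h", 0.0)], seed=5)
        label, reads, truth = out[0]
        assert label == "3h"
        assert (truth.origin == "decoy").all()
        assert len(reads) > 0  # library itself is not empty

    def test_negative_scale_rejected(self, model):
        base = LibrarySpec(seed=0)
        with pytest.raises(ValueError):
            simulate_time_course(model, base, [("bad", -0.5)], seed=0)

    def test_fixed_seed_reproducible(self, model):
        base = LibrarySpec(n_pingpong_pairs=40, n_background=10, seed=0)
        a = simulate_time_course(model, base, seed=8)
        b = simulate_time_course(model, base, seed=8)
        for (la, ra, ta), (lb, rb, tb) in zip(a, b):
            assert la == lb and ra == rb
            pd.testing.assert_frame_equal(ta, tb)


class TestScaffold:
    def test_no_copies_gives_random_scaffold_and_empty_truth(self, model):
        genome, truth = plant_retrocopy_scaffold(5000, model, [], seed=1)
        (seq,) = genome.values()
        assert len(seq) == 5000 and truth.empty

    def test_minus_strand_copy_truth(self, model):
        # partial exon 4 through full exon 6
        cp = RetrocopyPlant(600, model.exon_bounds(6)[1], strand="-")
        genome, truth = plant_retrocopy_scaffold(3000, model, [cp], seed=2)
        row = truth.iloc[0]
        assert row.strand == "-"
        assert row.exons_covered == "4*,5,6"
        (seq,) = genome.values()
        planted = seq[row.start - 1 : row.end]
        assert revcomp(planted) == model.sequence[599 : model.exon_bounds(6)[1]]

    def test_overlapping_plants_rejected(self, model):
        cps = [
            RetrocopyPlant(*DEFAULT_SHORT_SPAN, genome_start=500),
            RetrocopyPlant(*DEFAULT_SHORT_SPAN, genome_start=600),
        ]
        with pytest.raises(ValueError):
            plant_retrocopy_scaffold(5000, model, cps, seed=0)

    def test_tsd_written_immediately_outside_flanks(self, model):
        cp = RetrocopyPlant(
            *DEFAULT_SHORT_SPAN, flank5_motif="GGCC", flank3_motif="TTAA", tsd="ACACAAGGCT"
        )
        genome, truth = plant_retrocopy_scaffold(3000, model, [cp], seed=3)
        (seq,) = genome.values()
        row = truth.iloc[0]
        left = seq[row.insert_start - 11 : row.insert_start - 1]
        right = seq[row.insert_end : row.insert_end + 10]
        assert left == right == "ACACAAGGCT"

    def test_default_preset_composition(self, model):
        _, truth = plant_retrocopy_scaffold(
            15000, model, default_retrocopy_plants(), seed=0
        )
        assert len(truth) == 11
        assert (truth.copy_class == "long").sum() == 7
        assert (truth.copy_class == "short").sum() == 4
        assert set(truth[truth.copy_class == "short"].strand) == {"-"}
        assert set(truth[truth.copy_class == "long"].strand) == {"+"}


class TestAssay:
    def test_fixed_seed_identical_table(self):
        a = simulate_assay_table(10, 10, seed=6)
        b = simulate_assay_table(10, 10, seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_group_sizes(self):
        t = simulate_assay_table(24, 35, seed=0)
        assert (t.group == "F").sum() == 24
        assert (t.group == "M").sum() == 35
        assert (t.firefly > 0).all() and (t.nanoluc > 0).all()

    @pytest.mark.parametrize("nf,nm", [(1, 10), (10, 1)])
    def test_tiny_groups_rejected(self, nf, nm):
        with pytest.raises(ValueError):
            simulate_assay_table(nf, nm, seed=0)

    def test_effect_shifts_female_nanoluc(self):
        null = simulate_assay_table(2000, 2000, effect=1.0, cv=0.3, seed=1)
        shifted = simulate_assay_table(2000, 2000, effect=2.0, cv=0.3, seed=1)
        f_null = null[null.group == "F"].nanoluc.mean()
        f_shift = shifted[shifted.group == "F"].nanoluc.mean()
        assert f_shift / f_null == pytest.approx(2.0, rel=0.05)
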