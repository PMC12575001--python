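"""Window planning, track prediction, BED calls, and variant scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spliceworks.genomics_io import (
    GeneModel,
    GenomeSequence,
    Transcript,
    one_hot_encode,
)
from spliceworks.inference import (
    DeltaScores,
    align_alt_to_ref,
    annotate_vcf,
    call_sites,
    plan_windows,
    predict_track,
    score_variant,
    variant_eligibility,
)
from spliceworks.model import SpliceModel, build_config

from conftest import random_dna


class TestPlanWindows:
    def test_single_window_padding(self):
        plan = plan_windows(5000, 80)
        assert len(plan.windows) == 1
        w = plan.windows[0]
        assert (w.left_pad, w.right_pad) == (40, 40)
        assert w.end - w.start == 5080

    def test_three_window_tiling(self):
        plan = plan_windows(12_000, 80)
        assert len(plan.windows) == 3
        assert plan.windows[2].core_start == 10_000
        assert plan.windows[2].core_end == 12_000
        assert plan.windows[2].right_pad > 0

    def test_degenerate_single_base(self):
        plan = plan_windows(1, 80)
        w = plan.windows[0]
        assert (w.core_start, w.core_end) == (0, 1)

    @given(st.integers(1, 60_000), st.sampled_from([80, 400]))
    @settings(max_examples=40, deadline=None)
    def test_cores_tile_exactly(self, seq_len, flank):
        plan = plan_windows(seq_len, flank)
        pos = 0
        for w in plan.windows:
            assert w.core_start == pos
            assert w.end - w.start == 5000 + flank
            pos = w.core_end
        assert pos == seq_len

    def test_chunking_above_threshold(self):
        plan = plan_windows(40_000, 80, split_threshold=15_000)
        assert len(plan.chunks) > 1
        assert plan.chunks[0][0] == 0
        assert plan.chunks[-1][1] == 40_000
        # consecutive chunks overlap by at least flank/2
        for (a0, a1), (b0, b1) in zip(plan.chunks, plan.chunks[1:]):
            assert a1 - b0 >= 40 or a1 == 40_000


class TestPredictTrack:
    def test_track_covers_every_base(self, small_model, rng):
        seq = random_dna(rng, 7_531)
        track = predict_track(small_model, seq)
        assert len(track) == len(seq)

    def test_whole_vs_windowed_identical(self, small_model, rng):
        seq = random_dna(rng, 12_345)
        track = predict_track(small_model, seq)
        x = np.zeros((1, len(seq) + 80, 4), dtype=np.float32)
        x[0, 40 : 40 + len(seq)] = one_hot_encode(seq)
        whole = small_model.forward(x)[0]
        assert np.abs(whole[:, 1] - track.acceptor).max() < 1e-4
        assert np.abs(whole[:, 2] - track.donor).max() < 1e-4

    def test_identical_models_average_to_same(self, small_model, rng):
        seq = random_dna(rng, 600)
        single = predict_track(small_model, seq)
        ensemble = predict_track([small_model] * 5, seq)
        assert np.allclose(single.donor, ensemble.donor, atol=1e-6)

    def test_mixed_flanks_rejected(self, small_model):
        other = SpliceModel(build_config(400, channels=4), seed=0)
        with pytest.raises(ValueError, match="flank"):
            predict_track([small_model, other], "ACGT" * 100)

    def test_empty_sequence_rejected(self, small_model):
        with pytest.raises(ValueError):
            predict_track(small_model, "")


class TestCallSites:
    def _track(self, donor, acceptor):
        from spliceworks.inference import PredictionTrack

        donor = np.asarray(donor, dtype=float)
        acceptor = np.asarray(acceptor, dtype=float)
        return PredictionTrack("s", 1 - donor - acceptor, acceptor, donor)

    def test_all_below_threshold_empty(self):
        d, a = call_sites(self._track([0.1] * 5, [0.2] * 5))
        assert d == [] and a == []

    def test_planted_site_interval(self):
        donor = [0.0] * 10
        donor[4] = 0.9
        d, _ = call_sites(self._track(donor, [0.0] * 10))
        assert d == [("s", 4, 5, "donor", pytest.approx(0.9), "+")]

    def test_threshold_zero_emits_everything(self):
        d, a = call_sites(self._track([0.1] * 6, [0.1] * 6), threshold=0.0)
        assert len(d) == 6 and len(a) == 6

    def test_minus_strand_genomic_mapping(self):
        donor = [0.0] * 10
        donor[2] = 0.8  # sense position 2 of a gene ending at genomic 100
        d, _ = call_sites(
            self._track(donor, [0.0] * 10), chrom="chr1", strand="-",
            gene_end=100,
        )
        assert d[0][:3] == ("chr1", 97, 98)


class TestDeltaScores:
    def test_hand_worked_arrays(self):
        """a_ref=[0.1,0.9,0.3], a_alt=[0.8,0.2,0.3] -> gain 0.7, loss 0.7."""
        from spliceworks.inference import _max_and_pos

        offsets = np.array([-1, 0, 1])
        a_ref = np.array([0.1, 0.9, 0.3])
        a_alt = np.array([0.8, 0.2, 0.3])
        gain, gp = _max_and_pos(a_alt - a_ref, offsets)
        loss, lp = _max_and_pos(a_ref - a_alt, offsets)
        assert gain == pytest.approx(0.7) and gp == -1
        assert loss == pytest.approx(0.7) and lp == 0

    def test_tie_breaks_smallest_offset_then_upstream(self):
        from spliceworks.inference import _max_and_pos

        offsets = np.array([-2, -1, 0, 1, 2])
        diff = np.array([0.5, 0.0, 0.0, 0.5, 0.5])
        _, pos = _max_and_pos(diff, offsets)
        assert pos == 1  # |1| < |-2|; -2 vs 2 would pick -2
        diff2 = np.array([0.5, 0.0, 0.0, 0.0, 0.5])
        _, pos2 = _max_and_pos(diff2, offsets)
        assert pos2 == -2

    def test_all_negative_clamps_to_zero(self):
        from spliceworks.inference import _max_and_pos

        offsets = np.array([-1, 0, 1])
        value, pos = _max_and_pos(np.array([-0.2, -0.1, -0.3]), offsets)
        assert value == 0.0 and pos == 0


@pytest.fixture(scope="module")
def variant_setup():
    rng = np.random.default_rng(33)
    chrom = random_dna(rng, 4000)
    genome = GenomeSequence("c1", chrom)
    gene_plus = GeneModel(
        "gp", "c1", 301, 3700, "+", "protein_coding",
        [Transcript("gp.t", [(301, 3700)], "+")],
    )
    gene_minus = GeneModel(
        "gm", "c1", 301, 3700, "-", "protein_coding",
        [Transcript("gm.t", [(301, 3700)], "-")],
    )
    model = SpliceModel(build_config(80, channels=8), seed=2)
    return genome, gene_plus, gene_minus, model


class TestScoreVariant:
    def test_alt_equal_ref_all_zero(self, variant_setup):
        genome, gene, _, model = variant_setup
        base = genome.residues(1999, 2000)
        ds = score_variant(model, genome, ("c1", 2000, base, base), gene)
        assert (ds.ds_ag, ds.ds_al, ds.ds_dg, ds.ds_dl) == (0, 0, 0, 0)

    def test_ref_mismatch_rejected(self, variant_setup):
        genome, gene, _, model = variant_setup
        base = genome.residues(1999, 2000)
        wrong = "A" if base != "A" else "C"
        with pytest.raises(ValueError, match="mismatch"):
            score_variant(model, genome, ("c1", 2000, wrong, base), gene)

    def test_window_has_101_positions(self, variant_setup, monkeypatch):
        genome, gene, _, model = variant_setup
        captured = {}
        import spliceworks.inference as inf

        orig = inf._max_and_pos

        def spy(diff, offsets):
            captured["n"] = len(diff)
            return orig(diff, offsets)

        monkeypatch.setattr(inf, "_max_and_pos", spy)
        base = genome.residues(1999, 2000)
        alt = "A" if base != "A" else "C"
        score_variant(model, genome, ("c1", 2000, base, alt), gene,
                      distance=50)
        assert captured["n"] == 101

    def test_swap_symmetry(self, variant_setup):
        """Exchanging ref and alt swaps gain and loss channels exactly."""
        genome, gene, _, model = variant_setup
        pos = 2000
        ref = genome.residues(pos - 1, pos)
        alt = "A" if ref != "A" else "C"
        fwd = score_variant(model, genome, ("c1", pos, ref, alt), gene)
        mutated = GenomeSequence(
            "c1", str(genome)[: pos - 1] + alt + str(genome)[pos:]
        )
        rev = score_variant(model, mutated, ("c1", pos, alt, ref), gene)
        assert fwd.ds_ag == pytest.approx(rev.ds_al, abs=1e-6)
        assert fwd.ds_al == pytest.approx(rev.ds_ag, abs=1e-6)
        assert fwd.ds_dg == pytest.approx(rev.ds_dl, abs=1e-6)
        assert fwd.ds_dl == pytest.approx(rev.ds_dg, abs=1e-6)

    def test_scores_in_unit_interval(self, variant_setup):
        genome, gene, gene_minus, model = variant_setup
        for g in (gene, gene_minus):
            ref = genome.residues(1499, 1500)
            alt = "G" if ref != "G" else "T"
            ds = score_variant(model, genome, ("c1", 1500, ref, alt), g)
            for v in (ds.ds_ag, ds.ds_al, ds.ds_dg, ds.ds_dl):
                assert 0.0 <= v <= 1.0
            for p in (ds.dp_ag, ds.dp_al, ds.dp_dg, ds.dp_dl):
                assert -50 <= p <= 50

    def test_deletion_scored_without_index_error(self, variant_setup):
        genome, gene, _, model = variant_setup
        pos = 2000
        ref = genome.residues(pos - 1, pos + 7)  # 8-base deletion
        alt = ref[0]
        ds = score_variant(model, genome, ("c1", pos, ref, alt), gene)
        assert np.isfinite([ds.ds_ag, ds.ds_al, ds.ds_dg, ds.ds_dl]).all()

    def test_insertion_scored_without_index_error(self, variant_setup):
        genome, gene, _, model = variant_setup
        pos = 2000
        ref = genome.residues(pos - 1, pos)
        ds = score_variant(
            model, genome, ("c1", pos, ref, ref + "ACGTAC"), gene
        )
        assert np.isfinite([ds.ds_ag, ds.ds_al, ds.ds_dg, ds.ds_dl]).all()


class TestAlignAltToRef:
    def test_snv_identity_mapping(self):
        scores = np.arange(11, dtype=float)
        offsets = np.arange(-3, 4)
        out = align_alt_to_ref(scores, anchor=5, ref_len=1, alt_len=1,
                               offsets=offsets)
        assert np.array_equal(out, scores[2:9])

    def test_deletion_maps_to_junction(self):
        # ref ACGT -> alt A: deleted ref offsets 1..3 read the junction (A)
        scores = np.arange(10, dtype=float)
        offsets = np.arange(0, 6)
        out = align_alt_to_ref(scores, anchor=4, ref_len=4, alt_len=1,
                               offsets=offsets)
        assert out[0] == 4  # the anchor base itself
        assert list(out[1:4]) == [4, 4, 4]  # deletion junction
        assert out[4] == 5  # first base after the variant

    def test_insertion_skips_inserted(self):
        scores = np.arange(12, dtype=float)
        offsets = np.arange(0, 4)
        out = align_alt_to_ref(scores, anchor=4, ref_len=1, alt_len=3,
                               offsets=offsets)
        assert list(out) == [4, 7, 8, 9]  # offsets >= 1 jump the insertion


class TestVariantEligibility:
    def _gene(self):
        return GeneModel("g", "c1", 1000, 3000, "+", "protein_coding", [])

    def test_intergenic_skipped(self):
        gene, reason = variant_eligibility(
            ("c1", 100, "A", "C"), [self._gene()], 10_000, 80
        )
        assert gene is None and reason == "outside_gene"

    def test_long_deletion_skipped(self):
        gene, reason = variant_eligibility(
            ("c1", 1500, "A" * 151, "A"), [self._gene()], 10_000, 80,
            distance=50,
        )
        assert reason == "long_deletion"

    def test_borderline_deletion_allowed(self):
        gene, reason = variant_eligibility(
            ("c1", 1500, "A" * 101, "A"), [self._gene()], 10_000, 80,
            distance=50,
        )
        assert reason is None  # deletion of exactly 2*distance passes

    def test_near_chromosome_end_skipped(self):
        gene = GeneModel("g", "c1", 1, 3000, "+", "protein_coding", [])
        _, reason = variant_eligibility(("c1", 30, "A", "C"), [gene], 10_000,
                                        80)
        assert reason == "near_chromosome_end"

    def test_mid_gene_snv_eligible(self):
        gene, reason = variant_eligibility(
            ("c1", 2000, "A", "C"), [self._gene()], 10_000, 80
        )
        assert gene is not None and reason is None


class TestAnnotateVcf:
    def test_eligible_and_intergenic_records(self, tmp_path, variant_setup):
        genome, gene, _, model = variant_setup
        vcf_in = tmp_path / "in.vcf"
        ref_in_gene = genome.residues(1999, 2000)
        alt_in_gene = "A" if ref_in_gene != "A" else "C"
        ref_out = genome.residues(99, 100)
        alt_out = "A" if ref_out != "A" else "C"
        vcf_in.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=4000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            f"c1\t2000\tv1\t{ref_in_gene}\t{alt_in_gene}\t.\t.\t.\n"
            f"c1\t100\tv2\t{ref_out}\t{alt_out}\t.\t.\t.\n"
        )

        class _G:
            def __getitem__(self, name):
                return genome

        vcf_out = tmp_path / "out.vcf"
        counts = annotate_vcf(vcf_in, _G(), [gene], model, vcf_out)
        assert counts["annotated"] == 1
        assert counts["outside_gene"] == 1
        lines = [
            l for l in vcf_out.read_text().splitlines()
            if not l.startswith("#")
        ]
        assert len(lines) == 2  # both records preserved
        assert "SpliceDelta=" in lines[0]
        assert "SpliceDelta=" not in lines[1]
        header = [
            l for l in vcf_out.read_text().splitlines() if l.startswith("##")
        ]
        assert any("SpliceDelta" in l for l in header)

    def test_empty_body_valid_output(self, tmp_path, variant_setup):
        genome, gene, _, model = variant_setup
        vcf_in = tmp_path / "empty.vcf"
        vcf_in.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=4000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )

        class _G:
            def __getitem__(self, name):
                return genome

        vcf_out = tmp_path / "out.vcf"
        counts = annotate_vcf(vcf_in, _G(), [gene], model, vcf_out)
        assert counts == {"annotated": 0}
        assert any(
            "SpliceDelta" in l for l in vcf_out.read_text().splitlines()
        )
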