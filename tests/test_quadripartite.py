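import numpy as np
import pytest

from plastdeg._model import GeneFeature, PlastomeRecord, revcomp
from plastdeg.quadripartite import (
    Arc,
    NoInvertedRepeatError,
    RegionPartition,
    classify_ir_type,
    detect_inverted_repeat,
    junction_genes,
    region_stats,
)
from plastdeg.synthetic import default_template, synthesize_plastome


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestDetection:
    def test_planted_repeat_recovered_exactly(self):
        """20 kb LSC + 8 kb IR + 4 kb SSC + revcomp(IR), boundaries pinned
        so maximal extension stops at the planted coordinates."""
        rng = np.random.default_rng(11)
        lsc = "A" + _rand(rng, 19998) + "A"
        block = _rand(rng, 8000)
        ssc = _rand(rng, 3999)
        ssc = ssc + ssc[0]  # last base equals first: never complementary
        seq = lsc + block + ssc + revcomp(block)
        part = detect_inverted_repeat(seq, min_len=1000)
        assert part.lsc == Arc(0, 20000)
        assert part.irb == Arc(20000, 8000)
        assert part.ssc == Arc(28000, 4000)
        assert part.ira == Arc(32000, 8000)
        part.validate(seq)

    def test_random_sequence_has_no_kilobase_repeat(self):
        rng = np.random.default_rng(5)
        with pytest.raises(NoInvertedRepeatError):
            detect_inverted_repeat(_rand(rng, 10000), min_len=1000)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="min_len"):
            detect_inverted_repeat("ACGT" * 100, min_len=1000)

    @pytest.mark.parametrize("ir_type", ["I", "II", "III", "IV"])
    def test_generator_truth_recovered(self, ir_type):
        record, truth = synthesize_plastome(default_template(ir_type), seed=41)
        part = detect_inverted_repeat(record.sequence)
        assert part.regions() == truth.partition.regions()

    def test_rotation_invariance(self, type2_plastome):
        """Canonical regions are identical for any rotation of the circle."""
        record, _ = type2_plastome
        base = detect_inverted_repeat(record.sequence)
        for rot in (1, 7919, len(record) // 2):
            rotated = record.rotated(rot)
            part = detect_inverted_repeat(rotated.sequence)
            for name in ("LSC", "IRb", "SSC", "IRa"):
                assert part.regions()[name].length == base.regions()[name].length
                assert part.regions()[name].extract(rotated.sequence) == base.regions()[
                    name
                ].extract(record.sequence)

    def test_strand_flip_swaps_ir_labels_keeps_lengths(self, type2_plastome):
        record, _ = type2_plastome
        base = detect_inverted_repeat(record.sequence)
        flipped = detect_inverted_repeat(revcomp(record.sequence))
        assert flipped.lsc.length == base.lsc.length
        assert flipped.ssc.length == base.ssc.length
        # labels swap under the flip: the new IRb is the mirror image of the
        # old IRa, whose sequence is exactly the old IRb
        assert flipped.irb.extract(revcomp(record.sequence)) == base.irb.extract(record.sequence)


class TestRegionStats:
    def _partition16(self):
        return RegionPartition(
            lsc=Arc(0, 4), irb=Arc(4, 4), ssc=Arc(8, 4), ira=Arc(12, 4), genome_len=16
        )

    def test_half_gc_everywhere(self):
        rec = PlastomeRecord("X", "x", "ATGC" * 4, [])
        stats = region_stats(rec, self._partition16())
        assert all(v == 0.5 for v in stats.gc.values())
        assert stats.genome_gc == 0.5
        assert sum(stats.lengths.values()) == 16

    def test_all_g_genome(self):
        rec = PlastomeRecord("X", "x", "G" * 16, [])
        stats = region_stats(rec, self._partition16())
        assert all(v == 1.0 for v in stats.gc.values())

    def test_length_mismatch_rejected(self):
        rec = PlastomeRecord("X", "x", "ATGCATGCAA", [])
        with pytest.raises(ValueError, match="length"):
            region_stats(rec, self._partition16())

    def test_generator_hits_gc_targets(self, type2_plastome):
        """Spacer composition balances each region to its GC target."""
        record, truth = type2_plastome
        stats = region_stats(record, truth.partition)
        targets = {"LSC": 0.36, "IRb": 0.43, "SSC": 0.33, "IRa": 0.43}
        for region, target in targets.items():
            assert stats.gc[region] == pytest.approx(target, abs=0.005)


class TestIRTyping:
    @pytest.mark.parametrize("ir_type", ["I", "II", "III", "IV"])
    def test_generator_types_recovered(self, ir_type):
        record, truth = synthesize_plastome(default_template(ir_type), seed=59)
        part = detect_inverted_repeat(record.sequence)
        assert classify_ir_type(record, part).type == ir_type

    def test_type1_reports_ycf1_ir_overlap(self, type1_plastome):
        record, truth = type1_plastome
        res = classify_ir_type(record, truth.partition)
        assert res.type == "I"
        # the study reports 210-1628 bp of ycf1 inside the IRb for this type
        assert res.ycf1_overlap_bp == 900

    def test_missing_ycf1_is_unclassified_not_an_error(self, type1_plastome):
        record, truth = type1_plastome
        stripped = PlastomeRecord(
            record.id,
            record.taxon,
            record.sequence,
            [f for f in record.features if f.gene != "ycf1"],
        )
        res = classify_ir_type(stripped, truth.partition)
        assert res.type == "unclassified"

    def test_call_is_invariant_to_feature_order(self, type1_plastome):
        record, truth = type1_plastome
        rng = np.random.default_rng(3)
        shuffled = list(record.features)
        rng.shuffle(shuffled)
        permuted = PlastomeRecord(record.id, record.taxon, record.sequence, shuffled)
        assert classify_ir_type(permuted, truth.partition).type == "I"


class TestJunctions:
    def test_template_junction_flanks(self, type1_plastome):
        """rps19 | rpl2 at LSC/IRb and rpl2 | trnH-GUG at IRa/LSC, as in the
        canonical plastome layout the generator encodes."""
        record, truth = type1_plastome
        report = junction_genes(record, truth.partition)
        assert report["LSC-IRb"]["upstream"][0] == "rps19"
        assert report["LSC-IRb"]["downstream"][0] == "rpl2"
        assert report["IRa-LSC"]["upstream"][0] == "rpl2"
        assert report["IRa-LSC"]["downstream"][0] == "trnH-GUG"
        assert "ycf1" in report["IRb-SSC"]["spanning"]

    def test_gene_abutting_junction_is_distance_zero_not_spanning(self):
        seq = "ACGT" * 25
        rec = PlastomeRecord(
            "X", "x", seq, [GeneFeature("rps19", "CDS", "+", ((10, 40),))]
        )
        part = RegionPartition(
            lsc=Arc(0, 40), irb=Arc(40, 20), ssc=Arc(60, 20), ira=Arc(80, 20), genome_len=100
        )
        report = junction_genes(rec, part)
        assert report["LSC-IRb"]["upstream"] == ("rps19", 0)
        assert report["LSC-IRb"]["spanning"] == []

    def test_empty_annotation_gives_empty_report(self):
        rec = PlastomeRecord("X", "x", "ACGT" * 25, [])
        part = RegionPartition(
            lsc=Arc(0, 40), irb=Arc(40, 20), ssc=Arc(60, 20), ira=Arc(80, 20), genome_len=100
        )
        report = junction_genes(rec, part)
        assert all(v["upstream"] is None and v["spanning"] == [] for v in report.values())
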