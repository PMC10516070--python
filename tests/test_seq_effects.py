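"""5'UTR translational effects, Kozak rules, polyA-signal disruption."""

import numpy as np
import pytest

from oracles import oracle_five_prime

from nearcoding.seq_effects import (
    SplicedTranscriptSequence,
    TranscriptVariant,
    UTRConsequence,
    annotate_five_prime,
    apply_variant,
    high_impact_utr_filter,
    kozak_minus3_disruption,
    kozak_strength,
    polya_disruption,
    project_to_transcript,
)
from nearcoding.regions import TranscriptModel


def make_seq(utr: str, cds: str = "ATGAAATAG") -> SplicedTranscriptSequence:
    return SplicedTranscriptSequence(utr + cds, len(utr))


class TestKozakStrength:
    @pytest.mark.parametrize(
        "seq,aug,expected",
        [
            ("GACCATGG", 4, "strong"),       # -3 purine, +4 G
            ("TTTTATGC", 4, "weak"),          # both fail
            ("GATGA", 1, "weak"),             # no -3 base, +4 not G
            ("GATGG", 1, "moderate"),         # no -3 base, +4 G
            ("AAAATGC", 3, "moderate"),       # -3 purine only
        ],
    )
    def test_examples(self, seq, aug, expected):
        assert kozak_strength(seq, aug) == expected

    def test_requires_aug(self):
        with pytest.raises(ValueError):
            kozak_strength("AAAA", 0)

    def test_invariant_to_other_positions(self):
        rng = np.random.default_rng(2)
        base = "GACCATGGTT"
        ref = kozak_strength(base, 4)
        for _ in range(50):
            s = list(base)
            i = int(rng.integers(len(s)))
            if i in (1, 4, 5, 6, 7):  # -3, AUG itself, +4
                continue
            s[i] = "ACGT"[int(rng.integers(4))]
            assert kozak_strength("".join(s), 4) == ref


class TestAnnotateFivePrime:
    def test_uaug_gain_out_of_frame_oorf(self):
        seq = make_seq("GACCTTGGC")  # cds_offset 9
        got = annotate_five_prime(TranscriptVariant(4, "T", "A"), seq)
        assert got == [UTRConsequence("uAUG_gain", "outOfFrame_oORF", "strong", 4)]

    def test_neutral_snv_empty(self):
        seq = make_seq("GACCTTGGC")
        assert annotate_five_prime(TranscriptVariant(8, "C", "G"), seq) == []

    def test_ustop_loss_to_oorf(self):
        # ref uORF ATG..TAA with no later in-frame UTR stop
        seq = make_seq("ATGAAATAAGGG")
        got = annotate_five_prime(TranscriptVariant(8, "A", "C"), seq)
        assert got == [UTRConsequence("uSTOP_loss", "inFrame_oORF", "weak", 0)]

    def test_ustop_loss_still_uorf(self):
        # a second in-frame stop remains before the CDS
        seq = make_seq("ATGAAATAACCCTAAGGG")
        got = annotate_five_prime(TranscriptVariant(8, "A", "C"), seq)
        assert got == [UTRConsequence("uSTOP_loss", "uORF", "weak", 0)]

    def test_uaug_loss(self):
        seq = make_seq("AATGGTTTT")  # uAUG at 1, -3 off-end, +4 G -> moderate
        got = annotate_five_prime(TranscriptVariant(2, "T", "C"), seq)
        assert got == [UTRConsequence("uAUG_loss", "outOfFrame_oORF", "moderate", 1)]

    def test_uframeshift_deletion_in_uorf_body(self):
        # uORF ATG GCC CAC TGA then CDS; 1-bp deletion in the body
        seq = make_seq("ATGGCCCACTGAGGG")
        got = annotate_five_prime(TranscriptVariant(4, "C", ""), seq)
        assert any(c.effect_class == "uFrameshift" for c in got)
        (fs,) = [c for c in got if c.effect_class == "uFrameshift"]
        assert fs.orf_outcome in ("inFrame_oORF", "outOfFrame_oORF")

    def test_variant_outside_utr_empty(self):
        seq = make_seq("GACCTTGGC")
        assert annotate_five_prime(TranscriptVariant(10, "T", "A"), seq) == []

    def test_gain_and_reverse_loss_mirror(self):
        """alt->ref of a gain is the corresponding loss, and vice versa."""
        rng = np.random.default_rng(17)
        bases = "ACGT"
        checked = 0
        while checked < 300:
            utr = "".join(bases[int(b)] for b in rng.integers(0, 4, 30))
            seq = make_seq(utr)
            pos = int(rng.integers(0, 30))
            alt_b = bases[int(rng.integers(4))]
            if alt_b == utr[pos]:
                continue
            fwd = annotate_five_prime(TranscriptVariant(pos, utr[pos], alt_b), seq)
            alt_utr = utr[:pos] + alt_b + utr[pos + 1 :]
            rev = annotate_five_prime(
                TranscriptVariant(pos, alt_b, utr[pos]), make_seq(alt_utr)
            )
            gains_f = {c.uaug_position for c in fwd if c.effect_class == "uAUG_gain"}
            losses_r = {c.uaug_position for c in rev if c.effect_class == "uAUG_loss"}
            assert gains_f == losses_r
            checked += 1

    def test_oracle_equivalence_sample(self):
        """Implementation agrees with the enumeration oracle (SNVs + indels)."""
        rng = np.random.default_rng(23)
        bases = "ACGT"
        for _ in range(300):
            utr_len = int(rng.integers(6, 50))
            utr = "".join(bases[int(b)] for b in rng.integers(0, 4, utr_len))
            cds = "ATG" + "".join(bases[int(b)] for b in rng.integers(0, 4, 9))
            seq = SplicedTranscriptSequence(utr + cds, utr_len)
            kind = rng.integers(3)
            pos = int(rng.integers(0, utr_len))
            if kind == 0:  # SNV
                ref, alt = utr[pos], bases[int(rng.integers(4))]
                if ref == alt:
                    continue
            elif kind == 1:  # deletion of 1-3 bases
                n = int(rng.integers(1, 4))
                if pos + n > utr_len:
                    continue
                ref, alt = utr[pos : pos + n], ""
            else:  # insertion of 1-3 bases
                ref = ""
                alt = "".join(bases[int(b)] for b in rng.integers(0, 4, rng.integers(1, 4)))
            tv = TranscriptVariant(pos, ref, alt)
            got = {
                (c.effect_class, c.orf_outcome, c.kozak, c.uaug_position)
                for c in annotate_five_prime(tv, seq)
            }
            want = oracle_five_prime(seq.sequence, utr_len, pos, ref, alt)
            assert got == want, (utr, cds, pos, ref, alt)


class TestHighImpactFilter:
    @pytest.mark.parametrize(
        "effect,outcome,kozak,expected",
        [
            ("uAUG_gain", "outOfFrame_oORF", "strong", True),
            ("uAUG_gain", "inFrame_oORF", "moderate", True),
            ("uAUG_gain", "uORF", "strong", False),
            ("uAUG_gain", "outOfFrame_oORF", "weak", False),
            ("uSTOP_loss", "outOfFrame_oORF", "moderate", True),
            ("uSTOP_loss", "uORF", "strong", False),
            ("uAUG_loss", "uORF", "strong", True),
            ("uAUG_loss", "uORF", "moderate", False),
            ("uFrameshift", "inFrame_oORF", "moderate", True),
            ("uFrameshift", "uORF", "strong", False),
        ],
    )
    def test_rule_table(self, effect, outcome, kozak, expected):
        assert high_impact_utr_filter(UTRConsequence(effect, outcome, kozak, 0)) is expected


class TestKozakMinus3:
    SEQ = SplicedTranscriptSequence("GGGACCATGAAATAG", 6)  # -3 base 'A' at index 3

    def test_purine_to_pyrimidine(self):
        assert kozak_minus3_disruption(TranscriptVariant(3, "A", "C"), self.SEQ)

    def test_purine_to_purine(self):
        assert not kozak_minus3_disruption(TranscriptVariant(3, "A", "G"), self.SEQ)

    def test_wrong_position(self):
        assert not kozak_minus3_disruption(TranscriptVariant(2, "G", "T"), self.SEQ)

    def test_indel_not_covered(self):
        assert not kozak_minus3_disruption(TranscriptVariant(3, "AC", "A"), self.SEQ)


class TestPolyADisruption:
    def test_rescue_motif_created(self):
        utr3 = "CCCCAATAAACCCC"
        call = polya_disruption(TranscriptVariant(4, "A", "G"), utr3)
        assert not call.disrupted
        assert call.rescue_motif == "GATAAA"
        assert call.motif_interval == (4, 10)

    def test_disrupting_substitution(self):
        utr3 = "CCCCAATAAACCCC"
        call = polya_disruption(TranscriptVariant(6, "T", "C"), utr3)
        assert call.disrupted
        assert call.motif_interval == (4, 10)

    def test_no_signal_hit(self):
        call = polya_disruption(TranscriptVariant(1, "C", "G"), "CCCCAATAAACCCC")
        assert not call.disrupted
        assert call.motif_interval is None

    def test_att_variant_signal(self):
        call = polya_disruption(TranscriptVariant(7, "A", "C"), "CCCCATTAAACCCC")
        assert call.disrupted

    def test_no_hexamer_utr_never_disrupted(self):
        """Exhaustive: without a signal hexamer no SNV can disrupt."""
        rng = np.random.default_rng(9)
        while True:
            utr = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, 30))
            if "AATAAA" not in utr and "ATTAAA" not in utr:
                break
        for pos in range(30):
            for alt in "ACGT":
                if alt == utr[pos]:
                    continue
                assert not polya_disruption(
                    TranscriptVariant(pos, utr[pos], alt), utr
                ).disrupted


class TestProjection:
    def _scene(self):
        # minus-strand transcript: spliced sequence GACCTTGGCA + ATGAAATAGC
        genome = {
            "chr1": "A" * 10 + "GCTATTTCAT" + "G" * 10 + "TGCCAAGGTC" + "A" * 10
        }
        tx = TranscriptModel(
            "T1", "G1", "chr1", "-", [(10, 20), (30, 40)], 10, 20
        )
        return genome, tx

    def test_minus_strand_snv(self):
        genome, tx = self._scene()
        seq = SplicedTranscriptSequence.from_transcript(tx, genome)
        assert seq.sequence == "GACCTTGGCAATGAAATAGC"
        tv = project_to_transcript(seq, "chr1", 35, genome["chr1"][35], "G")
        assert tv == TranscriptVariant(4, "T", "C")

    def test_deletion_across_intron_rejected(self):
        genome, tx = self._scene()
        seq = SplicedTranscriptSequence.from_transcript(tx, genome)
        ref = genome["chr1"][17:32]
        assert (
            project_to_transcript(seq, "chr1", 17, ref, ref[0]) is None
        )

    def test_plus_strand_roundtrip(self):
        genome = {"chr1": "TTTTTGACCTTGGCATGAAATAGTTTTT"}
        tx = TranscriptModel("T1", "G1", "chr1", "+", [(5, 23)], 14, 23)
        seq = SplicedTranscriptSequence.from_transcript(tx, genome)
        tv = project_to_transcript(seq, "chr1", 9, "T", "A")
        assert tv == TranscriptVariant(4, "T", "A")
        got = annotate_five_prime(tv, seq)
        assert got and got[0].effect_class == "uAUG_gain"


def test_apply_variant_checks_reference():
    with pytest.raises(ValueError):
        apply_variant("ACGT", TranscriptVariant(1, "G", "A"))
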