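"""Allele calling: affine-gap alignment, signature extraction, allele tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from Bio import Align

from mosaicamp.allele_calling import (
    DEFAULT_SCORING,
    Rejection,
    align_global,
    build_allele_table,
    call_read,
    extract_signature,
)
from mosaicamp.signatures import WILD_TYPE, IndelSignature, apply_signature
from mosaicamp.synthetic_data import AlleleSpec, MosaicSampleSpec, simulate_reads

dna = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestAlignGlobal:
    def test_identity_alignment(self, reference):
        aln = align_global(reference.sequence, reference.sequence)
        assert aln.operations == (("M", len(reference)),)
        assert aln.score == 2 * len(reference)

    def test_single_deletion_hand_scored(self, reference):
        L = len(reference)
        read = apply_signature(reference.sequence, IndelSignature(309, 1, ""))
        aln = align_global(read, reference.sequence)
        assert aln.score == 2 * (L - 1) - 11
        assert [op for op, _ in aln.operations if op == "D"] == ["D"]
        assert sum(n for op, n in aln.operations if op == "D") == 1

    def test_consumed_lengths_match_inputs(self, reference):
        read = apply_signature(reference.sequence, IndelSignature(300, 2, "TTTT"))
        aln = align_global(read, reference.sequence)
        assert aln.reference_length == len(reference)
        assert aln.read_length == len(read)

    @given(read=dna, ref=dna)
    @settings(max_examples=40)
    def test_score_matches_exhaustive_oracle(self, read, ref, brute_force_score):
        assert align_global(read, ref).score == brute_force_score(
            read, ref, DEFAULT_SCORING
        )

    @given(read=dna, ref=dna)
    @settings(max_examples=40)
    def test_score_matches_biopython(self, read, ref):
        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=2,
            mismatch_score=-2,
            open_gap_score=-11,
            extend_gap_score=-1,
        )
        assert align_global(read, ref).score == aligner.score(ref, read)

    def test_n_scores_as_mismatch(self):
        assert align_global("ANA", "AAA").score == 2 + (-2) + 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "ACGT")


class TestExtractSignature:
    def test_substitution_only_read_is_wild_type(self, reference, target):
        read = list(reference.sequence)
        read[50] = "A" if read[50] != "A" else "C"
        assert call_read("".join(read), reference, target) is WILD_TYPE

    def test_deletion_at_cut(self, reference, target):
        sig = IndelSignature(target.cut_site, 3, "")
        read = apply_signature(reference.sequence, sig)
        called = call_read(read, reference, target)
        assert isinstance(called, IndelSignature)
        assert called.deleted_length == 3
        assert apply_signature(reference.sequence, called) == read

    def test_insertion_round_trip(self, reference, target):
        sig = IndelSignature(target.cut_site, 0, "A")
        read = apply_signature(reference.sequence, sig)
        called = call_read(read, reference, target)
        assert called.net_length == 1
        assert apply_signature(reference.sequence, called) == read

    def test_off_window_indel_rejected(self, reference, target):
        sig = IndelSignature(target.cut_site - 200, 3, "")
        read = apply_signature(reference.sequence, sig)
        res = call_read(read, reference, target)
        assert res == Rejection("off_window")

    def test_two_disjoint_indels_rejected(self, reference, target):
        read = apply_signature(reference.sequence, IndelSignature(350, 4, ""))
        read = apply_signature(read, IndelSignature(280, 4, ""))
        assert call_read(read, reference, target) == Rejection("multi_event")

    def test_excess_mismatches_rejected(self, reference, target):
        rng = np.random.default_rng(0)
        read = list(reference.sequence)
        for i in rng.choice(len(read), size=100, replace=False):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        assert call_read("".join(read), reference, target) == Rejection(
            "excess_mismatches"
        )

    def test_homopolymer_insertion_normalizes_uniquely(self, target):
        # reference with an A-run spanning the cut site of a hand-built target
        from mosaicamp.reference_model import GuideTarget, Interval

        ref_seq = "GGCCTT" + "A" * 8 + "CCGGTTCCAA" * 4
        t = GuideTarget(
            protospacer="A" * 20, pam="AGG", strand="+",
            protospacer_interval=Interval(0, 20), cut_site=10, window_radius=20,
        )

        class R:
            sequence = ref_seq

        calls = set()
        for p in range(6, 15):
            read = ref_seq[:p] + "A" + ref_seq[p:]
            calls.add(call_read(read, R, t))
        assert calls == {IndelSignature(6, 0, "A")}


class TestBuildAlleleTable:
    def test_pure_wild_type(self, reference, target):
        table = build_allele_table(
            [reference.sequence] * 100, reference, target, "s"
        )
        assert len(table.observations) == 1
        assert table.observations[0].label == "wt"
        assert table.observations[0].fraction_percent == 100.0

    def test_conservation_of_reads(self, reference, target):
        sig = IndelSignature(target.cut_site - 200, 3, "")  # off-window discard
        reads = [reference.sequence] * 10 + [
            apply_signature(reference.sequence, sig)
        ] * 5
        table = build_allele_table(reads, reference, target, "s")
        kept = sum(o.read_count for o in table.observations)
        assert kept + table.discarded_reads == table.total_reads == 15
        assert table.discard_reasons == {"off_window": 5}

    def test_three_allele_mix_recovered_exactly(self, reference, target):
        alleles = (
            AlleleSpec(0.5),
            AlleleSpec(0.3, signature=IndelSignature(309, 3, "")),
            AlleleSpec(0.2, signature=IndelSignature(309, 0, "A")),
        )
        spec = MosaicSampleSpec("s", "neck", alleles, depth=3000, seed=9)
        reads = simulate_reads(spec, reference)
        # ground truth realized counts from read ids
        truth = {}
        for r in reads:
            idx = int(r.id.split(":")[1].removeprefix("allele"))
            truth[idx] = truth.get(idx, 0) + 1
        table = build_allele_table(reads, reference, target, "s")
        assert table.discarded_reads == 0
        by_label = {o.label: o.read_count for o in table.observations}
        assert by_label["wt"] == truth[0]
        assert by_label["del:309:3"] == truth[1]
        # the +1 A insertion may normalize left of 309 inside a homopolymer,
        # but must be a single unique +1 signature
        plus_one = [o for o in table.observations if o.label.startswith("ins")]
        assert len(plus_one) == 1 and plus_one[0].read_count == truth[2]

    def test_zero_surviving_reads_is_error(self, reference, target):
        sig = IndelSignature(target.cut_site - 200, 3, "")
        reads = [apply_signature(reference.sequence, sig)] * 3
        with pytest.raises(ValueError, match="no reads"):
            build_allele_table(reads, reference, target, "s")
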