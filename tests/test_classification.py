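"""Genotype classification, functional percentage, large-insertion correction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pandas as pd
from Bio.Seq import Seq

from mosaicamp.classification import (
    AlleleCategory,
    classify_signature,
    compose_genotype,
    composition_from_counts,
    correct_composition,
    estimate_large_insertion_fraction,
)
from mosaicamp.signatures import WILD_TYPE, IndelSignature, apply_signature
from mosaicamp.allele_calling import build_allele_table
from mosaicamp.synthetic_data import AlleleSpec, MosaicSampleSpec, simulate_reads


class TestClassifySignature:
    def test_wild_type_marker(self, reference, target):
        assert classify_signature(WILD_TYPE, reference, target) is AlleleCategory.WILD_TYPE

    @pytest.mark.parametrize("position", [302, 309, 330])
    def test_plus_one_insertion_is_frameshift(self, reference, target, position):
        sig = IndelSignature(position, 0, "A")
        assert classify_signature(sig, reference, target) is AlleleCategory.FRAMESHIFT

    def test_inframe_deletion_between_cut_and_lys_is_functional(
        self, reference, target
    ):
        sig = IndelSignature(312, 3, "")  # strictly between cut (309) and Lys196 (318)
        cat = classify_signature(sig, reference, target)
        assert cat is AlleleCategory.INFRAME_FUNCTIONAL
        # independent translation oracle: mutated protein keeps K and H at the
        # annotated residues, shifted left by one codon
        mutated = apply_signature(reference.sequence, sig)
        protein = str(Seq(mutated[300:372]).translate())
        assert protein[(318 - 300) // 3 - 1] == "K"
        assert protein[(333 - 300) // 3 - 1] == "H"

    def test_inframe_deletion_hitting_lys_codon_is_nonfunctional(
        self, reference, target
    ):
        sig = IndelSignature(317, 6, "")  # overlaps Lys196 [318,321), not His201
        assert (
            classify_signature(sig, reference, target)
            is AlleleCategory.INFRAME_NONFUNCTIONAL
        )

    def test_inframe_insertion_with_stop_is_nonfunctional(self, reference, target):
        # +3 insertion at a codon boundary upstream of both residues, carrying
        # an in-frame TAA stop
        sig = IndelSignature(312, 0, "TAA")
        assert (
            classify_signature(sig, reference, target)
            is AlleleCategory.INFRAME_NONFUNCTIONAL
        )
        # same-size insertion without a stop stays functional
        benign = IndelSignature(312, 0, "GCA")
        assert (
            classify_signature(benign, reference, target)
            is AlleleCategory.INFRAME_FUNCTIONAL
        )

    def test_out_of_bounds_signature_rejected(self, reference, target):
        with pytest.raises(ValueError):
            classify_signature(
                IndelSignature(499, 10, ""), reference, target
            )

    @given(
        position=st.integers(min_value=290, max_value=340),
        deleted=st.integers(min_value=0, max_value=12),
        inserted=st.text(alphabet="ACGT", max_size=9),
    )
    def test_classification_is_total(self, reference, target, position, deleted, inserted):
        if deleted == 0 and not inserted:
            return
        cat = classify_signature(
            IndelSignature(position, deleted, inserted), reference, target
        )
        assert isinstance(cat, AlleleCategory)
        if (len(inserted) - deleted) % 3 != 0:
            assert cat is AlleleCategory.FRAMESHIFT


class TestComposeGenotype:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({AlleleCategory.WILD_TYPE: 4877, AlleleCategory.FRAMESHIFT: 18}, 99.63),
            (
                {AlleleCategory.WILD_TYPE: 29282, AlleleCategory.INFRAME_FUNCTIONAL: 11875},
                100.00,
            ),
            ({AlleleCategory.WILD_TYPE: 23077, AlleleCategory.FRAMESHIFT: 17464}, 56.92),
            (
                {
                    AlleleCategory.WILD_TYPE: 3441,
                    AlleleCategory.INFRAME_FUNCTIONAL: 2869,
                    AlleleCategory.FRAMESHIFT: 2690,
                },
                70.11,
            ),
        ],
    )
    def test_functional_percent_from_published_counts(self, counts, expected):
        comp = composition_from_counts(counts)
        assert round(comp.functional_percent, 2) == expected

    def test_error_free_simulation_recovered_exactly(self, reference, target):
        alleles = (
            AlleleSpec(0.5),
            AlleleSpec(0.3, signature=IndelSignature(312, 3, "")),  # functional
            AlleleSpec(0.2, signature=IndelSignature(309, 0, "A")),  # frameshift
        )
        spec = MosaicSampleSpec("s", "neck", alleles, depth=4000, seed=11)
        reads = simulate_reads(spec, reference)
        realized_functional = sum(
            not r.id.startswith("s:allele2") for r in reads
        ) / len(reads)
        table = build_allele_table(reads, reference, target, "s")
        comp = compose_genotype(table, reference, target)
        assert comp.functional_percent == pytest.approx(
            100 * realized_functional, abs=1e-9
        )


class TestLargeInsertionCorrection:
    def test_only_main_band_gives_zero(self):
        peaks = pd.DataFrame({"size_bp": [501.0], "molarity": [3.0]})
        assert estimate_large_insertion_fraction(peaks, 501) == 0.0

    def test_fraction_ratios(self):
        peaks = pd.DataFrame({"size_bp": [501, 830], "molarity": [3.0, 1.0]})
        assert estimate_large_insertion_fraction(peaks, 501) == pytest.approx(0.25)
        peaks = pd.DataFrame(
            {"size_bp": [501, 700, 900], "molarity": [1.0, 0.5, 0.5]}
        )
        assert estimate_large_insertion_fraction(peaks, 501) == pytest.approx(0.5)

    def test_sub_main_peaks_ignored_and_missing_main_is_error(self):
        peaks = pd.DataFrame(
            {"size_bp": [120, 501, 830], "molarity": [5.0, 3.0, 1.0]}
        )
        assert estimate_large_insertion_fraction(peaks, 501) == pytest.approx(0.25)
        with pytest.raises(ValueError, match="main"):
            estimate_large_insertion_fraction(
                pd.DataFrame({"size_bp": [830.0], "molarity": [1.0]}), 501
            )

    def test_proportional_rescaling(self):
        comp = composition_from_counts(
            {AlleleCategory.WILD_TYPE: 80, AlleleCategory.FRAMESHIFT: 20}
        )
        corrected = correct_composition(comp, 0.5)
        assert corrected.fractions[AlleleCategory.WILD_TYPE] == pytest.approx(40)
        assert corrected.fractions[AlleleCategory.FRAMESHIFT] == pytest.approx(10)
        assert corrected.fractions[AlleleCategory.LARGE_INSERTION] == pytest.approx(50)
        assert corrected.functional_percent == pytest.approx(40)
        assert correct_composition(comp, 0.0) is comp

    @given(f=st.floats(min_value=0, max_value=0.99))
    def test_mass_conserved_and_monotone(self, f):
        comp = composition_from_counts(
            {
                AlleleCategory.WILD_TYPE: 60,
                AlleleCategory.INFRAME_FUNCTIONAL: 15,
                AlleleCategory.FRAMESHIFT: 25,
            }
        )
        corrected = correct_composition(comp, f)
        assert sum(corrected.fractions.values()) == pytest.approx(100)
        for cat in comp.fractions:
            assert corrected.fractions[cat] <= comp.fractions[cat] + 1e-12

    def test_invalid_fraction_rejected(self):
        comp = composition_from_counts({AlleleCategory.WILD_TYPE: 10})
        with pytest.raises(ValueError):
            correct_composition(comp, 1.0)
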