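"""Genotype-category classification and the functional-genotype percentage.

Every called allele falls in exactly one category:

* ``WILD_TYPE`` — no indel;
* ``FRAMESHIFT`` — net indel length not divisible by 3;
* ``INFRAME_FUNCTIONAL`` — in-frame, every required critical-residue codon
  (Lys196 and His201 by default) untouched at the nucleotide level, and no
  premature stop introduced at or before the last required residue;
* ``INFRAME_NONFUNCTIONAL`` — in-frame but violating either condition;
* ``LARGE_INSERTION`` — an electrophoresis-detected allele too large to be
  genotyped by short reads, always non-functional.

The functional-genotype percentage of a sample is the percent of retained
reads that are wild type or in-frame functional.  Sequencing-derived fractions
can be proportionally corrected for large insertions quantified from a
capillary-electrophoresis peak table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .allele_calling import AlleleTable
from .reference_model import (
    AmpliconReference,
    FunctionalResidueSpec,
    GuideTarget,
    Interval,
)
from .signatures import WILD_TYPE, IndelSignature, apply_signature


class AlleleCategory(enum.Enum):
    WILD_TYPE = "Wt"
    INFRAME_FUNCTIONAL = "In (w)"
    INFRAME_NONFUNCTIONAL = "In (w/o)"
    FRAMESHIFT = "Out"
    LARGE_INSERTION = "Large ins"


FUNCTIONAL_CATEGORIES = (
    AlleleCategory.WILD_TYPE,
    AlleleCategory.INFRAME_FUNCTIONAL,
)


@dataclass(frozen=True)
class GenotypeComposition:
    """Per-category composition of one sample.

    ``fractions`` are percentages summing to 100; ``counts`` holds raw read
    counts for uncorrected compositions and is None after a proportional
    large-insertion correction (corrected fractions are no longer integral
    read counts).
    """

    sample_id: str
    fractions: dict[AlleleCategory, float]
    counts: dict[AlleleCategory, int] | None = None
    tissue: str = ""
    corrected: bool = False

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"fractions sum to {total}, expected 100")

    @property
    def functional_percent(self) -> float:
        return sum(self.fractions.get(c, 0.0) for c in FUNCTIONAL_CATEGORIES)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "tissue": self.tissue,
                "category": cat.value,
                "count": None if self.counts is None else self.counts.get(cat, 0),
                "fraction_percent": frac,
                "functional_percent": self.functional_percent,
                "corrected": self.corrected,
            }
            for cat, frac in self.fractions.items()
        ]
        return pd.DataFrame(rows)


def classify_signature(
    signature,
    reference: AmpliconReference,
    target: GuideTarget,
    residues: FunctionalResidueSpec = FunctionalResidueSpec(),
) -> AlleleCategory:
    """Classify one allele signature (or :data:`WILD_TYPE`).

    "Codon retained" is decided at the nucleotide level: the codon interval
    must be disjoint from the deleted interval and the insertion point must
    not fall strictly inside it.  In-frame alleles passing that test are then
    translated, and a stop codon at or before the last required residue
    demotes them to non-functional.
    """
    if signature is WILD_TYPE:
        return AlleleCategory.WILD_TYPE
    sig: IndelSignature = signature
    if sig.position + sig.deleted_length > len(reference):
        raise ValueError(f"signature {sig} outside amplicon")
    if sig.net_length % 3 != 0:
        return AlleleCategory.FRAMESHIFT
    residues.validate(reference)
    codons = [reference.residue_annotations[r] for r in residues.required_labels]
    p, d = sig.position, sig.deleted_length
    for codon in codons:
        if d and Interval(p, p + d).overlaps(codon):
            return AlleleCategory.INFRAME_NONFUNCTIONAL
        if sig.inserted_sequence and codon.start < p < codon.end:
            return AlleleCategory.INFRAME_NONFUNCTIONAL
    # translation check on the mutated coding segment, up to the last required
    # residue in mutated coordinates
    mutated = apply_signature(reference.sequence, sig)
    cs = reference.coding_segment
    net = sig.net_length
    deleted_before = max(0, min(p + d, cs.start) - p) if p < cs.start else 0
    inserted_before = len(sig.inserted_sequence) if p < cs.start else 0
    new_cs_start = cs.start - deleted_before + inserted_before
    last_end = max(
        codon.end + (net if p <= codon.start else 0) for codon in codons
    )
    frame_start = new_cs_start + reference.frame_offset
    coding = mutated[frame_start:last_end]
    coding = coding[: len(coding) - len(coding) % 3]
    from Bio.Seq import Seq

    protein = str(Seq(coding).translate())
    if "*" in protein:
        return AlleleCategory.INFRAME_NONFUNCTIONAL
    return AlleleCategory.INFRAME_FUNCTIONAL


def compose_genotype(
    table: AlleleTable,
    reference: AmpliconReference,
    target: GuideTarget,
    residues: FunctionalResidueSpec = FunctionalResidueSpec(),
    tissue: str = "",
) -> GenotypeComposition:
    """Classify every allele in a table and sum read counts per category."""
    if not table.observations:
        raise ValueError("empty allele table")
    counts: dict[AlleleCategory, int] = {}
    for obs in table.observations:
        cat = classify_signature(obs.signature, reference, target, residues)
        counts[cat] = counts.get(cat, 0) + obs.read_count
    total = sum(counts.values())
    fractions = {cat: 100.0 * n / total for cat, n in counts.items()}
    return GenotypeComposition(
        sample_id=table.sample_id,
        fractions=fractions,
        counts=counts,
        tissue=tissue,
    )


def composition_from_counts(
    counts: dict[AlleleCategory, int], sample_id: str = "sample", tissue: str = ""
) -> GenotypeComposition:
    """Build a composition directly from per-category read counts (e.g. from a
    published genotype table)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must be positive")
    fractions = {cat: 100.0 * n / total for cat, n in counts.items()}
    return GenotypeComposition(
        sample_id=sample_id, fractions=fractions, counts=dict(counts), tissue=tissue
    )


def estimate_large_insertion_fraction(
    peaks: pd.DataFrame,
    main_band_size: float,
    size_tolerance: float | None = None,
) -> float:
    """Fraction of template molecules carrying a large insertion, from a
    capillary-electrophoresis peak table (columns ``size_bp``, ``molarity``).

    Peaks larger than the main amplicon band (beyond ``size_tolerance``,
    default 10% of the main band size) are summed and divided by total peak
    molarity.  Peaks smaller than the main band are ignored as primer
    artifacts.  Raises if no peak lies within tolerance of the main band.
    """
    if size_tolerance is None:
        size_tolerance = 0.1 * main_band_size
    sizes = peaks["size_bp"].to_numpy(dtype=float)
    mol = peaks["molarity"].to_numpy(dtype=float)
    if (sizes <= 0).any() or (mol <= 0).any():
        raise ValueError("peak sizes and molarities must be positive")
    main = abs(sizes - main_band_size) <= size_tolerance
    if not main.any():
        raise ValueError("no main amplicon band detected in peak table")
    large = sizes > main_band_size + size_tolerance
    keep = main | large  # sub-main-band peaks are primer artifacts
    return float(mol[large].sum() / mol[keep].sum())


def correct_composition(
    composition: GenotypeComposition, large_insertion_fraction: float
) -> GenotypeComposition:
    """Proportionally rescale sequencing-derived fractions by ``(1 - f)`` and
    add a LARGE_INSERTION category of ``100 * f``; the total stays at 100 and
    the functional percentage shrinks by the same factor."""
    f = large_insertion_fraction
    if not 0.0 <= f < 1.0:
        raise ValueError("large-insertion fraction must be in [0, 1)")
    if f == 0.0:
        return composition
    fractions = {cat: frac * (1.0 - f) for cat, frac in composition.fractions.items()}
    fractions[AlleleCategory.LARGE_INSERTION] = (
        fractions.get(AlleleCategory.LARGE_INSERTION, 0.0) + 100.0 * f
    )
    return GenotypeComposition(
        sample_id=composition.sample_id,
        fractions=fractions,
        counts=None,
        tissue=composition.tissue,
        corrected=True,
    )
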