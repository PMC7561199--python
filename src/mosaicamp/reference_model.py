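"""Amplicon reference model: target sequence, guide site, reading frame and
critical-residue codons.

An :class:`AmpliconReference` describes the single PCR amplicon that the whole
pipeline operates on — its sequence, which interval of it is translated (and in
which frame), and where the codons for the critical residues lie.  For the
Fgf10 use case the critical residues are Lys196 and His201, both required for
FGF-receptor dimerization: an in-frame allele only counts as *functional* if
both codons survive untouched.

Coordinates are 0-based, half-open throughout.  A cut site is an
inter-nucleotide index (the blunt SpCas9 cut falls 3 bp 5' of the PAM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

_DNA = set("ACGT")

#: Default half-width, in nt, of the quantification window around the cut site.
DEFAULT_WINDOW_RADIUS = 20


class ReferenceError(ValueError):
    """Invalid reference annotation or guide lookup."""


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ReferenceError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class AmpliconReference:
    """Reference amplicon with coding frame and residue annotations.

    Parameters
    ----------
    name : str
        Label for the amplicon (e.g. the locus name).
    sequence : str
        Amplicon sequence over {A, C, G, T}.
    coding_segment : Interval
        Translated interval within the amplicon.
    frame_offset : int
        Offset in {0, 1, 2} of the first complete codon relative to
        ``coding_segment.start``.
    residue_annotations : dict[str, Interval]
        Map residue label (e.g. ``"Lys196"``) to its codon interval.
    primer_intervals : tuple[Interval, Interval] | None
        Optional forward/reverse primer footprints.
    """

    name: str
    sequence: str
    coding_segment: Interval
    frame_offset: int = 0
    residue_annotations: dict[str, Interval] = field(default_factory=dict)
    primer_intervals: tuple[Interval, Interval] | None = None

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - _DNA:
            raise ReferenceError("sequence must be non-empty over {A,C,G,T}")
        L = len(self.sequence)
        cs = self.coding_segment
        if cs.end > L:
            raise ReferenceError("coding segment outside amplicon")
        if self.frame_offset not in (0, 1, 2):
            raise ReferenceError("frame_offset must be 0, 1 or 2")
        for label, iv in self.residue_annotations.items():
            if len(iv) != 3:
                raise ReferenceError(f"{label}: codon interval must have length 3")
            if not cs.contains(iv):
                raise ReferenceError(f"{label}: codon outside coding segment")
            if (iv.start - cs.start - self.frame_offset) % 3 != 0:
                raise ReferenceError(f"{label}: codon not in frame")
            aa = str(Seq(self.sequence[iv.start:iv.end]).translate())
            expected = _THREE_TO_ONE.get(label[:3])
            if expected is not None and aa != expected:
                raise ReferenceError(
                    f"{label}: codon translates to {aa}, expected {expected}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def translate_coding(self, sequence: str | None = None) -> str:
        """Translate the coding segment (of ``sequence`` if given, else the
        reference), reading full codons only."""
        seq = self.sequence if sequence is None else sequence
        start = self.coding_segment.start + self.frame_offset
        sub = seq[start:self.coding_segment.end]
        sub = sub[: len(sub) - len(sub) % 3]
        return str(Seq(sub).translate())


_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


@dataclass(frozen=True)
class GuideTarget:
    """A located SpCas9 target: protospacer, PAM, strand and blunt cut site."""

    protospacer: str
    pam: str
    strand: str
    protospacer_interval: Interval
    cut_site: int
    window_radius: int = DEFAULT_WINDOW_RADIUS

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ReferenceError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ReferenceError("PAM must match NGG")
        if self.strand not in "+-":
            raise ReferenceError("strand must be '+' or '-'")
        if self.window_radius < 0:
            raise ReferenceError("window_radius must be >= 0")


@dataclass(frozen=True)
class FunctionalResidueSpec:
    """Residues whose codons must ALL be retained for an in-frame allele to
    count as functional.  Default: Lys196 and His201 of FGF10."""

    required_labels: tuple[str, ...] = ("Lys196", "His201")

    def __post_init__(self) -> None:
        if not self.required_labels:
            raise ReferenceError("required_labels must be non-empty")

    def validate(self, reference: AmpliconReference) -> None:
        for label in self.required_labels:
            if label not in reference.residue_annotations:
                raise ReferenceError(f"residue {label!r} not annotated on reference")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def locate_protospacer(
    reference: AmpliconReference,
    protospacer: str,
    window_radius: int = DEFAULT_WINDOW_RADIUS,
) -> GuideTarget:
    """Locate a 20-nt protospacer (followed by an NGG PAM) on either strand.

    The protospacer+PAM must occur exactly once across both strands, otherwise
    a :class:`ReferenceError` is raised.  The blunt cut site is placed 3 bp 5'
    of the PAM; on the minus strand this is 3 bp 3' of the reverse-strand PAM
    in amplicon (plus-strand) coordinates.
    """
    if len(protospacer) != 20 or set(protospacer) - _DNA:
        raise ReferenceError("protospacer must be 20 nt over {A,C,G,T}")
    seq = reference.sequence
    hits: list[GuideTarget] = []
    # plus strand: protospacer at [i, i+20), PAM at [i+20, i+23)
    i = seq.find(protospacer)
    while i != -1:
        pam = seq[i + 20:i + 23]
        if len(pam) == 3 and pam[1:] == "GG":
            hits.append(GuideTarget(protospacer, pam, "+", Interval(i, i + 20),
                                    cut_site=i + 17, window_radius=window_radius))
        i = seq.find(protospacer, i + 1)
    # minus strand: search for revcomp(PAM + protospacer) on the plus strand,
    # i.e. revcomp(protospacer) preceded-by-CCN in plus coordinates.
    rc = _revcomp(protospacer)
    i = seq.find(rc)
    while i != -1:
        pam_plus = seq[i - 3:i]  # revcomp of the minus-strand PAM
        if len(pam_plus) == 3 and pam_plus[:2] == "CC":
            hits.append(GuideTarget(protospacer, _revcomp(pam_plus), "-",
                                    Interval(i, i + 20), cut_site=i + 3,
                                    window_radius=window_radius))
        i = seq.find(rc, i + 1)
    if not hits:
        raise ReferenceError(f"protospacer {protospacer} not found with NGG PAM")
    if len(hits) > 1:
        raise ReferenceError(f"protospacer {protospacer} matches multiple sites")
    return hits[0]


def predicted_cleavage_fragments(
    reference: AmpliconReference, target: GuideTarget
) -> tuple[int, int]:
    """Fragment lengths produced by cutting the amplicon at the guide's cut
    site (as in an enzyme mismatch cleavage assay); they sum to the amplicon
    length."""
    L = len(reference)
    if not 0 <= target.cut_site <= L:
        raise ReferenceError("cut site outside amplicon")
    return target.cut_site, L - target.cut_site


def codon_interval(reference: AmpliconReference, residue_label: str) -> Interval:
    """Codon interval for an annotated residue label."""
    try:
        return reference.residue_annotations[residue_label]
    except KeyError:
        raise ReferenceError(f"unknown residue label {residue_label!r}") from None
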