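"""Synthetic mosaic-embryo data generator.

Emulates the study design the pipeline targets: per-tissue amplicon deep
sequencing of CRISPR founder (F0) embryos that are somatic mosaics — a mixture
of wild-type, in-frame and frameshift alleles whose per-tissue fractions are
fixed by the zygotic editing history — plus phenotype readouts generated as a
linear function of the functional-allele dose with Gaussian noise.

Reads are full-length amplicon copies (single-end) with an independent
per-base substitution error; sequencing indel errors are off by default but
can be enabled to stress the quantification-window filter.  Large-insertion
alleles do not amplify into sequenceable reads (they escape short-read
genotyping); they appear instead in the synthetic electrophoresis peak table,
mirroring how such alleles are detected and corrected for in practice.

All randomness flows from explicit integer seeds; identical specs and seeds
give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference_model import (
    AmpliconReference,
    FunctionalResidueSpec,
    GuideTarget,
    Interval,
    locate_protospacer,
)
from .signatures import (
    WILD_TYPE,
    IndelSignature,
    apply_signature,
    parse_signature,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# allele and sample specifications


@dataclass(frozen=True)
class AlleleSpec:
    """One allele of a mosaic sample: wild type, a small indel, or a large
    insertion (detected by electrophoresis, invisible to short reads)."""

    fraction: float
    signature: IndelSignature | None = None  # None => wild type
    large_insertion_size: int | None = None  # bp, exclusive with signature

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.signature is not None and self.large_insertion_size is not None:
            raise ValueError("allele cannot be both indel and large insertion")
        if self.large_insertion_size is not None and self.large_insertion_size <= 0:
            raise ValueError("large insertion size must be positive")

    @property
    def kind(self) -> str:
        if self.large_insertion_size is not None:
            return "large_insertion"
        return "wild_type" if self.signature is None else "indel"

    @property
    def label(self) -> str:
        if self.large_insertion_size is not None:
            return f"largeins:{self.large_insertion_size}"
        return "wt" if self.signature is None else str(self.signature)


def allele_spec_from_label(label: str, fraction: float) -> AlleleSpec:
    """Build an :class:`AlleleSpec` from a signature label, e.g. ``"wt"``,
    ``"del:309:3"`` or ``"largeins:300"``."""
    if label.startswith("largeins:"):
        return AlleleSpec(fraction, large_insertion_size=int(label.split(":")[1]))
    sig = parse_signature(label)
    return AlleleSpec(fraction, signature=None if sig is WILD_TYPE else sig)


@dataclass(frozen=True)
class MosaicSampleSpec:
    """Allele spectrum and sequencing parameters for one tissue sample."""

    sample_id: str
    tissue: str
    alleles: tuple[AlleleSpec, ...]
    depth: int
    substitution_error_rate: float = 0.0
    indel_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.substitution_error_rate <= 0.1:
            raise ValueError("substitution_error_rate must be in [0, 0.1]")
        if not 0.0 <= self.indel_error_rate <= 0.1:
            raise ValueError("indel_error_rate must be in [0, 0.1]")
        total = sum(a.fraction for a in self.alleles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class PhenotypeModel:
    """Linear dose model: phenotype = a + b * functional_percent + noise."""

    intercept: float = 0.0
    slope: float = 0.2
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FastqRecord:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"record {self.id}: sequence/quality length mismatch")


# ---------------------------------------------------------------------------
# the bundled synthetic reference


def synthetic_reference(
    window_radius: int = 20,
) -> tuple[AmpliconReference, GuideTarget]:
    """Construct the repository's synthetic 501-bp fixture amplicon.

    The exon-3 amplicon of the real locus is not public, so a synthetic stand-in
    is built that satisfies every known structural constraint: 501 bp total, a
    uniquely-placed protospacer with NGG PAM cutting at position 309 (mismatch
    cleavage fragments 309 + 192), a stop-free coding segment, and two
    annotated critical codons (Lys196 = AAA, His201 = CAC) downstream of the
    cut, five residues apart.
    """
    rng = np.random.default_rng(2020_1015)
    cs_start, cs_end = 300, 375
    # stop-free random codons for the coding segment
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) * 3 < cs_end - cs_start:
        c = "".join(chr(b) for b in rng.choice(_BASES, size=3))
        if c not in stops:
            codons.append(c)
    coding = list("".join(codons))
    # PAM at [312,315) => cut at 309; TGG is in-frame Trp, not a stop
    coding[12:15] = "TGG"
    coding[18:21] = "AAA"  # Lys196 at [318, 321)
    coding[33:36] = "CAC"  # His201 at [333, 336)
    seq = None
    for attempt in range(100):
        flank5 = "".join(chr(b) for b in rng.choice(_BASES, size=cs_start))
        flank3 = "".join(chr(b) for b in rng.choice(_BASES, size=501 - cs_end))
        candidate = flank5 + "".join(coding) + flank3
        ref = AmpliconReference(
            name="synthetic_fgf10_exon3",
            sequence=candidate,
            coding_segment=Interval(cs_start, cs_end),
            frame_offset=0,
            residue_annotations={
                "Lys196": Interval(318, 321),
                "His201": Interval(333, 336),
            },
        )
        try:
            target = locate_protospacer(
                ref, candidate[292:312], window_radius=window_radius
            )
        except Exception:
            continue
        if target.cut_site == 309 and "*" not in ref.translate_coding():
            seq = candidate
            break
    assert seq is not None, "fixture construction failed"
    return ref, target


# ---------------------------------------------------------------------------
# read simulation


def _mutate_substitutions(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(codes.size) < rate
    n = int(hit.sum())
    if n == 0:
        return seq
    # substitute to a uniformly random *different* base
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = _BASES[_BASES != codes[i]]
        codes[i] = rng.choice(choices)
    return codes.tobytes().decode()


def _mutate_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:  # deletion
            continue
        out.append(ch)
        if rate / 2 <= r < rate:  # insertion after this base
            out.append(chr(rng.choice(_BASES)))
    return "".join(out)


def simulate_reads(
    spec: MosaicSampleSpec, reference: AmpliconReference
) -> list[FastqRecord]:
    """Simulate one sample's FASTQ records.

    Reads are drawn from the allele spectrum by a seeded multinomial; each base
    is substituted independently at ``substitution_error_rate``.  Read ids
    encode the sample and the true allele index so recovery tests can consult
    ground truth.  Large-insertion alleles contribute no reads.
    """
    rng = np.random.default_rng(spec.seed)
    fractions = [a.fraction for a in spec.alleles]
    counts = rng.multinomial(spec.depth, fractions)
    allele_seqs: list[str | None] = []
    for a in spec.alleles:
        if a.large_insertion_size is not None:
            allele_seqs.append(None)
        elif a.signature is None:
            allele_seqs.append(reference.sequence)
        else:
            allele_seqs.append(apply_signature(reference.sequence, a.signature))
    records: list[FastqRecord] = []
    serial = 0
    for ai, (n, seq) in enumerate(zip(counts, allele_seqs)):
        if seq is None:
            continue  # escapes short-read sequencing
        errorfree = (
            spec.substitution_error_rate == 0.0 and spec.indel_error_rate == 0.0
        )
        qual = "I" * len(seq)
        for _ in range(int(n)):
            read = seq
            if not errorfree:
                if spec.indel_error_rate > 0.0:
                    read = _mutate_indels(read, spec.indel_error_rate, rng)
                if spec.substitution_error_rate > 0.0:
                    read = _mutate_substitutions(
                        read, spec.substitution_error_rate, rng
                    )
            records.append(
                FastqRecord(
                    id=f"{spec.sample_id}:allele{ai}:{serial}",
                    sequence=read,
                    quality=qual if len(read) == len(seq) else "I" * len(read),
                )
            )
            serial += 1
    return records


def electrophoresis_peaks(
    spec: MosaicSampleSpec, reference: AmpliconReference
) -> pd.DataFrame:
    """Idealized capillary-electrophoresis peak table for a sample: one main
    band at the amplicon size plus one band per large-insertion allele, with
    molarities proportional to allele fractions.  Columns: size_bp, molarity."""
    L = len(reference)
    main = sum(
        a.fraction for a in spec.alleles if a.large_insertion_size is None
    )
    rows = [(L, main)]
    for a in spec.alleles:
        if a.large_insertion_size is not None:
            rows.append((L + a.large_insertion_size, a.fraction))
    return pd.DataFrame(rows, columns=["size_bp", "molarity"])


# ---------------------------------------------------------------------------
# phenotype simulation


def simulate_phenotype(
    functional_percent: float,
    model: PhenotypeModel,
    seed: int,
    clamp: bool = True,
) -> float:
    """Draw one phenotype value from the linear dose model."""
    if not 0.0 <= functional_percent <= 100.0:
        raise ValueError("functional_percent must be in [0, 100]")
    rng = np.random.default_rng(seed)
    value = model.intercept + model.slope * functional_percent
    if model.noise_sd > 0:
        value += rng.normal(0.0, model.noise_sd)
    if clamp:
        value = min(100.0, max(0.0, value))
    return float(value)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class EmbryoSpec:
    """Allele spectra per tissue for one embryo."""

    embryo_id: str
    tissues: dict[str, tuple[AlleleSpec, ...]] = field(default_factory=dict)


@dataclass
class CohortResult:
    reads: dict[str, list[FastqRecord]]
    truth: pd.DataFrame
    embryos: pd.DataFrame


def _functional_fraction(
    alleles: Sequence[AlleleSpec],
    reference: AmpliconReference,
    target: GuideTarget,
    residues: FunctionalResidueSpec,
) -> float:
    # local import: classification depends on signatures, not on this module
    from .classification import AlleleCategory, classify_signature

    total = 0.0
    for a in alleles:
        if a.large_insertion_size is not None:
            continue
        sig = WILD_TYPE if a.signature is None else a.signature
        cat = classify_signature(sig, reference, target, residues)
        if cat in (AlleleCategory.WILD_TYPE, AlleleCategory.INFRAME_FUNCTIONAL):
            total += a.fraction
    return total


def simulate_cohort(
    embryos: Sequence[EmbryoSpec],
    reference: AmpliconReference,
    target: GuideTarget,
    depth: int = 5000,
    substitution_error_rate: float = 0.0,
    phenotype_model: PhenotypeModel = PhenotypeModel(),
    master_seed: int = 0,
    residues: FunctionalResidueSpec = FunctionalResidueSpec(),
    out_dir: str | Path | None = None,
) -> CohortResult:
    """Simulate a cohort of embryos x tissues.

    Returns per-sample reads, a truth table (sample_id, tissue, allele label,
    true fraction), and an embryo table with the true functional percent and
    the simulated phenotype.  Deterministic given ``master_seed``; optionally
    writes FASTQ files and TSV tables under ``out_dir``.
    """
    seen: set[str] = set()
    ss = np.random.SeedSequence(master_seed)
    n_samples = sum(len(e.tissues) for e in embryos)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_samples + len(embryos))]
    reads: dict[str, list[FastqRecord]] = {}
    truth_rows = []
    embryo_rows = []
    k = 0
    for e in embryos:
        for tissue, alleles in e.tissues.items():
            sample_id = f"{e.embryo_id}_{tissue}"
            if sample_id in seen:
                raise ValueError(f"duplicate sample id {sample_id}")
            seen.add(sample_id)
            spec = MosaicSampleSpec(
                sample_id=sample_id,
                tissue=tissue,
                alleles=tuple(alleles),
                depth=depth,
                substitution_error_rate=substitution_error_rate,
                seed=child_seeds[k],
            )
            k += 1
            reads[sample_id] = simulate_reads(spec, reference)
            for a in alleles:
                truth_rows.append(
                    (sample_id, tissue, a.kind, a.label, a.fraction)
                )
        first_tissue = next(iter(e.tissues.values()))
        functional = 100.0 * _functional_fraction(
            first_tissue, reference, target, residues
        )
        phenotype = simulate_phenotype(
            functional, phenotype_model, seed=child_seeds[k]
        )
        k += 1
        embryo_rows.append((e.embryo_id, functional, phenotype))
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "tissue", "allele_kind", "signature", "true_fraction"],
    )
    embryo_table = pd.DataFrame(
        embryo_rows, columns=["embryo_id", "functional_percent", "phenotype"]
    )
    if out_dir is not None:
        from .io import write_fastq, write_tsv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample_id, recs in reads.items():
            write_fastq(recs, out / f"{sample_id}.fastq")
        write_tsv(truth, out / "truth.tsv")
        write_tsv(embryo_table, out / "embryos.tsv")
    return CohortResult(reads=reads, truth=truth, embryos=embryo_table)
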