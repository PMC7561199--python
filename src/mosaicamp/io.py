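"""File formats, demultiplexing and run configuration.

FASTQ is 4-line Phred+33; references travel as single-record FASTA plus a YAML
config block (coding segment, frame offset, residue codons, protospacer,
window radius).  Demultiplexing is exact 5'-barcode prefix matching by
default (the barcode set must be prefix-free), with an optional one-mismatch
tolerance; matched barcodes are trimmed and unmatched reads land in an
``unassigned`` bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference_model import (
    AmpliconReference,
    GuideTarget,
    Interval,
    locate_protospacer,
)
from .synthetic_data import FastqRecord

logger = logging.getLogger("mosaicamp")


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTQ / FASTA / TSV


def read_fastq(path: str | Path) -> list[FastqRecord]:
    """Read a 4-line FASTQ file; raises on malformed records, naming the
    offending record."""
    records = []
    try:
        with open(path) as handle:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                if len(seq) != len(qual):
                    raise ValueError(
                        f"record {title!r} (#{i}): sequence and quality lengths differ"
                    )
                records.append(FastqRecord(id=title.split()[0], sequence=seq, quality=qual))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return records


def write_fastq(records, path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in records:
            handle.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fasta_single(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (name, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ConfigError(f"{path}: expected exactly 1 FASTA record, found {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference configuration

_REFERENCE_KEYS = {
    "fasta",
    "name",
    "coding_segment",
    "frame_offset",
    "residues",
    "protospacer",
    "window_radius",
}


def load_reference_config(path: str | Path) -> tuple[AmpliconReference, GuideTarget]:
    """Load an amplicon reference and guide target from a YAML config.

    Schema::

        fasta: amplicon.fa            # single-record FASTA
        coding_segment: [300, 375]    # 0-based half-open
        frame_offset: 0
        residues: {Lys196: [318, 321], His201: [333, 336]}
        protospacer: ACGT...          # 20 nt, must occur once with NGG PAM
        window_radius: 20             # optional
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _REFERENCE_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("fasta", "coding_segment", "residues", "protospacer"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required key {key!r}")
    fasta = path.parent / raw["fasta"]
    if not fasta.exists():
        raise ConfigError(f"{path}: reference FASTA {fasta} does not exist")
    name, sequence = read_fasta_single(fasta)
    cs = raw["coding_segment"]
    reference = AmpliconReference(
        name=raw.get("name", name),
        sequence=sequence,
        coding_segment=Interval(int(cs[0]), int(cs[1])),
        frame_offset=int(raw.get("frame_offset", 0)),
        residue_annotations={
            label: Interval(int(iv[0]), int(iv[1]))
            for label, iv in raw["residues"].items()
        },
    )
    target = locate_protospacer(
        reference,
        raw["protospacer"],
        window_radius=int(raw.get("window_radius", 20)),
    )
    return reference, target


def write_reference_config(
    reference: AmpliconReference,
    target: GuideTarget,
    directory: str | Path,
    stem: str = "reference",
) -> Path:
    """Write a reference as FASTA + YAML config; returns the config path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / f"{stem}.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{reference.name}\n{reference.sequence}\n")
    config = {
        "fasta": fasta.name,
        "name": reference.name,
        "coding_segment": [reference.coding_segment.start, reference.coding_segment.end],
        "frame_offset": reference.frame_offset,
        "residues": {
            label: [iv.start, iv.end]
            for label, iv in reference.residue_annotations.items()
        },
        "protospacer": target.protospacer,
        "window_radius": target.window_radius,
    }
    cfg_path = directory / f"{stem}.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return cfg_path


# ---------------------------------------------------------------------------
# demultiplexing


@dataclass(frozen=True)
class BarcodeMap:
    """sample_id -> 5' barcode (3' barcodes are accepted in the table but
    unused by prefix demultiplexing).  Barcodes must be unique and
    prefix-free."""

    barcodes: dict[str, str]

    def __post_init__(self) -> None:
        values = list(self.barcodes.values())
        if len(set(values)) != len(values):
            raise ConfigError("duplicate barcodes")
        for i, a in enumerate(values):
            for b in values[i + 1:]:
                if a.startswith(b) or b.startswith(a):
                    raise ConfigError(f"barcodes {a!r} and {b!r} are not prefix-free")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        frame = read_tsv(path)
        if "sample_id" not in frame.columns or "barcode" not in frame.columns:
            raise ConfigError(f"{path}: barcode table needs sample_id and barcode columns")
        return cls(dict(zip(frame["sample_id"], frame["barcode"])))


def _matches(prefix: str, barcode: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return prefix == barcode
    return sum(a != b for a, b in zip(prefix, barcode)) <= max_mismatch


def demultiplex(
    reads,
    barcodes: BarcodeMap,
    max_mismatch: int = 0,
) -> dict[str, list[FastqRecord]]:
    """Assign reads to samples by 5' barcode prefix; the matched barcode is
    trimmed.  Unmatched (or, under mismatch tolerance, ambiguous) reads go to
    the ``unassigned`` bin."""
    bins: dict[str, list[FastqRecord]] = {s: [] for s in barcodes.barcodes}
    bins["unassigned"] = []
    items = list(barcodes.barcodes.items())
    for r in reads:
        hits = [
            (sample, bc)
            for sample, bc in items
            if len(r.sequence) >= len(bc)
            and _matches(r.sequence[: len(bc)], bc, max_mismatch)
        ]
        if len(hits) == 1:
            sample, bc = hits[0]
            bins[sample].append(
                FastqRecord(
                    id=r.id,
                    sequence=r.sequence[len(bc):],
                    quality=r.quality[len(bc):],
                )
            )
        else:
            bins["unassigned"].append(r)
    return bins
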