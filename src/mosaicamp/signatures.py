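"""Canonical indel signatures.

An editing outcome at the target site is described by an anchored
:class:`IndelSignature`: a 0-based amplicon position, a deleted length, and an
inserted sequence (either may be trivial but not both).  Signatures are
serialized as ``del:309:3``, ``ins:309:A`` or ``delins:309:3:AT``; the
wild-type allele is the absence of a signature, serialized as ``wt`` and
represented in memory by the :data:`WILD_TYPE` sentinel.

Because the same physical indel inside a repeat can be placed at several
positions by an aligner, signatures are normalized to their leftmost
(lowest-coordinate) placement before use as dictionary keys.
"""

from __future__ import annotations

from dataclasses import dataclass

_DNA = set("ACGT")


class SignatureError(ValueError):
    pass


class _WildType:
    """Sentinel for the unedited allele."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "WILD_TYPE"


WILD_TYPE = _WildType()


@dataclass(frozen=True)
class IndelSignature:
    """One editing outcome: deletion of ``deleted_length`` bases starting at
    ``position``, with ``inserted_sequence`` spliced in at the same point."""

    position: int
    deleted_length: int = 0
    inserted_sequence: str = ""

    def __post_init__(self) -> None:
        if self.position < 0 or self.deleted_length < 0:
            raise SignatureError("negative position or deleted length")
        if self.deleted_length == 0 and not self.inserted_sequence:
            raise SignatureError(
                "empty signature; wild type is represented by WILD_TYPE"
            )
        if set(self.inserted_sequence) - _DNA:
            raise SignatureError("inserted sequence must be over {A,C,G,T}")

    @property
    def net_length(self) -> int:
        return len(self.inserted_sequence) - self.deleted_length

    def __str__(self) -> str:
        if self.deleted_length and self.inserted_sequence:
            return f"delins:{self.position}:{self.deleted_length}:{self.inserted_sequence}"
        if self.deleted_length:
            return f"del:{self.position}:{self.deleted_length}"
        return f"ins:{self.position}:{self.inserted_sequence}"


def parse_signature(text: str):
    """Parse a serialized signature; ``"wt"`` gives :data:`WILD_TYPE`."""
    if text == "wt":
        return WILD_TYPE
    parts = text.split(":")
    try:
        if parts[0] == "del" and len(parts) == 3:
            return IndelSignature(int(parts[1]), int(parts[2]), "")
        if parts[0] == "ins" and len(parts) == 3:
            return IndelSignature(int(parts[1]), 0, parts[2])
        if parts[0] == "delins" and len(parts) == 4:
            return IndelSignature(int(parts[1]), int(parts[2]), parts[3])
    except ValueError as exc:
        raise SignatureError(f"malformed signature {text!r}") from exc
    raise SignatureError(f"malformed signature {text!r}")


def apply_signature(reference_sequence: str, sig: IndelSignature) -> str:
    """Apply a signature to a reference sequence, returning the allele
    sequence (length ``L - deleted_length + len(inserted_sequence)``)."""
    L = len(reference_sequence)
    if sig.position + sig.deleted_length > L:
        raise SignatureError(f"signature {sig} out of bounds for length {L}")
    return (
        reference_sequence[: sig.position]
        + sig.inserted_sequence
        + reference_sequence[sig.position + sig.deleted_length:]
    )


def normalize_leftmost(reference_sequence: str, sig: IndelSignature) -> IndelSignature:
    """Shift a pure deletion or pure insertion to its leftmost equivalent
    placement (the allele sequence is unchanged).  Combined deletion+insertion
    events are returned unchanged."""
    p, d, ins = sig.position, sig.deleted_length, sig.inserted_sequence
    if d and not ins:
        while p > 0 and reference_sequence[p - 1] == reference_sequence[p + d - 1]:
            p -= 1
        return IndelSignature(p, d, "") if p != sig.position else sig
    if ins and not d:
        while p > 0 and reference_sequence[p - 1] == ins[-1]:
            ins = reference_sequence[p - 1] + ins[:-1]
            p -= 1
        return IndelSignature(p, 0, ins) if p != sig.position else sig
    return sig
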