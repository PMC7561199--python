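"""Read-to-allele calling.

Each read is globally aligned to the amplicon under an affine-gap scheme, a
canonical indel signature is extracted from the alignment if the read carries
exactly one contiguous indel event near the cut site, and reads are aggregated
into a per-sample allele table.  Reads with multiple indel events, indels far
from the quantification window, or an excess of mismatches are discarded (and
counted), never silently called wild type.

The dynamic program is jitted with numba; identical read sequences are aligned
once per sample and cached, which makes low-error deep samples cheap.
Base qualities are parsed but unused: no quality trimming is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from numba import njit

from .reference_model import AmpliconReference, GuideTarget
from .signatures import WILD_TYPE, IndelSignature, normalize_leftmost

NEG_INF = -1_000_000_000


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring; a gap run of length g scores gap_open + g*gap_extend."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -10
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentResult:
    """Global alignment as run-length operations in reference order.

    ``operations`` is a tuple of (op, length) pairs with op in {'M','X','D','I'}
    (match, mismatch, deletion from reference, insertion into read).
    """

    operations: tuple[tuple[str, int], ...]
    score: int

    @property
    def reference_length(self) -> int:
        return sum(n for op, n in self.operations if op in "MXD")

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.operations if op in "MXI")


@dataclass(frozen=True)
class Rejection:
    """A read excluded from the allele table, with the reason."""

    reason: str  # multi_event | off_window | excess_mismatches | unalignable


@dataclass(frozen=True)
class AlleleObservation:
    signature: IndelSignature | object  # IndelSignature or WILD_TYPE
    read_count: int
    fraction_percent: float

    @property
    def label(self) -> str:
        return "wt" if self.signature is WILD_TYPE else str(self.signature)


@dataclass
class AlleleTable:
    sample_id: str
    total_reads: int
    observations: list[AlleleObservation]
    discarded_reads: int
    discard_reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kept = sum(o.read_count for o in self.observations)
        if kept + self.discarded_reads != self.total_reads:
            raise ValueError("observation counts + discards != total reads")

    def fractions(self) -> dict[str, float]:
        return {o.label: o.fraction_percent for o in self.observations}


@njit(cache=True)
def _affine_dp(read, ref, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = read.size, ref.size
    M = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    X = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)  # gap in read (D)
    Y = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)  # gap in ref (I)
    tb_m = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_x = np.zeros((m + 1, n + 1), dtype=np.int8)
    tb_y = np.zeros((m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0
    for j in range(1, n + 1):
        X[0, j] = gap_open + j * gap_extend
        tb_x[0, j] = 1
    for i in range(1, m + 1):
        Y[i, 0] = gap_open + i * gap_extend
        tb_y[i, 0] = 2
    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            # N (code 4) scores as mismatch against everything
            s = match if (ri == ref[j - 1] and ri < 4) else mismatch
            best, src = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, src = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, src = Y[i - 1, j - 1], 2
            M[i, j] = best + s
            tb_m[i, j] = src
            # deletion state; on ties prefer extension (keeps runs contiguous)
            bx, sx = X[i, j - 1] + gap_extend, 1
            alt = M[i, j - 1] + gap_open + gap_extend
            if alt > bx:
                bx, sx = alt, 0
            alt = Y[i, j - 1] + gap_open + gap_extend
            if alt > bx:
                bx, sx = alt, 2
            X[i, j] = bx
            tb_x[i, j] = sx
            # insertion state
            by, sy = Y[i - 1, j] + gap_extend, 2
            alt = M[i - 1, j] + gap_open + gap_extend
            if alt > by:
                by, sy = alt, 0
            alt = X[i - 1, j] + gap_open + gap_extend
            if alt > by:
                by, sy = alt, 1
            Y[i, j] = by
            tb_y[i, j] = sy
    state = 0
    score = M[m, n]
    if X[m, n] > score:
        score, state = X[m, n], 1
    if Y[m, n] > score:
        score, state = Y[m, n], 2
    ops = np.empty(m + n, dtype=np.int8)
    k = m + n
    i, j = m, n
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ops[k] = 0 if (read[i - 1] == ref[j - 1] and read[i - 1] < 4) else 1
            state = tb_m[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 2
            state = tb_x[i, j]
            j -= 1
        else:
            ops[k] = 3
            state = tb_y[i, j]
            i -= 1
    return score, ops[k:]


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def align_global(
    read: str, reference_sequence: str, scoring: Scoring = DEFAULT_SCORING
) -> AlignmentResult:
    """Optimal global alignment of a read against the amplicon under affine-gap
    scoring.  On co-optimal ties the traceback prefers diagonal moves and gap
    extensions, which places gap runs toward lower reference coordinates; the
    extracted signature is additionally leftmost-normalized.  ``N`` in either
    sequence scores as a mismatch."""
    if not read or not reference_sequence:
        raise ValueError("empty sequence")
    score, op_codes = _affine_dp(
        _encode(read),
        _encode(reference_sequence),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    runs: list[tuple[str, int]] = []
    chars = "MXDI"
    for c in op_codes:
        ch = chars[c]
        if runs and runs[-1][0] == ch:
            runs[-1] = (ch, runs[-1][1] + 1)
        else:
            runs.append((ch, 1))
    return AlignmentResult(operations=tuple(runs), score=int(score))


def extract_signature(
    alignment: AlignmentResult,
    target: GuideTarget,
    reference_sequence: str,
    read: str,
    max_mismatch_fraction: float = 0.1,
):
    """Extract a canonical indel signature from an alignment.

    Returns :data:`WILD_TYPE` for indel-free reads within the mismatch budget;
    an :class:`IndelSignature` (leftmost-normalized) when the read carries
    exactly one contiguous indel event — a deletion run, an insertion run, or
    one adjacent deletion+insertion pair — whose reference footprint intersects
    the quantification window ``[cut - r, cut + r]``; otherwise a
    :class:`Rejection` naming the reason.
    """
    mismatches = 0
    aligned = 0
    ref_pos = 0
    read_pos = 0
    # each event: [ref_start, deleted_len, inserted_seq]
    events: list[list] = []
    open_event = False
    for op, length in alignment.operations:
        if op in "MX":
            aligned += length
            if op == "X":
                mismatches += length
            ref_pos += length
            read_pos += length
            open_event = False
            continue
        if not open_event:
            events.append([ref_pos, 0, ""])
            open_event = True
        if op == "D":
            events[-1][1] += length
            ref_pos += length
        else:  # I
            events[-1][2] += read[read_pos:read_pos + length]
            read_pos += length
    if aligned > 0 and mismatches / aligned > max_mismatch_fraction:
        return Rejection("excess_mismatches")
    if not events:
        return WILD_TYPE
    if len(events) > 1:
        return Rejection("multi_event")
    start, deleted, inserted = events[0]
    lo = target.cut_site - target.window_radius
    hi = target.cut_site + target.window_radius
    if deleted:
        in_window = start <= hi and start + deleted >= lo
    else:
        in_window = lo <= start <= hi
    if not in_window:
        return Rejection("off_window")
    sig = IndelSignature(start, deleted, inserted)
    return normalize_leftmost(reference_sequence, sig)


def call_read(
    read: str,
    reference: AmpliconReference,
    target: GuideTarget,
    scoring: Scoring = DEFAULT_SCORING,
    max_mismatch_fraction: float = 0.1,
):
    """Align one read and extract its signature, wild-type call or rejection."""
    aln = align_global(read, reference.sequence, scoring)
    return extract_signature(
        aln, target, reference.sequence, read, max_mismatch_fraction
    )


def build_allele_table(
    reads: Iterable,
    reference: AmpliconReference,
    target: GuideTarget,
    sample_id: str = "sample",
    scoring: Scoring = DEFAULT_SCORING,
    max_mismatch_fraction: float = 0.1,
) -> AlleleTable:
    """Aggregate one sample's reads into an allele table.

    ``reads`` may be FASTQ records (anything with a ``.sequence`` attribute) or
    plain strings.  Fractions are percent of non-discarded reads; rows are
    sorted by descending count, then by signature position (wild type first).
    """
    cache: dict[str, object] = {}
    counts: dict[object, int] = {}
    discard_reasons: dict[str, int] = {}
    total = 0
    for r in reads:
        seq = r if isinstance(r, str) else r.sequence
        total += 1
        res = cache.get(seq)
        if res is None:
            try:
                res = call_read(
                    seq, reference, target, scoring, max_mismatch_fraction
                )
            except ValueError:
                res = Rejection("unalignable")
            cache[seq] = res
        if isinstance(res, Rejection):
            discard_reasons[res.reason] = discard_reasons.get(res.reason, 0) + 1
        else:
            key = "wt" if res is WILD_TYPE else res
            counts[key] = counts.get(key, 0) + 1
    discarded = sum(discard_reasons.values())
    kept = total - discarded
    if kept == 0:
        raise ValueError(f"sample {sample_id}: no reads survived filtering")
    observations = [
        AlleleObservation(
            signature=WILD_TYPE if key == "wt" else key,
            read_count=n,
            fraction_percent=100.0 * n / kept,
        )
        for key, n in counts.items()
    ]
    observations.sort(
        key=lambda o: (
            -o.read_count,
            -1 if o.signature is WILD_TYPE else o.signature.position,
        )
    )
    return AlleleTable(
        sample_id=sample_id,
        total_reads=total,
        observations=observations,
        discarded_reads=discarded,
        discard_reasons=discard_reasons,
    )
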