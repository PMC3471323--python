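"""Streaming paired FASTQ input, encoding/mask detection, and assembled output.

Mate files from an Illumina run are positionally synchronized: record *k* of
the forward file pairs with record *k* of the reverse file.  We stream both
files in lockstep (O(1) memory), verify identifiers after stripping mate
designators, convert quality characters to error probabilities and flag
quality-masked tails (the trailing run of phred <= 2 that CASAVA uses to
mark unreliable read ends).
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .quality import PHRED33, PHRED64, PhredEncoding, error_prob_from_char, phred_from_prob

__all__ = [
    "SequenceRead",
    "ReadPair",
    "read_paired",
    "detect_encoding",
    "detect_masked_tail",
    "write_assemblies",
    "PairSyncError",
    "MalformedRecordError",
]

_VALID = frozenset("ACGTN")

#: Phred value at or below which a trailing run counts as a quality mask
#: ('B' in phred+64 output, '#' in phred+33).
MASK_PHRED = 2


class PairSyncError(ValueError):
    """Forward/reverse files desynchronized: identifiers disagree."""


class MalformedRecordError(ValueError):
    """A FASTQ record violating the format contract."""


@dataclass
class SequenceRead:
    """One sequencing read with per-base error probabilities and mask flags."""

    identifier: str
    mate: int
    sequence: str
    qualities: np.ndarray  # per-base error probability eps
    masked: np.ndarray  # bool, True inside the quality-masked tail
    quality_string: str = ""  # raw characters, kept for bit-exact round trips

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """A forward read and its reverse mate, sharing one template."""

    forward: SequenceRead
    reverse: SequenceRead

    @property
    def identifier(self) -> str:
        return self.forward.identifier


def _open_text(path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _normalize_id(title: str) -> tuple[str, int | None]:
    """Strip mate designators from a FASTQ title line.

    Handles the legacy ``name/1`` suffix and the CASAVA 1.8 comment style
    ``name 1:N:0:INDEX``; returns the bare identifier and the mate number if
    one was recognized.
    """
    name, _, comment = title.partition(" ")
    mate: int | None = None
    if comment[:2] in ("1:", "2:"):
        mate = int(comment[0])
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        mate = int(name[-1])
        name = name[:-2]
    return name, mate


def detect_masked_tail(qual_chars: str, enc: PhredEncoding = PHRED33) -> np.ndarray:
    """Flag the maximal trailing run of phred <= 2 as quality-masked.

    Interior low-quality bases not connected to the suffix are left
    unflagged: masking is a property of read *ends* in the Illumina
    pipeline.
    """
    n = len(qual_chars)
    masked = np.zeros(n, dtype=bool)
    i = n
    while i > 0 and ord(qual_chars[i - 1]) - enc.ascii_offset <= MASK_PHRED:
        i -= 1
    masked[i:] = True
    return masked


def detect_encoding(sample: Iterable[str]) -> PhredEncoding:
    """Guess the phred offset from a sample of quality strings.

    Any character below ASCII 59 can only occur at offset 33; a sample
    confined to [64, ...] with at least one character above 74 (phred > 10
    at offset 64, but phred > 41 at offset 33) indicates offset 64.
    Ambiguous samples default to offset 33 with a warning.
    """
    lo, hi = 0x7F, 0
    seen = False
    for q in sample:
        for ch in q:
            a = ord(ch)
            seen = True
            lo = min(lo, a)
            hi = max(hi, a)
    if seen and lo < 59:
        return PHRED33
    if seen and lo >= 64 and hi > 74:
        return PHRED64
    warnings.warn(
        "quality encoding ambiguous; defaulting to phred+33", stacklevel=2
    )
    return PHRED33


def _parse_read(
    title: str, seq: str, qual: str, mate: int, enc: PhredEncoding
) -> SequenceRead:
    seq = seq.upper()
    if len(seq) != len(qual):
        raise MalformedRecordError(
            f"record {title!r}: sequence length {len(seq)} != quality length {len(qual)}"
        )
    bad = set(seq) - _VALID
    if bad:
        raise MalformedRecordError(
            f"record {title!r}: invalid sequence symbol(s) {sorted(bad)}"
        )
    name, parsed_mate = _normalize_id(title)
    eps = np.fromiter(
        (error_prob_from_char(ch, enc) for ch in qual), dtype=float, count=len(qual)
    )
    masked = detect_masked_tail(qual, enc)
    return SequenceRead(
        identifier=name,
        mate=parsed_mate if parsed_mate is not None else mate,
        sequence=seq,
        qualities=eps,
        masked=masked,
        quality_string=qual,
    )


def _strict_zip(it_f, it_r):
    """Zip two record iterators, surfacing parser errors as malformed records
    and unequal file lengths as desynchronization."""
    while True:
        try:
            rec_f = next(it_f, None)
            rec_r = next(it_r, None)
        except MalformedRecordError:
            raise
        except ValueError as exc:  # Biopython's own format diagnostics
            raise MalformedRecordError(str(exc)) from exc
        if rec_f is None and rec_r is None:
            return
        if rec_f is None or rec_r is None:
            longer = "reverse" if rec_f is None else "forward"
            raise PairSyncError(f"{longer} file has more records than its mate")
        yield rec_f, rec_r


def read_paired(
    path_f, path_r, enc: PhredEncoding = PHRED33
) -> Iterator[ReadPair]:
    """Stream synchronized read pairs from two FASTQ files (plain or gzip).

    Pairing is positional; identifiers are verified after mate-designator
    normalization and a mismatch raises :class:`PairSyncError` naming both
    records.
    """
    with _open_text(path_f) as fh_f, _open_text(path_r) as fh_r:
        it_f = FastqGeneralIterator(fh_f)
        it_r = FastqGeneralIterator(fh_r)
        for k, (rec_f, rec_r) in enumerate(_strict_zip(it_f, it_r)):
            fwd = _parse_read(*rec_f, mate=1, enc=enc)
            rev = _parse_read(*rec_r, mate=2, enc=enc)
            if fwd.identifier != rev.identifier:
                raise PairSyncError(
                    f"pair {k}: forward id {fwd.identifier!r} != reverse id "
                    f"{rev.identifier!r}"
                )
            yield ReadPair(fwd, rev)


def write_assemblies(results, fmt: str, dest) -> int:
    """Write assembled sequences as FASTA or FASTQ; returns the record count.

    The header carries the read identifier, the overlap length and the
    geometric-mean quality to six decimals.  FASTQ qualities encode the
    per-base correctness probabilities as phred scores capped at 41.
    """
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"format must be 'fasta' or 'fastq', got {fmt!r}")
    count = 0
    own = not hasattr(dest, "write")
    fh = open(dest, "wt") if own else dest
    try:
        for res in results:
            header = f"{res.identifier}:{res.overlap_len}:{res.quality:.6f}"
            if fmt == "fasta":
                fh.write(f">{header}\n{res.sequence}\n")
            else:
                chars = "".join(
                    chr(phred_from_prob(p) + 33) for p in res.probs
                )
                fh.write(f"@{header}\n{res.sequence}\n+\n{chars}\n")
            count += 1
    finally:
        if own:
            fh.close()
    return count


def write_fastq_reads(reads: Iterable[SequenceRead], dest) -> int:
    """Write raw reads back out as FASTQ, preserving quality strings verbatim."""
    count = 0
    own = not hasattr(dest, "write")
    fh = open(dest, "wt") if own else dest
    try:
        for read in reads:
            fh.write(f"@{read.identifier}/{read.mate}\n{read.sequence}\n+\n{read.quality_string}\n")
            count += 1
    finally:
        if own:
            fh.close()
    return count
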