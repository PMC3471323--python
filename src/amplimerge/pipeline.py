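"""End-to-end assembly pipeline: primers -> overlap -> consensus -> validation.

`run` streams synchronized FASTQ mate files through the assembler and
writes accepted assemblies plus a tab-separated rejection log; `run_pairs`
is the same engine over in-memory read pairs, which is what the simulator
and the tests drive.  Processing is order-preserving and single-stream, and
the returned statistics always satisfy
``pairs_read == assembled + sum(rejected.values())``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

from . import assemble as asm
from .assemble import AssemblyResult, ValidationCriteria, reconstruct, validate
from .io_fastq import ReadPair, detect_encoding, read_paired, write_assemblies
from .overlap import (
    DEFAULT_EPS_FIXED,
    DEFAULT_MIN_OVERLAP,
    best_overlap,
    orient,
)
from .primer import DEFAULT_MAX_OFFSET, DEFAULT_THRESHOLD, PrimerSpec, locate_primer
from .quality import PHRED33, PHRED64, PhredEncoding

__all__ = ["RunConfig", "RunStats", "run", "run_pairs", "assemble_pair"]

logger = logging.getLogger(__name__)

_EMPTY = np.empty(0, dtype=float)

REJECT_REASONS = (
    asm.STATUS_PRIMER_MISSING,
    asm.STATUS_NO_OVERLAP,
    asm.STATUS_LOW_QUALITY,
    asm.STATUS_TOO_SHORT,
    asm.STATUS_TOO_LONG,
    asm.STATUS_CONTAINS_N,
)


@dataclass
class RunConfig:
    """Everything one assembly run needs.

    Primers may be given as IUPAC strings (located probabilistically) or as
    integers (strip a fixed prefix length without searching); None disables
    trimming on that side.
    """

    forward: str | None = None
    reverse: str | None = None
    output: str | None = None
    log: str | None = None
    encoding: PhredEncoding | None = None  # None -> auto-detect from the input
    fwd_primer: str | int | None = None
    rev_primer: str | int | None = None
    threshold: float = 0.6
    min_len: int = 0
    max_len: int | None = None
    forbid_uncalled: bool = False
    min_overlap: int = DEFAULT_MIN_OVERLAP
    eps_fixed: float = DEFAULT_EPS_FIXED
    primer_max_offset: int = DEFAULT_MAX_OFFSET
    primer_threshold: float = DEFAULT_THRESHOLD
    output_format: str = "fasta"
    validation_hooks: tuple[str, ...] = ()

    def criteria(self) -> ValidationCriteria:
        return ValidationCriteria(
            min_quality=self.threshold,
            min_len=self.min_len,
            max_len=self.max_len,
            forbid_uncalled=self.forbid_uncalled,
        )


@dataclass
class RunStats:
    """Accounting for one run: every input pair is assembled or rejected once."""

    pairs_read: int = 0
    assembled: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1

    @property
    def total_rejected(self) -> int:
        return sum(self.rejected.values())


def _as_primer(p: str | int | None, which: str) -> PrimerSpec | int | None:
    if p is None or isinstance(p, int):
        return p
    return PrimerSpec(p, which_read=which)


def assemble_pair(pair: ReadPair, config: RunConfig) -> AssemblyResult:
    """Assemble one read pair, returning a result whose status is final.

    The returned status is ``ok`` for an accepted assembly or a reason code
    (``primer-missing``, ``no-overlap``, ``low-quality``, ``too-short``,
    ``too-long``, ``contains-N``) otherwise.
    """
    fwd_p = _as_primer(config.fwd_primer, "forward")
    rev_p = _as_primer(config.rev_primer, "reverse")

    fwd_end: int | None = None
    rev_end: int | None = None
    if isinstance(fwd_p, int):
        fwd_end = fwd_p
    elif fwd_p is not None:
        x = locate_primer(
            pair.forward, fwd_p, config.primer_max_offset, config.primer_threshold
        )
        if x is None:
            return AssemblyResult(
                pair.identifier, "", probs=_EMPTY, quality=0.0, overlap_len=0,
                status=asm.STATUS_PRIMER_MISSING,
            )
        fwd_end = x + len(fwd_p)
    if isinstance(rev_p, int):
        rev_end = rev_p
    elif rev_p is not None:
        x = locate_primer(
            pair.reverse, rev_p, config.primer_max_offset, config.primer_threshold
        )
        if x is None:
            return AssemblyResult(
                pair.identifier, "", probs=_EMPTY, quality=0.0, overlap_len=0,
                status=asm.STATUS_PRIMER_MISSING,
            )
        rev_end = x + len(rev_p)

    op = orient(pair)
    choice = best_overlap(op, config.min_overlap, config.eps_fixed)
    if choice is None:
        return AssemblyResult(
            pair.identifier, "", probs=_EMPTY, quality=0.0, overlap_len=0,
            status=asm.STATUS_NO_OVERLAP,
        )
    result = reconstruct(op, choice, fwd_end, rev_end)
    return validate(result, config.criteria(), config.validation_hooks)


def run_pairs(
    pairs: Iterable[ReadPair],
    config: RunConfig,
    *,
    collect: bool = False,
    reject_log: IO[str] | None = None,
) -> tuple[RunStats, list[AssemblyResult]]:
    """Drive the assembler over in-memory pairs; optionally keep the results.

    With ``collect`` the accepted results are returned in input order;
    rejections are tallied in the stats and, if ``reject_log`` is given,
    written as tab-separated ``identifier<TAB>reason`` lines.
    """
    stats = RunStats()
    accepted: list[AssemblyResult] = []
    for pair in pairs:
        stats.pairs_read += 1
        result = assemble_pair(pair, config)
        if result.status == asm.STATUS_OK:
            stats.assembled += 1
            if collect:
                accepted.append(result)
        else:
            stats.reject(result.status)
            if reject_log is not None:
                reject_log.write(f"{result.identifier}\t{result.status}\n")
    return stats, accepted


def _sample_encoding(path_f: str, n: int = 100) -> PhredEncoding:
    from .io_fastq import _open_text
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    sample: list[str] = []
    with _open_text(path_f) as fh:
        for i, (_, _, qual) in enumerate(FastqGeneralIterator(fh)):
            sample.append(qual)
            if i + 1 >= n:
                break
    if not sample:
        return PHRED33
    return detect_encoding(sample)


def run(config: RunConfig) -> RunStats:
    """File-to-file assembly run.

    Reads the paired FASTQ inputs, assembles each pair, writes accepted
    sequences to ``config.output`` in the configured format and rejections
    to ``config.log`` (tab-separated identifier and reason).  Returns the
    run statistics.
    """
    if config.forward is None or config.reverse is None:
        raise ValueError("forward and reverse input paths are required")
    enc = config.encoding or _sample_encoding(config.forward)
    logger.info(
        "assembling %s + %s (encoding %s, t=%.2f, eps_fixed=%g, min_overlap=%d)",
        config.forward, config.reverse, enc.name, config.threshold,
        config.eps_fixed, config.min_overlap,
    )

    pairs = read_paired(config.forward, config.reverse, enc)

    log_fh = open(config.log, "wt") if config.log else None
    try:
        stats, accepted = run_pairs(pairs, config, collect=True, reject_log=log_fh)
    finally:
        if log_fh is not None:
            log_fh.close()

    if config.output is not None:
        write_assemblies(accepted, config.output_format, config.output)
    return stats
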