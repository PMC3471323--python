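"""Consensus reconstruction, geometric-mean quality, and validation.

Given an oriented pair and a chosen overlap, the full amplicon is rebuilt
position by position.  Unpaired regions are copied from the only available
strand with probability ``1 - eps`` of being correct.  In the overlap, two
agreeing calls reinforce each other; two disagreeing calls are resolved
toward the higher-quality base, with the matched/mismatched agreement
probabilities from the quality model attached.  Uncalled bases (N) are
rescued by the partner strand at the uniform prior 1/4, and quality-masked
tails defer to the unmasked partner.  Located primer windows are clipped
before any statistics are taken, so the reported score describes exactly
the reported sequence.

The overall score is the geometric mean of the per-base probabilities,
which keeps scores comparable across assemblies of different lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .overlap import OrientedPair, OverlapChoice
from .quality import prob_match_given_equal, prob_match_given_unequal

__all__ = [
    "AssemblyResult",
    "ValidationCriteria",
    "reconstruct",
    "overall_quality",
    "validate",
    "register_validator",
    "VALIDATORS",
]

_LETTERS = np.frombuffer(b"ACGTN", dtype=np.uint8)
_N = 4

# Rejection reason codes, in the order the rules are checked.
STATUS_OK = "ok"
STATUS_LOW_QUALITY = "low-quality"
STATUS_TOO_SHORT = "too-short"
STATUS_TOO_LONG = "too-long"
STATUS_CONTAINS_N = "contains-N"
STATUS_NO_OVERLAP = "no-overlap"
STATUS_PRIMER_MISSING = "primer-missing"


@dataclass
class AssemblyResult:
    identifier: str
    sequence: str
    probs: np.ndarray
    quality: float
    overlap_len: int
    n_mismatches_resolved: int = 0
    n_uncalled_rescued: int = 0
    status: str = STATUS_OK


@dataclass(frozen=True)
class ValidationCriteria:
    """User-facing accept/reject rules for assembled sequences."""

    min_quality: float = 0.6
    min_len: int = 0
    max_len: int | None = None
    forbid_uncalled: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_quality <= 1.0:
            raise ValueError("min_quality must lie in [0, 1]")
        if self.max_len is not None and self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


#: Registry for user-supplied validation hooks: name -> predicate(sequence, probs).
VALIDATORS: dict[str, Callable[[str, np.ndarray], bool]] = {}


def register_validator(name: str):
    """Register a named validation predicate run after the built-in rules.

    The predicate takes ``(sequence, probs)`` and returns True to accept.
    A failing hook sets the result status to the hook's name.
    """

    def deco(fn: Callable[[str, np.ndarray], bool]):
        VALIDATORS[name] = fn
        return fn

    return deco


def overall_quality(probs: Sequence[float] | np.ndarray) -> float:
    """Geometric mean of per-base correctness probabilities.

    Returns 0 if any probability is 0; raises on an empty input.
    """
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise ValueError("cannot score an empty sequence")
    if np.any(p <= 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(p))))


def _overlap_consensus(
    op: OrientedPair, f: int, c: int
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Consensus codes and probabilities for the c overlapped positions."""
    x = op.fwd_codes[f : f + c]
    y = op.rev_codes[:c]
    ex = op.fwd_eps[f : f + c]
    ey = op.rev_eps[:c]
    xm = op.fwd_masked[f : f + c]
    ym = op.rev_masked[:c]

    x_n = x == _N
    y_n = y == _N
    both_n = x_n & y_n
    one_n = x_n ^ y_n
    any_n = x_n | y_n
    equal = (x == y) & ~any_n
    any_m = (xm | ym) & ~any_n
    both_m = xm & ym & ~any_n
    one_m = (xm ^ ym) & ~any_n

    # Base choice: N defers to the called strand; agreement keeps the base;
    # a masked call defers to the unmasked one; otherwise the lower-eps call
    # wins, ties toward the forward read (earlier cycles, cleaner signal).
    fwd_wins = ex <= ey
    codes = np.where(
        one_n,
        np.where(x_n, y, x),
        np.where(
            equal,
            x,
            np.where(one_m, np.where(xm, y, x), np.where(fwd_wins, x, y)),
        ),
    )
    codes = np.where(both_n, _N, codes)

    p_eq = prob_match_given_equal(ex, ey)
    p_neq = prob_match_given_unequal(ex, ey)
    eps_unmasked = np.where(xm, ey, ex)
    probs = np.select(
        [
            any_n,
            both_m,
            one_m & equal,
            one_m & ~equal,
            equal,
        ],
        [
            0.25,
            0.25,
            1.0 - eps_unmasked,
            0.25,
            p_eq,
        ],
        default=p_neq,
    )
    n_mismatch = int((~any_n & ~equal).sum())
    n_rescued = int(one_n.sum())
    return codes, probs, n_mismatch, n_rescued


def reconstruct(
    op: OrientedPair,
    choice: OverlapChoice,
    fwd_primer_end: int | None = None,
    rev_primer_end: int | None = None,
) -> AssemblyResult:
    """Rebuild the amplicon for the chosen overlap and clip primer windows.

    ``fwd_primer_end`` is the first biological position of the forward read;
    ``rev_primer_end`` plays the same role for the reverse read as
    sequenced, which maps to the trailing end of the assembly.  Clipping
    happens before the quality statistic so the score describes the
    reported sequence.
    """
    f, c, r = choice.f, choice.c, choice.r

    codes_mid, probs_mid, n_mismatch, n_rescued = _overlap_consensus(op, f, c)

    codes = np.concatenate([op.fwd_codes[:f], codes_mid, op.rev_codes[c:]])
    probs = np.concatenate(
        [1.0 - op.fwd_eps[:f], probs_mid, 1.0 - op.rev_eps[c:]]
    )

    total = f + c + r
    start = fwd_primer_end or 0
    stop = total - (rev_primer_end or 0)
    if stop <= start:
        codes = codes[:0]
        probs = probs[:0]
    else:
        codes = codes[start:stop]
        probs = probs[start:stop]

    sequence = _LETTERS[codes].tobytes().decode("ascii")
    quality = overall_quality(probs) if probs.size else 0.0
    return AssemblyResult(
        identifier=op.identifier,
        sequence=sequence,
        probs=probs,
        quality=quality,
        overlap_len=c,
        n_mismatches_resolved=n_mismatch,
        n_uncalled_rescued=n_rescued,
    )


def validate(
    result: AssemblyResult,
    criteria: ValidationCriteria,
    hooks: Sequence[str] = (),
) -> AssemblyResult:
    """Set the result status from the first failing rule.

    Rules run in a fixed order — quality, too-short, too-long, uncalled
    bases — followed by any registered hooks; only the first failure is
    recorded.
    """
    if result.quality < criteria.min_quality or not result.sequence:
        result.status = STATUS_LOW_QUALITY if result.sequence else STATUS_TOO_SHORT
        return result
    n = len(result.sequence)
    if n < criteria.min_len:
        result.status = STATUS_TOO_SHORT
        return result
    if criteria.max_len is not None and n > criteria.max_len:
        result.status = STATUS_TOO_LONG
        return result
    if criteria.forbid_uncalled and "N" in result.sequence:
        result.status = STATUS_CONTAINS_N
        return result
    for name in hooks:
        if not VALIDATORS[name](result.sequence, result.probs):
            result.status = name
            return result
    result.status = STATUS_OK
    return result
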