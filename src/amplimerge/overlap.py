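"""Reverse-read orientation and maximum-likelihood overlap selection.

After reverse-complementing the reverse read, a candidate overlap length
``c`` aligns the last ``c`` bases of the forward read with the first ``c``
bases of the oriented reverse read.  The likelihood of the observed pair
given ``c`` multiplies a 1/4 prior for every unpaired position with, for
each overlapped position, the probability that the two true bases agree —
evaluated at a fixed nominal error rate ``eps_fixed``, since at this stage
only the agreement pattern matters, not the per-base qualities.  The ``c``
maximizing the likelihood is selected by exhaustive scan (gapped alignments
are not considered: indels are rare on this platform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_fastq import ReadPair, SequenceRead
from .quality import (
    UNIFORM_PRIOR,
    prob_match_given_equal,
    prob_match_given_unequal,
)

__all__ = ["OrientedPair", "OverlapChoice", "orient", "overlap_log_score", "best_overlap"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# numeric codes: A=0 C=1 G=2 T=3 N=4
_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
_N_CODE = 4

DEFAULT_EPS_FIXED = 0.01
DEFAULT_MIN_OVERLAP = 1


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class OrientedPair:
    """Forward read as sequenced plus the reverse read in forward coordinates.

    The reverse read's sequence is reverse-complemented and its error
    probabilities and mask flags reversed in lockstep, so that overlapped
    positions compare ``fwd[f + i]`` against ``rev_rc[i]``.
    """

    identifier: str
    fwd_seq: str
    fwd_eps: np.ndarray
    fwd_masked: np.ndarray
    rev_rc_seq: str
    rev_eps: np.ndarray
    rev_masked: np.ndarray

    def __post_init__(self) -> None:
        self._fwd_codes = _encode(self.fwd_seq)
        self._rev_codes = _encode(self.rev_rc_seq)

    @property
    def fwd_codes(self) -> np.ndarray:
        return self._fwd_codes

    @property
    def rev_codes(self) -> np.ndarray:
        return self._rev_codes


@dataclass(frozen=True)
class OverlapChoice:
    """A selected overlap length with its log likelihood.

    ``f`` and ``r`` are the unpaired forward/reverse lengths; the assembled
    length before primer clipping is ``f + c + r``.
    """

    c: int
    log_score: float
    f: int
    r: int


def orient(pair: ReadPair) -> OrientedPair:
    """Put both mates of a pair into forward-template coordinates."""
    rev = pair.reverse
    return OrientedPair(
        identifier=pair.identifier,
        fwd_seq=pair.forward.sequence,
        fwd_eps=np.asarray(pair.forward.qualities, dtype=float),
        fwd_masked=np.asarray(pair.forward.masked, dtype=bool),
        rev_rc_seq=reverse_complement(rev.sequence),
        rev_eps=np.asarray(rev.qualities, dtype=float)[::-1].copy(),
        rev_masked=np.asarray(rev.masked, dtype=bool)[::-1].copy(),
    )


def _match_counts(op: OrientedPair, c: int) -> tuple[int, int, int]:
    """(equal, unequal, uncalled) counts over the c overlapped positions."""
    a = op.fwd_codes[len(op.fwd_codes) - c :]
    b = op.rev_codes[:c]
    any_n = (a == _N_CODE) | (b == _N_CODE)
    n_n = int(any_n.sum())
    n_eq = int(((a == b) & ~any_n).sum())
    return n_eq, c - n_eq - n_n, n_n


def overlap_log_score(op: OrientedPair, c: int, eps_fixed: float = DEFAULT_EPS_FIXED) -> float:
    """Log likelihood of the oriented pair for overlap length ``c``."""
    nf, nr = len(op.fwd_codes), len(op.rev_codes)
    if not 1 <= c <= min(nf, nr):
        raise ValueError(f"overlap length {c} outside [1, {min(nf, nr)}]")
    n_eq, n_neq, n_n = _match_counts(op, c)
    log_q = math.log(UNIFORM_PRIOR)
    log_eq = math.log(prob_match_given_equal(eps_fixed, eps_fixed))
    log_neq = math.log(prob_match_given_unequal(eps_fixed, eps_fixed))
    f, r = nf - c, nr - c
    return (f + r + n_n) * log_q + n_eq * log_eq + n_neq * log_neq


def best_overlap(
    op: OrientedPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    eps_fixed: float = DEFAULT_EPS_FIXED,
) -> OverlapChoice | None:
    """Overlap length maximizing the likelihood; ties broken toward larger ``c``.

    Returns None when the reads are too short to overlap by ``min_overlap``
    (the pair is then discarded upstream as "no-overlap").
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    nf, nr = len(op.fwd_codes), len(op.rev_codes)
    cmax = min(nf, nr)
    if cmax < min_overlap:
        return None
    log_q = math.log(UNIFORM_PRIOR)
    log_eq = math.log(prob_match_given_equal(eps_fixed, eps_fixed))
    log_neq = math.log(prob_match_given_unequal(eps_fixed, eps_fixed))
    best_c, best_score = None, -math.inf
    for c in range(min_overlap, cmax + 1):
        n_eq, n_neq, n_n = _match_counts(op, c)
        score = (nf + nr - 2 * c + n_n) * log_q + n_eq * log_eq + n_neq * log_neq
        if score >= best_score:  # >= : ties go to the larger c
            best_c, best_score = c, score
    assert best_c is not None
    return OverlapChoice(c=best_c, log_score=best_score, f=nf - best_c, r=nr - best_c)
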