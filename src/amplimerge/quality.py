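"""Per-base error probabilities and base-agreement probabilities.

Illumina base callers attach a phred-scaled quality score to every base,
encoding the probability ``eps`` that the call is wrong::

    eps = 10 ** (-(ascii(ch) - offset) / 10)

with ASCII offset 33 (CASAVA >= 1.8) or 64 (earlier pipelines).  From the
two per-base error probabilities of an aligned read pair we compute the
probability that the *true* underlying nucleotides agree, assuming a uniform
prior over nucleotides and that miscalls hit the three alternative bases
with equal probability.  These probabilities are the scoring currency of the
whole assembler: primer location, overlap selection and per-base consensus
quality all consume them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhredEncoding",
    "PHRED33",
    "PHRED64",
    "EPS_FLOOR",
    "UNIFORM_PRIOR",
    "BaseCall",
    "error_prob_from_char",
    "prob_match_given_equal",
    "prob_match_given_unequal",
    "prob_match_uncalled",
    "prob_pair_masked",
]

#: Smallest error probability a base may carry (phred 41, the Illumina cap).
#: Clamping here keeps every probability strictly inside (0, 1) so that log
#: products never collapse to exactly zero or one.
EPS_FLOOR: float = 10.0 ** -4.1

#: Uniform prior that two random nucleotides agree.
UNIFORM_PRIOR: float = 0.25


class MalformedQualityError(ValueError):
    """A quality character below the encoding's ASCII offset."""


@dataclass(frozen=True)
class PhredEncoding:
    """ASCII encoding of phred quality scores.

    Parameters
    ----------
    ascii_offset:
        33 for CASAVA 1.8 and later ("sanger" dialect), 64 for earlier
        Illumina pipelines.
    name:
        Human-readable label used in log messages.
    """

    ascii_offset: int
    name: str

    def __post_init__(self) -> None:
        if self.ascii_offset not in (33, 64):
            raise ValueError(f"ascii_offset must be 33 or 64, got {self.ascii_offset}")


PHRED33 = PhredEncoding(33, "casava-1.8")
PHRED64 = PhredEncoding(64, "pre-1.8")


@dataclass(frozen=True)
class BaseCall:
    """One called nucleotide with its error probability and mask flag."""

    nucleotide: str
    error_prob: float
    masked: bool = False

    def __post_init__(self) -> None:
        if self.nucleotide not in "ACGTN":
            raise ValueError(f"invalid nucleotide {self.nucleotide!r}")
        if not 0.0 <= self.error_prob <= 1.0:
            raise ValueError(f"error_prob outside [0, 1]: {self.error_prob}")


def error_prob_from_char(
    ch: str, enc: PhredEncoding = PHRED33, *, clamp: bool = True
) -> float:
    """Error probability for a single quality character.

    With ``clamp`` (the default) the result is floored at :data:`EPS_FLOOR`
    so no base is ever treated as error-free.  Raises
    :class:`MalformedQualityError` if the character's ASCII value lies below
    the encoding's offset.
    """
    a = ord(ch)
    if a < enc.ascii_offset:
        raise MalformedQualityError(
            f"quality character {ch!r} (ASCII {a}) below {enc.name} offset "
            f"{enc.ascii_offset}"
        )
    eps = 10.0 ** (-(a - enc.ascii_offset) / 10.0)
    if clamp and eps < EPS_FLOOR:
        eps = EPS_FLOOR
    return eps


def prob_match_given_equal(eps_x: float, eps_y: float) -> float:
    """Probability the true bases agree given the sequenced bases agree.

    ``(1 - eps_x)(1 - eps_y) + eps_x * eps_y / 3``: either both calls are
    right, or both are wrong and happen to have hit the same alternative.
    """
    return (1.0 - eps_x) * (1.0 - eps_y) + eps_x * eps_y / 3.0


def prob_match_given_unequal(eps_x: float, eps_y: float) -> float:
    """Probability the true bases agree given the sequenced bases disagree.

    ``(1/3)(1 - eps_x) eps_y + (1/3)(1 - eps_y) eps_x + (2/9) eps_x eps_y``:
    exactly one call is wrong and the error landed on the other read's true
    base, or both are wrong in a compatible way.
    """
    return (
        (1.0 - eps_x) * eps_y / 3.0
        + (1.0 - eps_y) * eps_x / 3.0
        + 2.0 / 9.0 * eps_x * eps_y
    )


def prob_match_uncalled() -> float:
    """Agreement probability when either base is uncalled (N): the uniform prior.

    An N carries no information, so the partner base's quality is irrelevant.
    """
    return UNIFORM_PRIOR


def prob_pair_masked(x: BaseCall, y: BaseCall) -> float:
    """Agreement probability when at least one base lies in a quality-masked tail.

    One masked base and matching nucleotides: trust the unmasked call,
    ``1 - eps`` of the other base.  Mismatching nucleotides, or both bases
    masked: the masked region is uninformative, fall back to the uniform
    prior 1/4.
    """
    if not (x.masked or y.masked):
        raise ValueError("prob_pair_masked requires at least one masked base")
    if x.nucleotide == "N" or y.nucleotide == "N":
        return UNIFORM_PRIOR
    if x.masked and y.masked:
        return UNIFORM_PRIOR
    if x.nucleotide != y.nucleotide:
        return UNIFORM_PRIOR
    other = y if x.masked else x
    return 1.0 - other.error_prob


def phred_from_prob(p: float, *, cap: int = 41) -> int:
    """Phred score of a per-base correctness probability ``p``.

    ``round(-10 * log10(1 - p))`` clamped to ``[0, cap]``; ``p = 1`` maps to
    the cap.  Used when writing assembled output as FASTQ.
    """
    if p >= 1.0:
        return cap
    q = round(-10.0 * math.log10(1.0 - p))
    return max(0, min(cap, q))
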