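"""Probabilistic primer location and trimming offsets.

Amplicon reads begin with the PCR primer (possibly after a few spacer
bases).  The primer is located by scanning candidate offsets ``x`` from the
read start and scoring the window ``[x, x + |P|)`` as a product of per-base
agreement probabilities: a read base inside the IUPAC set of the primer
symbol contributes the matched-bases probability, a base outside it the
mismatched-bases probability, and an N the uniform prior.  Primer bases are
assigned a fixed error probability of 10^-4.1, the best score Illumina
emits, since the primer sequence itself is known exactly.

The first offset whose per-base geometric-mean agreement probability clears
a threshold wins; everything before the end of the primer window is then
excluded from the assembled product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

from .io_fastq import SequenceRead
from .quality import (
    EPS_FLOOR,
    UNIFORM_PRIOR,
    prob_match_given_equal,
    prob_match_given_unequal,
)

__all__ = ["PrimerSpec", "primer_offset_score", "locate_primer"]

#: IUPAC nucleotide code -> frozenset of concrete bases it matches.
IUPAC_SETS: dict[str, frozenset[str]] = {
    code.upper(): frozenset(bases.upper())
    for code, bases in ambiguous_dna_values.items()
}

DEFAULT_MAX_OFFSET = 5
DEFAULT_THRESHOLD = 0.75


@dataclass(frozen=True)
class PrimerSpec:
    """A primer sequence (IUPAC codes allowed) with a fixed per-base error prob."""

    sequence: str
    eps_primer: float = EPS_FLOOR
    which_read: str = "forward"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("primer sequence must be non-empty")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in primer: {sorted(bad)}")
        if self.which_read not in ("forward", "reverse"):
            raise ValueError("which_read must be 'forward' or 'reverse'")

    def __len__(self) -> int:
        return len(self.sequence)


def primer_offset_score(read: SequenceRead, primer: PrimerSpec, x: int) -> float:
    """Log probability that the primer sits at offset ``x`` of the read.

    Sum over primer positions of the log per-base agreement probability
    (IUPAC set membership decides matched vs mismatched).  The window must
    lie inside the read.
    """
    n = len(primer)
    if x < 0 or x + n > len(read):
        raise ValueError(
            f"primer window [{x}, {x + n}) exceeds read of length {len(read)}"
        )
    eps_p = primer.eps_primer
    total = 0.0
    for i, sym in enumerate(primer.sequence):
        base = read.sequence[x + i]
        if base == "N":
            total += math.log(UNIFORM_PRIOR)
            continue
        eps_r = read.qualities[x + i]
        if base in IUPAC_SETS[sym]:
            total += math.log(prob_match_given_equal(eps_r, eps_p))
        else:
            total += math.log(prob_match_given_unequal(eps_r, eps_p))
    return total


def locate_primer(
    read: SequenceRead,
    primer: PrimerSpec,
    max_offset: int = DEFAULT_MAX_OFFSET,
    threshold: float = DEFAULT_THRESHOLD,
) -> int | None:
    """First offset in ``[0, max_offset]`` where the primer aligns, or None.

    Qualification is a per-base geometric-mean agreement probability at or
    above ``threshold`` — length-independent, so one low-quality mismatch in
    a long primer does not sink the window.  ``max_offset`` is reduced if the
    read is too short to hold the window.
    """
    n = len(primer)
    log_t = n * math.log(threshold) if threshold > 0 else -math.inf
    last = min(max_offset, len(read) - n)
    for x in range(0, last + 1):
        if primer_offset_score(read, primer, x) >= log_t:
            return x
    return None
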