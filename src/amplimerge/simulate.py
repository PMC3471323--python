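"""Synthetic paired-end amplicon reads with ground truth, and error accounting.

The generator emulates an Illumina amplicon run over a short template (by
default a 135-base stand-in for a 16S rRNA V3 region read as 108-base
mates, so the true overlap is 81 bases): per-base phred scores decline
linearly along the read, a fraction of reads end in a quality-masked tail
forced to phred 2, uncalled bases appear in low-quality positions, and
substitution errors are drawn at exactly the rate the quality characters
claim — so the simulated world is quality-consistent by construction.

``transplant_masks`` reproduces the error-free-bases-under-real-masks
design: template-derived reads that are perfectly correct but carry
supplied quality strings verbatim, so any assembly error or quality loss is
attributable to the masks alone.

``evaluate`` joins assemblies with their truth records and buckets each one
into four disjoint categories — error-free in and out, all errors retained,
input errors reduced, errors introduced — plus a correct-overlap count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io_fastq import ReadPair, SequenceRead, detect_masked_tail
from .overlap import orient, reverse_complement
from .quality import PHRED33, PhredEncoding, error_prob_from_char

__all__ = [
    "SimConfig",
    "TruthRecord",
    "ErrorAccounting",
    "random_template",
    "simulate_pairs",
    "transplant_masks",
    "evaluate",
    "naive_assembles",
    "write_simulated",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MASKED_PHRED = 2


@dataclass(frozen=True)
class SimConfig:
    """Stated world of one simulation run.

    ``template=None`` draws a random template of ``template_len`` bases from
    the run's seed (a synthetic stand-in for a real V3 region).  Quality
    declines linearly from ``qual_start`` to ``qual_end`` along each read;
    ``mask_prob`` of reads get a phred-2 tail of uniform length
    ``1..mask_max_len``; bases at or below phred 2 become N with probability
    ``n_rate``; substitutions are drawn per base at the error probability
    implied by the final quality character unless ``inject_errors`` is off.
    """

    template: str | None = None
    template_len: int = 135
    fwd_primer: str = ""
    rev_primer: str = ""
    read_len: int = 108
    qual_start: int = 40
    qual_end: int = 15
    mask_prob: float = 0.2
    mask_max_len: int = 15
    n_rate: float = 0.05
    inject_errors: bool = True
    n_pairs: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated pair.

    ``template`` is the primer-clipped biological sequence the assembler
    should reconstruct; ``overlap`` the true overlap length in read
    positions; error positions are recorded both in read coordinates (for
    the truth file) and as template-coordinate sets (for accounting).
    """

    identifier: str
    template: str
    overlap: int
    fwd_errors: tuple[int, ...]
    rev_errors: tuple[int, ...]
    fwd_errors_t: frozenset[int] = field(default=frozenset())
    rev_errors_t: frozenset[int] = field(default=frozenset())

    @property
    def n_input_errors(self) -> int:
        """Erroneous calls over both reads, counted inside the template region."""
        return len(self.fwd_errors_t) + len(self.rev_errors_t)


@dataclass
class ErrorAccounting:
    """Four disjoint outcome categories plus the correct-overlap tally."""

    error_free: int = 0
    retained: int = 0
    reduced: int = 0
    introduced: int = 0
    correct_overlap: int = 0
    total: int = 0
    input_errors: int = 0
    output_errors: int = 0

    def as_table(self) -> str:
        rows = [
            ("Error-free Input and Output", self.error_free),
            ("All Errors Retained", self.retained),
            ("Input Errors Reduced", self.reduced),
            ("Errors Introduced", self.introduced),
            ("Total", self.total),
            ("Correct Overlap", self.correct_overlap),
        ]
        return "\n".join(f"{name}\t{n}" for name, n in rows)


def random_template(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _phred_profile(cfg: SimConfig) -> np.ndarray:
    j = np.arange(cfg.read_len)
    span = max(cfg.read_len - 1, 1)
    return np.rint(cfg.qual_start + (cfg.qual_end - cfg.qual_start) * j / span).astype(int)


def _make_read(
    true_seq: str, identifier: str, mate: int, cfg: SimConfig, rng: np.random.Generator
) -> tuple[SequenceRead, np.ndarray]:
    """One simulated read plus the boolean array of erroneous positions."""
    n = len(true_seq)
    phred = _phred_profile(cfg)[:n].copy()
    if cfg.mask_prob > 0 and rng.random() < cfg.mask_prob:
        tail = int(rng.integers(1, cfg.mask_max_len + 1))
        phred[max(0, n - tail):] = MASKED_PHRED

    bases = np.frombuffer(true_seq.encode("ascii"), dtype=np.uint8).copy()

    low_q = phred <= MASKED_PHRED
    is_n = low_q & (rng.random(n) < cfg.n_rate)
    bases[is_n] = ord("N")
    phred[is_n] = MASKED_PHRED  # uncalled bases always carry the lowest score

    if cfg.inject_errors:
        eps = 10.0 ** (-phred / 10.0)
        sub = (rng.random(n) < eps) & ~is_n
        if sub.any():
            # uniform over the three alternative bases
            idx = np.nonzero(sub)[0]
            for k in idx:
                alts = [b for b in b"ACGT" if b != bases[k]]
                bases[k] = alts[int(rng.integers(3))]

    seq = bases.tobytes().decode("ascii")
    qual = "".join(chr(q + 33) for q in phred)
    errors = np.frombuffer(seq.encode(), dtype=np.uint8) != np.frombuffer(
        true_seq.encode(), dtype=np.uint8
    )
    read = SequenceRead(
        identifier=identifier,
        mate=mate,
        sequence=seq,
        qualities=np.array([error_prob_from_char(ch) for ch in qual]),
        masked=detect_masked_tail(qual),
        quality_string=qual,
    )
    return read, errors


def _template_coords(
    positions: Iterable[int], *, reverse: bool, pf: int, amplicon_len: int, tlen: int
) -> frozenset[int]:
    out = set()
    for j in positions:
        t = (amplicon_len - 1 - j - pf) if reverse else (j - pf)
        if 0 <= t < tlen:
            out.add(t)
    return frozenset(out)


def simulate_pairs(cfg: SimConfig) -> Iterator[tuple[ReadPair, TruthRecord]]:
    """Yield simulated read pairs with their truth records, deterministically.

    The forward read covers the amplicon 5' end (forward primer first); the
    reverse read is the reverse complement of the amplicon 3' end (reverse
    primer first as sequenced).  The true overlap is
    ``2 * read_len - |amplicon|`` read positions.
    """
    rng = np.random.default_rng(cfg.seed)
    template = cfg.template or random_template(cfg.template_len, rng)
    amplicon = cfg.fwd_primer + template + reverse_complement(cfg.rev_primer)
    if cfg.read_len > len(amplicon):
        raise ValueError(
            f"read_len {cfg.read_len} exceeds amplicon length {len(amplicon)}"
        )
    fwd_true = amplicon[: cfg.read_len]
    rev_true = reverse_complement(amplicon)[: cfg.read_len]
    overlap = max(0, 2 * cfg.read_len - len(amplicon))
    pf = len(cfg.fwd_primer)

    for i in range(cfg.n_pairs):
        ident = f"sim{i:06d}"
        fwd, fwd_err = _make_read(fwd_true, ident, 1, cfg, rng)
        rev, rev_err = _make_read(rev_true, ident, 2, cfg, rng)
        fwd_pos = tuple(int(k) for k in np.nonzero(fwd_err)[0])
        rev_pos = tuple(int(k) for k in np.nonzero(rev_err)[0])
        truth = TruthRecord(
            identifier=ident,
            template=template,
            overlap=overlap,
            fwd_errors=fwd_pos,
            rev_errors=rev_pos,
            fwd_errors_t=_template_coords(
                fwd_pos, reverse=False, pf=pf, amplicon_len=len(amplicon),
                tlen=len(template),
            ),
            rev_errors_t=_template_coords(
                rev_pos, reverse=True, pf=pf, amplicon_len=len(amplicon),
                tlen=len(template),
            ),
        )
        yield ReadPair(fwd, rev), truth


def transplant_masks(
    template: str,
    quality_strings: Sequence[tuple[str, str]],
    fwd_primer: str = "",
    rev_primer: str = "",
    enc: PhredEncoding = PHRED33,
) -> Iterator[tuple[ReadPair, TruthRecord]]:
    """Error-free template reads carrying the supplied quality strings verbatim.

    Each ``(forward, reverse)`` quality-string pair produces one read pair
    whose bases are exact substrings of the (primer-flanked) template; only
    the quality characters — including any phred-2 masked tails — come from
    outside.  Quality strings must not be longer than the amplicon.
    """
    amplicon = fwd_primer + template + reverse_complement(rev_primer)
    rc = reverse_complement(amplicon)
    pf = len(fwd_primer)
    for i, (qf, qr) in enumerate(quality_strings):
        if len(qf) > len(amplicon) or len(qr) > len(amplicon):
            raise ValueError(
                f"pair {i}: quality string longer than the {len(amplicon)}-base amplicon"
            )
        ident = f"mask{i:06d}"
        reads = []
        for mate, (true_seq, qual) in enumerate(
            ((amplicon[: len(qf)], qf), (rc[: len(qr)], qr)), start=1
        ):
            reads.append(
                SequenceRead(
                    identifier=ident,
                    mate=mate,
                    sequence=true_seq,
                    qualities=np.array(
                        [error_prob_from_char(ch, enc) for ch in qual]
                    ),
                    masked=detect_masked_tail(qual, enc),
                    quality_string=qual,
                )
            )
        overlap = max(0, len(qf) + len(qr) - len(amplicon))
        truth = TruthRecord(
            identifier=ident, template=template, overlap=overlap,
            fwd_errors=(), rev_errors=(),
        )
        yield ReadPair(reads[0], reads[1]), truth


class AccountingError(KeyError):
    """An assembly identifier with no matching truth record."""


def evaluate(assemblies, truths: Iterable[TruthRecord]) -> ErrorAccounting:
    """Bucket assemblies into the four error-correction outcome categories.

    Output errors are positional mismatches between the assembled sequence
    and the primer-clipped template (a length difference counts one error
    per missing or surplus base).  An assembly lands in "introduced" if any
    output error sits where both input reads were correct — including any
    length change, which fabricates or drops positions no read supports;
    otherwise error-free / reduced / retained by comparing error counts.
    """
    by_id = {t.identifier: t for t in truths}
    acc = ErrorAccounting()
    for res in assemblies:
        truth = by_id.get(res.identifier)
        if truth is None:
            raise AccountingError(f"no truth record for assembly {res.identifier!r}")
        tmpl = truth.template
        m = min(len(res.sequence), len(tmpl))
        mismatch = [k for k in range(m) if res.sequence[k] != tmpl[k]]
        length_delta = abs(len(res.sequence) - len(tmpl))
        out_errors = len(mismatch) + length_delta
        in_errors = truth.n_input_errors
        input_error_pos = truth.fwd_errors_t | truth.rev_errors_t
        introduced = length_delta > 0 or any(
            k not in input_error_pos for k in mismatch
        )

        acc.total += 1
        acc.input_errors += in_errors
        acc.output_errors += out_errors
        if introduced:
            acc.introduced += 1
        elif in_errors == 0 and out_errors == 0:
            acc.error_free += 1
        elif out_errors < in_errors:
            acc.reduced += 1
        else:
            acc.retained += 1
        if res.overlap_len == truth.overlap:
            acc.correct_overlap += 1
    return acc


def naive_assembles(pair: ReadPair, min_overlap: int = 1) -> int | None:
    """Perfect-match baseline: largest overlap that matches exactly with no N.

    Returns the overlap length, or None when every candidate overlap has a
    mismatch or an uncalled base — the pair a naive merger would discard.
    """
    op = orient(pair)
    nf, nr = len(op.fwd_codes), len(op.rev_codes)
    for c in range(min(nf, nr), min_overlap - 1, -1):
        a = op.fwd_codes[nf - c:]
        b = op.rev_codes[:c]
        if np.array_equal(a, b) and not np.any(a == 4):
            return c
    return None


def write_simulated(cfg: SimConfig, fwd_path, rev_path, truth_path) -> int:
    """Write a simulated dataset as two FASTQ files plus a truth TSV.

    Truth columns: identifier, clipped template, true overlap length, and
    comma-separated per-read error positions (read coordinates).
    """
    from .io_fastq import write_fastq_reads

    n = 0
    with open(fwd_path, "wt") as ff, open(rev_path, "wt") as fr, \
            open(truth_path, "wt") as ft:
        ft.write(f"# seed={cfg.seed}\n")
        for pair, truth in simulate_pairs(cfg):
            write_fastq_reads([pair.forward], ff)
            write_fastq_reads([pair.reverse], fr)
            fe = ",".join(map(str, truth.fwd_errors))
            re_ = ",".join(map(str, truth.rev_errors))
            ft.write(f"{truth.identifier}\t{truth.template}\t{truth.overlap}\t{fe}\t{re_}\n")
            n += 1
    return n
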