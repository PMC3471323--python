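import numpy as np
import pytest

from amplimerge.io_fastq import ReadPair, SequenceRead, detect_masked_tail
from amplimerge.quality import PHRED33, error_prob_from_char


def make_read(
    seq: str,
    qual: str | None = None,
    *,
    identifier: str = "r",
    mate: int = 1,
    eps: float | list | None = None,
    masked: list | None = None,
    enc=PHRED33,
) -> SequenceRead:
    """Build a SequenceRead either from a quality string or explicit eps values."""
    n = len(seq)
    if qual is not None:
        eps_arr = np.array([error_prob_from_char(c, enc) for c in qual])
        masked_arr = detect_masked_tail(qual, enc)
    else:
        if eps is None:
            eps = 1e-4
        eps_arr = np.full(n, eps, dtype=float) if np.isscalar(eps) else np.asarray(eps, dtype=float)
        masked_arr = (
            np.zeros(n, dtype=bool) if masked is None else np.asarray(masked, dtype=bool)
        )
        qual = "I" * n
    return SequenceRead(
        identifier=identifier,
        mate=mate,
        sequence=seq,
        qualities=eps_arr,
        masked=masked_arr,
        quality_string=qual,
    )


def make_pair(fwd_seq: str, rev_seq: str, identifier: str = "r", **kw) -> ReadPair:
    """Pair of reads sharing an identifier; kwargs forwarded to both."""
    return ReadPair(
        make_read(fwd_seq, identifier=identifier, mate=1, **kw),
        make_read(rev_seq, identifier=identifier, mate=2, **kw),
    )


def make_oriented(
    fwd_seq: str,
    rev_rc_seq: str,
    *,
    fwd_eps=1e-4,
    rev_eps=1e-4,
    fwd_masked=None,
    rev_masked=None,
    identifier: str = "t",
):
    """OrientedPair built directly in forward-template coordinates."""
    from amplimerge.overlap import OrientedPair

    def _eps(e, n):
        return np.full(n, e, dtype=float) if np.isscalar(e) else np.asarray(e, dtype=float)

    def _mask(m, n):
        return np.zeros(n, dtype=bool) if m is None else np.asarray(m, dtype=bool)

    return OrientedPair(
        identifier=identifier,
        fwd_seq=fwd_seq,
        fwd_eps=_eps(fwd_eps, len(fwd_seq)),
        fwd_masked=_mask(fwd_masked, len(fwd_seq)),
        rev_rc_seq=rev_rc_seq,
        rev_eps=_eps(rev_eps, len(rev_rc_seq)),
        rev_masked=_mask(rev_masked, len(rev_rc_seq)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
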