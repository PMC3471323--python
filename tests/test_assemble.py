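"""Consensus reconstruction rules, geometric-mean quality, and validation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from amplimerge.assemble import (
    AssemblyResult,
    ValidationCriteria,
    overall_quality,
    reconstruct,
    register_validator,
    validate,
)
from amplimerge.overlap import OverlapChoice, best_overlap
from amplimerge.quality import (
    prob_match_given_equal,
    prob_match_given_unequal,
)

from conftest import make_oriented


def full_overlap_choice(op):
    n = len(op.fwd_seq)
    return OverlapChoice(c=n, log_score=0.0, f=0, r=0)


class TestReconstructOverlapRules:
    def test_agreeing_bases_reinforce(self):
        op = make_oriented("ACGT", "ACGT", fwd_eps=1e-4, rev_eps=1e-4)
        res = reconstruct(op, full_overlap_choice(op))
        assert res.sequence == "ACGT"
        expected = prob_match_given_equal(1e-4, 1e-4)
        assert res.probs == pytest.approx([expected] * 4)
        assert res.n_mismatches_resolved == 0 and res.n_uncalled_rescued == 0

    def test_disagreement_resolved_to_higher_quality_base(self):
        op = make_oriented("A", "G", fwd_eps=[0.001], rev_eps=[0.1])
        res = reconstruct(op, full_overlap_choice(op))
        assert res.sequence == "A"
        assert res.probs[0] == pytest.approx(prob_match_given_unequal(0.001, 0.1))
        assert res.n_mismatches_resolved == 1

        # mirrored qualities pick the other base
        op = make_oriented("A", "G", fwd_eps=[0.1], rev_eps=[0.001])
        assert reconstruct(op, full_overlap_choice(op)).sequence == "G"

    def test_equal_eps_tie_takes_forward_base(self):
        op = make_oriented("A", "G", fwd_eps=[0.01], rev_eps=[0.01])
        assert reconstruct(op, full_overlap_choice(op)).sequence == "A"

    def test_uncalled_base_rescued_by_partner(self):
        op = make_oriented("NC", "CC", fwd_eps=0.63, rev_eps=[0.001, 0.001])
        res = reconstruct(op, full_overlap_choice(op))
        assert res.sequence == "CC"
        assert res.probs[0] == 0.25
        assert res.n_uncalled_rescued == 1

    def test_both_uncalled_stays_n(self):
        op = make_oriented("N", "N")
        res = reconstruct(op, full_overlap_choice(op))
        assert res.sequence == "N"
        assert res.probs[0] == 0.25

    def test_one_masked_matching_uses_partner_probability(self):
        op = make_oriented(
            "A", "A", fwd_eps=[0.63], rev_eps=[0.001],
            fwd_masked=[True],
        )
        res = reconstruct(op, full_overlap_choice(op))
        assert res.sequence == "A"
        assert res.probs[0] == pytest.approx(0.999)

    def test_one_masked_mismatching_takes_unmasked_base_at_prior(self):
        op = make_oriented(
            "A", "G", fwd_eps=[0.63], rev_eps=[0.001],
            fwd_masked=[True],
        )
        res = reconstruct(op, full_overlap_choice(op))
        assert res.sequence == "G"
        assert res.probs[0] == 0.25

    def test_both_masked_is_uniform_prior(self):
        op = make_oriented(
            "A", "A", fwd_eps=[0.63], rev_eps=[0.63],
            fwd_masked=[True], rev_masked=[True],
        )
        res = reconstruct(op, full_overlap_choice(op))
        assert res.probs[0] == 0.25


class TestReconstructRegions:
    def test_unpaired_regions_copied_with_own_probability(self):
        # fwd = AACC GG, rev_rc = GG TTAA: c=2 overlap on GG
        op = make_oriented("AACCGG", "GGTTAA", fwd_eps=0.01, rev_eps=0.02)
        res = reconstruct(op, OverlapChoice(c=2, log_score=0.0, f=4, r=4))
        assert res.sequence == "AACCGGTTAA"
        assert res.probs[:4] == pytest.approx([0.99] * 4)
        assert res.probs[4:6] == pytest.approx([prob_match_given_equal(0.01, 0.02)] * 2)
        assert res.probs[6:] == pytest.approx([0.98] * 4)
        assert res.overlap_len == 2

    def test_primer_clipping_removes_both_flanks(self):
        op = make_oriented("AACCGG", "GGTTAA", fwd_eps=0.01, rev_eps=0.02)
        res = reconstruct(
            op, OverlapChoice(c=2, log_score=0.0, f=4, r=4),
            fwd_primer_end=2, rev_primer_end=3,
        )
        assert res.sequence == "CCGGT"
        assert len(res.probs) == 5
        assert res.quality == pytest.approx(overall_quality(res.probs))

    def test_quality_is_geometric_mean_of_retained_probs(self):
        op = make_oriented("ACGT", "ACGT")
        res = reconstruct(op, full_overlap_choice(op))
        assert res.quality == pytest.approx(
            math.exp(np.mean(np.log(res.probs))), rel=1e-12
        )

    def test_determinism(self):
        op = make_oriented("ACGTAC", "GTACGT", fwd_eps=0.01, rev_eps=0.01)
        choice = best_overlap(op)
        a = reconstruct(op, choice)
        b = reconstruct(op, choice)
        assert a.sequence == b.sequence
        assert a.probs.tolist() == b.probs.tolist()


class TestOverallQuality:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ([1.0, 1.0, 1.0], 1.0),
            ([0.25], 0.25),
            ([1.0, 1.0, 0.25], 0.25 ** (1 / 3)),
        ],
    )
    def test_examples(self, probs, expected):
        assert overall_quality(probs) == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overall_quality([])

    def test_zero_probability_gives_zero(self):
        assert overall_quality([1.0, 0.0]) == 0.0

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=50),
        st.floats(min_value=0.0, max_value=0.99),
    )
    def test_bounded_below_by_minimum(self, probs, t):
        """If every base clears t, the geometric mean clears t."""
        if min(probs) > t:
            assert overall_quality(probs) > t


class TestValidate:
    def _result(self, quality=0.95, seq="ACGT"):
        probs = np.full(len(seq), quality)
        return AssemblyResult("r", seq, probs, quality, overlap_len=2)

    def test_passing_result_is_ok(self):
        res = validate(self._result(), ValidationCriteria(min_quality=0.9))
        assert res.status == "ok"

    def test_low_quality(self):
        res = validate(self._result(quality=0.85), ValidationCriteria(min_quality=0.9))
        assert res.status == "low-quality"

    def test_rejection_order_quality_first(self):
        # fails quality AND length: quality is reported
        res = validate(
            self._result(quality=0.5), ValidationCriteria(min_quality=0.9, min_len=100)
        )
        assert res.status == "low-quality"

    def test_length_bounds(self):
        crit = ValidationCriteria(min_quality=0.5, min_len=5, max_len=10)
        assert validate(self._result(), crit).status == "too-short"
        crit = ValidationCriteria(min_quality=0.5, max_len=3)
        assert validate(self._result(), crit).status == "too-long"

    def test_contains_n(self):
        crit = ValidationCriteria(min_quality=0.5, forbid_uncalled=True)
        assert validate(self._result(seq="ACNT"), crit).status == "contains-N"
        crit = ValidationCriteria(min_quality=0.5, forbid_uncalled=False)
        assert validate(self._result(seq="ACNT"), crit).status == "ok"

    def test_monotone_in_threshold(self):
        """Raising the quality threshold never accepts more sequences."""
        results = [self._result(quality=q) for q in np.linspace(0.5, 1.0, 21)]
        ok_06 = {
            id(r) for r in results
            if validate(r, ValidationCriteria(min_quality=0.6)).status == "ok"
        }
        ok_09 = {
            id(r) for r in results
            if validate(r, ValidationCriteria(min_quality=0.9)).status == "ok"
        }
        assert ok_09 <= ok_06

    def test_validation_hook_runs_after_builtins(self):
        @register_validator("no-homopolymer")
        def _hook(seq, probs):
            return "AAAA" not in seq

        crit = ValidationCriteria(min_quality=0.5)
        ok = validate(self._result(seq="ACGT"), crit, hooks=("no-homopolymer",))
        assert ok.status == "ok"
        bad = validate(self._result(seq="AAAAC"), crit, hooks=("no-homopolymer",))
        assert bad.status == "no-homopolymer"

    def test_bad_criteria_rejected(self):
        with pytest.raises(ValueError):
            ValidationCriteria(min_quality=1.5)
        with pytest.raises(ValueError):
            ValidationCriteria(min_len=10, max_len=5)
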