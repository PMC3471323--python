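"""How quality scores turn into base-agreement probabilities.

Two aligned bases that agree reinforce each other; two that disagree are
resolved toward the higher-quality call, with an agreement probability that
reflects how surprising the conflict was.  At eps = 0.75 (a uniformly
random call) both probabilities collapse to the 1/4 prior: agreement
between garbage calls carries no information.
"""

from amplimerge import (
    PHRED33,
    error_prob_from_char,
    prob_match_given_equal,
    prob_match_given_unequal,
)

for ch in "I5#":
    eps = error_prob_from_char(ch, PHRED33)
    print(f"quality char {ch!r}: phred {ord(ch) - 33:2d}, error probability {eps:.5f}")

print()
for ex, ey in [(1e-4, 1e-4), (0.01, 0.1), (0.75, 0.75)]:
    pe = prob_match_given_equal(ex, ey)
    pu = prob_match_given_unequal(ex, ey)
    print(
        f"eps=({ex:g}, {ey:g}):  P(true match | calls agree) = {pe:.4f}   "
        f"P(true match | calls disagree) = {pu:.4f}"
    )

print(
    "\nHigh-quality agreement is near-certain truth; high-quality disagreement"
    "\nmeans one read erred, so the consensus keeps the better base at low"
    "\nconfidence.  At eps=0.75 both columns hit the uninformative prior 0.25."
)
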