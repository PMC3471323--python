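"""Assemble simulated paired-end reads of a short amplicon.

A 135-base template read as 108-base mates overlaps by 81 positions; the
assembler finds that overlap by likelihood maximization, corrects
disagreements from the partner strand, and scores each assembly by the
geometric mean of its per-base correctness probabilities.
"""

from amplimerge import RunConfig, SimConfig, run_pairs, simulate_pairs

cfg = SimConfig(n_pairs=500, seed=7)
pairs, truths = zip(*simulate_pairs(cfg))

stats, accepted = run_pairs(pairs, RunConfig(threshold=0.9), collect=True)
print(f"pairs read      : {stats.pairs_read}")
print(f"assembled (>=0.9): {stats.assembled}")
print(f"rejected        : {stats.rejected}")

res = accepted[0]
print(f"\nfirst assembly  : {res.identifier}")
print(f"  length        : {len(res.sequence)} (template is {len(truths[0].template)})")
print(f"  overlap       : {res.overlap_len} read positions (true overlap {truths[0].overlap})")
print(f"  quality       : {res.quality:.4f} (geometric mean of per-base probabilities)")
print(f"  mismatches resolved: {res.n_mismatches_resolved}")
print(f"  exact match to template: {res.sequence == truths[0].template}")

print(
    "\nRejected pairs failed the 0.9 geometric-mean threshold, typically"
    "\nbecause disagreements fell in quality-masked tails where neither call"
    "\nis trustworthy; rerun with threshold=0.6 to recover most of them."
)
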