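"""Measure how many sequencing errors assembly corrects versus introduces.

Errors are injected at exactly the rate each base's quality score claims,
so ground truth is known for every read.  Each accepted assembly lands in
one of four disjoint outcome categories; a healthy assembler shows a large
"Input Errors Reduced" row and a near-zero "Errors Introduced" row.
"""

from amplimerge import RunConfig, SimConfig, evaluate, run_pairs, simulate_pairs

cfg = SimConfig(n_pairs=5000, seed=11)
pairs, truths = zip(*simulate_pairs(cfg))

for threshold in (0.9, 0.6):
    stats, accepted = run_pairs(pairs, RunConfig(threshold=threshold), collect=True)
    acc = evaluate(accepted, truths)
    print(f"--- quality threshold {threshold} ---")
    print(acc.as_table())
    print(
        f"mean errors: {acc.input_errors / (2 * acc.total):.3f} per input read, "
        f"{acc.output_errors / acc.total:.3f} per assembled sequence\n"
    )

print(
    "Raising the threshold trades yield for purity: the 0.9 run accepts"
    "\nfewer sequences but both runs keep introduced errors at or near zero,"
    "\nbecause a consensus base always comes from one of the two reads."
)
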