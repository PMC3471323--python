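# Methods

## Model and assumptions

`amplimerge` treats each base call as a Bernoulli observation of the true
nucleotide: with probability `eps` (from the phred quality) the call is
wrong, and errors are independent across positions and uniform over the
three alternative nucleotides. Under a uniform prior over nucleotides,
these assumptions give closed forms for the probability that two aligned
true bases agree given that the observed calls agree or disagree (see the
README); both collapse to the ¼ prior at `eps = 0.75`, the uniformly
random call. The model deliberately ignores position-dependent,
dinucleotide-context and strand-specific error structure: it is a
per-base, per-pair model chosen for speed and robustness, not a
recalibration method.

Three special cases override the closed forms:

- **Uncalled bases (N)** carry no information; any comparison involving an
  N scores the prior ¼, and the consensus takes the called partner base.
  Base callers always attach the lowest emitted quality to an N, so no
  information is discarded by this rule.
- **Quality-masked tails.** Illumina pipelines mark unreliable read ends
  by overwriting the trailing qualities with phred 2 (`#` at offset 33,
  `B` at offset 64). The phred value of such a base (eps ≈ 0.63) is a
  sentinel, not a calibrated rate, so masked bases get their own rule: if
  one base of an overlapped pair is masked and the nucleotides agree, the
  probability of the unmasked base (`1 − eps`) is used; if they disagree,
  or both are masked, the prior ¼. Masking is detected as the maximal
  trailing run of phred ≤ 2 — an interior phred-2 base is low quality, not
  masked.
- **Unpaired regions** are covered by one strand only; each base is copied
  with correctness probability `1 − eps`.

## Pipeline

Per pair: (1) locate primers if supplied; (2) orient the reverse read
(reverse complement, qualities and mask flags reversed in lockstep) and
choose the overlap length `c` maximizing the pair likelihood; (3) build
the consensus, clip primer windows, score, validate. Overlap selection
runs on the *full* reads including any primer bases, because short
templates can overlap into the primer regions; the search range is
`min_overlap ≤ c ≤ min(|F|, |R|)` with the upper bound closed so a fully
overlapping pair is assemblable. Rejection reasons are exclusive and
checked in a fixed order: primer-missing, no-overlap, low-quality,
too-short, too-long, contains-N; user validation hooks (registered
predicates over sequence and per-base probabilities) run after the
built-ins.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.6 | minimum geometric-mean assembly quality (dimensionless probability). 0.6 is the permissive operating point; 0.9 is the conservative one. On error-free reads under realistic quality masks assemblies score just above 0.9, so thresholds above 0.9 demand more than perfectly correct data can deliver. |
| `eps_fixed` | 0.01 | nominal per-base error rate used only for overlap scoring. The choice is non-critical: it shifts all candidate scores smoothly and the argmax is dominated by the match/mismatch pattern. |
| `min_overlap` | 1 | smallest admissible overlap (bases). |
| primer `max_offset` | 5 | furthest read offset searched for a primer start; primers sit at or near the read start in Illumina amplicon layouts. |
| primer `threshold` | 0.75 | per-base geometric-mean agreement a primer window must reach. Length-independent, so one low-quality mismatch does not sink a 17-base primer. |
| `eps_primer` | 10^-4.1 | error probability assigned to primer bases (the primer sequence is known; 10^-4.1 is the best score Illumina emits). |
| eps floor | 10^-4.1 | per-base error probabilities are floored here so no base is treated as error-free and log-products stay finite. |

All probability products are accumulated in log space; a 2×100-base pair
multiplies hundreds of factors ≤ 1, which would underflow doubles.

## Deliberate design choices

Where the procedure admitted more than one reasonable reading, the
package fixes these conventions:

- **Mismatch ties** (equal `eps` on both sides, including two masked
  bases) resolve to the forward base: forward cycles are sequenced
  earlier and are empirically cleaner, and the rule is deterministic.
- **Overlap score ties** resolve to the larger `c` — the hypothesis
  explaining more of the observed data as overlap, and the shorter
  assembly.
- **Primer clipping precedes scoring**, so the reported quality describes
  exactly the reported sequence; ¼-probability contributions of N-rescued
  positions are included in the geometric mean.
- **Masking does not affect overlap selection**, only consensus scoring;
  the selection step already abstracts per-base quality into `eps_fixed`.
- **Degenerate IUPAC primer codes** are exact-match sets (no partial
  credit by degeneracy).
- Output FASTQ qualities are `round(−10·log10(1 − p))` capped at phred 41.

## The simulator: what it emulates and what it does not

`simulate_pairs` builds an amplicon (forward primer + template + reverse
complement of the reverse primer; default template a seeded random
135-base stand-in for a 16S V3 region, read as 108-base mates, true
overlap 81), then for each read: a linear phred decline 40 → 15 along the
read; with probability 0.2 a masked tail of uniform length 1–15 forced to
phred 2; Ns at phred ≤ 2 positions with probability 0.05; substitution
errors drawn per base at exactly the rate the final quality character
claims, uniform over the three alternatives. The simulated world is
therefore *quality-consistent by construction* — the assembler's model
assumptions hold exactly. `transplant_masks` reproduces the complementary
design: perfectly correct template bases under externally supplied quality
strings, isolating the effect of the masks themselves.

Real data violates these assumptions in ways the simulator does not
reproduce: correlated and context-dependent errors, miscalibrated
qualities, platform-specific mask-length distributions, chimeras, and
abundance structure across templates. A green test on this world
establishes that the algorithm is implemented correctly and behaves as
designed when its model holds; it does not certify error rates on any
real run.

`evaluate` buckets each assembly into four disjoint categories against
ground truth — error-free in and out; all errors retained; input errors
reduced; errors introduced (any output error at a position where both
reads were correct, including any length change, which fabricates or
drops unsupported positions) — plus a correct-overlap tally. Introduced
errors are structurally rare: every consensus base is one of the two
observed calls, so a wrong output base at an error-free position can only
come from a wrong overlap choice.

## Known limitations

- No gapped overlap alignment: an indel inside the overlap shifts the
  register and the pair will assemble poorly or be rejected.
- Exhaustive `c`-scan is O(|F|·|R|) per pair — fast at amplicon lengths,
  inappropriate for long reads.
- The encoding heuristic cannot distinguish offsets on short, uniformly
  mid-range quality samples; it then defaults to offset 33 with a warning
  and can be overridden explicitly.
- Negative-overhang layouts (reads reading through the opposite primer)
  are handled only insofar as primer clipping removes the read-through;
  overlap lengths beyond `min(|F|, |R|)` are not modeled.
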