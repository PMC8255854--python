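# Methods

## Alignment model and cost

An alignment of sequences `s_1 .. s_k` over alphabet Σ is a `k × ℓ` matrix
over `Σ ∪ {-}`; row i with gaps removed must equal `s_i` exactly, and this
invariant is enforced at construction, not assumed. The sum-of-pairs (SP)
cost under a score scheme `d` is the double sum over row pairs and columns;
`CostReport` carries both the per-pair and per-column decompositions of the
same sum and asserts they agree.

The gap is written as ASCII `-`; the typographic dashes `–`, `—` and the
minus sign `−` are accepted everywhere on input and normalized, so printed
instances can be pasted verbatim. Sequences are uppercased on read.
Costs stay exact Python integers whenever the scheme table is integral
(every built-in and sampled scheme is); non-integer tables are compared
with a 1e-9 tolerance.

## Score schemes

A `ScoreScheme` is a symmetric, non-negative table with zero diagonal over
`Σ ∪ {-}` — those axioms are structural and enforced at construction.
Two further properties are *flags* computed by `validate`, which reports
every violated axiom with a witness pair or triple:

* **metric**: strictly positive off the diagonal and triangle inequality
  over all triples (the gap is an ordinary point of the space);
* **gap-dominant**: `d(a,b) ≤ d(a,-)` for all characters `a, b` — the one
  property of the unit metric that the length-2 optimality argument needs.

Schemes that fail the metric axioms are still admitted for plain scoring
(the SP sum is well-defined for any table); the closed-form evaluators
refuse them, and the solver warns unless `strict=True` makes it refuse too.

`random_metric(alphabet, seed, value_range=(1, 9))` draws symmetric integer
off-diagonal values uniformly and repairs them by metric closure
(Floyd–Warshall all-pairs shortest paths). Closure only ever shrinks
entries and never below the smallest sampled edge, so positivity survives
and the result is always a metric; on an already-metric table it is the
identity. The default range 1–9 gives single-digit integer distances —
wide enough that sampled metrics are frequently non-gap-dominant, which is
what the counterexample hunt needs, while keeping all arithmetic exact.
`random_gap_dominant_metric` samples the character–character block the same
way and then sets every gap distance to the maximum character–character
distance: a constant dominating gap cost keeps all triangles valid and
makes gap dominance hold by construction.

## Closed forms

* `optimal_cost_len1_unit(k) = k(k−1)/2` — optimum for k pairwise-distinct
  length-1 sequences under the unit metric.
* `max_cost_len1_unit(k, ℓ) = k² − k/2 − k²/(2ℓ)` — the maximum SP cost of
  any ℓ-column alignment of those sequences; returned as an exact
  `Fraction` when not integral so tests never depend on float rounding.
  The bound comes from the occupancy identity: an alignment whose columns
  hold `k_1 .. k_ℓ` characters costs `k² − (k + Σk_i²)/2`, and `Σk_i²` is
  at least `k²/ℓ`. `OccupancyProfile` exposes that identity directly and
  `enumerate_profiles` enumerates all compositions for exhaustive checks.
* `optimal_cost_len1(seqs, metric)` — the pairwise-distance sum, valid for
  any metric.
* `optimal_cost_len2_unit(seqs)` — the two columnwise mismatch-pair sums.

The formulas are evaluated over the input *multiset* without deduplication:
identical sequences are aligned identically in some optimum and contribute
zero to each other, so the multiset sums equal the distinct-sequence
formulas. This keeps record identity intact for reports, and the
equivalence is property-tested rather than assumed.

## Exact solver

`solve_exact` runs a dynamic program over the k-dimensional lattice of
per-sequence positions. A state records how many characters of each
sequence have been consumed; each transition advances a non-empty subset of
the unfinished sequences and emits one column (advanced sequences
contribute their next character, the others a gap). The SP cost decomposes
exactly over columns *because* `d(-,-) = 0` — this is asserted at solve
time, since a nonzero gap–gap cost would both break the decomposition and
make all-gap columns matter. For the same reason no optimum is lost by
excluding all-gap columns, so the lattice-path model is complete.

Tie-breaking: among co-optimal alignments the solver returns the one whose
advance-subset sequence is lexicographically smallest, with sequences in
input order and "advance" sorting before "gap". This is implemented by
computing cost-to-go for every state and reconstructing greedily, and it
makes solver output byte-reproducible; `count_optima=True` adds a counting
pass over the optimal sub-DAG. Default limits are 6 sequences of length at
most 6 (≈ 7⁶ states × 63 transitions, well under a second); both limits are
keyword-overridable.

`solve_bruteforce` minimizes over `enumerate_alignments`, a depth-first
enumeration of every monotone lattice path in the same tie-break order
(so its first optimum coincides with the DP's). It is deliberately naive —
its job is to be an *independent* oracle for the DP, and the two are
compared on hundreds of random instances. Costs are accumulated
column-by-column along the search tree, but every canonical alignment is
still visited. Enumeration refuses instances with more than 500 000
alignments by default (`count_alignments` prices this exactly; for two
length-n sequences it is the central Delannoy number). Oracle-equivalence
trials cap instances at 30 000 alignments: that still covers every
four-sequence instance of lengths ≤ 2 and every three-sequence instance of
lengths ≤ 3, while four sequences of length 3 (10.7 million alignments)
are checked by the DP against the closed forms instead.

## Randomized verification and the counterexample hunt

`verify_theorem` draws random instances under each result's hypotheses and
compares the exact solver against the closed form and the trivial cost:

| id | instances | expected optimum |
|----|-----------|------------------|
| `T4` | k ∈ 2..6 distinct length-1, unit metric | `k(k−1)/2` |
| `T5` | k ∈ 2..5 length-1 (duplicates allowed), random metric | pairwise-distance sum |
| `T6` | k ∈ 2..4 length-2, unit metric | columnwise mismatch sums |
| `gap_dominance` | k ∈ 2..4, length 1 or 2, random gap-dominant metric | trivial cost |

These results are proved, so the tolerance is zero: any violation is an
implementation bug, and the report serializes the full witness (sequences,
scheme TSV, both costs, the solver's alignment) as a self-contained
regression fixture. The default alphabet size 4 mirrors nucleotide data
while keeping collisions (duplicate sequences) common enough to exercise
the multiset path.

`hunt_counterexamples` samples random metrics and sequence sets and returns
every instance where the optimum strictly beats the trivial alignment.
For length-2 inputs a hit from a gap-dominant metric would contradict a
proved result, so the hunter raises rather than returning it; every
returned record re-validates (`sp_cost(witness) == optimal < trivial`).
`check_instance` accepts explicit instances, which is how the two canonical
counterexamples are exercised as named fixtures.

All randomness flows through integer seeds via `numpy`'s `SeedSequence`;
per-trial child seeds are surfaced in reports so any single trial can be
replayed.

## What the generators do and do not emulate

Random instances are uniform draws of short strings over small alphabets
(2–4 symbols by default — binary alphabets make counterexamples densest,
4 symbols mirrors DNA), and random schemes are uniform integer metrics.
These are the study conditions for exhaustive/exact claims, not models of
biological sequence data: no composition bias, no similarity structure
between sequences, no affine gap penalties, no BLOSUM/PAM-style log-odds
semantics. Passing tests certify the combinatorics and the solver, not
performance on real alignments — which is the intended scope: the solver
is an oracle for theory, not a production aligner.

## Known limitations

* The solver's state space is exponential in k; limits exist to keep it at
  desk scale, and there is no Carrillo–Lipman-style pruning.
* Only linear (per-column) gap costs are supported; affine or
  position-dependent penalties are out of scope.
* `trivial_alignment` requires equal-length inputs by design — padding
  would silently change the object the optimality statements are about.
* The hunt records per-(metric, set) witnesses only; it does not attempt
  to characterize which metrics keep the trivial alignment optimal, which
  remains open.
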