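# shortmsa

Exact sum-of-pairs multiple sequence alignment of **very short** sequences.

Most MSA work targets a handful of long sequences. The opposite regime —
many sequences of length 1, 2 or 3 — is where exact optimality can actually
be settled, and it behaves unexpectedly: whether the obvious gapless
alignment is optimal depends delicately on the score scheme. `shortmsa` is
a small toolkit for studying that question: it scores alignments under
arbitrary metric score schemes, evaluates the known closed-form optima,
solves small instances *exactly*, verifies the known optimality results on
randomized instances, and hunts for counterexamples where a gapped
alignment strictly beats the gapless one.

## The model

A multiple alignment of sequences `s_1 .. s_k` over an alphabet Σ is a
`k × ℓ` matrix over `Σ ∪ {-}` whose rows, with gaps removed, reproduce the
input sequences. Under a score scheme `d` (a symmetric distance on
`Σ ∪ {-}` with zero diagonal, usually a metric), the sum-of-pairs cost is

    SP(A) = Σ_{i<j} Σ_{c=1..ℓ} d(A[i][c], A[j][c])

The *trivial alignment* of equal-length sequences writes them under one
another with no gaps. The facts this package operationalizes:

* **Length 1, unit metric** (`d = 1` off the diagonal): the trivial
  alignment is optimal; for k distinct characters the optimum is
  `k(k−1)/2`, and no ℓ-column alignment costs more than
  `k² − k/2 − k²/(2ℓ)` (so at most `k² − k`).
* **Length 1, arbitrary metric**: the trivial alignment is still optimal,
  with cost `Σ_{i<j} d(a_i, a_j)`.
* **Length 2, unit metric** — or any *gap-dominant* metric, meaning
  `d(a,b) ≤ d(a,−)` for all characters: the trivial alignment is optimal,
  with cost equal to the two columnwise pair sums.
* **Beyond that, nothing**: with `d(C,G) = 2` and unit gap costs,
  `{CG, GC, GG}` has a gapped alignment of cost 6 against a trivial cost
  of 8; under the unit metric `{CCG, GCG, CGC}` has a gapped alignment of
  cost 5 against a trivial cost of 6. Which metrics keep the trivial
  alignment optimal for length-2 sequences is open; `shortmsa hunt`
  searches for such counterexamples.

The exact solver is a dynamic program over the k-dimensional lattice of
per-sequence positions (each transition advances a non-empty subset of
sequences and emits one column); a full-enumeration brute force over all
monotone lattice paths serves as its independent oracle.

## Worked example

The two-letter metric with `d(C,G)=2` and unit gap costs, as a TSV
(`metric.tsv`):

```
C	G	-
C	0	2	1
G	2	0	1
-	1	1	0
```

With `seqs.txt` containing the lines `CG`, `GC`, `GG`:

```
$ shortmsa trivial seqs.txt --metric metric.tsv
>s1
CG
>s2
GC
>s3
GG
total cost: 8

$ shortmsa solve seqs.txt --metric metric.tsv --count-optima
>s1
CG-
>s2
-GC
>s3
GG-
optimal cost: 6
co-optimal alignments: 7
```

The trivial alignment pays `d(C,G)=2` four times (8); the solver finds that
spending cheap gap columns instead brings the total down to 6 — possible
only because this metric is not gap-dominant:

```
$ shortmsa validate-metric metric.tsv
metric: yes
gap-dominant: no
gap dominance violation: (C, G)
gap dominance violation: (G, C)
```

Randomized re-verification of a proved case (length-2, unit metric) and a
counterexample hunt over random non-gap-dominant metrics:

```
$ shortmsa verify T6 --trials 50 --seed 1
T6: 50 trials, seed 1: PASS

$ shortmsa hunt --seq-len 2 --n-schemes 10 --seed 5
counterexamples found: 10
  ['BA', 'BA', 'AB']: trivial 12 -> optimal 8 (rows ['BA-', 'BA-', '-AB'])
  ...
```

Other subcommands: `score` (cost of an aligned FASTA file, with per-column
breakdown) and `closed-form` (formula optima for length-1/length-2 inputs).
The same functionality is available as a library (`shortmsa.sp_cost`,
`shortmsa.solve_exact`, `shortmsa.verify_theorem`, ...).

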