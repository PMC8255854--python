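"""Randomized verification of the short-sequence optimality results and
counterexample hunting.

The proved facts under check (each compared against the exact solver on
randomly generated instances):

* ``T4`` — length-1 sequences, unit metric: the trivial alignment is
  optimal; for k pairwise-distinct characters the optimum is k(k-1)/2.
* ``T5`` — length-1 sequences, arbitrary metric: the trivial alignment is
  optimal with cost equal to the sum of pairwise distances.
* ``T6`` — length-2 sequences, unit metric: the trivial alignment is
  optimal, with the columnwise mismatch-count cost.
* ``gap_dominance`` — lengths 1 and 2, any metric with
  d(a,b) <= d(a,-): the trivial alignment is still optimal (the only
  property of the unit metric the length-2 argument uses).

Any violation is an implementation bug, and the witness instance is
serialized in full so it can be replayed as a regression fixture.

Which metrics keep the trivial alignment optimal for length-2 sequences in
general is open; :func:`hunt_counterexamples` searches (metric, sequence
set) pairs for strict improvements over the trivial alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Alignment, Alphabet, SequenceSet, ShortMSAError, sp_cost
from .metrics import (
    ScoreScheme,
    format_metric_tsv,
    random_gap_dominant_metric,
    random_metric,
    unit_metric,
    validate,
)
from .closed_forms import optimal_cost_len1, optimal_cost_len1_unit, optimal_cost_len2_unit
from .solver import solve_exact, trivial_cost

THEOREM_IDS = ("T4", "T5", "T6", "gap_dominance")

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def random_instance(
    k: int,
    seq_len: int,
    alphabet: Alphabet,
    seed: int,
    distinct: bool = False,
) -> SequenceSet:
    """Uniformly sample k sequences of the given length; deterministic per seed.

    With ``distinct=True`` the sequences are drawn without replacement from
    the |alphabet|^seq_len possible strings (infeasible requests error).
    """
    rng = np.random.default_rng(seed)
    space = len(alphabet) ** seq_len
    if distinct and space < k:
        raise ShortMSAError(
            f"cannot draw {k} distinct sequences from a space of {space}"
        )
    symbols = alphabet.symbols
    if distinct:
        picks = rng.choice(space, size=k, replace=False)
        seqs = []
        for code in picks:
            code = int(code)
            s = ""
            for _ in range(seq_len):
                s += symbols[code % len(symbols)]
                code //= len(symbols)
            seqs.append(s)
    else:
        seqs = [
            "".join(symbols[int(c)] for c in rng.integers(0, len(symbols), size=seq_len))
            for _ in range(k)
        ]
    return SequenceSet.from_strings(seqs, alphabet=alphabet)


@dataclass(frozen=True)
class Violation:
    """Self-contained witness of a theorem-check mismatch."""

    sequences: tuple[str, ...]
    scheme_tsv: str
    expected_cost: int | float
    solver_cost: int | float
    alignment_rows: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "sequences": list(self.sequences),
            "scheme_tsv": self.scheme_tsv,
            "expected_cost": self.expected_cost,
            "solver_cost": self.solver_cost,
            "alignment_rows": list(self.alignment_rows),
        }


@dataclass(frozen=True)
class VerificationReport:
    theorem: str
    trials: int
    seed: int
    violations: tuple[Violation, ...] = ()
    params: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "theorem": self.theorem,
            "trials": self.trials,
            "seed": self.seed,
            "passed": self.passed,
            "violations": [v.to_dict() for v in self.violations],
            "params": dict(self.params),
        }


@dataclass(frozen=True)
class CounterexampleRecord:
    """A (sequence set, metric) pair whose optimum beats the trivial alignment."""

    seqs: SequenceSet
    scheme: ScoreScheme
    trivial_cost: int | float
    optimal_cost: int | float
    witness: Alignment

    def __post_init__(self) -> None:
        if not self.optimal_cost < self.trivial_cost:
            raise ShortMSAError("counterexample requires a strict improvement")

    def revalidate(self) -> bool:
        return (
            sp_cost(self.witness, self.scheme).total == self.optimal_cost
            and self.optimal_cost < self.trivial_cost
        )

    def to_dict(self) -> dict:
        return {
            "sequences": list(self.seqs.sequences),
            "scheme_tsv": format_metric_tsv(self.scheme),
            "trivial_cost": self.trivial_cost,
            "optimal_cost": self.optimal_cost,
            "witness_rows": list(self.witness.rows),
        }


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep below 2**31


def verify_theorem(
    theorem: str,
    trials: int,
    seed: int,
    *,
    alphabet_size: int = 4,
) -> VerificationReport:
    """Compare the exact solver against the closed form / trivial cost on
    ``trials`` random instances drawn under the theorem's hypotheses."""
    if theorem not in THEOREM_IDS:
        raise ShortMSAError(f"unknown theorem id {theorem!r}; expected one of {THEOREM_IDS}")
    violations: list[Violation] = []
    seeds = _child_seeds(seed, trials)
    params: dict = {"alphabet_size": alphabet_size}

    for t, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        if theorem == "T4":
            k = int(rng.integers(2, 7))
            alpha = Alphabet(tuple(_LETTERS[:max(k, 2)]))
            seqs = random_instance(k, 1, alpha, s + 1, distinct=True)
            scheme = unit_metric(alpha)
            expected = optimal_cost_len1_unit(k)
        elif theorem == "T5":
            k = int(rng.integers(2, 6))
            alpha = Alphabet(tuple(_LETTERS[:alphabet_size]))
            seqs = random_instance(k, 1, alpha, s + 1)
            scheme = random_metric(alpha, s + 2)
            expected = optimal_cost_len1(seqs, scheme)
        elif theorem == "T6":
            k = int(rng.integers(2, 5))
            alpha = Alphabet(tuple(_LETTERS[:alphabet_size]))
            seqs = random_instance(k, 2, alpha, s + 1)
            scheme = unit_metric(alpha)
            expected = optimal_cost_len2_unit(seqs)
        else:  # gap_dominance
            k = int(rng.integers(2, 5))
            seq_len = int(rng.integers(1, 3))
            alpha = Alphabet(tuple(_LETTERS[:alphabet_size]))
            seqs = random_instance(k, seq_len, alpha, s + 1)
            scheme = random_gap_dominant_metric(alpha, s + 2)
            expected = trivial_cost(seqs, scheme)

        result = solve_exact(seqs, scheme)
        triv = trivial_cost(seqs, scheme)
        if result.cost != expected or result.cost != triv:
            violations.append(
                Violation(
                    sequences=seqs.sequences,
                    scheme_tsv=format_metric_tsv(scheme),
                    expected_cost=expected,
                    solver_cost=result.cost,
                    alignment_rows=result.best.rows,
                )
            )
    return VerificationReport(
        theorem=theorem,
        trials=trials,
        seed=seed,
        violations=tuple(violations),
        params=params,
    )


def check_instance(seqs: SequenceSet, scheme: ScoreScheme) -> CounterexampleRecord | None:
    """Solve one explicit instance; return a record iff the optimum strictly
    beats the trivial alignment (None otherwise)."""
    triv = trivial_cost(seqs, scheme)
    result = solve_exact(seqs, scheme)
    if result.cost < triv:
        return CounterexampleRecord(
            seqs=seqs,
            scheme=scheme,
            trivial_cost=triv,
            optimal_cost=result.cost,
            witness=result.best,
        )
    return None


def hunt_counterexamples(
    seq_len: int,
    alphabet_size: int,
    n_schemes: int,
    seed: int,
    *,
    k: int = 3,
    sets_per_scheme: int = 5,
) -> list[CounterexampleRecord]:
    """Search random (metric, sequence set) pairs for strict improvements of
    the exact optimum over the trivial alignment.

    For length-1 inputs none can exist (trivial is optimal under any
    metric); for length-2 every returned scheme is certified
    non-gap-dominant — a gap-dominant hit would contradict a proved result
    and raises instead of being returned.
    """
    if seq_len < 1:
        raise ShortMSAError("seq_len must be >= 1")
    alpha = Alphabet(tuple(_LETTERS[:alphabet_size]))
    records: list[CounterexampleRecord] = []
    scheme_seeds = _child_seeds(seed, n_schemes)
    for s in scheme_seeds:
        scheme = random_metric(alpha, s)
        set_seeds = _child_seeds(s ^ 0x5EED, sets_per_scheme)
        for ss in set_seeds:
            seqs = random_instance(k, seq_len, alpha, ss)
            rec = check_instance(seqs, scheme)
            if rec is None:
                continue
            if seq_len == 2 and validate(scheme).is_gap_dominant:
                raise AssertionError(
                    "gap-dominant metric produced a length-2 counterexample; "
                    "this contradicts a proved result and indicates a solver bug"
                )
            records.append(rec)
    return records
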