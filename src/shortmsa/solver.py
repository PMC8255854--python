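"""Exact minimum sum-of-pairs MSA for small instances.

Two independent routes to the global optimum:

* :func:`solve_exact` — dynamic programming over the k-dimensional lattice
  of per-sequence positions.  A state is the tuple of characters consumed
  from each sequence; each transition advances a non-empty subset of the
  unfinished sequences and emits one alignment column (advanced sequences
  contribute their next character, the rest a gap).  Because d(-,-) = 0,
  the SP cost decomposes exactly over columns and no optimum is lost by
  forbidding all-gap columns, so the lattice DP is exact.

* :func:`solve_bruteforce` — full enumeration of every canonical alignment
  (every monotone lattice path), kept deliberately naive so it can serve as
  an oracle for the DP.

Both are meant for *very short* sequences — the regime where exact optima
are the object of study — not as production aligners.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterator

from .core import GAP, Alignment, SequenceSet, ShortMSAError, sp_cost, trivial_alignment
from .metrics import ScoreScheme, validate

K_MAX_DEFAULT = 6
L_MAX_DEFAULT = 6


class SolverLimitError(ShortMSAError):
    """Instance exceeds the configured solver limits."""


@dataclass(frozen=True)
class SolveResult:
    best: Alignment
    cost: int | float
    optima_count: int | None = None
    explored: dict = field(default_factory=dict)


def _check_limits(seqs: SequenceSet, k_max: int, l_max: int) -> None:
    if seqs.k > k_max:
        raise SolverLimitError(f"{seqs.k} sequences exceeds k_max={k_max}")
    too_long = [len(s) for s in seqs.sequences if len(s) > l_max]
    if too_long:
        raise SolverLimitError(f"sequence length {max(too_long)} exceeds L_max={l_max}")


def _check_scheme(scheme: ScoreScheme, strict: bool) -> None:
    if scheme.d(GAP, GAP) != 0:
        # column decomposition of the SP cost breaks without this
        raise ShortMSAError("solver requires d(-,-) = 0")
    if not validate(scheme).is_metric:
        msg = "score scheme is not a metric; the optimum is still well-defined"
        if strict:
            raise ShortMSAError(msg)
        warnings.warn(msg, stacklevel=3)


def _ordered_masks(k: int) -> list[int]:
    """Non-empty advance subsets, lexicographically by per-sequence action.

    For each sequence position, advancing sorts before gapping; the mask
    advancing sequence 1 alone therefore comes after the mask advancing all
    of them, etc.  This fixed order is the tie-break that makes solver
    output reproducible.
    """
    masks = list(range(1, 1 << k))
    masks.sort(key=lambda m: tuple(0 if (m >> i) & 1 else 1 for i in range(k)))
    return masks


def _column_for(seqs: tuple[str, ...], state: tuple[int, ...], mask: int) -> tuple[str, ...]:
    return tuple(
        seqs[i][state[i]] if (mask >> i) & 1 else GAP for i in range(len(seqs))
    )


def _column_cost(col: tuple[str, ...], scheme: ScoreScheme) -> int | float:
    return sum(scheme.d(a, b) for a, b in itertools.combinations(col, 2))


def solve_exact(
    seqs: SequenceSet,
    scheme: ScoreScheme,
    *,
    k_max: int = K_MAX_DEFAULT,
    l_max: int = L_MAX_DEFAULT,
    strict: bool = False,
    count_optima: bool = False,
) -> SolveResult:
    """Global minimum SP cost by DP over the k-dimensional position lattice.

    Returns the optimal cost together with one optimal alignment — the one
    whose advance-subset sequence is lexicographically smallest among all
    co-optima (sequences in input order, advancing before gapping).  With
    ``count_optima=True`` a second counting pass reports how many canonical
    alignments attain the optimum.
    """
    _check_limits(seqs, k_max, l_max)
    _check_scheme(scheme, strict)
    strings = seqs.sequences
    k = len(strings)
    lengths = tuple(len(s) for s in strings)
    masks = _ordered_masks(k)
    final = lengths

    # cost-to-go from every state, filled in decreasing order of progress
    g: dict[tuple[int, ...], int | float] = {final: 0}
    states = sorted(
        itertools.product(*(range(n + 1) for n in lengths)),
        key=sum,
        reverse=True,
    )
    transitions = 0
    for state in states:
        if state == final:
            continue
        best = None
        for mask in masks:
            if any((mask >> i) & 1 and state[i] >= lengths[i] for i in range(k)):
                continue
            nxt = tuple(state[i] + ((mask >> i) & 1) for i in range(k))
            c = _column_cost(_column_for(strings, state, mask), scheme) + g[nxt]
            transitions += 1
            if best is None or c < best:
                best = c
        g[state] = best

    # greedy reconstruction: smallest mask (in tie-break order) that attains g
    columns: list[tuple[str, ...]] = []
    state = tuple(0 for _ in range(k))
    while state != final:
        for mask in masks:
            if any((mask >> i) & 1 and state[i] >= lengths[i] for i in range(k)):
                continue
            nxt = tuple(state[i] + ((mask >> i) & 1) for i in range(k))
            col = _column_for(strings, state, mask)
            if _column_cost(col, scheme) + g[nxt] == g[state]:
                columns.append(col)
                state = nxt
                break
        else:  # pragma: no cover - unreachable if the DP is correct
            raise AssertionError("no transition attains the DP optimum")

    rows = tuple("".join(col[i] for col in columns) for i in range(k))
    best_aln = Alignment(rows=rows, source=seqs)
    cost = g[tuple(0 for _ in range(k))]
    assert sp_cost(best_aln, scheme).total == cost

    optima = None
    if count_optima:
        counts: dict[tuple[int, ...], int] = {final: 1}
        for state in states:
            if state == final:
                continue
            total = 0
            for mask in masks:
                if any((mask >> i) & 1 and state[i] >= lengths[i] for i in range(k)):
                    continue
                nxt = tuple(state[i] + ((mask >> i) & 1) for i in range(k))
                if _column_cost(_column_for(strings, state, mask), scheme) + g[nxt] == g[state]:
                    total += counts[nxt]
            counts[state] = total
        optima = counts[tuple(0 for _ in range(k))]

    return SolveResult(
        best=best_aln,
        cost=cost,
        optima_count=optima,
        explored={"states": len(g), "transitions": transitions},
    )


def count_alignments(lengths: tuple[int, ...]) -> int:
    """Number of canonical alignments = monotone lattice paths to the origin.

    For two length-n sequences this is the central Delannoy number D(n, n).
    """
    counts: dict[tuple[int, ...], int] = {tuple(0 for _ in lengths): 1}
    for state in sorted(itertools.product(*(range(n + 1) for n in lengths)), key=sum):
        if state in counts:
            continue
        total = 0
        for mask in range(1, 1 << len(lengths)):
            prev = tuple(state[i] - ((mask >> i) & 1) for i in range(len(lengths)))
            if all(p >= 0 for p in prev):
                total += counts[prev]
        counts[state] = total
    return counts[lengths]


def enumerate_alignments(
    seqs: SequenceSet,
    max_columns: int | None = None,
    *,
    max_enumerated: int = 500_000,
) -> Iterator[Alignment]:
    """Yield every canonical alignment exactly once.

    Alignments are produced in lexicographic order of their advance-subset
    sequences (the same order that breaks ties in :func:`solve_exact`).
    ``max_columns`` prunes paths longer than the given column count;
    canonical alignments never need more than the total input length.
    Instances whose alignment count exceeds ``max_enumerated`` are refused.
    """
    strings = seqs.sequences
    k = len(strings)
    lengths = tuple(len(s) for s in strings)
    if count_alignments(lengths) > max_enumerated:
        raise SolverLimitError(
            f"instance has more than {max_enumerated} alignments; enumeration refused"
        )
    if max_columns is None:
        max_columns = sum(lengths)
    if max_columns < max(lengths, default=0):
        raise ShortMSAError("max_columns below the longest sequence admits no alignment")
    masks = _ordered_masks(k)
    final = lengths

    def rec(state: tuple[int, ...], columns: list[tuple[str, ...]]) -> Iterator[Alignment]:
        if state == final:
            rows = tuple("".join(col[i] for col in columns) for i in range(k))
            yield Alignment(rows=rows, source=seqs)
            return
        if len(columns) >= max_columns:
            return
        for mask in masks:
            if any((mask >> i) & 1 and state[i] >= lengths[i] for i in range(k)):
                continue
            nxt = tuple(state[i] + ((mask >> i) & 1) for i in range(k))
            columns.append(_column_for(strings, state, mask))
            yield from rec(nxt, columns)
            columns.pop()

    yield from rec(tuple(0 for _ in range(k)), [])


def solve_bruteforce(
    seqs: SequenceSet,
    scheme: ScoreScheme,
    *,
    max_enumerated: int = 500_000,
    strict: bool = False,
) -> SolveResult:
    """Minimum over the full enumeration — the independent oracle for the DP.

    Costs are accumulated column-by-column along the search tree rather than
    rescoring whole alignments, but every canonical alignment is still
    visited.  The first optimum met in enumeration order is returned, which
    coincides with the DP's lexicographic tie-break.
    """
    _check_scheme(scheme, strict)
    strings = seqs.sequences
    k = len(strings)
    lengths = tuple(len(s) for s in strings)
    n_paths = count_alignments(lengths)
    if n_paths > max_enumerated:
        raise SolverLimitError(
            f"instance has {n_paths} alignments; brute force refused"
        )
    masks = _ordered_masks(k)
    final = lengths
    best_cost: int | float | None = None
    best_columns: list[tuple[str, ...]] | None = None
    visited = 0

    def rec(state: tuple[int, ...], columns: list[tuple[str, ...]], cost) -> None:
        nonlocal best_cost, best_columns, visited
        if state == final:
            visited += 1
            if best_cost is None or cost < best_cost:
                best_cost = cost
                best_columns = list(columns)
            return
        for mask in masks:
            if any((mask >> i) & 1 and state[i] >= lengths[i] for i in range(k)):
                continue
            nxt = tuple(state[i] + ((mask >> i) & 1) for i in range(k))
            col = _column_for(strings, state, mask)
            columns.append(col)
            rec(nxt, columns, cost + _column_cost(col, scheme))
            columns.pop()

    rec(tuple(0 for _ in range(k)), [], 0)
    assert best_columns is not None
    rows = tuple("".join(col[i] for col in best_columns) for i in range(k))
    best = Alignment(rows=rows, source=seqs)
    return SolveResult(best=best, cost=best_cost, explored={"alignments": visited})


def max_cost_over_alignments(seqs: SequenceSet, scheme: ScoreScheme) -> int | float:
    """Maximum SP cost over all canonical alignments (enumeration; tiny inputs)."""
    return max(sp_cost(a, scheme).total for a in enumerate_alignments(seqs))


def trivial_cost(seqs: SequenceSet, scheme: ScoreScheme) -> int | float:
    """SP cost of the trivial alignment (equal-length inputs only)."""
    return sp_cost(trivial_alignment(seqs), scheme).total
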