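"""Closed-form optimal costs and bounds for length-1 and length-2 inputs.

For length-1 sequences the trivial (single-column) alignment is optimal
under any metric, with cost equal to the sum of pairwise distances between
the characters; under the unit metric with k distinct characters this is
simply C(k, 2).  For length-2 sequences the trivial alignment is optimal
under the unit metric (and any gap-dominant metric), with cost given by the
columnwise mismatch counts.  No such closed form exists for length-2 under
arbitrary metrics or for length >= 3 even under the unit metric — the
counterexample instances live in :mod:`shortmsa.propcheck`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

from .core import SequenceSet, ShortMSAError
from .metrics import ScoreScheme, validate


@dataclass(frozen=True)
class OccupancyProfile:
    """Column occupancies (k_1, .., k_l) of a length-1 alignment.

    Each of the k characters occupies exactly one column, so the counts are
    positive and sum to k.  The SP cost of any such alignment under the unit
    metric depends on the profile alone.
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.counts or any(c < 1 for c in self.counts):
            raise ShortMSAError("occupancy counts must be positive")

    @property
    def k(self) -> int:
        return sum(self.counts)

    @property
    def columns(self) -> int:
        return len(self.counts)

    def cost_unit(self) -> int:
        """Unit-metric SP cost of an alignment with this profile: k^2 - (k + sum k_i^2)/2.

        Column i holds k_i distinct characters (C(k_i,2) mismatches) plus
        k - k_i gaps, each costing 1 against every character in the column.
        """
        k = self.k
        sq = sum(c * c for c in self.counts)
        # k + sum k_i^2 is always even (k_i^2 = k_i mod 2)
        return k * k - (k + sq) // 2


def enumerate_profiles(k: int, columns: int):
    """All occupancy profiles of k characters over a fixed number of columns."""
    if not 1 <= columns <= k:
        raise ShortMSAError(f"columns must be in 1..{k}")
    for cuts in itertools.combinations(range(1, k), columns - 1):
        bounds = (0, *cuts, k)
        yield OccupancyProfile(tuple(b - a for a, b in zip(bounds, bounds[1:])))


def optimal_cost_len1_unit(k: int) -> int:
    """Optimal SP cost of k pairwise-distinct length-1 sequences, unit metric: k(k-1)/2."""
    if k < 1:
        raise ShortMSAError("k must be >= 1")
    return k * (k - 1) // 2


def max_cost_len1_unit(k: int, columns: int) -> int | Fraction:
    """Upper bound on the SP cost of any l-column alignment of k distinct
    length-1 sequences under the unit metric: k^2 - k/2 - k^2/(2l).

    At l = k the bound is k^2 - k, attained by the one-character-per-column
    alignment; at l = 1 it collapses to the optimum k(k-1)/2.  Returned as
    an exact integer or Fraction so tests never fight float rounding.
    """
    if k < 1:
        raise ShortMSAError("k must be >= 1")
    if not 1 <= columns <= k:
        raise ShortMSAError(f"columns must be in 1..{k}")
    value = Fraction(k * k) - Fraction(k, 2) - Fraction(k * k, 2 * columns)
    return int(value) if value.denominator == 1 else value


def optimal_cost_len1(seqs: SequenceSet, scheme: ScoreScheme) -> int | float:
    """Optimal SP cost of length-1 sequences under an arbitrary metric.

    Equals the trivial-alignment cost: the sum of d over all record pairs.
    Duplicate records contribute zero to each other, so the multiset sum
    coincides with the distinct-character formula.
    """
    if any(len(s) != 1 for s in seqs.sequences):
        raise ShortMSAError("optimal_cost_len1 requires length-1 sequences")
    if not validate(scheme).is_metric:
        raise ShortMSAError("optimal_cost_len1 requires a metric score scheme")
    chars = [s for s in seqs.sequences]
    return sum(scheme.d(a, b) for a, b in itertools.combinations(chars, 2))


def optimal_cost_len2_unit(seqs: SequenceSet) -> int:
    """Optimal SP cost of length-2 sequences under the unit metric.

    Equals the trivial-alignment cost: mismatch pairs among first characters
    plus mismatch pairs among second characters.
    """
    if any(len(s) != 2 for s in seqs.sequences):
        raise ShortMSAError("optimal_cost_len2_unit requires length-2 sequences")
    firsts = [s[0] for s in seqs.sequences]
    seconds = [s[1] for s in seqs.sequences]
    return sum(a != b for a, b in itertools.combinations(firsts, 2)) + sum(
        a != b for a, b in itertools.combinations(seconds, 2)
    )
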