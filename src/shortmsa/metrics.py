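"""Score schemes: construction, validation, TSV I/O, random generation.

A *score scheme* is a symmetric non-negative distance table over
``alphabet + {gap}`` with zero diagonal.  A scheme is a *metric* when in
addition every off-diagonal entry is strictly positive and the triangle
inequality ``d(u,w) <= d(u,v) + d(v,w)`` holds for all triples.  The gap
symbol is an ordinary point of the metric space.

*Gap dominance* — ``d(a,b) <= d(a,-)`` for all alphabet characters ``a, b``
— is the single property of the unit metric that makes the trivial
alignment optimal for length-2 sequences; it is tracked as a separate flag
because metrics without it admit counterexamples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from numbers import Real
from pathlib import Path

import numpy as np

from .core import GAP, Alphabet, ShortMSAError, normalize_gaps

_TOL = 1e-9  # axiom-check tolerance for non-integer tables


def _eq(a, b, integral: bool) -> bool:
    return a == b if integral else abs(a - b) <= _TOL


def _le(a, b, integral: bool) -> bool:
    return a <= b if integral else a <= b + _TOL


@dataclass(frozen=True)
class ScoreScheme:
    """Symmetric cost table over the alphabet plus the gap symbol.

    Construction enforces what every score scheme must satisfy: a square,
    symmetric, non-negative table with zero diagonal over a domain ending in
    the gap.  Whether the table is additionally a metric (positivity off the
    diagonal + triangle inequality) or gap-dominant is recorded as flags and
    checked by :func:`validate`.
    """

    domain: tuple[str, ...]  # alphabet symbols followed by the gap
    table: tuple[tuple[int | float, ...], ...]
    _index: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        n = len(self.domain)
        if GAP not in self.domain:
            raise ShortMSAError("scheme domain must include the gap symbol")
        if len(set(self.domain)) != n:
            raise ShortMSAError("scheme domain has duplicate symbols")
        if len(self.table) != n or any(len(row) != n for row in self.table):
            raise ShortMSAError("scheme table must be square over the full domain")
        for i in range(n):
            if self.table[i][i] != 0:
                raise ShortMSAError(f"d({self.domain[i]},{self.domain[i]}) must be 0")
            for j in range(n):
                v = self.table[i][j]
                if not isinstance(v, Real) or v < 0:
                    raise ShortMSAError("scheme entries must be non-negative numbers")
                if not _eq(v, self.table[j][i], self.is_integral):
                    raise ShortMSAError(
                        f"scheme not symmetric at ({self.domain[i]},{self.domain[j]})"
                    )
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.domain)})

    @classmethod
    def from_table(cls, symbols, table) -> "ScoreScheme":
        """Build a scheme from domain symbols and a nested-sequence table.

        The gap may appear anywhere in ``symbols``; the domain is reordered
        so the gap comes last.  Integer-valued entries are kept as exact ints.
        """
        symbols = [normalize_gaps(s) for s in symbols]
        if GAP not in symbols:
            raise ShortMSAError("symbols must include the gap")
        order = [i for i, s in enumerate(symbols) if s != GAP] + [symbols.index(GAP)]
        dom = tuple(symbols[i] for i in order)
        tab = tuple(
            tuple(_as_number(table[i][j]) for j in order) for i in order
        )
        return cls(domain=dom, table=tab)

    @property
    def alphabet(self) -> Alphabet:
        return Alphabet(tuple(s for s in self.domain if s != GAP))

    @property
    def is_integral(self) -> bool:
        return all(isinstance(v, int) for row in self.table for v in row)

    def d(self, u: str, v: str) -> int | float:
        """Distance between two domain symbols (gap aliases accepted)."""
        try:
            return self.table[self._index[u]][self._index[v]]
        except KeyError:
            u2, v2 = normalize_gaps(u), normalize_gaps(v)
            if u2 in self._index and v2 in self._index:
                return self.table[self._index[u2]][self._index[v2]]
            missing = u if u2 not in self._index else v
            raise ShortMSAError(f"symbol {missing!r} not covered by the score scheme")

    @property
    def is_metric(self) -> bool:
        return validate(self).is_metric

    @property
    def is_gap_dominant(self) -> bool:
        return validate(self).is_gap_dominant

    def scale(self, c: int | float) -> "ScoreScheme":
        if c <= 0:
            raise ShortMSAError("scale factor must be positive")
        tab = tuple(tuple(v * c for v in row) for row in self.table)
        return ScoreScheme(domain=self.domain, table=tab)


def _as_number(v) -> int | float:
    f = float(v)
    return int(f) if f.is_integer() else f


def unit_metric(alphabet: Alphabet) -> ScoreScheme:
    """The unit metric: 0 on the diagonal, 1 for every other pair (gap included)."""
    dom = tuple(alphabet.symbols) + (GAP,)
    n = len(dom)
    tab = tuple(tuple(0 if i == j else 1 for j in range(n)) for i in range(n))
    return ScoreScheme(domain=dom, table=tab)


@dataclass(frozen=True)
class SchemeValidation:
    """Axiom-by-axiom report; each violation carries its witness pair/triple."""

    positivity_violations: tuple[tuple[str, str], ...]
    triangle_violations: tuple[tuple[str, str, str], ...]  # (u, v, w): d(u,w) > d(u,v)+d(v,w)
    gap_dominance_violations: tuple[tuple[str, str], ...]

    @property
    def is_metric(self) -> bool:
        return not self.positivity_violations and not self.triangle_violations

    @property
    def is_gap_dominant(self) -> bool:
        return not self.gap_dominance_violations


def validate(scheme: ScoreScheme) -> SchemeValidation:
    """Check positivity, the triangle inequality and gap dominance.

    Symmetry, the zero diagonal and non-negativity are already enforced at
    construction, so only the remaining axioms can fail here.
    """
    dom = scheme.domain
    integral = scheme.is_integral
    pos = tuple(
        (u, v)
        for i, u in enumerate(dom)
        for v in dom[i + 1:]
        if _eq(scheme.d(u, v), 0, integral)
    )
    tri = tuple(
        (u, v, w)
        for u in dom
        for v in dom
        for w in dom
        if not _le(scheme.d(u, w), scheme.d(u, v) + scheme.d(v, w), integral)
    )
    alpha = [s for s in dom if s != GAP]
    gd = tuple(
        (a, b)
        for a in alpha
        for b in alpha
        if not _le(scheme.d(a, b), scheme.d(a, GAP), integral)
    )
    return SchemeValidation(pos, tri, gd)


def gap_dominant(scheme: ScoreScheme) -> tuple[bool, tuple[tuple[str, str], ...]]:
    """Whether d(a,b) <= d(a,-) for all alphabet characters, with witnesses."""
    report = validate(scheme)
    return report.is_gap_dominant, report.gap_dominance_violations


def random_metric(
    alphabet: Alphabet,
    seed: int,
    value_range: tuple[int, int] = (1, 9),
) -> ScoreScheme:
    """Sample a valid integer metric on ``alphabet + {gap}``.

    Symmetric off-diagonal values are drawn uniformly from ``value_range``
    and repaired into a metric by taking the metric closure (all-pairs
    shortest paths), which can only shrink entries and never below the
    smallest sampled edge, so positivity is preserved.  Deterministic per
    seed.
    """
    lo, hi = value_range
    if not (0 < lo <= hi):
        raise ShortMSAError(f"degenerate value range {value_range}")
    rng = np.random.default_rng(seed)
    n = len(alphabet) + 1
    m = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = rng.integers(lo, hi + 1)
    m = _metric_closure(m)
    dom = tuple(alphabet.symbols) + (GAP,)
    tab = tuple(tuple(int(v) for v in row) for row in m)
    return ScoreScheme(domain=dom, table=tab)


def random_gap_dominant_metric(
    alphabet: Alphabet,
    seed: int,
    value_range: tuple[int, int] = (1, 9),
) -> ScoreScheme:
    """Sample an integer metric with the gap-dominance property.

    Character-character distances are sampled and metric-closed as in
    :func:`random_metric`; every gap distance is then set to the maximum
    character-character distance.  A constant gap distance that dominates
    the table keeps every triangle valid and makes dominance hold by
    construction.
    """
    inner = random_metric(alphabet, seed, value_range)
    n = len(alphabet)
    big = max(
        (inner.d(a, b) for a in alphabet for b in alphabet if a != b),
        default=max(1, value_range[0]),
    )
    dom = tuple(alphabet.symbols) + (GAP,)
    tab = []
    for i in range(n + 1):
        row = []
        for j in range(n + 1):
            if i == j:
                row.append(0)
            elif i == n or j == n:
                row.append(int(big))
            else:
                row.append(inner.d(dom[i], dom[j]))
        tab.append(tuple(row))
    return ScoreScheme(domain=dom, table=tuple(tab))


def _metric_closure(m: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths (Floyd–Warshall) on an integer distance table."""
    d = m.copy()
    for k in range(d.shape[0]):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


# ---------------------------------------------------------------------------
# Metric TSV dialect: header row of tab-separated symbols (gap included);
# each following row is a symbol label then its numeric entries.  Square and
# symmetric by contract.

def parse_metric_tsv(text: str) -> ScoreScheme:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ShortMSAError("metric TSV needs a header row and one row per symbol")
    header = [normalize_gaps(c.strip()) for c in lines[0].split("\t") if c.strip()]
    n = len(header)
    if len(lines) != n + 1:
        raise ShortMSAError(f"metric TSV must have {n} data rows for {n} symbols")
    table = [[0] * n for _ in range(n)]
    order = {}
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split("\t")]
        label = normalize_gaps(cells[0])
        if label not in header:
            raise ShortMSAError(f"row label {label!r} not in TSV header")
        if len(cells) != n + 1:
            raise ShortMSAError(f"row {label!r} must have {n} entries")
        order[label] = [_as_number(c) for c in cells[1:]]
    if set(order) != set(header):
        raise ShortMSAError("metric TSV rows do not cover the header symbols")
    for i, u in enumerate(header):
        for j in range(n):
            table[i][j] = order[u][j]
    return ScoreScheme.from_table(header, table)


def read_metric_tsv(path: str | Path) -> ScoreScheme:
    return parse_metric_tsv(Path(path).read_text())


def format_metric_tsv(scheme: ScoreScheme) -> str:
    buf = io.StringIO()
    buf.write("\t".join(scheme.domain) + "\n")
    for u in scheme.domain:
        buf.write(u + "\t" + "\t".join(str(scheme.d(u, v)) for v in scheme.domain) + "\n")
    return buf.getvalue()


def write_metric_tsv(scheme: ScoreScheme, path: str | Path) -> None:
    Path(path).write_text(format_metric_tsv(scheme))


def example_two_letter_metric() -> ScoreScheme:
    """The printed C/G metric with d(C,G)=2 and unit gap costs.

    A metric that is *not* gap-dominant (2 > 1): the canonical source of
    counterexamples where a gapped alignment beats the trivial one.
    """
    return ScoreScheme.from_table(
        ["C", "G", GAP],
        [[0, 2, 1], [2, 0, 1], [1, 1, 0]],
    )
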