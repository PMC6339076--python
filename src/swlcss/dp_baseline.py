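"""Classical dynamic-programming longest-common-subsequence baseline.

This is the quadratic-time comparator the windowed heuristic is benchmarked
against, and the internal optimality oracle for tests: the greedy algorithm
can never exceed the DP length.  The full (m+1) x (n+1) prefix-length table
is materialized only on request; the length-only path keeps two rolling rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    EXACT,
    EqSpec,
    MatchTrace,
    MultivariateSeries,
    SwlcssError,
    SymbolSequence,
    eq,
)

__all__ = ["DpTable", "DpResult", "dp_lcs", "dp_lcs_multivariate"]


@dataclass(frozen=True)
class DpTable:
    """The (m+1) x (n+1) grid of optimal prefix LCS lengths."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = self.grid
        if g.ndim != 2:
            raise ValueError("DP table must be two-dimensional")
        if g[0, :].any() or g[:, 0].any():
            raise ValueError("row 0 and column 0 of a DP table must be zero")


@dataclass(frozen=True)
class DpResult:
    length: int
    trace: MatchTrace
    table: DpTable | None = None
    comparisons: int = 0
    #: True when a non-transitive tolerance predicate was used; the returned
    #: length is then the DP recurrence value but not a certified optimum.
    optimality_certified: bool = True


def _values(x) -> tuple:
    return x.values if isinstance(x, SymbolSequence) else tuple(x)


def _check_kinds(a: tuple, b: tuple) -> None:
    """Reject mixed symbol/number inputs up front (same error the predicate gives)."""
    from numbers import Real

    def kind(v):
        return isinstance(v, Real) and not isinstance(v, bool)

    kinds = {kind(v) for v in a} | {kind(v) for v in b}
    if len(kinds) > 1:
        sym = next(v for v in (*a, *b) if not kind(v))
        num = next(v for v in (*a, *b) if kind(v))
        from .core import IncomparableValuesError

        raise IncomparableValuesError(sym, num)


def dp_lcs(
    A,
    B,
    spec: EqSpec = EXACT,
    *,
    keep_table: bool = False,
) -> DpResult:
    """Optimal LCS of two univariate sequences by dynamic programming.

    Returns the optimum length, one canonical traceback (ties broken
    diagonal-first, then up, then left, giving a deterministic trace), and —
    when ``keep_table`` — the full prefix-length table.

    With an exact predicate the length is the true optimum.  A tolerance
    predicate is accepted but flagged (``optimality_certified=False``) because
    non-transitive equality voids the DP optimality argument.
    """
    a, b = _values(A), _values(B)
    m, n = len(a), len(b)

    if spec.is_exact:
        _check_kinds(a, b)

    grid = np.zeros((m + 1, n + 1), dtype=np.int64)
    comparisons = 0
    exact = spec.is_exact
    for i in range(1, m + 1):
        row = grid[i]
        prev = grid[i - 1]
        ai = a[i - 1]
        for j in range(1, n + 1):
            comparisons += 1
            # exact mode compares inline (kinds pre-checked above)
            if (ai == b[j - 1]) if exact else eq(ai, b[j - 1], spec):
                row[j] = prev[j - 1] + 1
            else:
                row[j] = prev[j] if prev[j] >= row[j - 1] else row[j - 1]

    # Canonical traceback: prefer the diagonal (match), then up, then left.
    pairs: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 and j > 0:
        if eq(a[i - 1], b[j - 1], spec) and grid[i, j] == grid[i - 1, j - 1] + 1:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif grid[i - 1, j] >= grid[i, j - 1]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()

    length = int(grid[m, n])
    trace = MatchTrace(pairs, sigma=None, start_offset=0)
    assert len(trace) == length
    return DpResult(
        length=length,
        trace=trace,
        table=DpTable(grid) if keep_table else None,
        comparisons=comparisons,
        optimality_certified=spec.is_exact,
    )


def dp_lcs_multivariate(
    S: MultivariateSeries,
    T: MultivariateSeries,
    spec: EqSpec = EXACT,
    *,
    keep_table: bool = False,
) -> DpResult:
    """Optimal LCS over whole rows: two rows match iff every variable matches.

    Serves as the optimality reference for the anchor-then-filter multivariate
    pipeline (whose result can be shorter, never longer).
    """
    if set(S.variable_names) != set(T.variable_names):
        raise SwlcssError(
            f"variable sets differ between {S.identifier!r} and {T.identifier!r}: "
            f"{sorted(set(S.variable_names) ^ set(T.variable_names))}"
        )
    order = S.variable_names
    a = [S.row(i) for i in range(len(S))]
    b = [
        tuple(T.column(name)[j] for name in order)
        for j in range(len(T))
    ]
    if spec.is_exact:
        return dp_lcs(
            SymbolSequence(S.identifier, a),
            SymbolSequence(T.identifier, b),
            spec,
            keep_table=keep_table,
        )
    # Tolerance mode: tuples need element-wise comparison, so wrap each row.
    wrapped_spec = spec

    class _Row(tuple):
        def __eq__(self, other):  # pragma: no cover - exercised via eq()
            return len(self) == len(other) and all(
                abs(x - y) <= wrapped_spec.epsilon for x, y in zip(self, other)
            )

        __hash__ = tuple.__hash__

    res = dp_lcs(
        SymbolSequence(S.identifier, [_Row(r) for r in a]),
        SymbolSequence(T.identifier, [_Row(r) for r in b]),
        EqSpec(),  # _Row.__eq__ embeds the tolerance
        keep_table=keep_table,
    )
    return replace(res, optimality_certified=False)
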