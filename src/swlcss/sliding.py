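"""Sliding-window greedy LCSS on one variable.

The algorithm scans the first sequence S left to right, keeping a trace
pointer TP into the second sequence T.  For each element of S it examines at
most ``sigma`` candidate positions of T starting at TP; on the first match it
records the index pair and moves TP past the matched position, on failure TP
stays put and the scan advances to the next element of S.  One such scan is a
*pass*.  Passes are repeated from successive start offsets of S (dropping one
leading element each time) up to a maximum offset M, and the longest pass
wins; ties go to the earliest start.  An optional early stop ends the restart
loop as soon as the incumbent length reaches M.

The window caps the number of comparisons at ``sigma`` per element, giving
O(m) work per pass and O(M * n * sigma) in the worst case over all passes —
versus the m x n table of the dynamic-programming baseline.  The price is
greediness: the first match in a window is taken, so the result is a lower
bound on the true LCS length, not the optimum.
"""

from __future__ import annotations

from bisect import bisect_left

from .core import (
    EXACT,
    EqSpec,
    LcssResult,
    MatchTrace,
    SwlcssError,
    SymbolSequence,
    eq,
)

__all__ = ["greedy_pass", "sliding_lcss", "comparison_count", "default_max_start"]


class WindowError(SwlcssError, ValueError):
    """Raised for an invalid sliding-window parameter."""


def _values(x) -> tuple:
    return x.values if isinstance(x, SymbolSequence) else tuple(x)


class _Counter:
    __slots__ = ("n",)

    def __init__(self) -> None:
        self.n = 0


def _check_sigma(sigma) -> int:
    if sigma is None:
        return None
    if not isinstance(sigma, int) or sigma < 1:
        raise WindowError(f"sigma must be a positive integer or None, got {sigma!r}")
    return sigma


def _occurrence_index(t: tuple) -> dict:
    """Sorted T positions per value, for the exact-equality fast path.

    Values that are not equal to themselves (NaN) can never match and are
    left out, so index lookups agree with the naive scan.
    """
    occ: dict = {}
    for j, v in enumerate(t):
        if v == v:
            occ.setdefault(v, []).append(j)
    return occ


def _pass_naive(s, t, start, sigma, spec, counter):
    n = len(t)
    pairs: list[tuple[int, int]] = []
    tp = 0
    for i in range(start, len(s)):
        hi = n if sigma is None else min(tp + sigma, n)
        for j in range(tp, hi):
            counter.n += 1
            if eq(s[i], t[j], spec):
                pairs.append((i, j))
                tp = j + 1
                break
        # no match in the window: TP stays frozen, move to the next element
    return pairs


def _pass_indexed(s, n, occ, start, sigma, counter):
    # Same trace and same comparison count as the naive scan, but each window
    # is resolved with one binary search instead of up to sigma eq calls.
    pairs: list[tuple[int, int]] = []
    tp = 0
    for i in range(start, len(s)):
        hi = n if sigma is None else min(tp + sigma, n)
        positions = occ.get(s[i])
        j = -1
        if positions is not None:
            k = bisect_left(positions, tp)
            if k < len(positions) and positions[k] < hi:
                j = positions[k]
        if j >= 0:
            counter.n += j - tp + 1
            pairs.append((i, j))
            tp = j + 1
        else:
            counter.n += hi - tp
    return pairs


def _hashable(values: tuple) -> bool:
    try:
        for v in values:
            hash(v)
    except TypeError:
        return False
    return True


def _fast_path_ok(s: tuple, t: tuple) -> bool:
    """Use the indexed path only for homogeneous, hashable inputs.

    Mixed symbol/number inputs must go through the literal scan so the
    incomparable-kinds error surfaces exactly where the scan would hit it.
    """
    from numbers import Real

    def kinds(vals):
        return {isinstance(v, Real) and not isinstance(v, bool) for v in vals}

    ks, kt = kinds(s), kinds(t)
    if len(ks) > 1 or len(kt) > 1 or (ks and kt and ks != kt):
        return False
    return _hashable(s) and _hashable(t)


def greedy_pass(
    S,
    T,
    start: int = 0,
    sigma: int | None = 3,
    spec: EqSpec = EXACT,
    _counter: _Counter | None = None,
    _occ: dict | None = None,
) -> MatchTrace:
    """One greedy left-to-right matching pass from start offset *start*.

    Positions in the returned trace are in original S coordinates (the start
    offset is recorded on the trace, not subtracted).  ``sigma=None`` means an
    unbounded window (every remaining position of T is a candidate).

    In exact mode with hashable values the pass is resolved against a sorted
    occurrence index of T; the trace and the reported comparison count are
    identical to the literal window scan, which remains the fallback (and the
    only path in tolerance mode).

    Raises
    ------
    WindowError
        If ``sigma < 1`` or ``start`` is out of range.
    """
    sigma = _check_sigma(sigma)
    s, t = _values(S), _values(T)
    m, n = len(s), len(t)
    if not 0 <= start <= m:
        raise WindowError(f"start offset {start} out of range for length {m}")

    counter = _counter if _counter is not None else _Counter()
    if spec.is_exact and (_occ is not None or _fast_path_ok(s, t)):
        occ = _occ if _occ is not None else _occurrence_index(t)
        pairs = _pass_indexed(s, n, occ, start, sigma, counter)
    else:
        pairs = _pass_naive(s, t, start, sigma, spec, counter)
    return MatchTrace(pairs, sigma=sigma, start_offset=start)


def default_max_start(m: int, fraction: float = 0.5) -> int:
    """Maximum restart offset: a fraction of the first sequence's length.

    The default fraction 0.5 makes M the half-length of S.
    """
    if not 0 <= fraction <= 1:
        raise WindowError(f"max-start fraction must be in [0, 1], got {fraction}")
    return int(m * fraction)


def sliding_lcss(
    S,
    T,
    sigma: int | None = 3,
    max_start: int | None = None,
    early_stop: bool = True,
    spec: EqSpec = EXACT,
    *,
    max_start_fraction: float = 0.5,
    auto_order: bool = False,
) -> LcssResult:
    """Sliding-window LCSS with suffix restarts.

    Runs :func:`greedy_pass` from start offsets ``a = 0, 1, ..., max_start``,
    keeping the longest trace; a later pass replaces the incumbent only when
    strictly longer, so the earliest best start wins ties.  With
    ``early_stop`` (default on) the restart loop ends as soon as the
    incumbent length reaches ``max_start`` — the regime in which the method
    approaches linear time on highly similar inputs, at the risk of missing a
    longer trace from a later start.

    Parameters
    ----------
    sigma:
        Window width: candidate positions examined per element, counted from
        the trace pointer.  ``None`` = unbounded.  Default 3.
    max_start:
        Largest start offset M (inclusive).  Default ``len(S) * max_start_fraction``.
    auto_order:
        When True, swap the inputs so the shorter sequence is scanned (the
        restart loop deletes prefixes of the first argument only); the
        returned trace is swapped back to (S, T) orientation.
    """
    sigma = _check_sigma(sigma)
    s_vals, t_vals = _values(S), _values(T)
    swapped = False
    if auto_order and len(t_vals) < len(s_vals):
        s_vals, t_vals = t_vals, s_vals
        swapped = True
    m = len(s_vals)
    if max_start is None:
        max_start = default_max_start(m, max_start_fraction)
    if not 0 <= max_start <= m:
        raise WindowError(f"max_start {max_start} out of range for length {m}")

    counter = _Counter()
    occ = None
    if spec.is_exact and _fast_path_ok(s_vals, t_vals):
        occ = _occurrence_index(t_vals)
    best: MatchTrace = MatchTrace([], sigma=sigma, start_offset=0)
    best_len = 0
    best_start = 0
    pass_lengths: list[int] = []
    for a in range(0, max_start + 1):
        if early_stop and best_len >= max_start and max_start > 0:
            break
        if a >= m and a > 0:
            break
        trace = greedy_pass(s_vals, t_vals, a, sigma, spec, _counter=counter, _occ=occ)
        pass_lengths.append(len(trace))
        if len(trace) > best_len:  # strict improvement only
            best, best_len, best_start = trace, len(trace), a

    if swapped:
        best = MatchTrace(
            [(p.j, p.i) for p in best.pairs], sigma=None, start_offset=0
        )

    return LcssResult(
        best_trace=best,
        length=best_len,
        best_start=best_start,
        pass_lengths=pass_lengths,
        stage_lengths=[best_len],
        comparisons=counter.n,
        parameters={
            "sigma": sigma,
            "max_start": max_start,
            "early_stop": early_stop,
            "eq_mode": spec.mode,
            "epsilon": spec.epsilon,
            "auto_order": auto_order,
        },
    )


def comparison_count(result: LcssResult) -> int:
    """Exact number of equality-predicate evaluations a run performed."""
    return result.comparisons
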