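"""Multivariate similarity by anchor-then-filter refinement.

The multivariate procedure runs the sliding-window matcher on a single
anchor variable (the first column by default), producing a trace of matched
index pairs, then filters that trace variable by variable: a pair survives
only if the two series also agree on every remaining variable at those
positions.  Filtering is a pure intersection over the pair set, so it is
idempotent, monotone non-increasing in trace length, and independent of the
order in which variables are applied (order affects only the per-stage
diagnostics).
"""

from __future__ import annotations

from typing import Sequence

from .core import (
    EXACT,
    EqSpec,
    LcssResult,
    MatchTrace,
    MultivariateSeries,
    SwlcssError,
    eq,
)
from .sliding import sliding_lcss

__all__ = ["refine_trace", "mlcss", "similarity_index"]


class VariableError(SwlcssError, KeyError):
    """Raised when a requested variable is absent from a series."""


class _RefineCounter:
    __slots__ = ("n",)

    def __init__(self) -> None:
        self.n = 0


def _check_variables(S: MultivariateSeries, T: MultivariateSeries, names) -> None:
    for name in names:
        for series in (S, T):
            if name not in series.variable_names:
                raise VariableError(
                    f"variable {name!r} absent from series {series.identifier!r}"
                )


def refine_trace(
    trace: MatchTrace,
    S: MultivariateSeries,
    T: MultivariateSeries,
    variables: Sequence[str] | None = None,
    spec: EqSpec = EXACT,
    _counter=None,
) -> MatchTrace:
    """Keep only the pairs on which every requested variable also matches.

    ``variables`` defaults to all variables after the first (the usual call
    after anchoring on column one).  The input trace is not modified.  The
    returned trace carries no window parameter: deleting pairs can widen the
    gaps between survivors beyond the original window.
    """
    if variables is None:
        variables = list(S.variable_names[1:])
    _check_variables(S, T, variables)

    surviving = []
    for pair in trace:
        keep = True
        for v in variables:
            if _counter is not None:
                _counter.n += 1
            if not eq(S.column(v)[pair.i], T.column(v)[pair.j], spec):
                keep = False
                break
        if keep:
            surviving.append((pair.i, pair.j))
    return MatchTrace(surviving, sigma=None, start_offset=trace.start_offset)


def mlcss(
    S: MultivariateSeries,
    T: MultivariateSeries,
    sigma: int | None = 3,
    *,
    anchor_variable: str | None = None,
    max_start: int | None = None,
    early_stop: bool = True,
    spec: EqSpec = EXACT,
    max_start_fraction: float = 0.5,
) -> LcssResult:
    """Multivariate sliding-window LCSS: anchor on one variable, filter by the rest.

    Stage 1 runs :func:`~swlcss.sliding.sliding_lcss` on the anchor variable
    (first column unless ``anchor_variable`` names another).  Stage 2 refines
    the resulting trace with every remaining variable in column order.  The
    result records the trace length after each stage in ``stage_lengths``
    (anchor first).
    """
    if set(S.variable_names) != set(T.variable_names):
        raise VariableError(
            f"variable sets differ: {sorted(set(S.variable_names) ^ set(T.variable_names))}"
        )
    anchor = anchor_variable if anchor_variable is not None else S.variable_names[0]
    _check_variables(S, T, [anchor])

    stage1 = sliding_lcss(
        S.column(anchor),
        T.column(anchor),
        sigma=sigma,
        max_start=max_start,
        early_stop=early_stop,
        spec=spec,
        max_start_fraction=max_start_fraction,
    )

    rest = [v for v in S.variable_names if v != anchor]
    trace = stage1.best_trace
    stage_lengths = [stage1.length]
    counter = _RefineCounter()
    for v in rest:
        trace = refine_trace(trace, S, T, [v], spec, _counter=counter)
        stage_lengths.append(len(trace))

    params = dict(stage1.parameters)
    params.update({"anchor_variable": anchor, "refined_variables": rest})
    return LcssResult(
        best_trace=trace,
        length=len(trace),
        best_start=stage1.best_start,
        pass_lengths=stage1.pass_lengths,
        stage_lengths=stage_lengths,
        comparisons=stage1.comparisons + counter.n,
        parameters=params,
    )


def similarity_index(result: LcssResult, m: int, n: int) -> float:
    """Final trace length normalized by the shorter input's length.

    Returns a value in [0, 1]; defined as 0 when either input is empty.
    """
    if m <= 0 or n <= 0:
        return 0.0
    return result.length / min(m, n)
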