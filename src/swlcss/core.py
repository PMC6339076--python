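"""Shared domain types for sequence similarity computation.

The package works on two kinds of inputs: univariate symbol sequences
(characters or numbers) and multivariate series (several aligned numeric
columns, optionally timestamped).  Matching is driven by a single equality
predicate, :func:`eq`, configured through :class:`EqSpec`; every algorithm in
the package — the greedy windowed matcher, the dynamic-programming baseline
and the cross-variable refinement — calls the same predicate.

Match results are recorded as a :class:`MatchTrace`: an ordered list of
``(i, j)`` index pairs, strictly increasing in both coordinates, expressed in
the *original* coordinates of both inputs.  Keeping original coordinates is
essential because the multivariate refinement stage must look up the values
of the remaining variables at exactly those positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Real
from typing import Iterator, Sequence

__all__ = [
    "SwlcssError",
    "IncomparableValuesError",
    "SymbolSequence",
    "MultivariateSeries",
    "EqSpec",
    "MatchPair",
    "MatchTrace",
    "LcssResult",
    "eq",
]


class SwlcssError(Exception):
    """Base class for all errors raised by this package."""


class IncomparableValuesError(SwlcssError, TypeError):
    """Raised when the equality predicate is asked to compare a symbol with a number."""

    def __init__(self, a: object, b: object) -> None:
        super().__init__(
            f"cannot compare {a!r} (type {type(a).__name__}) with "
            f"{b!r} (type {type(b).__name__}): mixed symbol/number comparison"
        )
        self.a = a
        self.b = b


def _is_number(x: object) -> bool:
    return isinstance(x, Real) and not isinstance(x, bool)


@dataclass(frozen=True)
class EqSpec:
    """Configuration of the value-equality predicate.

    Parameters
    ----------
    mode:
        ``"exact"`` (default) compares values with ``==``; ``"tolerance"``
        declares two numbers equal when ``|a - b| <= epsilon``.
    epsilon:
        Absolute tolerance, per comparison.  Must be 0 in exact mode.

    Notes
    -----
    The predicate is symmetric in both modes.  Exact equality is transitive;
    tolerance equality is *not* (``a ~ b`` and ``b ~ c`` do not imply
    ``a ~ c``), so optimality guarantees of the DP baseline only hold in
    exact mode.
    """

    mode: str = "exact"
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "tolerance"):
            raise ValueError(f"unknown EqSpec mode {self.mode!r}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")
        if self.mode == "exact" and self.epsilon != 0:
            raise ValueError("exact mode requires epsilon = 0")

    @property
    def is_exact(self) -> bool:
        return self.mode == "exact"


#: Default predicate: exact equality of raw values.
EXACT = EqSpec()


def eq(a, b, spec: EqSpec = EXACT) -> bool:
    """Decide whether two values match under *spec*.

    Raises
    ------
    IncomparableValuesError
        If one operand is a number and the other is not (e.g. ``"A"`` vs 35).
    """
    a_num = _is_number(a)
    b_num = _is_number(b)
    if a_num != b_num:
        raise IncomparableValuesError(a, b)
    if spec.mode == "tolerance" and a_num:
        return abs(a - b) <= spec.epsilon
    return a == b


@dataclass(frozen=True)
class SymbolSequence:
    """An ordered univariate series of symbols or numbers."""

    identifier: str
    values: tuple

    def __init__(self, identifier: str, values: Sequence) -> None:
        object.__setattr__(self, "identifier", identifier)
        object.__setattr__(self, "values", tuple(values))

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, idx):
        return self.values[idx]

    def __iter__(self) -> Iterator:
        return iter(self.values)

    @classmethod
    def from_string(cls, identifier: str, text: str) -> "SymbolSequence":
        return cls(identifier, tuple(text))

    def as_string(self) -> str:
        """Join character values back into a string (symbolic sequences only)."""
        return "".join(str(v) for v in self.values)


@dataclass(frozen=True)
class MultivariateSeries:
    """``m`` aligned rows over ``h`` named variables, with optional timestamps.

    Each variable is stored as a :class:`SymbolSequence` column; all columns
    share the same length.  Timestamps are carried as labels only — they never
    participate in matching.
    """

    identifier: str
    variable_names: tuple[str, ...]
    columns: tuple[SymbolSequence, ...]
    timestamps: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.variable_names) < 1:
            raise ValueError("a MultivariateSeries needs at least one variable")
        if len(self.variable_names) != len(self.columns):
            raise ValueError(
                f"{len(self.variable_names)} variable names but {len(self.columns)} columns"
            )
        lengths = {len(c) for c in self.columns}
        if len(lengths) > 1:
            raise ValueError(f"columns have unequal lengths: {sorted(lengths)}")
        if self.timestamps is not None and len(self.timestamps) != len(self):
            raise ValueError(
                f"{len(self.timestamps)} timestamps for {len(self)} rows"
            )

    @classmethod
    def from_columns(
        cls,
        identifier: str,
        data: dict[str, Sequence],
        timestamps: Sequence | None = None,
    ) -> "MultivariateSeries":
        names = tuple(data.keys())
        cols = tuple(
            SymbolSequence(f"{identifier}:{name}", vals) for name, vals in data.items()
        )
        ts = tuple(timestamps) if timestamps is not None else None
        return cls(identifier, names, cols, ts)

    def __len__(self) -> int:
        return len(self.columns[0])

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    def column(self, name: str) -> SymbolSequence:
        try:
            idx = self.variable_names.index(name)
        except ValueError:
            raise KeyError(
                f"variable {name!r} not in series {self.identifier!r} "
                f"(has {list(self.variable_names)})"
            ) from None
        return self.columns[idx]

    def row(self, i: int) -> tuple:
        """The composite value tuple of row *i* across all variables."""
        return tuple(c[i] for c in self.columns)


@dataclass(frozen=True, order=True)
class MatchPair:
    """One matched position: index *i* in the first input, *j* in the second."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i < 0 or self.j < 0:
            raise ValueError(f"match positions must be non-negative, got {self}")


@dataclass(frozen=True)
class MatchTrace:
    """An ordered list of matched index pairs with the window parameter in force.

    Invariants (checked on construction):

    * pairs strictly increase in both coordinates;
    * consecutive pairs obey the window discipline
      ``j_{k+1} - (j_k + 1) <= sigma - 1`` — each match opens at most
      ``sigma`` candidate positions past the previous one.
    """

    pairs: tuple[MatchPair, ...]
    sigma: int | None = None
    start_offset: int = 0

    def __init__(
        self,
        pairs: Sequence[MatchPair | tuple[int, int]],
        sigma: int | None = None,
        start_offset: int = 0,
    ) -> None:
        norm = tuple(p if isinstance(p, MatchPair) else MatchPair(*p) for p in pairs)
        object.__setattr__(self, "pairs", norm)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "start_offset", start_offset)
        self._validate()

    def _validate(self) -> None:
        if self.start_offset < 0:
            raise ValueError("start_offset must be non-negative")
        for k in range(1, len(self.pairs)):
            prev, cur = self.pairs[k - 1], self.pairs[k]
            if not (cur.i > prev.i and cur.j > prev.j):
                raise ValueError(
                    f"match trace not strictly increasing: {prev} then {cur}"
                )
            if self.sigma is not None and cur.j - (prev.j + 1) > self.sigma - 1:
                raise ValueError(
                    f"window discipline violated between {prev} and {cur} "
                    f"with sigma={self.sigma}"
                )
    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[MatchPair]:
        return iter(self.pairs)

    def __getitem__(self, k: int) -> MatchPair:
        return self.pairs[k]

    def indices(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """The two position lists (the algorithm's classes K1 and K2)."""
        return tuple(p.i for p in self.pairs), tuple(p.j for p in self.pairs)

    def matched_values(self, seq: SymbolSequence, side: str = "first") -> tuple:
        """Values of *seq* at the matched positions on the requested side."""
        if side == "first":
            return tuple(seq[p.i] for p in self.pairs)
        if side == "second":
            return tuple(seq[p.j] for p in self.pairs)
        raise ValueError("side must be 'first' or 'second'")


@dataclass
class LcssResult:
    """Outcome of a sliding-window LCSS run (possibly followed by refinement).

    Attributes
    ----------
    best_trace:
        The longest match trace found over all suffix starts (after any
        refinement stages).
    length:
        ``len(best_trace)`` — the similarity count.
    best_start:
        The smallest start offset attaining the maximum.
    pass_lengths:
        Per-pass match counts, one entry per executed pass.
    stage_lengths:
        For multivariate runs: trace length after the anchor stage and after
        each refinement variable, in processing order.
    comparisons:
        Number of equality-predicate evaluations performed.
    parameters:
        Effective parameters of the run (sigma, max_start, early_stop, spec...).
    """

    best_trace: MatchTrace
    length: int
    best_start: int
    pass_lengths: list[int] = field(default_factory=list)
    stage_lengths: list[int] = field(default_factory=list)
    comparisons: int = 0
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length != len(self.best_trace):
            raise ValueError(
                f"inconsistent result: length={self.length} but trace has "
                f"{len(self.best_trace)} pairs"
            )
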