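"""Generator of sequence pairs with controllable, planted similarity.

The generator builds a first series S from a chosen value model, then derives
a second series T by copying each row of S with probability ``delta`` (a
*planted* match, optionally displaced by a bounded positional jitter) and
replacing it otherwise.  The planted rows form a strictly increasing match
trace, which is returned alongside the pair: it is a feasible solution for
the greedy matcher under a sufficiently wide window, so its length lower
bounds what the matcher can recover.  ``delta`` therefore plays the role of a
per-position match probability and directly controls the expected similarity
of the pair.

Two replacement regimes are available.  In the default *strict* regime,
replacement values are drawn from a reserved pool disjoint from the value
model (lowercase letters for symbolic data, out-of-range numbers otherwise),
so non-planted positions can never match on the anchor variable and the
planted trace is a sharp ground truth.  With ``honest_noise=True``
replacements come from the same pool as the data and accidental matches are
possible — closer to real sensor records, but the planted trace is then only
a lower bound on the best achievable trace.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .core import MatchTrace, MultivariateSeries, SwlcssError, SymbolSequence

__all__ = ["SyntheticConfig", "generate_pair", "generate_benchmark_suite"]

SYMBOLIC = "symbolic"
INTEGER = "integer"
REAL = "real"


class GenerationError(SwlcssError, ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for one generated pair.

    Parameters
    ----------
    length:
        Number of rows m in each series.
    n_variables:
        Number of variables h (columns).
    delta:
        Probability that a row of S is planted (copied) into T.
    value_model:
        ``"real"`` (default) — uniform floats in ``[0, noise_amplitude]``,
        almost surely distinct, the regime of physical sensor readings where
        planted similarity is sharply identifiable; ``"integer"`` — uniform
        integers in ``integer_range`` (inclusive); ``"symbolic"`` — uppercase
        letters from an alphabet of ``alphabet_size``.  Small value spaces
        produce frequent accidental value collisions, under which even
        unrelated pairs share long common subsequences — realistic for DNA,
        but then the planted trace is only a loose lower bound on what any
        matcher can find.
    displacement:
        Maximum extra positional jitter of each planted match in T
        (0 = planted rows keep their relative order and spacing).
    delta2:
        Probability that each *additional* variable of a planted row is
        copied exactly (default 1); with probability ``1 - delta2`` it is
        replaced, so the row survives anchor matching but fails refinement.
    honest_noise:
        Draw replacement values from the same pool as the data instead of a
        reserved disjoint pool.
    seed:
        Seed for the internal random generator; same config (including seed)
        reproduces the pair exactly.
    """

    length: int = 500
    n_variables: int = 1
    delta: float = 0.5
    value_model: str = REAL
    alphabet_size: int = 4
    integer_range: tuple[int, int] = (0, 9)
    noise_amplitude: float = 1.0
    displacement: int = 0
    delta2: float = 1.0
    honest_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.delta <= 1:
            raise GenerationError(f"delta must be in [0, 1], got {self.delta}")
        if not 0 <= self.delta2 <= 1:
            raise GenerationError(f"delta2 must be in [0, 1], got {self.delta2}")
        if self.length < 0:
            raise GenerationError(f"length must be non-negative, got {self.length}")
        if self.n_variables < 1:
            raise GenerationError(f"need at least one variable, got {self.n_variables}")
        if self.displacement < 0:
            raise GenerationError(f"displacement must be non-negative, got {self.displacement}")
        if self.length > 0 and self.displacement >= self.length:
            raise GenerationError(
                f"displacement {self.displacement} must be smaller than length {self.length}"
            )
        if self.value_model not in (SYMBOLIC, INTEGER, REAL):
            raise GenerationError(f"unknown value model {self.value_model!r}")
        if self.value_model == SYMBOLIC and not 1 <= self.alphabet_size <= 26:
            raise GenerationError("alphabet_size must be between 1 and 26")


def _draw_values(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> list:
    if cfg.value_model == SYMBOLIC:
        letters = string.ascii_uppercase[: cfg.alphabet_size]
        return [letters[k] for k in rng.integers(0, cfg.alphabet_size, size=n)]
    if cfg.value_model == INTEGER:
        lo, hi = cfg.integer_range
        return [int(v) for v in rng.integers(lo, hi + 1, size=n)]
    return [float(v) for v in rng.uniform(0.0, cfg.noise_amplitude, size=n)]


def _draw_replacements(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> list:
    if cfg.honest_noise:
        return _draw_values(cfg, rng, n)
    # Reserved pools disjoint from the data pools: lowercase letters,
    # integers below the configured range, negative reals.
    if cfg.value_model == SYMBOLIC:
        letters = string.ascii_lowercase[: cfg.alphabet_size]
        return [letters[k] for k in rng.integers(0, cfg.alphabet_size, size=n)]
    if cfg.value_model == INTEGER:
        lo, hi = cfg.integer_range
        span = hi - lo + 1
        return [int(v) for v in rng.integers(lo - span, lo, size=n)]
    return [float(v) for v in rng.uniform(-2.0 * cfg.noise_amplitude - 1.0,
                                          -cfg.noise_amplitude - 1.0, size=n)]


def generate_pair(cfg: SyntheticConfig):
    """Generate one (S, T, planted) triple from *cfg*.

    ``planted`` is the strictly increasing :class:`MatchTrace` of rows copied
    from S into T; every planted pair agrees on variable 1 by construction.
    T has the same length as S; positions of T not claimed by a planted row
    are filled with replacement values.
    """
    rng = np.random.default_rng(cfg.seed)
    m, h = cfg.length, cfg.n_variables

    s_cols = [_draw_values(cfg, rng, m) for _ in range(h)]

    planted_flags = rng.random(m) < cfg.delta
    # Assign strictly increasing T positions with bounded jitter.
    pairs: list[tuple[int, int]] = []
    next_j = 0
    for i in range(m):
        if not planted_flags[i]:
            continue
        base = max(next_j, i - cfg.displacement)
        jitter = int(rng.integers(0, cfg.displacement + 1)) if cfg.displacement else 0
        j = max(base, min(i + jitter, m - 1))
        if j < next_j or j >= m:
            continue  # no room left for this planted row
        pairs.append((i, j))
        next_j = j + 1

    t_cols: list[list] = [[None] * m for _ in range(h)]
    for i, j in pairs:
        t_cols[0][j] = s_cols[0][i]
        for v in range(1, h):
            if rng.random() < cfg.delta2:
                t_cols[v][j] = s_cols[v][i]
            else:
                t_cols[v][j] = _draw_replacements(cfg, rng, 1)[0]
    for v in range(h):
        holes = [j for j in range(m) if t_cols[v][j] is None]
        fills = _draw_replacements(cfg, rng, len(holes))
        for j, val in zip(holes, fills):
            t_cols[v][j] = val

    names = tuple(f"var{v + 1}" for v in range(h))
    S = MultivariateSeries(
        "S", names, tuple(SymbolSequence(f"S:{n}", c) for n, c in zip(names, s_cols))
    )
    T = MultivariateSeries(
        "T", names, tuple(SymbolSequence(f"T:{n}", c) for n, c in zip(names, t_cols))
    )
    planted = MatchTrace(pairs, sigma=None, start_offset=0)
    return S, T, planted


#: The three benchmark protocol shapes: fixed length with growing
#: dimensionality, fixed dimensionality with growing length, and one large
#: univariate pair.
_SUITES = {
    "constant_length": dict(lengths=(500,), dims=tuple(range(1, 11))),
    "constant_dimension": dict(lengths=(100, 500, 1000, 5000), dims=(3,)),
    "large": dict(lengths=(12000,), dims=(1,)),
}


def generate_benchmark_suite(
    suite: str | dict,
    *,
    delta: float = 0.5,
    value_model: str = SYMBOLIC,
    seed: int = 0,
) -> list[SyntheticConfig]:
    """Deterministic list of configs covering one benchmark protocol.

    *suite* is one of ``"constant_length"`` (m = 500, h = 1..10),
    ``"constant_dimension"`` (h = 3, m in {100, 500, 1000, 5000}),
    ``"large"`` (one 12 000-row univariate pair), or a dict with explicit
    ``lengths`` and ``dims`` iterables.  Each config gets a distinct seed
    derived from *seed* so reruns are reproducible.
    """
    if isinstance(suite, str):
        try:
            desc = _SUITES[suite]
        except KeyError:
            raise GenerationError(
                f"unknown suite {suite!r}; available: {sorted(_SUITES)}"
            ) from None
    else:
        desc = suite
    configs = []
    k = 0
    for m in desc["lengths"]:
        for h in desc["dims"]:
            configs.append(
                SyntheticConfig(
                    length=int(m),
                    n_variables=int(h),
                    delta=delta,
                    value_model=value_model,
                    seed=(seed * 100003 + k) % (2**31),
                )
            )
            k += 1
    return configs
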