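"""Min-max normalization of series prior to similarity computation.

Sensor channels recorded on different scales are rescaled to [0, 1] with the
classic min-max transform ``(v - Tmin) / (Tmax - Tmin)``.  Because the
matching predicate is exact value equality by default, the *scope* of the
extremes matters: rescaling each series by its own extremes destroys
cross-series value identity, so the default pools the extremes over both
members of a pair ("joint-pair" scope).  Per-series scope remains available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MultivariateSeries, SwlcssError, SymbolSequence

__all__ = [
    "NormalizationError",
    "NormalizationReport",
    "normalize_minmax",
    "normalize_pair",
]

JOINT_PAIR = "joint-pair"
PER_SERIES = "per-series"


class NormalizationError(SwlcssError, ValueError):
    pass


@dataclass(frozen=True)
class NormalizationReport:
    """The (Tmin, Tmax) extremes used per variable, and the pooling scope."""

    extremes: dict[str, tuple[float, float]]
    scope: str

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.extremes.items():
            if lo > hi:
                raise ValueError(f"Tmin > Tmax for variable {name!r}: {lo} > {hi}")


def _check_numeric(values) -> np.ndarray:
    if len(values) == 0:
        raise NormalizationError("cannot normalize an empty sequence")
    arr = np.empty(len(values), dtype=float)
    for pos, v in enumerate(values):
        try:
            arr[pos] = float(v)
        except (TypeError, ValueError):
            raise NormalizationError(
                f"non-numeric value {v!r} at position {pos}"
            ) from None
    return arr


def _rescale(arr: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi == lo:
        # Constant channels occur in practice (saturated or stuck sensors);
        # map them to 0 rather than aborting the pipeline.
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def normalize_minmax(values, *, name: str = "values"):
    """Rescale a numeric sequence to [0, 1].

    Returns the rescaled values (a list of floats) and a
    :class:`NormalizationReport` carrying the extremes used.  A constant
    input maps to all zeros.

    Raises
    ------
    NormalizationError
        On empty input or a non-numeric value (the position is named).
    """
    arr = _check_numeric(values)
    lo, hi = float(arr.min()), float(arr.max())
    out = _rescale(arr, lo, hi)
    report = NormalizationReport({name: (lo, hi)}, scope=PER_SERIES)
    return list(out), report


def normalize_pair(
    S: MultivariateSeries,
    T: MultivariateSeries,
    scope: str = JOINT_PAIR,
):
    """Min-max normalize every variable of a series pair.

    With ``scope="joint-pair"`` (default) the extremes of each variable are
    pooled over both series, so equal raw values stay equal after rescaling.
    With ``scope="per-series"`` each series uses its own extremes.

    Returns ``(S', T', report)``.
    """
    if scope not in (JOINT_PAIR, PER_SERIES):
        raise NormalizationError(f"unknown scope {scope!r}")
    if set(S.variable_names) != set(T.variable_names):
        only_s = sorted(set(S.variable_names) - set(T.variable_names))
        only_t = sorted(set(T.variable_names) - set(S.variable_names))
        raise NormalizationError(
            f"variable sets differ: only in {S.identifier!r}: {only_s}; "
            f"only in {T.identifier!r}: {only_t}"
        )

    extremes: dict[str, tuple[float, float]] = {}
    new_cols: dict[str, list[SymbolSequence]] = {"S": [], "T": []}
    for name in S.variable_names:
        s_arr = _check_numeric(S.column(name).values)
        t_arr = _check_numeric(T.column(name).values)
        if scope == JOINT_PAIR:
            lo = float(min(s_arr.min(), t_arr.min()))
            hi = float(max(s_arr.max(), t_arr.max()))
            s_out, t_out = _rescale(s_arr, lo, hi), _rescale(t_arr, lo, hi)
            extremes[name] = (lo, hi)
        else:
            s_lo, s_hi = float(s_arr.min()), float(s_arr.max())
            t_lo, t_hi = float(t_arr.min()), float(t_arr.max())
            s_out, t_out = _rescale(s_arr, s_lo, s_hi), _rescale(t_arr, t_lo, t_hi)
            extremes[name] = (min(s_lo, t_lo), max(s_hi, t_hi))
        new_cols["S"].append(SymbolSequence(f"{S.identifier}:{name}", s_out.tolist()))
        new_cols["T"].append(SymbolSequence(f"{T.identifier}:{name}", t_out.tolist()))

    # T's columns follow S's variable order so downstream matching lines up.
    S_norm = MultivariateSeries(S.identifier, S.variable_names, tuple(new_cols["S"]), S.timestamps)
    T_norm = MultivariateSeries(T.identifier, S.variable_names, tuple(new_cols["T"]), T.timestamps)
    return S_norm, T_norm, NormalizationReport(extremes, scope=scope)
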