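"""Benchmark harness: windowed matcher vs the DP baseline on synthetic suites.

Reports *comparison counts* (equality-predicate evaluations) as the primary,
hardware-independent cost measure — the quantity the complexity bounds speak
about — alongside wall-clock timings, which are labelled hardware-dependent
and are not part of any stated guarantee.
"""

from __future__ import annotations

import time

import pandas as pd

from .dp_baseline import dp_lcs
from .multivariate_refine import mlcss
from .synthetic_data import SyntheticConfig, generate_pair

__all__ = ["run_benchmark", "bench_row"]


def bench_row(cfg: SyntheticConfig, sigma: int | None = 3, repeats: int = 1) -> dict:
    """Run both algorithms on one generated pair; return a report row.

    Comparison counts are deterministic given the config; the timing columns
    (``*_seconds``) depend on the host and are averaged over *repeats*.
    """
    S, T, planted = generate_pair(cfg)
    anchor = S.variable_names[0]

    t0 = time.perf_counter()
    for _ in range(repeats):
        sliding_res = mlcss(S, T, sigma=sigma)
    sliding_s = (time.perf_counter() - t0) / repeats

    t0 = time.perf_counter()
    for _ in range(repeats):
        dp_res = dp_lcs(S.column(anchor), T.column(anchor))
    dp_s = (time.perf_counter() - t0) / repeats

    return {
        "m": cfg.length,
        "h": cfg.n_variables,
        "delta": cfg.delta,
        "sigma": sigma,
        "seed": cfg.seed,
        "planted_length": len(planted),
        "passes": len(sliding_res.pass_lengths),
        "sliding_length": sliding_res.length,
        "dp_length": dp_res.length,
        "sliding_comparisons": sliding_res.comparisons,
        "dp_comparisons": dp_res.comparisons,
        "sliding_seconds": sliding_s,
        "dp_seconds": dp_s,
    }


def run_benchmark(
    configs: list[SyntheticConfig],
    sigma: int | None = 3,
    repeats: int = 1,
) -> pd.DataFrame:
    """Benchmark every config; one row per generated pair."""
    return pd.DataFrame([bench_row(c, sigma=sigma, repeats=repeats) for c in configs])


def plot_benchmark(report: pd.DataFrame, path, x: str = "m") -> None:
    """Comparison-count plot (sliding vs DP) against *x* (``m`` or ``h``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    grouped = report.groupby(x)[["sliding_comparisons", "dp_comparisons"]].mean()
    grouped.plot(ax=ax, marker="o")
    ax.set_xlabel(x)
    ax.set_ylabel("equality comparisons")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
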