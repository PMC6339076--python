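"""Shared fixtures: the bundled worked examples and an independent LCS oracle."""

from __future__ import annotations

from itertools import combinations

import pytest

from swlcss.datasets import load_example_strings, load_sensor_pair


def is_subsequence(sub, seq) -> bool:
    it = iter(seq)
    return all(any(x == y for y in it) for x in sub)


def brute_force_lcs_length(a, b) -> int:
    """Exhaustive LCS oracle: enumerate all subsequences of the shorter input.

    Exponential in the shorter length — usable up to ~15 elements.  Kept
    deliberately independent of the dynamic-programming implementation.
    """
    a, b = (tuple(a), tuple(b))
    short, other = (a, b) if len(a) <= len(b) else (b, a)
    for r in range(len(short), 0, -1):
        for picks in combinations(range(len(short)), r):
            if is_subsequence([short[k] for k in picks], other):
                return r
    return 0


@pytest.fixture(scope="session")
def sensor_pair():
    """The two bundled 10-row sensor series (temperature, humidity, soil_moisture)."""
    return load_sensor_pair()


@pytest.fixture(scope="session")
def example_strings():
    """The univariate worked-example pair (AEBACFDADB, CABDACDADB)."""
    return load_example_strings()
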