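"""The windowed greedy matcher: worked traces, bounds, instrumentation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swlcss.core import EqSpec
from swlcss.dp_baseline import dp_lcs
from swlcss.sliding import (
    WindowError,
    _Counter,
    _pass_naive,
    comparison_count,
    default_max_start,
    greedy_pass,
    sliding_lcss,
)

sequences = st.text(alphabet="ABCDEF", max_size=25)


class TestGreedyPass:
    def test_worked_example_trace(self, example_strings):
        s1, s2 = example_strings
        trace = greedy_pass(s1, s2, 0, 3)
        assert "".join(trace.matched_values(s1)) == "ABACDADB"
        assert [(p.i, p.j) for p in trace] == [
            (0, 1), (2, 2), (3, 4), (4, 5), (6, 6), (7, 7), (8, 8), (9, 9)
        ]

    def test_sensor_temperature_trace(self, sensor_pair):
        S, T = sensor_pair
        trace = greedy_pass(S.column("temperature"), T.column("temperature"), 0, 3)
        assert [(p.i, p.j) for p in trace] == [
            (0, 1), (2, 2), (3, 4), (4, 5), (6, 6), (7, 7), (8, 8), (9, 9)
        ]

    def test_empty_inputs_give_empty_trace(self):
        assert len(greedy_pass([], "ABC", 0, 3)) == 0
        assert len(greedy_pass("ABC", [], 0, 3)) == 0

    def test_greedy_consumes_late_position_blocking_rest(self):
        # A consumes T's last position; B, C, D have nothing left to match
        trace = greedy_pass("ABCD", "BCDA", 0, 4)
        assert [(p.i, p.j) for p in trace] == [(0, 3)]

    def test_frozen_pointer_on_failed_window(self):
        # after the second element fails its window, the third is tried from
        # the same pointer position (not advanced past the failed window)
        trace = greedy_pass([35, 39, 36], [37, 35, 36], 0, 3)
        assert [(p.i, p.j) for p in trace] == [(0, 1), (2, 2)]

    def test_invalid_sigma_rejected(self):
        with pytest.raises(WindowError):
            greedy_pass("AB", "AB", 0, 0)
        with pytest.raises(WindowError):
            greedy_pass("AB", "AB", 0, -2)

    @given(s=sequences, t=sequences, sigma=st.sampled_from([1, 2, 3, 5, None]),
           start=st.integers(0, 25))
    @settings(max_examples=300, derandomize=True)
    def test_indexed_path_equals_literal_scan(self, s, t, sigma, start):
        """The exact-mode fast path must replicate the literal window scan."""
        if start > len(s):
            start = len(s)
        c_fast, c_naive = _Counter(), _Counter()
        fast = greedy_pass(tuple(s), tuple(t), start, sigma, _counter=c_fast,
                           _occ=None)
        naive_pairs = _pass_naive(tuple(s), tuple(t), start, sigma, EqSpec(), c_naive)
        assert [(p.i, p.j) for p in fast] == naive_pairs
        assert c_fast.n == c_naive.n

    @given(s=sequences, t=sequences, sigma=st.sampled_from([1, 2, 3, None]),
           start=st.integers(0, 10))
    @settings(max_examples=200, derandomize=True)
    def test_window_discipline_and_monotonicity(self, s, t, sigma, start):
        start = min(start, len(s))
        trace = greedy_pass(s, t, start, sigma)
        for k in range(1, len(trace)):
            prev, cur = trace[k - 1], trace[k]
            assert cur.i > prev.i and cur.j > prev.j
            if sigma is not None:
                assert cur.j - (prev.j + 1) <= sigma - 1


class TestSlidingLcss:
    def test_sensor_temperature_length_and_start(self, sensor_pair):
        S, T = sensor_pair
        res = sliding_lcss(S.column("temperature"), T.column("temperature"),
                           sigma=3, max_start=5)
        assert res.length == 8
        assert res.best_start == 0

    def test_restart_finds_longer_trace(self):
        # pass a=0 matches only (0,3); pass a=1 matches B,C,D at T positions 0,1,2
        res = sliding_lcss("ABCD", "BCDA", sigma=4, max_start=2, early_stop=False)
        assert res.length == 3
        assert res.best_start == 1
        assert res.pass_lengths == [1, 3, 2]

    def test_identity_early_stop_single_pass(self):
        m = 30
        seq = list(range(m))
        res = sliding_lcss(seq, seq, sigma=3)
        assert res.length == m
        assert len(res.pass_lengths) == 1
        assert comparison_count(res) == m

    def test_empty_input(self):
        res = sliding_lcss([], [1, 2, 3], sigma=3)
        assert res.length == 0 and res.comparisons == 0

    def test_tie_breaking_prefers_earliest_start(self):
        # both a=0 and a=1 give length 1; the incumbent from a=0 is kept
        res = sliding_lcss("AA", "AB", sigma=2, max_start=1, early_stop=False)
        assert res.best_start == 0

    def test_early_stop_never_beats_exhaustive(self):
        rnd = random.Random(3)
        for _ in range(100):
            s = "".join(rnd.choice("ABC") for _ in range(rnd.randint(0, 20)))
            t = "".join(rnd.choice("ABC") for _ in range(rnd.randint(0, 20)))
            on = sliding_lcss(s, t, sigma=2, early_stop=True)
            off = sliding_lcss(s, t, sigma=2, early_stop=False)
            assert off.length >= on.length

    def test_auto_order_swaps_and_restores_coordinates(self):
        res = sliding_lcss("BCDA", "BCD", sigma=3, auto_order=True,
                           max_start=0)
        # scanned the shorter side, but pairs are reported as (S, T) positions
        for p in res.best_trace:
            assert "BCDA"[p.i] == "BCD"[p.j]

    def test_default_max_start_is_half_length(self):
        assert default_max_start(10) == 5
        assert default_max_start(11) == 5
        assert default_max_start(10, fraction=0.25) == 2


class TestBoundsAgainstOracle:
    def test_never_exceeds_dp_and_matches_on_identity(self):
        rnd = random.Random(2024)
        for _ in range(400):
            k = rnd.randint(2, 6)
            m, n = rnd.randint(0, 30), rnd.randint(0, 30)
            s = "".join(rnd.choice("ABCDEF"[:k]) for _ in range(m))
            t = "".join(rnd.choice("ABCDEF"[:k]) for _ in range(n))
            sigma = rnd.choice([1, 2, 3, None])
            res = sliding_lcss(s, t, sigma=sigma, early_stop=False)
            opt = dp_lcs(s, t).length
            assert res.length <= opt, (s, t, sigma)
            ident = sliding_lcss(s, s, sigma=rnd.choice([1, 2, 3, None]))
            assert ident.length == len(s)

    def test_window_widening_preserves_trace_feasibility(self):
        """A trace found under window sigma stays feasible under any wider
        window.  Note greedy *length* is not monotone in sigma: with
        S=DDABCCACCADA, T=BAAA the sigma=1 pass finds 4 pairs while the
        unbounded pass greedily wastes T's only B-free prefix and finds 3.
        """
        rnd = random.Random(11)
        for _ in range(150):
            s = "".join(rnd.choice("ABCD") for _ in range(rnd.randint(0, 25)))
            t = "".join(rnd.choice("ABCD") for _ in range(rnd.randint(0, 25)))
            for sigma in (1, 2, 3):
                trace = greedy_pass(s, t, 0, sigma)
                from swlcss.core import MatchTrace

                for wider in (sigma + 1, sigma + 5, None):
                    MatchTrace([(p.i, p.j) for p in trace], sigma=wider)

    def test_greedy_length_not_monotone_in_window_width(self):
        # the documented counterexample, pinned so the non-monotonicity
        # stays on record
        assert len(greedy_pass("DDABCCACCADA", "BAAA", 0, 1)) == 4
        assert len(greedy_pass("DDABCCACCADA", "BAAA", 0, None)) == 3


class TestComparisonCounts:
    def test_identical_sequences_cost_m_comparisons(self):
        for m in (1, 5, 40):
            seq = list(range(m))
            res = sliding_lcss(seq, seq, sigma=3)
            assert comparison_count(res) == m

    def test_worst_case_bound(self):
        rnd = random.Random(5)
        for _ in range(200):
            m = rnd.randint(0, 25)
            s = "".join(rnd.choice("AB") for _ in range(m))
            t = "".join(rnd.choice("AB") for _ in range(rnd.randint(0, 25)))
            sigma = rnd.choice([1, 2, 3])
            M = rnd.randint(0, m)
            res = sliding_lcss(s, t, sigma=sigma, max_start=M, early_stop=False)
            assert res.comparisons <= (M + 1) * max(m, 1) * sigma

    def test_empty_first_sequence_costs_nothing(self):
        assert sliding_lcss([], [1, 2], sigma=3).comparisons == 0
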