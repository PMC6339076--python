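# Methods

## Model and procedure

`swlcss` scores the similarity of two ordered data sets by the length of a
common subsequence found under a windowed greedy discipline, instead of the
exact optimum the quadratic dynamic-programming (DP) recurrence provides.
The design trades optimality for a comparison budget that is linear in the
input length per pass.

### The greedy windowed pass

For sequences `S` (length *m*) and `T` (length *n*), a single pass scans
`S[i]` for `i = a … m−1` while a trace pointer `TP` (initially 0) marks the
next unconsumed position of `T`:

* candidate window for `S[i]`: positions `TP … min(TP+σ−1, n−1)`;
* first equal position `j` ⇒ record `(i, j)`, set `TP = j+1`;
* no equal position ⇒ `TP` unchanged, advance `i`.

The frozen-pointer rule on failure matters: a non-matching element of `S`
costs at most σ comparisons and does not discard any of `T`. Matched pairs
are therefore strictly increasing in both coordinates, and consecutive pairs
satisfy the window discipline `j_{k+1} − (j_k + 1) ≤ σ − 1` (at most σ
candidate positions were opened past the previous match). These two
invariants are enforced by the `MatchTrace` type at construction.

### Suffix restarts and early stop

A single greedy pass is sensitive to its first matches, so the pass is
repeated with the leading element of `S` removed each time: start offsets
`a = 0 … M`, with `M = ⌊m·f⌋` and the fraction `f = 0.5` by default
(configurable, `max_start_fraction`). A later pass replaces the incumbent
only when strictly longer, so the earliest best start wins ties and the
result is deterministic. By default the restart loop also terminates as soon
as the incumbent length reaches `M` (`early_stop`); on highly similar inputs
the first pass already does this and total cost approaches one comparison
per element. The early stop can forfeit longer traces reachable from later
starts, so it is exposed as a flag; the exhaustive setting
(`max_start = m`, `early_stop=False`) is what the recovery experiments use.

### Multivariate refinement

A multivariate record is scored anchor-then-filter: the windowed matcher
runs on one anchor variable (first column by default, overridable); the
resulting index-pair trace is then filtered by each remaining variable,
keeping exactly the pairs whose values are also equal on that variable.
Because the filter is a pure intersection over the pair set, it is
idempotent, monotone non-increasing, and independent of variable order
(verified by property tests); per-variable stage lengths are kept for
diagnostics. The anchor choice, by contrast, is material: anchoring on a
different variable explores a different trace. The final index is
`length / min(m, n)`, in [0, 1].

### Equality predicate

All matching goes through one predicate: exact equality by default (the
regime of integer-valued sensor readings and symbol data), or absolute
tolerance `|a−b| ≤ ε` per variable as an opt-in for continuous data —
especially after min-max normalization, which maps values into [0, 1].
Tolerance equality is not transitive; the DP baseline accepts it but flags
its result as an uncertified optimum in that mode. Comparing a symbol with
a number raises a typed error rather than returning unequal.

### Normalization

Min-max rescaling `(v − Tmin)/(Tmax − Tmin)` is available as a preprocessing
step. The default scope pools the extremes of each variable over *both*
series of a pair, because per-series extremes destroy cross-series value
identity — fatal under exact matching. Per-series scope exists behind a
flag; constant channels (Tmax = Tmin) map to all zeros rather than erroring,
since stuck sensors occur in practice. Normalization is off by default in
the CLI: the bundled worked examples match raw values.

## Algorithmic properties worth knowing

* **Lower bound, not optimum.** The greedy length never exceeds the DP
  length (tested over thousands of random pairs) and attains it on identical
  inputs; its gap on adversarial inputs can be large.
* **Not monotone in σ.** Widening the window can *shorten* the result: for
  `S = DDABCCACCADA`, `T = BAAA`, the σ = 1 pass finds 4 pairs while the
  unbounded pass finds 3, because the unbounded window lets an early `A` of
  `S` consume a position of `T` that a later element needed. The pinned test
  keeps this counterexample on record. σ should be chosen from the data's
  variation scale, not maximized.
* **Collapse on long mismatch runs.** If `T` contains a run of ≥ σ
  consecutive positions that match nothing in the remainder of `S`, the
  frozen pointer can never cross it and the pass ends effectively there.
  This is the method's worst regime — dissimilar inputs — and the reason the
  early stop may not fire, pushing cost toward the `(M+1)·m·σ` worst case.
* **Comparison counts as the cost measure.** Every run reports the exact
  number of equality-predicate evaluations. Identical length-m inputs cost
  exactly m comparisons in one pass; every run respects
  `(M+1)·m·σ`. Wall-clock times in the bench harness are labelled
  hardware-dependent and carry no guarantee.

## Implementation notes

* The exact-equality path resolves each window with a binary search over a
  precomputed per-value occurrence index of `T`, returning the identical
  trace and identical comparison count as the literal scan (cross-checked
  property-wise against the naive scan, which remains the fallback and the
  tolerance-mode path). NaN values are excluded from the index — they never
  match — and mixed symbol/number inputs take the literal path so the
  incomparable-kinds error surfaces where the scan would raise it.
* The DP baseline materializes its (m+1)×(n+1) table only on request;
  the default path keeps two rolling rows' worth of state plus the table
  needed for traceback. Traceback ties break diagonal-first, then up, then
  left, giving one canonical optimal trace for reproducibility.
* Coordinates are 0-based everywhere; traces always store *original*
  `S` coordinates even when a pass started at an offset, because refinement
  must index the other variables at those positions.

## Synthetic data generator

The generator emulates the matching structure of paired sensor records: `S`
is drawn from a value model; `T` copies each row of `S` with probability δ
(a *planted* match, optionally jittered by at most `d` positions while
keeping the planted trace strictly increasing) and otherwise takes a
replacement value. Replacements come from a pool disjoint from the data
values (lowercase letters / out-of-range numbers), so in this default
regime non-planted positions cannot match the anchor variable and the
planted trace is sharp ground truth; `honest_noise=True` draws replacements
from the data pool instead, allowing accidental matches. Additional
variables of a planted row are copied with probability δ₂ (default 1), so
δ₂ < 1 manufactures rows that survive anchor matching but fail refinement —
the 82-vs-81 situation of the worked example.

The default value model is continuous uniform (`real`): values are almost
surely distinct, which is what makes δ *identifiable* — the recovered
length/m of the exhaustive unbounded matcher then tracks δ closely. With a
small symbolic alphabet (the DNA-like `symbolic` model, alphabet 4),
unrelated sequences already share long common subsequences and elements of
`S` steal planted positions of equal value, so recovery systematically
undershoots δ; that model is provided for sequence-analysis tests, not for
calibration. What the generator does **not** emulate: autocorrelation,
trends, or daily cycles of real microclimate data, measurement drift, or
missing rows — passing recovery tests shows the matcher recovers planted
order-preserving agreement, not that it understands weather.

Benchmark suites cover three protocol shapes: fixed length (m = 500) with
dimensionality h = 1…10, fixed dimensionality (h = 3) with
m ∈ {100, 500, 1000, 5000}, and one large univariate pair (m = 12 000).

## Problem sizes in the shipped tests

The test suite runs the oracle-bound sweep at m, n ≤ 30 (1000+ pairs), the
brute-force DP cross-check at m, n ≤ 12 (220 pairs), refinement algebra on
500 random traces, and parameter recovery at m = 500 with 200 seeds per
δ ∈ {0.2, 0.5, 0.8} in the acceptance test (a scaled m = 200, 25-seed sweep
runs in the unit suite). The full suite completes in well under a minute on
a laptop-class core.

## Known limitations

* The greedy result depends on which argument is scanned (`S`); the
  `auto_order` flag can canonicalize by scanning the shorter input, off by
  default to preserve the asymmetric definition.
* No gap-state alignment, no DTW-style time warping, no timestamp-aware
  matching: timestamps are labels only.
* The similarity index normalizes by `min(m, n)`; other normalizations
  (mean length, max length) are not provided.
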