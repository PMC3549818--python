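# Methods

## Model and procedure

Input is an m × n real matrix: m series (rows) observed at n equally
spaced time points. The pipeline is fixed-order:

1. **Interpolation.** Missing entries are filled from the nearest observed
   temporal neighbours: interior gaps by linear interpolation between the
   nearest observed value on each side (for a single missing point this is
   exactly the average of the two nearest time points), boundary runs by
   copying the single nearest observed value. The "two nearest points"
   rule is undefined at series ends, so boundary fill is a documented
   package choice. A row with fewer than two observed values is an error
   naming the row. The operation is idempotent.
2. **Zero filtering.** Rows whose fraction of *exact* zeros exceeds 25%
   (configurable) are dropped. Zeros are counted in raw interpolated
   values, not standardized ones, because the rule is a statement about
   raw counts (e.g. taxon absences). The comparison is strict, so a row at
   exactly the threshold is retained. Whether the original analyses
   interpolated before or after filtering is not documented anywhere we
   could rely on; this package fixes interpolate → filter → standardize.
3. **Standardization.** Each row is centred and scaled by its *population*
   (divisor n) standard deviation. The population divisor is chosen so
   that a series' squared values sum to n, which makes self-similarity
   exactly 1 and, via Cauchy–Schwarz on any window, caps |LSA| at 1.
   Constant rows are an error naming the row.

## The statistic

For standardized X, Y and lag bound D, the dynamic program runs one
reset-at-zero running sum per diagonal (fixed shift d = i − j, |d| ≤ D)
over the aligned products and over their negation — O((2D+1)·n) time,
O(1) extra memory per diagonal, rather than materializing n × n arrays;
the results are identical because each diagonal is independent. P̂ and N̂
are the maxima of the two runs; the statistic is
sign(P̂ − N̂)·max(P̂, N̂)/n.

* **Tie P̂ = N̂**: reported with positive sign and magnitude P̂/n. A
  literal sign(0) reading would zero out the magnitude, destroying the
  "report the strongest association" semantics.
* **Reported location**: the method itself does not define *where* the
  best window is, only its value. As an extension the package reports one
  maximizing (lag, window) pair: lags are scanned −D..D and a new maximum
  is recorded only on strict improvement, so the first maximizing lag in
  scan order wins. Within a diagonal the dynamic program resolves exact
  float ties by scan position (earliest window end), while the exhaustive
  oracle scans windows by start then end; on exact ties the two routes can
  therefore name different (equally optimal) windows, but never different
  statistics. Windows are half-open, 0-based, in coordinates of the first
  series.
* **Oracle**: `lsa_pair_oracle` enumerates every shift and every
  contiguous window with plain sums (O(D·n²)). Reset-at-zero running
  maxima coincide with maximum-subarray sums, so the two routes agree
  exactly; the suite asserts agreement to 1e-12 on 1,000 random instances.

The all-pairs path runs the same recursion inside a numba-compiled kernel
(cross-checked against `lsa_pair` in the tests). Pairs are enumerated in a
canonical order (series sorted by label, index pairs i < j), chunked, and
written into preallocated output slices; thread count therefore cannot
affect the output, which is asserted byte-for-byte in the tests.

## Significance

With Φ the standard normal CDF and G(t) = 2Φ(t) − 1 the CDF of |Z|, two
bound variants are implemented (`pvalue_bound`):

* `table` (default): min(1, 2n·(1 − Φ(x√(n/Var)))). This form reproduces
  the published reference grid of bound values at all three tabulated
  lengths (n = 30, 50, 100) at printed precision, which is why it is the
  default.
* `theorem`: min(1, 2·(n² − (n−D−1)(n−D))·(1 − G(x√(n/Var)))), the literal
  union bound over all in-window index pairs. At D = 0 it is exactly twice
  the table form and it is pointwise at least as conservative for any
  D ≥ 0.

Numerics: 1 − G(t) is evaluated as 2·Φ̄(t) via the normal survival
function; the naive 1 − (2Φ(t) − 1) saturates to 0 beyond t ≈ 8 and would
erase the deep tail. Var(X₁Y₁) is 1 after standardization and is exposed
as a parameter for un-standardized use.

The bound is asymptotic in n. Below n = 30 the package warns (a
`UserWarning`, not an error) and still answers: the bound only becomes
more conservative for short series, so short-n use risks lost power, not
false positives.

One printed cell of the reference grid (threshold 0.99 at n = 100) is
inconsistent with the bound's own monotonicity in both arguments — every
neighbouring cell is "< 0.001" while it prints "0.001" — and is treated as
"< 0.001" by the reproduction test.

The permutation comparator shuffles the time indices of one series
(`shuffle_one`, default — shuffling one side already breaks all
cross-dependence; shuffling both adds cost without changing the null) and
returns the add-one estimator (1 + exceedances)/(1 + permutations), which
cannot report zero. Per-pair seeds are derived by counter from the run
seed, so results are independent of evaluation order. Bonferroni divides
α by the actual test count C(m, 2) = m(m−1)/2, not m².

Significance in the edge table is a conjunction: p-bound ≤ corrected α
**and** |LSA| ≥ the optional magnitude threshold (default 0, i.e.
disabled). Published network figures use both gates (e.g. α = 0.001 with
|LSA| ≥ 0.85), so both are user parameters rather than constants.

## Defaults

| parameter | default | rationale |
|---|---|---|
| D (max lag, time steps) | 3 | benchmark setting of the reference analyses |
| α | 0.001 | level used in the reference network figures |
| correction | bonferroni over C(m,2) | actual number of tests |
| bound variant | table | reproduces the published grid |
| lsa_threshold | 0 | magnitude gate off unless asked for |
| perms | 0 | the analytic bound replaces permutation |
| max zero fraction | 0.25 | the raw-count sparsity filter |

## Synthetic data

The generators define the test conditions for every other module:

* `null_matrix`: m × n iid draws, uniform on [0, 1) (support is arbitrary
  since standardization removes location and scale) or standard normal,
  optionally with planted exact zeros and missing flags for the
  preprocessing stages. The large null screens use 1,000 × 30 and
  1,000 × 100 uniform matrices — scaled-down stand-ins for the
  million-series screens the method targets; pair count grows as C(m, 2),
  so the statistical character (a huge family of independent tests under
  a conservative bound) is preserved at tractable size.
* `lagged_pair`: series b tracks series a at a fixed delay with tunable
  coupling and additive noise, iid noise outside the overlap — the planted
  ground truth for recovery tests.
* `empirical_null_tail`: vectorized |LSA| over thousands of simulated
  null pairs, the Monte-Carlo yardstick for the bound's conservativeness.
  Standard normal by default (the asymptotic regime the bound is derived
  in); uniform is available and the conservativeness property holds for
  both.

What the generators do *not* emulate: compositionality and
autocorrelation of real abundance data, seasonal or periodic structure,
heavy-tailed counts. Passing tests therefore demonstrate correctness of
the statistic, the bound and the pipeline under the stated null and
planted-signal models — not robustness to every failure mode of real
data (the bound's independence assumption, in particular, is an
approximation for autocorrelated series).

## Problem sizes used in the test suite

Oracle cross-checks run at n ≤ 12, D ≤ 3 (1,000 instances), where
exhaustive enumeration is exact and cheap. Conservativeness uses 10,000
simulated pairs at n ∈ {50, 100}, D = 0, with a 3-binomial-SE allowance
at each grid threshold. The false-positive screen uses 1,000 × 30
(499,500 pairs, Bonferroni at α = 0.05); the clique check runs ten seeded
1,000 × 100 screens at uncorrected α = 0.05 and asserts no clique of size
≥ 4 in at least 9 of 10 (clique detection via networkx on the significant
subgraph). These sizes were chosen so the whole suite completes in well
under a minute on one core while keeping every assertion sharp.

## Known limitations

* The location report (best lag/window) is a package extension; other
  implementations may legitimately report a different, equally optimal
  window.
* Only Bonferroni correction is provided; no FDR procedures.
* Unevenly spaced or missing-at-analysis-time observations are not
  modelled; interpolation is the only missing-data path.
* The rank-normal transform used by earlier LSA implementations is
  deliberately out of scope: the bound requires only finite variance, so
  data are analyzed untransformed after standardization.
* LSA is not symmetric under time reversal; no such symmetry is claimed
  or tested.
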