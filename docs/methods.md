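# Methods

## Model and procedure

Given two time courses `a` (length t_a) and `b` (length t_b), a warp
path is an ordered sequence of index pairs starting at (1, 1), ending at
(t_a, t_b), moving only by unit steps right, down, or diagonally. The
DTW distance is the minimum over all such paths of the accumulated local
cost, computed by the dynamic program

    D(i, j) = d(i, j) + min(D(i-1, j), D(i, j-1), D(i-1, j-1)),  D(1, 1) = d(1, 1)

with local cost `d(i, j) = |a_i - b_j|` by default. This unweighted
recursion (the `fewer_delays` step pattern, classically "symmetric1")
makes longer paths pay more cells, biasing the optimum towards
alignments with fewer inserted delays. A `symmetric_weighted`
("symmetric2") variant charges diagonal steps `2·d(i,j)` so that a
path's total weight is independent of its slant; it is offered because
general-purpose DTW libraries often default to it, and which pattern a
given historical analysis used is rarely recorded. A squared local
distance is available. Both patterns yield symmetric distances.

No global window constraint and no open-begin/open-end alignment are
supported: the series screened here are short (t ≈ 9–20), and every
alignment is boundary-complete. Time-point values are carried through to
plots but do not enter the cost — warping operates on index order, and
no cost for non-uniform spacing is defined.

Traceback tie-breaking is deterministic: diagonal first, then the
(i−1, j) predecessor, then (i, j−1). Ties never affect the distance,
only which of several co-optimal paths is reported.

### Scaling

Entities and endpoints live on incomparable scales (log-expression vs
percent of cells in G1, say), so by default each series is autoscaled:
centred and divided by its sample (t−1) standard deviation. Constant
series cannot be autoscaled and are dropped with a warning. Mean-centring
only, or no scaling, can be selected per run.

### Significance

Each permutation draw independently shuffles the order of the entity's
values and, separately, the endpoint's values (uniformly over the t!
orderings of each), realigns, and records the distance; B = 1000 draws
by default. The p-value is the add-one estimator
`(1 + #{null ≤ observed}) / (B + 1)`: it can never be exactly zero
(which would break BH) and counts ties against significance, which is
conservative. BH step-up correction is applied within each endpoint's
family of n entities (per-endpoint results are reported per-endpoint
directory, so families are per endpoint; no correction across
endpoints). For the matched screen the family is the label intersection.

Randomness is reproducible and order-independent: the endpoint screen
derives one stream per (endpoint index, entity index) from the run seed;
the matched screen keys streams by a CRC-32 of the entity label and
assigns the two per-series streams by comparing the series' own values,
so swapping the input matrices reproduces identical p-values.

### Pre-filter

A row enters the screen only if it is complete (no missing values) and
at least one time point deviates from the row's own mean by ≥ 2 sample
standard deviations (threshold configurable). Mean and SD are taken
across the row's time points: the input matrix is assumed already
replicate-averaged, and no replicate-level variance is available to the
tool — this across-time-points reading is an interpretive choice, and
the main one this module makes. The criterion is scale-equivariant and
idempotent; constant rows always fail it.

### Correlation arm

For the DTW-vs-correlation comparison, each entity is tested for
Pearson correlation with the endpoint across the t time points
(two-sided p from the t-distribution), BH-corrected at the same q
threshold as the DTW arm so the comparison is like-for-like, and
counted as a positive-correlation hit only if r > 0. Overlap summaries
report integer percentages (rounded half away from zero), with a dash
when a denominator is zero.

## Synthetic benchmark

The generator emulates paired experiments where the second measurement
of each entity is a delayed, noisier copy of the first:

* **Smoothness.** Each mother series is a cubic spline through
  `max(4, ceil(length/5))` iid standard-normal knots at evenly spaced
  positions, evaluated at integer positions. Real expression time
  courses are smooth; smoothness is also precisely what makes
  permutation p-values anti-conservative, so the benchmark must have it.
* **Shift.** The mother is `length + max_shift` points long; the first
  experiment's row is its first `length` points, the second's starts
  `shift` points later. Windowing a longer mother (rather than rolling)
  avoids wrap-around artefacts. Shifts 0–9 on length-20 series by
  default.
* **Noise.** Iid Gaussian with sd = `noise_level × 0.1 ×` the mother's
  own sd, levels 1–10, i.e. 10%–100% of signal sd. Whether the original
  design's lowest level was exactly zero is unknown; level 1 here is
  nonzero, and a zero-corruption configuration (`noise_step=0`,
  `max_shift=0`) is available for controls.
* **Decoys.** Pairs of independent smooth series sharing a label, so the
  screen compares unrelated curves with realistic autocorrelation.
* **Balance.** (shift, noise) cells are filled round-robin; counts not
  divisible by the 100 cells are truncated to the largest balanced count.

Scoring asks two questions per truly matched pair: was it flagged at
q ≤ FDR (detection), and does the returned warp path equal, pair for
pair, the intended path — hold B's first point through A's un-shared
prefix, run diagonally, hold A's last point (exact-path recovery).
Co-optimal alternatives count as failures; "exact" means exact.

### What the benchmark does and does not show

Detection behaves as expected: essentially complete at zero shift even
under heavy noise, decaying with shift, with decoy detection far above
the nominal FDR — the smoothness caveat made measurable. Exact-path
recovery is a much harsher metric: under even 10% noise, literal
path equality is rare at length 20, because smooth neighbours are cheap
to warp onto; and for large shifts the intended minimal-step path is
often not the DTW optimum at all (a slanted path through the smooth
curve can be genuinely cheaper), so recovery decays quickly in both
noise and shift. Noiseless pairs with shifts ≤ 2 recover the intended
path ≥ 95% of the time. The practical reading: hit lists are more
robust than the inferred delay patterns, and experiments expecting
shifts larger than ~2 sampling intervals should sample more densely.

The generator does not emulate: replicate structure, heteroscedastic or
correlated noise, missing values, batch effects, or non-smooth (e.g.
impulse) dynamics. Passing benchmarks therefore demonstrates correctness
of the machinery and qualitative power patterns, not performance on any
particular real platform.

## Problem sizes

Tests and the acceptance script run the benchmark at 400 matched pairs +
40 decoys with B = 199 draws, calibration screens at n = 500 entities
(t = 9, B = 199), and oracle comparisons on series of length ≤ 5 where
exhaustive path enumeration is feasible; these sizes give stable
percentages (cells of 4 pairs each) while keeping a full run in seconds.
The full-scale design (10,000 + 1,000 pairs, B = 1000) is the
generator's default and runs in a few minutes.

## Numerical choices and edge cases

* Sample (t−1) SD everywhere (scaling, filter) for consistency.
* Permutation ties count as hits (≤, not <): conservative.
* Traceback uses `np.isclose` when matching a cell to its predecessor;
  distances themselves are exact dynamic-programming sums.
* p-values from a numerically perfect correlation (p = 0 from scipy) are
  clamped to the smallest positive float so BH input stays in (0, 1].
* Duplicate row labels are rejected at matrix construction (pairing
  would be ambiguous); an empty label intersection in the matched screen
  is an error, an empty filter result only a warning.
* Matrix TSV round trips are bit-exact (`%.17g` on write, round-trip
  float parsing on read).

## Known limitations

* Permutation nulls assume exchangeable time points under the null;
  autocorrelated (smooth) series violate this and inflate significance.
  The q threshold is exposed (use 0.01 for long smooth series); no
  analytic correction is attempted, and block permutations are out of
  scope.
* No windowed, derivative, open-ended, or multi-dimensional DTW.
* The correlation arm is Pearson-only (no Spearman, partial, or lagged
  cross-correlation).
* p-value resolution is bounded by 1/(B+1); with the B = 199 fast mode,
  the smallest attainable p is 0.005.
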