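# Methods

## The detection problem

Given n observations of one feature from one animal (n ≈ 11–55 in the
motivating recordings, n ≥ 34 for the analyses this toolkit targets), decide
whether the values are best described by a continuous distribution
(k_est = 1) or by k ≥ 2 discrete modes. The decision must control the
false-positive rate explicitly: at these sample sizes, naive cluster-number
estimators and discontinuity scores flag continuous data as modular at
unacceptable and sometimes guaranteed rates.

## Within-cluster dispersion

For a candidate k, the data are partitioned to minimize the pooled
within-cluster sum of squares. In one dimension the optimum is contiguous
on the sorted values, so an O(k·n²) dynamic program finds the exact global
optimum (`modgap.cluster`). Exactness matters: restart-based k-means adds
stochasticity to W_k that would contaminate the Monte-Carlo calibration of
thresholds. Ties between equal-cost partitions are broken toward the
leftmost boundary set, making every quantity deterministic given the data.
W_k is defined through the pairwise form Σ_r D_r/(2 n_r) (D_r the sum of
ordered pairwise squared distances within cluster r), which is algebraically
the block WCSS; the test suite asserts the identity to 1e-9 relative.

Two implementations coexist: a scalar DP with backtracking (returns the
partition) and a row-batched DP used by the simulation machinery, JIT
compiled with numba when available and falling back to vectorized numpy
otherwise. The two are cross-checked in the tests.

## The gap statistic and its calibrated decision rule

Gap(k) compares log W_k with its mean over B reference datasets drawn
uniformly over [min(x), max(x)] with the same n. The uniform-over-range
reference is the natural continuous null in 1-D (the principal-axis variant
of the reference box coincides with the range), and makes every statistic
invariant under affine maps of the data. The spread term
s_k = sd_b(log W*_kb)·√(1 + 1/B) is recorded with each curve.

The classical stopping rule is replaced by a calibrated one:

- evidence e_k = Gap(k) − Gap(1) for k = 2..kmax;
- candidate k* = argmax_k (e_k − T_k), ties toward smaller k;
- k_est = k* if e_{k*} > T_{k*}, else 1.

The thresholds T_k are set on `null_reps` simulated uniform datasets so
that the *full* rule selects each specific k with probability
`alpha_per_k`. Because the rule couples the k's through the argmax, the
thresholds cannot be independent marginal quantiles; they are found by
coordinate descent on order-statistic ranks of the null evidence sample
(raise or lower each T_k by one rank until every per-k selection count
equals round(alpha_per_k·null_reps); in practice this converges in two or
three passes). A held-out null sample then verifies each per-k rate within
exact binomial bounds. Calibration that cannot reach its target (e.g.
alpha_per_k·null_reps < 1) raises a calibration error rather than
returning a silently mis-calibrated table.

The exact functional form of a threshold rule is a genuine design choice —
only the calibration target (per-k false-positive rate 0.01) is fixed by
the problem statement. The additive evidence e_k = Gap(k) − Gap(1) was
adopted because it measures clustering *relative to the one-cluster
account* of the same dataset, couples directly to the per-k calibration
target, and needs no extra tuning constants. With kmax = 8 and
alpha_per_k = 0.01 the overall null rate is ≈ 0.07, and the benchmark
power at 5 SD mode separation, n = 40, is ≈ 0.8.

### Defaults and their meaning

| parameter | default | meaning |
|---|---|---|
| kmax | 8 | largest number of modes entertained (upper bound on plausible grid-module counts) |
| alpha_per_k | 0.01 | per-k false-positive rate on continuous data |
| B | 100 | uniform reference draws per gap curve |
| null_reps | 1000 | simulated null datasets used for calibration |
| min_n | 34 | per-animal sample size at which 5-SD modularity is detected in ≥ half of datasets |
| extent_um | 2500 | dorsoventral sampling extent for location generators, µm |

Thresholds are calibrated per exact n; a table may be reused within ±10%
of its n (with a warning), otherwise recalibration is the safe path even
though the overall null rate is empirically insensitive to n.

Degenerate inputs are policy, not errors, inside batch sweeps: constant
values give a degenerate gap curve and k_est = 1 (no evidence of multiple
modes); n < 4 is rejected for single-dataset calls.

## Discontinuity and discreteness scores

The literature scores are reconstructed from their verbal descriptions:
*discontinuity* is the mean squared adjacent gap of the z-scored sorted
values; *discreteness* is the coefficient of variation of equal-width
histogram bin counts (default 10 bins). lnDS is log(score(values) /
score(locations)); the inherited rule flags modularity when lnDS > 0.
Exact constant factors of the original scores are not recoverable from the
available descriptions, but every property used downstream — identity zero,
affine invariance, the even-location pathology, ≈ half-positive under
uniform locations, and the matched-α power ordering — is insensitive to
those constants.

With evenly spaced locations the denominator score is (asymptotically) the
minimum over same-range location sets, so lnDS > 0 with probability 1 for
continuous data: the raw rule is structurally guaranteed to produce false
positives under even sampling. The calibrated variant replaces 0 by the
(1 − α) null quantile of lnDS under the stated location scheme, estimated
by simulation, restoring a chosen null rate; at matched α the calibrated
gap statistic remains the more sensitive detector on the 5-SD benchmark.

## Synthetic data

The generators emulate per-animal feature panels: uniform nulls (the
continuous hypothesis), homogeneous-σ Gaussian mixtures with adjacent-mean
separation expressed in component SDs (the modular hypothesis; the
benchmark alternative is k = 2, σ = 1, separation 5 SD, n = 40),
grid-module-like specs with geometric means (ratio 1.42 by default,
echoing adjacent grid-scale ratios), σ ∝ mean, and equal or geometrically
declining weights, and location schemes (even grid or uniform draws over
0–2500 µm). Mixture sampling composes component choice then a normal draw
so that true labels are retained for validation.

What the generators do *not* emulate: location-dependence of the feature
within an animal (values and locations are independent under both
hypotheses here), inter-animal variance structure, measurement error
models, and non-Gaussian mode shapes. Passing tests therefore establish
calibration and power properties under idealized sampling, not the
validity of any particular biological conclusion from real recordings.

## Binomial inference

Detection counts are summarized with exact Clopper–Pearson intervals
(beta-quantile form, closed forms at x = 0 and x = n) and two-sided exact
binomial tests under the minimum-likelihood convention (sum of the
probabilities of all outcomes no more likely than the observed one), both
via scipy and both verified against enumeration oracles for n ≤ 30. The
expected null proportion p0 is always an explicit argument — the natural
choice is the calibrated overall false-positive rate (≈ 0.07 at defaults),
and the expected modular proportion is the calibrated p_detect at the
panel's n and a stated separation (computed, never hard-coded).

## Numerical choices and limitations

- All randomness flows from integer seeds through numpy Generators;
  batch routes draw uniforms once and scale them, so evidence is exactly
  affine-equivariant across transformed copies of a dataset.
- log W_k floors W_k at 1e-300 before the log; only degenerate or
  duplicate-heavy inputs approach that regime, and those are routed to
  k_est = 1 upstream.
- Monte-Carlo problem sizes: calibration uses 1000 nulls with B = 100 by
  default; the packaged validation suite runs held-out checks at 400–1000
  replicates, sizes at which exact binomial bounds around the targeted
  rates are decisive.
- The per-k calibration is exact only at the calibration n; the ±10%
  reuse window is a documented convenience, not a guarantee.
- Power comparisons between detectors are made at matched *overall* α;
  matching per-k rates instead would require a per-k notion of detection
  for lnDS, which does not exist (it is a binary score).
- At small separations (≲ 2 SD) a mixture is effectively unimodal and its
  detection rate can fall below the uniform-null rate, because the uniform
  reference penalizes light-tailed unimodal data less than clustered data;
  this is a property of any uniform-reference gap statistic.
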