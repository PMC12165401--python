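# Methods

This note records the model conventions, parameter defaults, numerical
choices and known limitations of entrospect. It documents decisions, not
results: every empirical statement here is computed by the test suite or
`scripts/acceptance.py`.

## Estimation model

A discrete probability-based complexity measure is estimated in four
orthogonal stages: data → outcome space (symbolization) → counts →
probabilities estimator → PMF → information measure + measure estimator.
Compatibility between stages is decided by component metadata only: a
space is either count-based (integer window counts) or weight-based
(real-valued weights), and an estimator either accepts any measure
("generic") or only Shannon. Weighted spaces (weighted and
amplitude-aware ordinal patterns, power spectrum) admit only
relative-amount probabilities and plug-in estimation, mirroring the
count/non-count split of the design.

## Outcome-space conventions

- **Indexing/binning.** Time indices are 0-based. Bins are half-open
  `[lo, hi)` with the global maximum assigned to the top bin, so no
  orphan outcome exists at the boundary.
- **Ordinal patterns.** A window maps to the permutation that sorts it
  ascending, computed with a stable argsort: *equal values keep their
  temporal order*. The permutation is ranked by its Lehmer code (an exact
  bijection onto `0..m!-1`, verified exhaustively for m ≤ 6); the
  identity permutation (strictly increasing window) has rank 0.
- **Dispersion patterns.** Values map to categories
  `clamp(ceil(c·Φ(x)), 1, c)` where Φ is the normal CDF with the series'
  empirical mean and *uncorrected* (population) standard deviation. The
  ceil-based mapping is the common dispersion-entropy convention;
  round-based dialects exist and give slightly different categories.
- **Weighted ordinal patterns** weight each window by its (population)
  variance — the weighted-permutation-entropy convention. **Amplitude-
  aware** patterns blend mean absolute amplitude and mean absolute
  adjacent difference with factor A (default 0.5).
- **Sequential pair distances** use the Chebyshev metric by default and
  bin the distances of *consecutive* embedding-vector pairs into
  equal-width bins over the observed range.
- **Sparse joint histogram.** D-dimensional bin indices are computed per
  point and aggregated with a hash/unique pass, so memory scales with the
  number of occupied bins (≤ N), never with the product of per-dimension
  bin counts. Equality with a dense histogram is oracle-tested in ≤ 3-D.
- **Spatial encodings** slide a stencil (arbitrary offset template, first
  offset (0,0)) over a 2-D array and apply the ordinal or dispersion
  encoding to the pixel vector in stencil order; dispersion categories
  are derived from the whole image's empirical distribution.

## Probabilities estimators

Defaults: add-constant c = 1 (Laplace), Bayesian regularization a = 1
(symmetric Dirichlet), shrinkage target = uniform with the data-driven
intensity λ = clamp((1 − Σp̂²)/((N−1)·Σ(t−p̂)²), 0, 1), λ := 1 when the
denominator vanishes. The λ formula is evaluated on whatever support the
PMF is built over; full support is used whenever |Ω| is finite and the
caller asks for it. Information estimators consume observed-support PMFs
by default — with the convention 0·log 0 := 0 the Shannon value is
identical either way — while missing-outcome statistics and normalization
always use the full support.

## Information measures

Default logarithm base is 2 and overridable for the log-based measures;
internally everything is computed in nats with a single conversion.
Tsallis, Curado, Kaniadakis and the Tsallis extropy are base-free.
Singular parameters dispatch to the Shannon limit when |q−1| (or |κ|)
< 1e−12 rather than erroring.

Two definitions deserve comment because the literature gives several
q-extropy dialects. We use

- Rényi extropy  J_q = log(Σ(1−pᵢ)^q − (K−2)) / (1−q),
- Tsallis extropy J_q = (K − 1 − Σ(1−pᵢ)^q) / (q−1),

both chosen because they reduce exactly to the Shannon extropy as q → 1
and vanish on degenerate PMFs. The stretched-exponential
(Anteneodo–Plastino) entropy is computed through the upper incomplete
gamma function in nats, with the base entering as a unit conversion, so
η = 1 recovers Shannon in the requested base exactly.

`measure_maximum` returns the value at the uniform PMF (the maximizer for
all supported definitions — property-tested against random PMFs), with
closed forms for Shannon, Rényi and Tsallis. Fluctuation complexity is
zero at the uniform PMF and therefore has no normalizing maximum; asking
for one raises.

## Discrete estimators

- Miller–Madow adds (K_obs − 1)/(2N) in the measure's log base, with
  K_obs the number of *observed* outcomes (standard convention).
- Horvitz–Thompson and Chao–Shen use maximum-likelihood p̂ inside the
  correction. Chao–Shen's coverage C = 1 − f₁/N is defined as 1 when
  every outcome is a singleton (f₁ = N).
- The jackknife groups the N leave-one-out terms by outcome (removing any
  of the n_k copies of outcome k yields the same configuration), giving
  O(K) measure evaluations; equality with the naive O(N) recomputation is
  oracle-tested. For non-Shannon measures the same leave-one-out scheme is
  applied to the measure's plug-in value.
- `information_normalized` divides by the measure maximum at
  K = |Ω| and clamps to [0, 1]; bias-corrected estimators can otherwise
  overshoot the theoretical maximum marginally.

The in-scope catalog enumerates to 39 PMF routes (9 count-based spaces ×
4 estimators + 3 weighted spaces) and 23 discrete-measure routes (10
definitions × 2 generic + 3 Shannon-specific) — a deliberate subset of
the larger catalogs shipped by mature implementations of this design.

## Differential estimators

Spacing estimators operate on order statistics with boundary clamping;
the default window is w = ⌊√N⌋. Neighbor estimators use a KD-tree
(equality with brute-force all-pairs distances is tested at N ≤ 500) and
the Euclidean metric with unit-ball volume V_d = π^{d/2}/Γ(d/2+1);
Chebyshev (V_d = 2^d) is optional. The Kraskov convention
H = ψ(N) − ψ(k) + log V_d + (d/N)·Σ log ρ_{i,k} is anchored by recovery
of the Gaussian closed form ½ln(2πe) within 0.05 nats at N = 10⁴, the
scale/translation laws, and the exact identity Kozachenko–Leonenko =
Kraskov(k=1). Leonenko–Prozanto–Savani estimates Σp^q with the k-NN
construction (requires k + 1 − q > 0) and returns Rényi or Tsallis
entropy; at q = 1 it uses the explicit Shannon-limit formula
log(N−1) − ψ(k) + log V_d + (d/N)Σ log ρ. Duplicate points with zero
neighbor distance are dropped from the log-sum with a warning; ties in
spacing estimators raise with a jitter hint. Output is in nats, converted
at the API boundary.

## Complexity estimators

- Sample/approximate entropy scale the default tolerance r = 0.2·σ by
  the standard deviation of the *original* series, before embedding.
  SampEn restricts both dimensions to the same template index set and
  excludes self-matches; a zero match count returns +∞ with a structured
  warning rather than erroring, so surrogate loops survive degenerate
  draws. Both use Chebyshev balls via KD-tree, oracle-tested against
  all-pairs counting.
- LZ76 counts exhaustive production-parsing phrases (Kaspar–Schuster
  scan); real series are binarized at the median.
- Statistical complexity C = Q_J · H_norm with Q_J the Jensen–Shannon
  divergence from the uniform PMF normalized by the point-mass/uniform
  divergence; any normalizable measure definition can replace Shannon in
  H_norm.
- Bubble entropy differences *unnormalized* Rényi-2 entropies (natural
  log) of swap-count distributions at m and m+1 and divides by
  log((m+1)/(m−1)); a normalized-dialect variant exists in the
  literature.
- The multiscale wrapper offers the two classical schemes —
  non-overlapping coarse-graining (window means, length ⌊N/s⌋) and a
  moving average — and composes with every complexity estimator and every
  discrete pipeline; scale 1 is the identity.

## Synthetic signals and the surrogate test

Generator defaults define the study conditions of the tests: logistic map
r = 4, x0 = 0.4, 1000 transient points; AR(2) φ₁ = 0.9, φ₂ = −0.2
(stationarity enforced via the characteristic roots), σ = 1, 500-point
burn-in; Lorenz-96 D = 8, F = 8, RK4 with dt = 0.05, 1000 transient
steps, coordinate 0 observed, deterministic 0.01 perturbation off the
fixed point. "10% white noise" means additive Gaussian noise with
standard deviation 0.1·σ(signal). All randomness flows through an
explicit integer seed or numpy Generator; identical seeds give identical
output bit-for-bit.

Surrogates: `shuffle` permutes the values (iid null, value distribution
preserved exactly); `fourier_phase` randomizes spectral phases with DC
and Nyquist terms pinned, preserving the periodogram to rounding error
(linear null). The missing-outcome surrogate test reports the percentage
of missing outcomes for the data and for K surrogates and flags the
series when the data value falls outside the surrogate [min, max] range.
The qualitative reproduction in the tests uses 5000-point series, 30
shuffle surrogates, dispersion patterns (c = 3, m = 3) for the noisy
logistic map and ordinal patterns (m = 4) for the AR(2) control, over 20
seeds — sizes chosen so the whole suite runs comfortably on one CPU.

The generators emulate the canonical benchmark systems, not real
physiological or financial data: no missing samples, no nonstationarity,
no heavy-tailed measurement noise. Passing tests demonstrate correctness
of the estimators under these controlled conditions, not robustness to
real-world artifacts.

## Numerical details and limitations

- PMFs are renormalized exactly after estimation; the unit-sum invariant
  is asserted to 1e−12 across the full estimator × space grid.
- The RK4 integration oracle compares full vs halved step size over a
  1-time-unit horizon; over longer horizons chaotic error amplification
  dominates the step-size error and the comparison is uninformative.
- Ordinal tie-breaking by temporal order means heavily quantized data
  (many exact ties) bias ordinal statistics toward the identity pattern;
  dispersion or value-binning spaces are more appropriate there.
- Data-dependent outcome spaces (unique elements, data-derived bin edges,
  power spectrum) support neither missing-outcome counts nor
  normalization, by construction.
- The CLI exposes the library surface; batch orchestration across many
  files is left to the shell.
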