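# Methods

## Estimator conventions

**Index population.** A delay vector at dimension `m` and its extension at
`m+1` are both evaluated over the same template indices
`i = 1 … N − m·τ` (univariate) or `i = 1 … N − max_k(m_k τ_k)`
(multivariate, all schemes). Matched populations make the extended match
probability structurally no larger than the un-extended one, so SE ≥ 0
always, and remove the small-sample bias that mismatched ranges introduce.

**Matching.** A pair of vectors matches when their Chebyshev (maximum-norm)
distance is ≤ r, inclusive, with self-pairs excluded. Match probabilities
are reported as (matching unordered pairs)/(all unordered pairs); the
normalization cancels in the entropy ratio except for the full scheme,
whose pooled set is P times larger than the un-extended set. Counting is
exact (integer) and delegated to a k-d tree; an O(n²) double loop gives
the same integers on every input.

**Standardization.** Zero mean, unit *population* standard deviation
(divide by N). `r` is therefore a fraction of each channel's SD.
Multivariate entry points standardize each channel internally; the
univariate `sample_entropy` operates on the data as given so that raw and
standardized analyses are both possible.

**Multiscale operation.** The series is standardized once; each scale
factor ε replaces it by non-overlapping window means of length ε (trailing
remainder dropped) with `r` held fixed in units of the original SD and no
re-standardization. This is what makes the white-noise profile decay with
scale while 1/f noise stays flat.

**Undefined values.** If no pair matches at either dimension the entropy is
undefined: functions return `nan` and emit `UndefinedEntropyWarning`;
downstream statistics (per-scale t-tests, surrogate summaries, sleep
separation) drop flagged values, adjusting degrees of freedom, and warn.

**Full-scheme pair rule.** In the pooled (full) extension, a pair is
excluded only when both origin index and subspace coincide — literal
self-pairs; cross-subspace pairs sharing an origin index are counted.
Note the full scheme is *not* invariant to channel relabelling: its
cross-subspace distances compare elements of different channels, so the
concatenation order matters. This is one of the alignment inconsistencies
that motivates the proposed scheme (which, like the naive scheme, is
permutation-symmetric); the test suite documents the asymmetry rather than
hiding it.

## The analytic model of the proposed scheme

For bivariate data white in time with cross-channel correlation ρ
(`M=[1,1]`, `τ=[1,1]`), the per-channel sample differences of a vector
pair, `(D₁, D₂)`, are zero-mean bivariate normal with variance 2 and
correlation ρ. The two extra coordinates of the proposed extension involve
the next time step, independent of the first under whiteness, so the
extended match probability factorizes, `Φ_ext = Φ_unext²`, giving

    mSE(ρ, r) = −ln P(|D₁| ≤ r, |D₂| ≤ r).

The rectangle probability is evaluated by adaptive Gauss quadrature of the
conditional-normal integrand to ≤ 1e−8 absolute error. Endpoints:
`−2 ln erf(r/2)` at ρ=0 and `−ln erf(r/2)` at |ρ|=1; the function is
strictly decreasing on ρ ∈ [0, 1]. Negative ρ is accepted (the rectangle
is symmetric, so mSE(−ρ) = mSE(ρ)). Simulated proposed-scheme entropy on
generated correlated WGN agrees with the model within Monte-Carlo error at
N = 10⁴ (tested at ρ ∈ {0, 0.3, 0.6, 0.95} × r ∈ {0.15, 0.4}).

## Synthetic generators (what they emulate, and what they don't)

All generators are pure functions of parameters and seed
(`numpy.random.default_rng`).

- **Correlated WGN** — channels `z₁` and `ρ z₁ + √(1−ρ²) z₂` (the Cholesky
  factor of the 2×2 correlation matrix).
- **Power-law noise** — rFFT amplitude shaping of complex Gaussian noise,
  amplitude ∝ f^(β/2), zero DC, then standardized. β = 0 white, −1 pink,
  −2 Brownian; the binned log-log periodogram slope recovers β within
  ±0.2.
- **Synchronized-regularity pair** — each channel is
  `√λ·v + √(1−λ)·u` with `v` WGN and `u` 1/f noise, all components
  mutually independent; `λ_i ∈ {0,1}` is the sign of a power-law noise
  `z(β)` (ties at exactly zero map to 0, a measure-zero rule fixed for
  determinism). Synchronized runs share one λ sequence across channels;
  independent runs draw two. The channels have identical marginals in both
  cases and no linear cross-correlation — the *only* cross-channel
  structure is the timing of regularity changes, which is what a
  multivariate entropy must detect and a correlation estimator cannot.
  Components are standardized before mixing and the mixture standardized
  once more, so λ interpolates between unit-variance processes.
- **Alternating protocol** — emulates paced breathing imprinting
  regularity on heart-rate variability: 30 s blocks alternate between a
  0.25 Hz sinusoid (15 cycles/min) plus 20 % white noise (low SE, the
  entrained state) and pure white noise (high SE, unconstrained). Trial 2
  starts in the opposite block phase and its pattern is delayed by `lag`
  seconds. The trials share no amplitude coupling, only regularity timing.
  The lagged-mSE profile attains its minimum at `lag + block_period`
  (patterns coincide at lags ≡ lag + block_period mod 2·block_period, and
  the truncated overlap contains the largest share of paired low-entropy
  samples at that candidate when trial 1 starts low); the generator
  returns this ground truth.
- **Sleep-like recording** — wake blocks: independent broadband noise
  (~20 µV SD); slow-wave blocks: a shared 1/f source plus small
  independent noise (~25 µV SD, cross-correlation ≈ 0.8); short 150 µV
  bursts exercise artifact rejection. It reproduces the
  regularity-plus-coupling contrast between states, *not* EEG morphology,
  spindles, or annotation noise — so passing tests show the pipeline
  mechanics and the direction of the scheme comparison, not clinical
  performance.

## Pipelines

**R-R profiling.** R-peak times → successive differences attached at the
later peak → cubic-spline resampling on a 0.25 s grid → zero-phase (
forward-backward) 4th-order Butterworth high-pass at 0.1 Hz. The lag
profile pairs trial 1 with trial 2 advanced by L over their truncated
overlap (no wrapping; lags with < 50 % overlap skipped), standardizes per
channel, and computes proposed-scheme mSE (r = 0.4). The profile spectrum
is the rFFT magnitude of the mean-removed profile; the dominant
synchronization frequency must exceed 4× the median non-zero-bin magnitude
to count as a peak (for ~10²-bin spectra of structureless profiles the
Rayleigh-distributed maximum is typically only 2.5–3× the median).
Because the minimum of the profile sits in a triangular basin whose
per-grid-step slope (≈ 0.006 entropy units) is below the single-lag
estimator noise (≈ 0.01–0.03), `LagProfile.min_lag` optionally smooths the
profile with a centered 2 s moving average before locating the vertex;
the raw argmin can wander a few 0.25 s steps.

**Sleep separation.** 2.5 s windows, 50 % overlap, majority label per
window (exact tie → "other"), rejection of windows with any |sample| >
100 µV, per-segment channel standardization (so r = 0.4 acts relative to
local variability), mv-SE per segment at `M=[1,1]`, `τ=[1,1]`, and the
Bhattacharyya distance between the Gaussian-summarized wake and slow-wave
SE distributions, reported per extension scheme.

**Surrogates.** Random alignment = circular rotation of every channel
after the first by an independent uniform offset in {1, …, N−1} (length
and marginals preserved exactly; only ≤ m·τ boundary-spanning delay
vectors differ, so per-channel SE is preserved to ~10⁻²). The pooled
two-sample t-test per scale uses the pooled-variance form (df =
n_a + n_b − 2; 38 for the default 20 + 20 replicates), two-tailed,
α = 0.05, uncorrected across scales.

## Problem sizes and statistical design of the tests

The validation suite uses the benchmark sizes of the study design:
N = 15000 for the mixing benchmark (20 replicates per scenario, scales
1–4), N = 5000 for the correlation and surrogate comparisons (10 seeds),
N = 10⁴ for closed-form checks, 50 random instances with N ≤ 100 for
exact oracle equality. Monte-Carlo assertions compare a fixed-seed batch
mean against its own replicate standard error (3×), not against hand-set
tolerances.

One benchmark claim is deliberately tested directionally rather than by a
per-run significance threshold: the proposed scheme's scale-1 separation
of synchronized vs independent mixing is consistently ordered (synchronized
lower) but small relative to replicate scatter (two-sample p at 20+20
replicates ranged 0.39–0.003 across batches), so the test asserts the
ordering of group means. The full scheme's scale-4 separation — the
quantity the acceptance script reports — is significant (p < 0.02) in
every batch tried.

## Known limitations

- Delay τ is configurable but all reference experiments use τ = 1; the
  effect of larger delays on the entropy is not studied here.
- The analytic model assumes whiteness in time; for temporally correlated
  channels only simulation applies.
- The sleep and breathing pipelines are validated on synthetic stand-ins;
  absolute separation values on real polysomnography or ECG recordings
  depend on the recordings themselves and are not reproduced here.
- Composite/refined multiscale variants and embedding-dimension selection
  are out of scope.
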