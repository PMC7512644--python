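# mvsampen

Multivariate sample entropy (mSE) and its multiscale extension (mMSE) for
regularity, complexity and *synchronization* analysis of multichannel
time series — heart-rate variability, EEG, or any other real-valued
recordings.

## The problem and the algorithm

Sample entropy estimates the regularity of a series `x_1 … x_N` as

    SE(m, r, τ) = −ln( Φ_{m+1}(r) / Φ_m(r) )

where `Φ_m(r)` is the probability that two delay vectors
`X_m(i) = [x_i, x_{i+τ}, …, x_{i+(m−1)τ}]` lie within a Chebyshev distance
`r` of each other (self-matches excluded). Stochastic signals score high,
regular signals low; computing SE on coarse-grained copies of the series
(non-overlapping window means at scale factor ε — multiscale entropy)
distinguishes genuinely complex signals (1/f noise: entropy sustained
across scales) from structureless ones (white noise: entropy decays).

For a P-channel series the un-extended delay vectors concatenate
per-channel embeddings (embedding vector `M = [m_1 … m_P]`, lags
`τ = [τ_1 … τ_P]`). The schemes differ in the `m → m+1` extension step:

- **naive** — P subspaces, each extending one channel; matches counted per
  subspace and averaged. Blind to cross-channel coupling.
- **full** (the existing method) — the same subspaces, but distances taken
  across *all* subspaces pooled. Sensitive to coupling, but it compares
  elements of different channels against each other and reads increasing
  correlation as *increasing* entropy.
- **proposed** — every channel extended simultaneously in a single aligned
  vector, so distances are only ever taken between corresponding channels.
  Correlation and synchronized regularity both *lower* the entropy,
  consistent with the intuition that coupling means order.

For standardized bivariate white Gaussian noise with cross-correlation ρ
(at `M=[1,1]`, `τ=[1,1]`) the proposed scheme admits a closed-form model:
`mSE = −ln P(|D₁| ≤ r, |D₂| ≤ r)` with `(D₁, D₂)` zero-mean bivariate
normal, variance 2, correlation ρ — implemented by quadrature in
`analytic_proposed_mse_wgn` and strictly decreasing in ρ.

The package also ships the synthetic benchmarks that exercise these
properties (correlated WGN, power-law noise, the synchronized-regularity
mixing model, an alternating paced-breathing protocol, a labelled
sleep-like recording), random-alignment surrogates, per-scale pooled
t-tests, the Bhattacharyya separation distance, and two application
pipelines (lagged-mSE synchronization profiling of R-R interval trials;
wake vs slow-wave-sleep separation of segmented 2-channel recordings).

## Worked example

```python
import mvsampen as mv

X = mv.gen_correlated_wgn(5000, 0.9, seed=42)          # bivariate, rho=0.9
res = mv.MultiscaleEntropy(X, r=0.15, scheme="proposed", max_scale=5).fit()
print(res.summary())
```

```
Multiscale Sample Entropy
=========================================
kind:            multivariate (proposed scheme)
n_samples:       5000
channels:        2
m:               (1, 1)
tau:             (1, 1)
r:               0.15 (per-channel SD units)
-----------------------------------------
 scale       entropy
     1        4.1181
     2        3.5144
     3        3.0830
     4        2.7938
     5        2.6251
```

The scale-1 value 4.118 sits close to the analytic model
`mv.analytic_proposed_mse_wgn(0.9, 0.15) = 4.1281`, and well below the
uncoupled value `−2 ln erf(r/2) ≈ 4.94`: correlation between the channels
reads as increased cross-channel regularity. A random-alignment surrogate
test makes the coupling explicit — rotating channel 2 destroys it:

```python
print(res.surrogate_test(n_surrogates=10, seed=0).to_frame().round(4))
```

```
 scale  original  surrogate_mean  surrogate_sd
     1    4.1181          4.9313        0.0474
     2    3.5144          4.2653        0.0324
     3    3.0830          3.8529        0.0480
     4    2.7938          3.5551        0.0324
     5    2.6251          3.3428        0.0665
```

The original entropy lies far below the surrogate distribution at every
scale: the two channels share dynamics that vanish under misalignment.

A command-line interface mirrors the library
(`mvsampen mse|mmse|generate|benchmark-correlation|benchmark-syncreg|
surrogate-test|rsa-profile|sleep-separation`), reading and writing plain
CSV with `#`-comment metadata; run `mvsampen --help`.

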