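# Methods

## Problem and model

The task is binary classification of interictal intracranial-EEG
segments: does a segment originate from the epileptogenic zone (ES) or
not (NES)? The model combines a feature-driven branch and an
end-to-end branch and fuses their learned representations.

**Classical branch.** A segment is split into `n_timesteps = 4`
contiguous, non-overlapping sub-windows. Each sub-window yields a
70-dimensional feature vector (families below). The 4×70 sequence is
encoded by a 2-layer bidirectional LSTM (hidden size 64 per direction,
inter-layer dropout 0.1) whose per-timestep outputs `e_t ∈ R^128` are
pooled by additive attention: `u_t = tanh(W_w e_t + b_w)`,
`h_t = softmax_t(u_tᵀ u_w)`, `v = Σ_t h_t e_t`. The attention
parameters are trainable with score dimension 128 (equal to `e_t`;
the original description leaves the dimension open). `v` is the 128-d
classical embedding; a 256-unit ReLU layer with dropout 0.3 and one
sigmoid unit produce the branch probability.

**Deep branch.** The preprocessed single-channel trace (dual channels
are averaged, each trace z-scored) passes four blocks of
convolution → batch normalization → ReLU → max-pool(2) with
(in, out, kernel, stride, padding) = (1,16,3,1,1), (16,32,3,1,1),
(32,32,3,1,1), (32,32,2,1,1). Because the flattened map length depends
on the input length, an adaptive max-pool to 4 positions per channel
produces a fixed 32×4 = 128-d automatic embedding for any input; the
head is 128 → 64 → 1 sigmoid. ReLU and pool size 2 are our choices
where the source description is silent.

**Fusion.** Both branches are trained first, then frozen (their
weights are bit-identical before and after fusion training; this is
asserted in tests). Embeddings are concatenated classical-first into a
256-d fusion feature, standardized with train-set statistics, and
classified by an MLP 256 → 64 → 1 under binary cross-entropy with
probability clipping at 1e-7. Ties at p = 0.5 are called ES
(sensitivity-favouring). A joint fine-tuning mode is deliberately not
enabled by default. All three stages use Adam at learning rate 1e-3
(batch sizes 20 / 32 / 32, epochs configurable), keeping the
best-on-validation weights.

All networks run on the in-package numpy reverse-mode autodiff engine
(`ieegfuse.nn`); gradients of every primitive are verified against
central finite differences in the test suite.

## Preprocessing

* Zero-phase Butterworth band-pass, default 0.5–80 Hz. Default order
  is 6: a 4th-order zero-phase filter leaves ~10% of a 100 Hz tone at
  the 80 Hz edge, while order 6 reaches ~3%, which matches the
  out-of-band rejection the pipeline is specified to deliver. A
  clinical wide band (0.5–256 Hz) can be configured upstream; the
  sub-80 Hz analysis path is identical for all dialects.
* Resampling to `analysis_fs = 160 Hz` before the wavelet transform.
  Rationale: a dyadic 4-level DWT at 160 Hz lands exactly on the
  nominal sub-band table A4: 0.5–5, D4: 5–10, D3: 10–20, D2: 20–40,
  D1: 40–80 Hz; at native 512/2048 Hz no dyadic scheme matches that
  table. Polyphase resampling (rational approximation of the rate
  ratio, denominator ≤ 1000).
* 4-level `db4` DWT with periodized boundaries, so sub-band energies
  sum to the signal energy exactly (orthogonality); the listed
  coefficient sets A4, D4..D1 correspond to a 4-level transform even
  where the source text says "five-level". Dual-channel segments are
  decomposed per channel and averaged coefficient-wise per level.
* Window segmentation drops partial trailing windows. Counting
  conventions: non-overlapping `n = floor(dur/S)`; overlapping
  `m = fix((dur−S)/slidsize)`. We implement the printed `fix` count
  exactly and do not add the extra window at t = 0 that a `+1`
  convention would give.

## Features (70 per timestep)

Time domain (12): mean; population variance; coefficient of variation
σ/μ (0 when μ = 0); skewness with the (N−1) inner normalizer as
printed; excess kurtosis; IQR via the (N+1)p order-statistic rule;
Hjorth activity/mobility/complexity; zero-crossing count; Hurst
exponent via single-scale rescaled range on the cumulative-deviation
profile, `H = log(R/S)/log N`; DFA slope over dyadic windows 4..N/4
with linear detrending.

Frequency domain (6), computed on the wide-band signal at its native
rate (before the 80 Hz low-pass) so the 60–140 Hz band exists whenever
the sampling rate allows: sub-band power ratio P(60–140)/P(0–60)
(0 with a warning if Nyquist ≤ 60 Hz); mean Welch PSD and mean ASD
over the full band (the source table names the transforms but not the
scalar reduction — the mean is our documented choice); spectral
centroid; spectral kurtosis; spectral entropy normalized by the log of
the number of frequency bins (∈ [0, 1], ≈ 1 for white noise). Welch
window 1 s.

Time–frequency (2): EMD (classic sifting, cubic-spline envelopes,
Huang SD stopping criterion 0.2, ≤ 5 IMFs) followed by fuzzy entropy
`FE = ln O^m − ln O^{m+1}` of each IMF with m = 2,
r = 0.2 × SD(IMF), fuzzy membership `exp(−(d/r)²)` with
baseline-removed templates; the features are the first and third
quartiles of the IMF fuzzy entropies (linear-interpolation quantiles).

Nonlinear (10 × 5 sub-bands = 50): Kozachenko–Leonenko (Kraskov)
k-NN differential entropy with k = 4; Rényi entropy (α = 2) and
Shannon entropy of the normalized squared-coefficient distribution
(for equal-magnitude coefficients both equal ln N); permutation
entropy (order 3, base-2 logs, normalized by log₂ 3!); sample entropy
(m = 2, r = 0.2σ, Chebyshev distance, self-matches excluded, the same
template count for both lengths); energy Σx²; SVD entropy of a
delay-embedding (dimension 10, delay 1, normalized by log of the
number of singular values); Petrosian, Katz and Higuchi
(k_max = 10) fractal dimensions.

Degenerate inputs (zero-energy or constant arrays, empty match counts)
return 0 rather than NaN/inf so the networks always see finite values.
The manifest `ieegfuse.features.FEATURE_NAMES` fixes the order.

## Synthetic data

Both classes share a 1/f^β Gaussian background (β = 1, synthesized in
the frequency domain, unit SD). ES segments superimpose Ricker
(Mexican-hat) spike-wave transients (rate 1.5/s, amplitude 5× the
background SD, ±30% jitter, random polarity) and Gaussian-windowed
sinusoidal HFO bursts (80–150 Hz at the default 512 Hz rate, 1/s,
1.5× SD); NES segments are background only. Inter-event intervals are
jittered uniformly. All randomness flows from one seeded generator per
call, so identical configurations are bitwise-reproducible. Sessions
draw per-lead seeds from a root generator; the first `n_epi` leads use
the ES process. At sampling rates too low for the default HFO band the
band is clamped below Nyquist.

What this emulates — and what it does not: the generator reproduces
the *statistical contrast* used clinically (spikes, fast oscillatory
bursts, the resulting entropy/spectral differences) and the lead
imbalance of SEEG, but not physiological seizure dynamics, electrode
geometry, artifacts, or inter-patient variability. Passing the
end-to-end tests therefore shows that the pipeline can learn a
realistic class contrast from its specified inputs, not that it
reaches any particular accuracy on real recordings.

## Problem sizes and defaults

The default synthetic segment matches the dual-channel public dialect
(20 s at 512 Hz = 10,240 points). The end-to-end study used by the
tests and the acceptance script runs 400 segments per class of 10 s
(4 timesteps of 2.5 s; 1,600 analysis samples per trace at 160 Hz),
with 25% held out for validation, stratified by label, and 30 / 12 /
40 epochs for the classical / CNN / fusion stages — sizes chosen so a
scientist can re-run the whole study on a laptop CPU in minutes. The
reproducibility check reruns a 12-per-class configuration twice and
requires identical metrics.

## Numerical choices and edge cases

* Softmax in the attention subtracts the max score (constant shift)
  for stability; weights sum to 1 at machine precision.
* Training minimizes BCE on logits in the numerically stable
  `max(z,0) − zy + log(1+e^{−|z|})` form; the public
  `fusion.bce_loss` clips probabilities at 1e-7.
* k-NN distances in the Kraskov estimator are clamped at 1e-12 before
  the log (duplicate coefficient values).
* EDF output quantizes to 16 bits over the per-channel data range;
  round-trip error is bounded by (max−min)/65535. The writer requires
  integer sampling rates and whole-second durations (true of all
  synthetic sessions).
* Metric reports round half-up to 2 decimals only at format time; all
  aggregation is done in full precision.

## Known limitations

* The 60–140 Hz power-ratio numerator is empty for the 173.61 Hz
  single-channel dialect (Nyquist ≈ 86.8 Hz); the feature degrades to
  band power above 60 Hz there, and to 0 with a warning below 60 Hz.
* The R/S Hurst estimator is single-scale; multi-scale regression
  variants give slightly different values on short windows.
* The EMD sifting uses endpoint anchoring for envelopes; other
  boundary rules (mirror extension) change IMFs near the edges.
* Sample entropy returns the 0 sentinel when no template matches
  survive at m+1, which occurs on very short sub-bands (A4/D4 of a
  sub-second timestep).
* Training is full-precision CPU numpy; it is sized for hundreds, not
  tens of thousands, of segments.
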