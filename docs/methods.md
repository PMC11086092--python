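# Methods

## Overview

`eegcomplexity` implements a multiband non-linear analysis of awake
resting-state EEG: each subject's recording is band-passed (0.1–45 Hz),
downsampled to 256 Hz, trimmed to its first minute and split into
twelve 5 s windows; every window and channel is decomposed into the
five canonical sub-bands with a biorthogonal-3.5 discrete wavelet
filter bank; ten non-linear descriptors are computed per band-limited
window; windows are averaged to one value per (subject, channel, band,
feature); for each two-group contrast the values are z-scored per cell
and fed to a 16-model classifier suite under leave-one-out
cross-validation (LOOCV), yielding an accuracy grid over channels ×
bands × classifiers with per-band mean/max summaries and a best
classifier per contrast.

Because no public recordings accompany this kind of study design, the
package ships a fully seeded synthetic cohort generator that defines
the test-bed on which every stage is validated.

## Preprocessing

* **Band-pass.** Zero-phase (forward–backward) filtering: an order-4
  Butterworth high-pass at 0.1 Hz plus a Chebyshev-II low-pass designed
  by `cheb2ord(45, 50, 0.5 dB, 15 dB)` (order 7). The sharp low-pass
  side is deliberate: a low-order Butterworth corner at 45 Hz leaves
  most of a 50 Hz mains tone standing (|H|² ≈ 0.30 even applied twice),
  whereas the Chebyshev-II design passes 10 Hz at 1.00 and 50 Hz at
  |H|² ≈ 0.003 while keeping the passband flat. The DC component is
  removed explicitly after filtering. Padding of 2048 samples keeps the
  0.1 Hz corner's edge transients out of the analysed segment.
* **Resampling.** Polyphase anti-aliased decimation (e.g. 2048 → 256 Hz).
  One minute at 256 Hz is exactly 15,360 samples, which windows evenly
  into 12 × 1280; the pipeline uses that exact count.
* **Re-referencing** to named channels (e.g. linked mastoids) is an
  optional hook and a no-op for synthetic data, which has no montage.
  Bad-channel interpolation and ICA artifact rejection are
  human-in-the-loop steps and out of scope; the loader instead refuses
  non-finite data.

## Sub-band decomposition

A 5-level critically decimated octave filter bank (`bior3.5`, symmetric
extension) maps branches to bands at fs = 256 Hz: gamma ← D2
(32–64 Hz; content above 45 Hz is already removed upstream), beta ← D3,
alpha ← D4, theta ← D5, delta ← A5. D1 (64–128 Hz) is discarded.

Features are computed on single-branch *reconstructions*, not on the
decimated coefficients: a 1280-sample window leaves only ~50 level-5
coefficients — far too short for attractor-based estimators — and
reconstruction keeps all five band series length-comparable.

Two physical limits of this prescribed bank are worth knowing:

* Perfect reconstruction holds to ~1e-12: the five band branches plus
  D1 sum back to the input exactly.
* Band selectivity is soft. Octave halfband filters roll off slowly, so
  tones near band edges share energy with the neighbouring branch: a
  tone at 40 Hz places ~73% of its reconstructed energy in the gamma
  branch (a quarter leaks into beta across the 32 Hz split), and a
  10 Hz tone ~70% in alpha. Band-centre tones (2, 6, 12, 24 Hz) reach
  86–99.7%. These are properties of the bior3.5 filters, not of the
  implementation, and they bound what any selectivity test can demand.

## Non-linear features

Per band-limited window series (N = 1280, Ts = 1/256 s):

* **Embedding.** Delay τ = first genuine local minimum of the auto
  mutual information (16-bin histogram estimator; a dip must undercut
  both neighbours by 0.1% of the lag-1 AMI so that the flat plateaus of
  periodic signals do not trigger spurious minima), falling back to the
  autocorrelation zero crossing, capped at N/10. Dimension m = smallest
  m ≤ 10 whose false-nearest-neighbour fraction (distance-ratio
  tolerance 15, Theiler exclusion τ) drops below 1%; noise-like series
  return the cap with a flag. States x_i = [x(i), x(i+τ), …,
  x(i+(m−1)τ)], M = N − (m−1)τ.
* **Correlation dimension (D2).** Grassberger–Procaccia: exact pair
  counting of C(r) on a 20-point log-spaced radius grid spanning the
  0.2th–15th percentile of pairwise state distances, Theiler window
  m·τ; D2 is the log–log slope over the automatically selected scaling
  region (longest contiguous sub-range whose point-to-point slopes vary
  by < 15% around their mean). The grid leans deliberately toward small
  radii because D2 is defined in the r → 0 limit; at mid-range radii
  C(r) already saturates toward the attractor's macroscopic extent and
  the slope is biased low (on the Lorenz attractor that bias is ≈ −0.4).
  Attractors beyond 1024 states are strided down deterministically
  before counting; radius percentiles are probed from ≤ 256 states.
* **Largest Lyapunov exponent (LLE).** Rosenstein-style: each reference
  state (≤ 256, strided) is paired with its nearest neighbour outside
  the Theiler window; the mean log divergence over k = 0…40 follow-up
  steps is fitted over its automatically selected linear region and the
  slope divided by Ts (units: 1/s). Validated against the closed form
  ln 2 of the r = 4 logistic map.
* **Approximate entropy.** ApEn(m=2, r=0.2·SD), self-matches included,
  so the statistic is finite and scale-invariant by construction. A
  constant series returns 0 (perfect regularity).
* **Hurst exponent.** Rescaled-range analysis over dyadic segment sizes
  16…N/2, averaged over non-overlapping segments; Ĥ = regression slope
  of log R/S vs log n, clipped to [0, 1] with a flag. Mean |Ĥ−H| on fGn
  (n = 4096) measures ≤ 0.08 for H ∈ {0.3, 0.5, 0.8}.
* **DFA exponent.** Cumulative deviation series, order-1 detrending per
  segment, F(m) over 16 log-spaced scales in [4, N/4]; Δ = log–log
  slope. White noise → 0.5, integrated noise → 1.5, fGn → ≈ H.
* **Higuchi FD** with k_max = 8 (the classical default); slope of
  ln L(k) vs ln(1/k).
* **Katz FD** on (index, value) pairs with unit index step; an evenly
  spaced monotone line gives exactly 1 by the ratio identity.
* **Energy** Σ|x|², **Shannon entropy** −Σ|x|²·ln|x|² and **log-energy
  entropy** −Σ ln|x|², with |x|² floored at ε = 1e-12 inside the logs
  (a sample below ε contributes 0 to the Shannon sum). The log-energy
  sign convention is kept as printed even though it is nonstandard;
  both entropies serve as discriminative statistics, not calibrated
  information measures.

Estimators whose preconditions fail on a given window (constant signal,
attractor too short, vanishing variance) record a NaN value plus a
status string instead of aborting the window; window averaging then
skips them and reports the surviving window count.

The O(N²) pair-counting kernels (ApEn, correlation integral) are exact
enumerations, numba-compiled when numba is importable with an identical
pure-numpy fallback. Brute-force reference implementations in the test
suite confirm C(r), L_m(k), R/S(n) and F(m) to 1e-10 on the same code
path the pipeline uses.

## Aggregation, normalisation and classification

Window values are averaged per (subject, channel, band, feature). For
each group pair the features are z-scored per (channel, band, feature)
against the pooled two-group mean and SD (denominator n−1); zero-
variance cells become 0 with a warning. Missing cells are mean-imputed
within group before pooling. Pooled z-scoring uses all subjects before
cross-validation and therefore leaks distributional information into
LOOCV; it is nevertheless the default because it mirrors the study
design this package reproduces. A fold-safe variant (standardisation
from the training fold only, `fold_normalize=True`) is provided, and a
seeded simulation in the test suite documents that pooled scoring is
no worse than fold-safe on average under the null.

The 16 classifier presets mirror a commercial classification-learner
catalogue: trees with at most 4/20/100 splits (Gini); unpenalised
logistic regression (a 1e-8 ridge keeps separable fits finite); linear
(C=3), quadratic (C=3), cubic (C=4) and Gaussian SVMs with kernel
scales √P/4, √P, 4√P over P = 10 predictors (C = 3, 3, 1); and six
KNNs — fine k=1, medium k=10, coarse k=100 (capped at the training
fold size), cosine, Minkowski-3 and squared-inverse-distance weighted.
Every preset is a deterministic fit; KNN prediction ties break toward
the smallest class index. LOOCV accuracy is computed per (channel,
band) cell on that cell's 10 features; cross-channel pooling is never
performed. Summaries report per-band mean and max over channels per
classifier; the best classifier maximises the grand mean accuracy,
ties broken lexicographically with a logged note.

## Synthetic cohort generator

Each channel is a sum of five band components plus 5% broadband sensor
noise. A band component mixes, at amplitude A_b (defaults 4.0 / 2.5 /
3.0 / 1.5 / 0.8 µV-equivalents for delta…gamma, a 1/f-like profile with
an alpha peak):

* a narrow-band oscillation — randomised-phase sinusoid with ±5% slow
  frequency drift and 20% amplitude modulation at ~0.2 Hz, carrier
  drawn from the central 60% of the band; and
* band-projected fractional Gaussian noise — an exact Davies–Harte fGn
  source, unit-normalised, projected onto the band's own wavelet branch
  so it sits exactly inside one branch of the analysis bank.

The two parts are mixed 1:1 in variance by default (noise fraction 0.5).
The stochastic part is scaled against the *reference* Hurst exponent
via a shared Gaussian draw: at baseline the mix is exactly 1:1, while a
shifted exponent keeps the natural change in the band's energy share.

Baseline Hurst is 0.5: the null background is spectrally flat within
each band, which makes the null condition neutral and gives injected
persistence shifts a well-defined footprint. Effect families shift one
generator parameter of group 2 at a (channel, band) cell:

* `hurst` — adds to the fGn exponent (clipped to [0.05, 0.95]). A
  narrow-band series cannot carry long-range dependence itself (the
  relevant frequencies lie below the band), so the band-wise Hurst
  *estimate* barely moves; the shift instead expresses itself through
  the within-band spectral footprint, chiefly the band's energy share
  (≈ 2.3× in theta for +0.25 from baseline), which is exactly how a
  global 1/f-slope change manifests inside one band of real EEG.
* `energy` — multiplies the component amplitude by (1 + magnitude).
* `irregularity` — adds to the stochastic variance fraction.

Pseudo-PSQI scores are drawn uniformly from 0–5 (first group) and 6–15
(second group); only the > 5 cutoff is functionally meaningful.

What the generator does *not* emulate: volume conduction, a montage,
artifacts, non-stationarity across minutes, or any biophysical source
model. Passing tests therefore demonstrate that the pipeline detects
controlled spectral/irregularity differences at the correct cells under
realistic estimator noise — not that it reproduces clinical effect
sizes on real recordings.

## Verification conditions and statistical design

The heavyweight end-to-end check runs a scaled-down study: two groups
of 12 subjects, 8 channels, 60 s at 256 Hz, with a Hurst shift of
+0.25 injected at three channels in theta, and a companion cohort with
zero effect. Detection is assessed on the best classifier's theta
accuracies: injected channels must reach ≥ 0.8; untouched channels must
stay inside a familywise 95% binomial band around chance
(0.5 ± z_{1−0.025/K}·√(0.25/24) for K simultaneously tested channels —
Bonferroni, since K cells are checked at once). Estimator-recovery
checks use 50 fGn draws at n = 4096; the Lorenz reference uses 10k
states at dt = 0.05 embedded at m = 5 (Takens: m ≥ 2·D2 + 1; the
false-nearest-neighbour choice m = 3 underestimates D2 by ≈ 0.15).
Problem sizes are the package's own verification conditions, chosen so
the full suite runs on a single CPU in well under half an hour.

## Known limitations

* Band selectivity near octave edges is bounded by the bior3.5 filters
  (see above); the gamma branch holds at most ~73% of a 40 Hz tone.
* LOOCV accuracy on 24 subjects has a binomial SD of ≈ 0.10; single-cell
  accuracies are correspondingly noisy, which is why summaries average
  over channels.
* The delay/dimension estimators are heuristics; on noise-dominated
  series the dimension search returns its cap with a flag rather than a
  meaningful minimum.
* Pooled z-scoring is reproduced as the paper-faithful default despite
  its leakage; fold-safe mode exists for methodological comparisons.
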