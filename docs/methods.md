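# Methods

## Signal model and normalization

An MFC series is one scalar clearance height per stride. Because each
patient walks at a self-selected constant treadmill speed, the series is
treated as uniformly sampled at one sample per stride and frequencies are
reported in cycles/stride (`k / nfft` for bin `k`; Nyquist 0.5). Stride
indices are 1-based and must be consecutive.

Series are normalized per subject before feature extraction, by default
min-max to [0, 1]. The choice is per subject (not pooled across the cohort)
because normalization exists to remove between-subject scale and level
differences; min-max is consistent with published normalized group levels
in the 0.5-0.7 range on a unit scale. Tone-entropy is the one family
computed on max-normalized values instead, because the percentage index
divides by the previous stride's value and min-max normalization introduces
an exact zero. `none` is available for pre-normalized input.

## Short-term spectrum

Framing: `n_segments` frames (default 8) at fractional overlap `o`
(default 0.5). The segment length is `seg = floor(N / (1 + (n_segments-1)
(1-o)))` and the hop `floor(seg (1-o))`, chosen so the requested number of
frames tiles as much of the series as possible; for N = 200 this gives
seg = 44, hop = 22, frames starting at 0, 22, ..., 154 and two trailing
samples discarded. Series shorter than `n_segments + 2` strides are
rejected as degenerate.

Each frame is multiplied by a **symmetric** window (Hamming by default,
`0.54 - 0.46 cos(2 pi n / (M-1))`), zero-padded to `nfft = 256` (truncation
is forbidden) and transformed with a real FFT; the one-sided magnitudes
(129 bins) are averaged over frames with an unweighted arithmetic mean. No
magnitude scaling is applied — no `1/M`, no window-energy compensation — so
the bin-0 magnitude of a frame is exactly `|sum w[n] x[n]|`. This makes the
DC feature an interpretable window-weighted local mean: for a constant
series at level c, `spec_k0 = c * sum(w)` (= 23.3 c for the 44-sample
Hamming window), which is also what anchors the feature scale to the
published group values (~16.6 and ~11.5 for levels 0.71 and 0.52). The DC
component is deliberately *not* removed before transforming; the method
depends on it.

A consequence of zero-padding worth knowing: the 44-sample Hamming mainlobe
spans roughly +/-12 of the 256-point bins, so for a near-constant signal
bins 1-2 are mainlobe samples of the window transform (about 0.98 and 0.92
of bin 0), not zeros, and the first ~10 bins of the mean spectrum are
strongly correlated.

## F-ratio

For bin `k`, `F(k)` is the unweighted sum over classes of squared
deviations of class means from the pooled mean, divided by the sum over
classes of the size-averaged within-class squared deviations (population
normalization, `1/C_i`). It is computed on per-subject mean spectra (one
sample per subject). Bins with exactly zero within-class variance are
flagged undefined and carry NaN — never silently 0 or infinity — so
downstream ranking stays explicit. F is invariant to shifting all samples
of a bin by a constant and to common rescaling.

## Baseline feature families

* **Descriptive** (6): mean, median, sample SD (n-1), Q1, Q3
  (linear-interpolation quantiles), IQR.
* **Histogram + Poincaré** (24): the descriptive set plus skewness (g1),
  excess kurtosis (g2), histogram mode (midpoint of the fullest of 16
  equal-width bins), min, max and the quartile coefficient of dispersion
  `(Q3-Q1)/(Q3+Q1)`; plus Poincaré descriptors SD1 = SD(lagged
  differences)/sqrt(2), SD2 = SD(lagged sums)/sqrt(2), SD1/SD2 and the
  ellipse area `pi SD1 SD2`, each at lags 1-3. The published family has 24
  features but its exact composition is not enumerated anywhere we can
  check; the multi-lag Poincaré extension is our documented stand-in and
  its lag-1 subset matches the standard definitions exactly. SD2 = 0
  (constant series) yields a ratio of 0 by convention.
* **Tone-entropy** (2): the percentage index `PI_i = 100 (x_{i+1} - x_i) /
  x_i` summarized by its mean (tone) and the Shannon entropy (base 2) of a
  50-bin equal-width histogram spanning [min, max], empty bins skipped.
  The cited construction does not fix the bin count or log base; 50 bins
  and log2 are package defaults, configurable. A constant PI series has
  entropy 0 by definition, not by error.
* **Wavelet multiscale** (6): Daubechies-6 decomposition with symmetric
  extension to at most 8 levels, capped at `floor(log2 N)` with a warning
  (7 levels for 200 strides); per-level log2 detail-coefficient variances
  `v_1..v_5` plus the least-squares slope of `v_l` against `l` over all
  available levels. The slope is a multiscale exponent: 0 for white noise,
  positive when coarse scales dominate. The published work derives six
  wavelet features without listing them; this set is our stand-in for
  "correlations among detail variances across scales". Series shorter than
  32 samples cannot supply `v_5` and are rejected.

## Screening and evaluation

Mann-Whitney U is two-sided, exact by enumeration when the combined sample
is at most 20 without ties, and the tie-corrected normal approximation with
continuity correction otherwise; the reported U is the smaller of the two
one-sided statistics. The per-feature AUC is the rank statistic
`U_pos / (n_pos n_neg)` (ties one half), reported orientation-normalized to
>= 0.5 with the flip recorded. `improved` is the positive class throughout:
the degenerate all-positive predictor on a 14/5 cohort then reproduces
ACC 73.68 / SENS 100 / SPEC 0 / F1 84.85.

Classifiers are scikit-learn estimators behind a small contract that admits
the published hyperparameter grids (SVM kernels linear/RBF/poly-3 with C in
{0.01..100}; forests and bagged trees with min leaf {1,5,10} and 5-100
trees; AdaBoost depth-1 stumps with learning rate {0.001,0.01,0.1} and
15-30 learners; one-hidden-layer MLP with 10/20/50 nodes, learning rate
{0.1,0.01,0.001}, 1000 epochs, L2 0.01). Features are z-scored with
training-split statistics inside every CV iteration — necessary because
the families span scales from 0.1 to 17.

Cross-validation protocols:

* **LOSO** — every subject held out once. Metrics come from the single
  pooled confusion matrix over the held-out predictions (per-iteration
  metrics are degenerate for one test sample) and the AUC is pooled over
  held-out decision scores.
* **LOFO** — train on 4 random subjects per class, test on the rest,
  repeat 50 times; per-repeat metrics and decision-score AUCs are averaged,
  never recomputed from pooled counts.
* **Stratified k-fold** (k = 5) — shuffled, seeded folds; per-fold metrics
  averaged. If k exceeds the minority class size it is clamped (with a
  warning) so every fold keeps at least one minority subject.

Noise robustness follows the train-clean / test-noisy design: the model is
fit on clean features, and the held-out subject's features are recomputed
from a copy of its series contaminated with white Gaussian noise whose SD
is `percent/100` of the series' own sample SD (the published levels are 0,
10, 20, 30; any non-negative level is accepted). Level 0 reproduces the
clean LOSO report exactly. Noisy values may leave [0, 1] slightly; such
series carry the normalized flag with the range invariant waived.

All randomness funnels through seeded numpy generators; the pipeline
derives stage seeds from one top-level seed via `SeedSequence`, records the
seed in every report and writes a manifest (config echo + library
versions), so any stage can be re-run in isolation bit-identically.

## Synthetic cohorts

The generator emulates the reported statistical structure of the two
outcome classes, not gait biomechanics. Per subject it draws a normalized
level `mu_s ~ N(mean_mu, mean_sd)` and a target stride SD
`sigma_s ~ N(sd_mu, sd_sd)` (both truncated), then adds three stationary
components whose variances share the `sigma_s^2` budget:

* a slow AR(1) drift of the local level (pole 0.985, decorrelating over
  ~66 strides), weighted by `0.5 (1 - osc_stability)` — the "unstable
  low-frequency content" of improved subjects;
* a sinusoid at `osc_freq` = 0.03 cycles/stride whose log-amplitude is an
  AR(1) process and whose phase performs a random walk, with innovation
  scales proportional to `1 - osc_stability`;
* white Gaussian stride noise taking the remaining variance.

The realized fluctuation is centered and rescaled so the pre-clip series
mean and SD equal `mu_s` and `sigma_s` exactly; without this conditioning,
the drift's series-mean component inflates the between-subject level spread
and the finite-window sampling of slow drift deflates the realized SD by
~10%, both corrupting the calibration. Values are clipped to the open unit
interval (clip counts recorded in the series metadata) rather than
re-normalized, keeping the generator independent of the normalization code.

Class defaults: improved `(mean 0.5164 +/- 0.1282, SD 0.1351 +/- 0.0319,
stability 0.2)`, unimproved `(0.7148 +/- 0.0537, 0.0933 +/- 0.0186,
stability 0.9)`; oscillation frequency 0.03 cycles/stride for both (inside
the discriminative low-frequency zone), nominal amplitude 0.08 capped so
the oscillation never exceeds 90% of the variance budget. The levels and
spreads are the published group statistics; the oscillation/drift
parameters are modeling choices set so the DC feature's group means land
near the published 16.63 / 11.50 and the improved class shows visibly
higher across-frame spectral variance.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: per-subject min-max pinning (real normalized
series touch 0 and 1 exactly; synthetic series only stay inside the
interval), skewed clearance distributions, left/right asymmetry, session
drift or fatigue trends, and any covariance between level and variability
beyond what clipping induces. One known consequence: with the class levels
and spreads fixed at the published values, the first three spectral bins
are nearly collinear (all inside the window mainlobe), the classification
problem is effectively one-dimensional, and the leave-one-sample-out
accuracy of the 3-feature linear SVM on 50/50 cohorts concentrates around
88-89% — the Bayes ceiling implied by those level spreads — rather than
the mid-90s reported on the real 19-subject cohort.

## Numerical choices and degenerate inputs

* Quantiles use linear interpolation; SDs use the n-1 denominator unless
  stated otherwise; histogram mode uses 16 bins.
* Constant series: min-max normalization raises a degenerate-input error;
  descriptive SD/IQR are 0; PI is all zeros (tone = 0, entropy = 0).
* A zero clearance value makes the percentage index undefined; the error
  reports the offending stride.
* Wavelet detail variances are floored at 1e-300 before the log.
* Undefined classifier metrics (zero denominators) are reported as 0 with
  an explicit flag; undefined F-ratio bins are NaN with a flag.
* Metric tables print percentages at 2 decimals; stored values are full
  precision. CSV floats are written at 17 significant digits and parsed in
  round-trip mode, so write/read cycles are bit-exact.

## Problem sizes

Statistical checks run at sizes chosen to keep Monte-Carlo error well below
the effects being tested: calibration and recovery use 50 subjects per
class (5 replicate cohorts), the null type-I-error check uses 200 replicate
10v10 cohorts, and the effect-direction check uses 100 replicate 10v10
cohorts.
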