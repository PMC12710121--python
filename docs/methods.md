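# Methods

This document specifies the models, parameters, and numerical choices behind
`tremorlab`, and states where the synthetic data generator is realistic and
where it deliberately is not.

## 1. Canonical preprocessing

Every analysis operates on a scalar series in a canonical form:

1. **Vector amplitude sum.** Triaxial recordings are collapsed to
   `sqrt(x^2 + y^2 + z^2)` per sample; monoaxial recordings pass through
   unchanged.
2. **Resampling to 100 Hz.** Polyphase resampling
   (`scipy.signal.resample_poly`) with the rational rate ratio; the built-in
   anti-alias filter runs before decimation. Upsampling is rejected — the
   analysis never fabricates bandwidth.
3. **Segment extraction.** The first 15 s after discarding 1 s of leading
   samples (filter transients, movement onset). Shorter segments are an
   error unless explicitly allowed (the length-ablation study truncates on
   purpose).
4. **Band-pass 2–30 Hz.** 4th-order Butterworth applied forward-backward
   (`sosfiltfilt`): zero phase distortion, so the waveform asymmetries and
   regime boundaries that the model features read are not smeared.
5. **z-normalization.** Two exact passes pin `|mean| < 1e-8` and
   `|sd - 1| < 1e-6`. Amplitude information needed by AUC and peak power is
   taken from the non-normalized series instead.

Recording exclusion follows two rules: a recording is dropped when its peak
frequency shifts by strictly more than 1 Hz under 500 g/1000 g loading
(enhanced physiological tremor), and an automated screen flags flat-lines
(≥ 5 identical consecutive samples) and extreme outliers (|z| > 8) in place
of manual visual inspection.

**Hand selection.** For each condition recorded bilaterally, the relative
spectral-power side difference `(AUC_R − AUC_L) / (AUC_R + AUC_L)` is
computed on the non-normalized amplitude-sum series; the condition with the
largest absolute difference decides, ties prefer rest, and the hand on the
stronger side becomes the analysis hand.

## 2. Standard tremor characteristics

All six are computed from the canonical series; the spectral ones from a
Welch periodogram with 5 s Hann windows and 50% overlap (0.2 Hz resolution
at 100 Hz).

| characteristic | definition |
| --- | --- |
| AUC | trapezoidal integral of the power density over 2–30 Hz, with interpolated band edges so the integral is exactly additive over sub-bands |
| peak frequency / power | argmax and max of the density in-band; spectral ties resolve to the lower frequency |
| FWHM | width between the linearly interpolated half-maximum crossings flanking the peak; a single-bin spike yields one grid step; truncation at a band edge is flagged |
| HWP | power integrated over the FWHM interval (≤ AUC by construction) |
| TSI | interquartile range of consecutive cycle-to-cycle changes in instantaneous frequency; the instantaneous frequency comes from the unwrapped Hilbert-transform phase, averaged per 2π revolution, with low-envelope epochs (< 0.1 × median) and out-of-range values (outside 0.5–30 Hz) excluded |

TSI is invariant under amplitude rescaling; the Hilbert-phase cycle
segmentation needs at least 20 valid cycles or the value is refused rather
than returned noisy.

## 3. The two model features

Both are computed on the **z-normalized** canonical series and are therefore
amplitude-invariant — by design, since recording amplitude depends on sensor
placement and effort, not diagnosis.

### 3.1 `garch_ks` — residual non-Gaussianity after conditional-variance whitening

1. Fit an autoregressive model with AIC order selection over lags 1–8
   (`statsmodels.AutoReg`, constant trend). This removes the predictable
   oscillatory structure, including any *deterministic* waveform asymmetry.
2. Rescale the residuals to unit variance (this, plus the scale-free KS
   statistic, makes the feature exactly amplitude-invariant).
3. Fit GARCH(1,1) by Gaussian quasi-maximum likelihood. The conditional
   variance recursion `sigma2_t = omega + alpha*e2_{t-1} + beta*sigma2_{t-1}`
   is evaluated as a first-order IIR filter (`scipy.signal.lfilter`), with
   the sample variance as backcast initialization. The likelihood surface is
   hostile near the stationarity boundary `alpha + beta -> 1`, so the
   optimizer is layered: four variance-targeted L-BFGS-B starts, then a
   restarted Nelder-Mead polish (up to 3 rounds). Convergence is reported
   honestly; a non-convergent fit invalidates the feature rather than
   returning a number.
4. Report the Kolmogorov-Smirnov statistic of the standardized residuals
   against a standard normal.

The feature reads *distributional asymmetry that survives volatility
modelling*. A GARCH filter can whiten any symmetric scale-mixture (bursty
variance, regime switching); what it cannot whiten is one-sided innovations.
Parkinsonian tremor produces exactly that — direction-specific acceleration
events — so its KS statistic stays elevated while ET sits at the finite-sample
null floor (≈ 0.87/√n ≈ 0.022 at n ≈ 1490).

### 3.2 `hmm_nstates_ll` — Gaussian-HMM state-structure likelihood

Gaussian-emission hidden Markov models with 2, 3, and 4 states are trained
by Baum-Welch EM (`hmmlearn`) on the first 60% of the series; 3 restarts per
state count from deterministic per-restart seeds; the feature is the best
per-sample train log-likelihood. Choices that matter:

- **Train log-likelihood, per sample.** The feature measures how well a
  small set of Gaussian states *can* describe the signal, not out-of-sample
  fit; per-sample scaling keeps values comparable across lengths.
- **Variance handling.** `covars_prior = 0`, `covars_weight = 0` and a
  variance floor of 1e-6 (flagged when active) make the 1-state fit agree
  with the closed-form single-Gaussian MLE to < 1e-6 nats — the analytic
  anchor used in the acceptance tests.
- **EM trace.** A recording convergence monitor stores the full per-iteration
  log-likelihood, so the EM monotonicity guarantee is testable.

PD tremor alternates between distinct amplitude regimes; conditioned on the
regime, the sample distribution is well covered by a few Gaussian states,
giving a high per-sample likelihood. ET's smoothly amplitude-modulated
oscillation spreads its marginal out and fits worse. PD > ET on both
features, which is the ordering the classifier exploits.

## 4. Classification protocol

- **Patient-grouped, label-stratified k-fold CV** (default k = 10). Patients
  are dealt to folds, never recordings: all recordings of one patient share
  one fold (enforced by an invariant check, not convention).
- **Train-only min-max scaling.** Each fold's scaling bounds come from its
  training rows; held-out values may leave [0, 1] and are not clipped.
- **Models.** Linear SVM (C = 1), logistic regression, random forest
  (200 trees). The linear SVM is the headline model.
- **Metrics.** Accuracy, sensitivity, specificity, PPV, NPV (all percent;
  PD is the positive class) plus balanced accuracy = (sensitivity +
  specificity)/2, the headline number for class-imbalance robustness.
- **Feature selection.** Univariate screen at strictly > 75% CV accuracy,
  then exhaustive combination search over the screened set, ranked by CV
  accuracy with deterministic tie-breaking.
- **Null check.** Patient-level label permutation repeated over the whole CV
  loop; with healthy plumbing the mean balanced accuracy sits at 50%.

## 5. Synthetic data generator

The generator produces phenotype-conditioned cohorts with known ground
truth. Per patient: a base tremor frequency (ET uniform 5–8 Hz, PD uniform
4–7 Hz), a log-normal amplitude scale (sd 0.25), an affected side, and four
recordings (2 hands × rest/posture) routed through per-center device
profiles (200/500/1000 Hz triaxial by default; a 160 Hz monoaxial profile
for the axis-count comparison).

The oscillator is phase-continuous: per-cycle frequency jitter integrates
into the phase (`phase = 2π·cumsum(f)·dt`), a second harmonic with
configurable phase shapes the waveform, per-cycle amplitude jitter and a
slow sinusoidal AM modulate the envelope, and a hidden Markov regime path
(exponential sojourns, minimum one tremor cycle) switches amplitude scales
and frequency offsets.

Phenotype defaults (the study conditions):

| parameter | ET | PD |
| --- | --- | --- |
| frequency jitter sd | 0.05 Hz | 0.30 Hz |
| amplitude jitter sd | 0.05 | 0.15 |
| 2nd harmonic (ratio, phase) | 0.10, 0 | 0.45, π/2 |
| slow AM (depth, rate) | 0.35, 0.25 Hz | 0.15, 0.15 Hz |
| regime states | 1 | 2 (70%) or 3; scales (1.0, 0.15, 0.5), dwell 2 s |
| bursts (prob/cycle, amplitude) | — | 0.55, 0.9 |
| rest vs posture amplitude | 0.35 / 1.0 | 1.0 / 0.5 |

Two generator mechanisms deserve explanation because they were calibrated
against the features rather than copied from literature:

- **One-sided bursts** (half-sine pulses, ~40 ms, on average every other
  cycle) model direction-specific acceleration events. They scale with the
  *patient-level* amplitude, not the momentary regime amplitude: bursts that
  shrink proportionally with the regime are absorbed by the regime-tracking
  GARCH variance, while patient-scaled bursts stand out in quiet regimes and
  keep the standardized residuals right-skewed. Purely deterministic
  waveform asymmetry (the harmonic at π/2) is invisible to `garch_ks`
  because the AR stage absorbs it — the bursts are what the feature reads.
- **The enhanced-physiological posture component** (8.5–10.5 Hz, amplitude
  0.8 × the patient scale, posture only) is the diagnosis-independent
  position marker. Without it, rest-vs-posture classification fails:
  the amplitude contrast between conditions has *opposite* signs for ET
  (posture-dominant) and PD (rest-dominant) and is not linearly separable
  when diagnoses are pooled.

**Triaxial projection.** The scalar oscillation is projected onto three axes
through one fixed random unit vector per recording plus small per-axis noise;
the vector amplitude sum then recovers ≈ the rectified envelope. This is the
simplest model that exercises the amplitude-sum code path. Consequence:
the spectral peak of the canonical series sits near *twice* the oscillator
frequency (rectification doubles the fundamental). The monoaxial profile
projects onto a single axis (signed waveform retained, amplitude attenuated
by the random projection cosine), which is why matched monoaxial cohorts
classify worse — a structural ordering the acceptance tests assert.

**Realism and limitations.**

- Realistic: phenotype-level contrasts (frequency ranges, cycle-to-cycle
  variability, waveform asymmetry, amplitude-regime intermittency,
  rest/posture amplitude direction, side asymmetry), device heterogeneity in
  sampling rate and axis count, sensor noise.
- Not modelled: rigid-body kinematics and gravity in the axis signals
  (hence the rectified-envelope behavior above), voluntary movement
  artifacts, re-emergent tremor latency, medication state, tremor amplitude
  nonstationarity beyond the regime/AM structure, and any attempt to match
  absolute clinical feature values (e.g. TSI magnitudes differ from clinical
  reports; only orderings and separations are calibrated).
- Calibrated, not emergent: the class separation of the two model features
  is a *construction target* of the defaults (the paired-seed direction
  fraction and the ≥ 90% cohort CV balanced accuracy), so cohort-level
  results on default settings validate the pipeline, not the clinical claim.

## 6. Numerical choices worth knowing

- Welch, not multitaper: the 5 s Hann window pins the 0.2 Hz resolution the
  characteristics are defined on, and the estimator is additive-friendly
  for the AUC identities.
- Band AUC interpolates the exact band edges, making sub-band additivity an
  identity (tested to 1e-10 relative) rather than an approximation.
- GARCH stationarity is enforced by a hard reject (`alpha + beta < 0.9999`,
  `omega > 0`) inside the objective; estimates are clipped to bounds after
  optimization.
- All stochastic stages take explicit integer seeds (< 2^31) derived from
  `numpy.random.SeedSequence` hierarchies or SHA-256 hashes of stable string
  keys, so every artifact is bit-reproducible from its configuration.
- Quartiles (TSI) use linear interpolation, the numpy default, stated here
  because IQR conventions differ across packages.
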