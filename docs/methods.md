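# Methods

This document records the models, parameter choices, and numerical
conventions implemented in `ecgaging`. Quantities quoted here are either
definitions or values asserted by the test suite / reproduction script; no
further empirical claims are made.

## 1. Synthetic cohort generator (`ecgaging.synthetic`)

The generator is the ground-truth harness for every estimator in the
package: interval measurement is validated against its morphology
parameters, detection against its R-peak times, and the risk models against
its configured hazard ratios and odds ratios.

### 1.1 Waveform model

Each beat is a sum of Gaussian deflections (P, R, T; an S slot exists and
defaults to zero) projected onto 12 leads through fixed amplitude templates.
A wave of nominal duration `W` uses `sigma = W / (2k)` with
`k = sqrt(2 ln 20) ≈ 2.448`, so the amplitude falls to exactly 5 % of the
peak at the nominal onset/offset. Consequence: a 5 %-threshold delineator
recovers the generator's intervals essentially exactly on noise-free
records, which is what makes the interval round-trip test meaningful.

Fiducials per beat (relative to the R-peak at 0): QRS spans
`[-QRS/2, +QRS/2]`; the P-wave ends `PR` before QRS onset; the T-wave ends
`QT` after QRS onset, with the ST segment taking 15 % of QT. R-wave lead
amplitudes interpolate linearly between a left-precordial-dominant template
and a V1–V3-dominant one as `r_progression` rises from 0 to 1, emulating
amplitude remodelling with age; `r_progression = clip((age-18)/82, 0, 1)`
plus Gaussian jitter (sd 0.015).

Records are 10 s at 400 Hz by default, first R-peak at 0.4 s, 0.45 s tail
reserved for the final T-wave, plus additive white Gaussian noise
(sd 0.01 mV by default).

### 1.2 Interval model

All four intervals are affine in biological age (ms):

| interval | intercept | slope / year | jitter sd |
|----------|-----------|--------------|-----------|
| P duration | 85 | 0.35 | 5 |
| PR interval | 130 | 0.60 | 5 |
| QRS duration | 80 | 0.25 | 5 |
| QTc | 360 | 0.70 | 5 |

Females receive +10 ms QTc. The rendered QT is Bazett-scaled,
`QT = QTc * sqrt(RR)`, at the subject's heart rate (normal, mean 65 bpm,
sd 5). Slopes are generator choices producing clearly positive age trends in
all four intervals; they are configurable per call.

### 1.3 Cohort model

Per subject (all draws from a per-subject `SeedSequence` spawn, so the
cohort is reproducible and order-independent):

- Chronological baseline age ~ N(49.7, 16.4²) clipped to [25, 85];
  female fraction 0.51 — of the order of a population-based cohort.
- Aging offset (biological − chronological age) from a three-component
  normal mixture: means (+14, 0, −14), sds (4, 5, 4), weights (⅓, ⅓, ⅓).
  The ±14 means sit clearly beyond the ±8 δ-age threshold so the three
  aging-effect groups are populated roughly evenly; the offset drifts
  between exams with sd 2 y, so most but not all subjects keep their group.
- Two exams 5–6 years apart (uniform gap); the follow-up exam exists only
  if the subject survives to it.
- Covariate prevalences: hypertension 0.48, hyperlipidemia 0.20, diabetes
  0.07, beta-blocker 0.015, calcium-channel blocker 0.03, antiarrhythmic
  0.01.
- Survival: exponential with piecewise-constant hazard
  `0.010 / y × group multiplier × covariate HRs × exp(0.05 (age-55))`,
  administratively censored at 21 years. Group multipliers: over 1.4,
  correct 1.0, under 0.65 — the generator truths the Cox models must
  recover. Covariate HRs: male 1.6, hypertension 1.4, diabetes 1.6,
  hyperlipidemia 1.1. Optionally, the hazard after the follow-up exam can be
  re-keyed by the ordered (baseline, follow-up) group pair
  (`serial_hazard_multipliers`), giving a consistency-dependent hazard for
  serial-analysis experiments.
- Disease status: prevalence and incidence of AF / HF / MI from logistic
  models with group-specific odds ratios (e.g. AF incidence OR 2.5 for the
  overestimation group — the truth the logistic estimator must recover),
  hypertension/diabetes OR 1.4, and OR 1.04 per year of age. Incidence is
  undefined (NaN) for subjects already prevalent or without a follow-up
  exam.

### 1.4 What the generator does and does not emulate

Emulated: age-dependent P-QRS-T intervals and R-progression; two-exam
longitudinal structure; covariate prevalences of realistic magnitude;
proportional-hazards mortality keyed to the aging-effect group; group-keyed
disease odds; measurement noise.

Not emulated: real ECG morphology variation (notched QRS, ST depression,
arrhythmias, ectopy), rate variability within a record, drift/powerline
artefacts, correlated covariates, competing risks, time-varying hazards
(other than the optional serial re-keying), loss to follow-up other than
death, or any feature of real cohort data beyond the above. The generator
is an oracle for the pipeline's statistics, not a physiological simulator.

## 2. Preprocessing (`ecgaging.preprocessing`)

- **SNR**: per lead, `10 log10(P_in / P_out)` with the in-band region
  0.66–2.5 Hz (40–150 bpm fundamentals). The DC bin is excluded from the
  noise total; a Hann taper is applied by default (`window=None` disables
  it, which the analytic acceptance check uses). An all-zero lead maps to a
  −200 dB sentinel instead of −inf. Records must be ≥ 4 s.
- **Detection**: Pan-Tompkins-style per lead (5–25 Hz band-pass, squared
  derivative, 150 ms moving-window integral, threshold at 20 % of the
  99.5th-percentile envelope, 200 ms refractory period, peak refinement to
  the band-passed extremum within ±50 ms). Squaring makes it
  polarity-insensitive. The detector is pluggable; any callable with the
  same contract can replace it.
- **Consensus**: peaks pooled across leads and clustered by single linkage
  (consecutive gap ≤ 10 ms; equivalent to pairwise transitive clustering on
  a line, which is how the test oracle implements it). Each lead contributes
  at most one peak per cluster (closest to the cluster median); clusters
  backed by ≥ 7 distinct leads emit the median of contributing times. With
  `fs` given, times are quantised to samples first so comparisons are exact.
- **Segmentation**: half-open windows `[r − 250 ms, r + 400 ms)`,
  `L = round(0.65 fs)` samples. Neighbouring windows that intersect
  invalidate **both** beats; windows that touch exactly (RR = 650 ms) do not
  intersect and are retained — the half-open convention resolves the
  boundary case. Windows not fully inside the record are dropped.
- **Waveform windows** for relevance aggregation: P [−250, −120), PQ
  [−120, −60), QRS [−60, +100), ST-T [+100, +400) ms — a partition of the
  segment.

## 3. Surrogate age model (`ecgaging.ecg_age`)

A differentiable, closed-form stand-in for a pre-trained network, honouring
the same contract (scalar prediction + exact input gradient). Five smooth
features:

- **Duty cycles** (fraction of samples whose smoothed envelope exceeds a
  threshold, with the step softened by a sigmoid of width 0.01):
  `p_duration` on V1 between 0.05 and 0.15 mV, `qrs_duration` on high-passed
  V4 above 0.12 mV, `qt_interval` on lead II above 0.22 mV. Envelopes are
  `smooth(sqrt(x² + ε²) − ε)` with circular-FFT Gaussian kernels
  (σ = 12.5–45 ms). Note these features are deliberately simple and can be
  amplitude-confounded (e.g. the QRS duty cycle *falls* with age because the
  high-passed V4 bump gets wider but lower); only the calibrated linear
  combination, not each feature, needs to track age.
- **Heart rate** as the ridge-regularised spectral power centroid over
  0.66–2.5 Hz (ridge 2e-4 on the normalised power scale, so the feature is
  smooth at zero input).
- **R-progression** as the smoothed-amplitude ratio
  `A_V1 / (A_V1 + A_V5 + 0.10 mV)`, with per-sample amplitudes pooled by a
  temperature-0.03 softmax. The 0.10 mV ridge is essential: without it the
  ratio is scale-invariant and jumps discontinuously at the zero baseline,
  which breaks integrated-gradients completeness (the path integral misses
  the jump regardless of step count).

The five features map to age through ordinary least squares fitted on 500
noise-free generator records (ages 28–92, fixed calibration seed); the
contract is MAE ≤ 3 y on noise-free generator output. Gradients are exact
analytic backpropagation through every feature (the circular Gaussian
convolutions are self-adjoint; the spectral-centroid gradient is an inverse
FFT of the reweighted spectrum), verified against finite differences.

δ-age grouping: over if δ > +8 y, under if δ < −8 y, otherwise correct (the
boundary belongs to the middle class). Screening-range filtering keeps
40 ≤ age ≤ 75 (closed interval). Validation metrics: MAE, Pearson r, and
r² reported as the squared correlation.

## 4. Explainability (`ecgaging.xai`)

Integrated gradients with the zero record as default baseline and midpoint
quadrature:
`IG_i = (x_i − b_i) · mean_k grad_i(b + (k−½)/K · (x − b))`.
The completeness residual `|Σ IG − (f(x) − f(b))|` is stored on every map;
the acceptance threshold is ≤ 1e-3 of the prediction difference at 256
steps. Maps are normalised to max |relevance| = 1 per record (all-zero maps
are flagged, not divided), sliced into the retained 650 ms beat segments,
aligned on the R-peak, and averaged lead-wise across beats and records
(permutation-invariant). Lead importance is the lead-wise sum of absolute
relevance normalised to sum to 1 (uniform 1/12 for a degenerate all-zero
map); it is invariant to scaling the relevance map by construction.

## 5. Clinical features (`ecgaging.clinical`)

P, PR, QRS, QT are measured on lead II around each consensus R-peak: the
smoothed absolute signal (Gaussian, σ = 2.5 ms) is delineated by crossings
of 5 % of the local peak amplitude with subsample interpolation; P is the
strongest deflection in [R − 280 ms, QRS onset − 10 ms] subject to a
0.03 mV amplitude floor (absent → `None` with a reason code), T-end is the
5 % crossing after the strongest post-QRS deflection. Intervals are beat
medians; at least three consensus beats are required. QTc uses Bazett
(`QT/√RR`) by default, Fridericia (`QT/RR^⅓`) optionally. Relative
thresholds make every interval invariant to uniform amplitude scaling.
Group comparisons use two-sided Welch t-tests; a Benjamini-Hochberg helper
is provided but not applied by default.

## 6. Risk statistics (`ecgaging.risk`)

- **Kaplan-Meier** per group via lifelines.
- **Cox PH** via statsmodels `PHReg`, Breslow tie handling by default
  (Efron optional; the test suite cross-checks Efron fits against
  lifelines). Group factors enter as dummies with "correct" as reference;
  default adjustment: age at exam, sex, hypertension, hyperlipidemia,
  diabetes, beta-blocker, calcium-channel blocker, antiarrhythmic. Wald
  95 % CIs with exponents clamped at ±700 to avoid overflow on degenerate
  columns. Constant columns and event-free groups raise `ModelFitError`.
- **Logistic ORs** via statsmodels `Logit` with the same factor coding;
  optional sex stratification runs two independent fits with sex dropped.
  Perfect separation and non-convergence raise `ModelFitError`. Note: rare
  binary covariates with zero events (e.g. 1 % medication flags against a
  ~1 % incidence outcome) cause quasi-separation; analyses of rare outcomes
  should adjust only for covariates that plausibly drive the outcome (the
  reproduction script falls back along a documented covariate chain).
- **Serial analysis**: three Cox models — baseline (group and clock from
  exam 0), follow-up (group and clock from exam 1), serial (ordered group
  pair, reference "correct,correct", clock from exam 1) — adjusted for age
  and sex by default, returned as one tidy frame. Leakage guard: time at
  risk is anchored at the group-defining exam and asserted non-negative row
  by row, so survival accrued before that exam is never credited. Subjects
  who die before the follow-up exam are absent from the follow-up and
  serial models by construction.

## 7. Numerical choices

- Sigmoid width 0.01 for duty cycles and softmax temperature 0.03 mV for
  amplitude pooling: small enough to approximate the hard quantities on
  clean signals, large enough for stable gradients at 400 Hz.
- Ridges (2e-4 spectral, 0.10 mV amplitude-ratio) remove scale invariance
  at the origin so the zero-baseline path integral is C¹; chosen during
  model design as the smallest values giving a comfortable completeness
  margin without affecting calibration accuracy.
- Midpoint quadrature for integrated gradients: second-order accurate, and
  its gap(2k) ≤ 1.1 gap(k) convergence is asserted for k ≥ 32 (at very
  small k the error can fluctuate through accidental cancellation).
- WFDB format 16 with gain 1000 (1 µV LSB) bounds the IO round-trip error
  at 0.5 µV per sample.
- All simulation randomness flows from `numpy.random.SeedSequence` spawns,
  making every cohort a pure function of its config.

## 8. Limitations

- The surrogate is a linear model over five hand-built features: it tracks
  the generator's aging axis but has none of the representational capacity,
  failure modes, or fairness concerns of a trained network, and its
  relevance maps reflect its own features (V1/V4/II/V5), not learned ones.
- Generator realism is deliberately limited (§1.4); absolute effect sizes
  computed on it characterise the estimators, not any real population.
- Cox models assume proportional hazards — true by construction here, but
  untested diagnostics (Schoenfeld residuals, etc.) are out of scope.
- Wald intervals are used throughout; no profile-likelihood or robust
  variants.
- The serial analysis conditions on surviving to the follow-up exam;
  between-exam immortal time is excluded by design rather than modelled.
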