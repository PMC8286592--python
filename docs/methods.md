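# Methods

This note documents the models implemented in `resppat`, the
assumptions behind the synthetic-data generator, the numerical choices,
and the limitations a user should keep in mind when transferring
conclusions from synthetic cohorts to real telemonitoring data.

## Signal model and the synthetic generator

The generator emulates the pressure signal measured in an oxygen
circuit at 10 Hz, in which inspiration through the nasal cannula
appears as minima below a slowly drifting baseline.

Each breath cycle of length `L` is rendered as a half-sine inspiratory
trough of depth `d` over the first 30 % of the cycle, a shallower
positive expiration hump (30 % of `d`) over the next 35 %, and an
end-expiratory pause at baseline for the remainder. The pause matters:
it anchors the rolling-median baseline estimate at the true zero, so
the measured inspiratory depth is unbiased on clean signal.

Per subject, breathing is controlled by a `SubjectProfile`:

| parameter | unit | default | rationale |
|---|---|---|---|
| `rest_rate` | breaths/min | sampled 12–18 | adult resting band |
| `rest_amplitude` | pressure units | sampled 0.8–1.2 | arbitrary device units |
| `exercise_rate_multiplier` | – | strategy-dependent (≈1.45 rate-dominant, ≈1.08 amplitude-dominant, ≈1.3 mixed) | mild 3-min exercise raises rate moderately |
| `exercise_amplitude_multiplier` | – | ≈1.2 / ≈1.9 / ≈1.45 | depth responds strongly to load |
| `breath_length_cv` | – | 0.08 | cycle-to-cycle jitter, gamma-distributed (positive support) |
| `amplitude_cv` | – | 0.12 | breath-to-breath depth jitter |
| `rate_wander_sd` | log scale | 0.18 | slow within-subject wander of the resting rate target (OU process, `τ` = 150 s) |
| `amplitude_wander_sd` | log scale | 0.08 | depth wanders much less, relative to its exercise response |
| `noise_sd` | pressure units | 0.12 | broadband sensor noise |
| `baseline_drift_amplitude` | pressure units | 0.15 | sinusoidal drift, period 90 s |

The two wander processes encode the central physiological asymmetry the
analysis probes: resting respiratory rate is highly variable from
window to window (attention, posture, speech), while inspiratory depth
is comparatively stable yet roughly doubles under load in
depth-adapting subjects. Without rate wander, a window-median rate
would be precise to a few percent and rate-only classification would be
unrealistically easy. Subjects split into *rate-dominant* and
*amplitude-dominant* adaptation strategies (alternating in generated
cohorts), mirroring the observation that different people increase
ventilation in different ways — the reason per-subject models are
needed and rate alone is weak.

Instantaneous breathing frequency is hard-capped at 2 Hz (cycle length
clipped at 0.5 s); faster oscillation is treated as noise throughout.

The healthy protocol template lasts 30 minutes: 23 reference windows
(four of which carry 10-s artifact bursts standing in for
drinking/cough/speech/mouth-breathing; they remain labelled reference),
4 exercise windows (the 3-minute block), and 13 transition windows in
which rate and amplitude decay exponentially back to rest
(`τ` = 120 s), so transition windows are genuinely intermediate and are
excluded from classification. COPD-like recordings are observational:
absence gaps (oxygen off / patient away), a configurable number of
exercise blocks each followed by a recovery period, and an *annotation*
track that differs from the truth — recovery is annotated as reference
and exercise-block edges are shifted by up to ±2 windows — emulating an
approximate activity diary. The generator emits its true per-breath
cycle log so detection can be scored against ground truth.

What the generator does **not** emulate: real sensor physics, oxygen
flow, apneas/periodic breathing, body-movement artifacts with
structured spectra, or inter-day drift. Passing tests therefore
demonstrate the pipeline's correctness and the qualitative geometry of
the feature comparison, not clinical performance levels.

## Preprocessing

Windows are exactly 45 s (450 samples); trailing partial segments are
discarded, never padded. Window labels follow the majority regime
within the window, ties broken toward the regime appearing earlier.
Subject presence requires respiratory-band (0.1–2 Hz) power at least 3×
the broadband noise floor extrapolated from the spectrum above 2.5 Hz;
windows at exactly the threshold count as present. Breath minima are
located on a zero-phase low-passed copy of the signal (Butterworth,
2 Hz — the physiological ceiling), with prominence at least half the
standard deviation of the baseline-corrected window and separation
≥ 0.5 s; depths are then measured on the *raw* trace with parabolic
sub-sample refinement (the low-pass attenuates narrow exercise troughs)
against a 5-s rolling-median baseline, and minima shallower than 35 %
of the window's median depth are rejected as noise dips. Windows with
fewer than 4 identified breath cycles are `too_few_breaths` (hard
rule); cycle-length CV above 0.5 is `too_variable`; both are excluded
from all classification data.

## Features

Fourier coefficients use the plain FFT scaled by `1/N`, matching the
`1/T` integral normalization, magnitudes only (phases discarded). The
DC bin is retained by default — the 2 Hz rule alone does not exclude
it — with a config switch, and "below 2 Hz" is read inclusively (the
2 Hz bin kept). No detrending or tapering is applied.

The ARIMA(1,1,1) triple is fitted by exact maximum likelihood as an
ARMA(1,1)-with-constant on the differenced window, stationarity and
invertibility enforced. The estimator's additive MA convention is
mapped to the subtracted-θ convention of the prediction equation
(`θ = −θ_est`), and the drift is recovered from the fitted mean `m` of
the differences as `μ = m(1 − Φ)`; a sign-mapping test guards this.
Constant series and failed fits yield missing triples. Note that on
white-noise differences the ARMA(1,1) pair is non-identified along the
ridge `Φ = θ` (AR and MA cancel); only `Φ − θ` and `μ` are pinned
there, which the tests respect.

## Classification

**One-class.** Per subject, reference windows are split into 5
contiguous folds (contiguity preserves temporal autocorrelation
honesty; a seeded random scheme is available). For each fold the mean
and covariance are learned on the other four; the held-out reference
fold is scored, and exercise windows are scored by all five models
(protocol cohorts, few exercise windows — five predictions per
exercise point) or partitioned across folds (observational cohorts —
one prediction per point). The covariance is shrunk toward its own
diagonal with a Schäfer–Strimmer-style data-driven intensity
`λ* = Σ_{i≠j} Var(s_ij) / Σ_{i≠j} s_ij²`, floored at 10⁻³, so
small-fold or collinear covariances stay positive-definite while
well-conditioned ones are nearly untouched; the Mahalanobis distance is
evaluated by Cholesky solve, never an explicit inverse. For the Fourier
set, a 5-component PCA is fitted inside each training fold; held-out
rows only pass through the fitted projection.

**Supervised.** A binomial GLMM with logit link, fixed effects for the
(training-standardized) feature set, and per-subject random intercepts
and random slopes on every covariate with diagonal random-effect
covariance — the most literal identifiable reading of "random
intercepts and slopes". It is fitted by Laplace/MAP approximation
(statsmodels `BinomialBayesMixedGLM.fit_map`, weak priors, prior sd 3
on log random-effect scales); on failure it falls back to random
intercepts only, then to plain logistic regression, with a logged
reason. In the zero-heterogeneity limit the fixed effects agree with
ordinary logistic regression to well under 0.05, which is verified.
Evaluation uses 5-fold cross-validation stratified within subject
(every subject, and where possible both classes, appear in each
training fold, so random effects are estimable for all test subjects);
an in-sample mode is available (`supervised_eval: in-sample`) since
the evaluation protocol for a supervised panel is genuinely
underdetermined — cross-validation is the default as the more
conservative choice.

## Evaluation

ROC curves are empirical over all distinct thresholds with tied scores
grouped into single steps; AUC is the trapezoidal area, which equals
the tie-corrected Mann–Whitney statistic exactly (property-tested
against pair counting and against scikit-learn). The 95% CI uses
DeLong's structural-components variance by default (stratified
bootstrap available). The operating cut-off minimizes
`√(FPR² + (1−TPR)²)`; the sign in the second term corrects an obvious
typo in the printed source formula (`(1+TPR)²` is minimized at
TPR = 0, contradicting the upper-left-corner intent), and the literal
form remains available via `cutoff_formula: as-printed` for audit.
Ties are broken toward higher sensitivity. Accuracy, sensitivity and
specificity are recomputed from the raw pooled scores at the selected
cut-off. Metrics are pooled across subjects by default.

## Problem sizes and runtime

The default experiment uses the protocol cohort size of 20 healthy
subjects (30 min each) and 8 COPD-like patients; the package's default
demo duration for the observational recordings is 2 hours with two
exercise blocks, which keeps a full two-cohort, six-feature-set,
two-mode experiment to a few minutes on one CPU (the per-window ARIMA
maximum-likelihood fit, ~50 ms, dominates). Longer observational
recordings (up to the device's 8-hour memory limit) are supported by
configuration.

## Known limitations

- Synthetic artifacts are unstructured noise bursts; real swallowing or
  speech has structured spectra and can fool the presence detector
  differently. Artifact-burst windows here often fail presence or
  quality checks, which mirrors deployed behaviour but means the
  effective reference count per protocol subject is slightly below 23.
- Absolute metric values depend on generator settings (wander sds,
  multipliers); only the relative ordering of feature sets is the
  designed, tested outcome.
- The MAP-fitted GLMM is an approximation to maximum likelihood; with
  very few subjects the weak priors shrink random-effect variances
  noticeably.
- DeLong CIs assume independent windows; within-subject correlation
  makes them anti-conservative on pooled scores. A per-subject
  macro-average or cluster bootstrap would be the conservative
  alternative.
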