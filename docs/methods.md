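# Methods

This note records the models, conventions and design choices behind
`ecgquant`, in the order the pipeline runs.

## Beat model and measurements

A delineated beat is nine fiducial sample indices (P onset/peak/offset,
QRS onset/R peak/QRS offset, T onset/peak/offset) plus a six-category
T-wave morphology class (normal, inverted, positive monophasic, negative
monophasic, biphasic negative–positive, biphasic positive–negative).
Fiducials must be strictly increasing within a beat; violations are
rejected at parse time with a reason, never downstream. A missing wave
leaves its fiducials absent, and every measurement that needs them is
absent (`nan`) for that beat — absence is per measurement, not per beat.

Measurement conventions:

- **Spans** (s): RR = next R peak − R peak (absent for the last beat);
  PR = P onset → QRS onset; QT = QRS onset → T offset; wave widths from
  onset to offset.
- **Baseline** (mV): the mean of all samples *pooled* across the PR, ST
  and TP segments (not the mean of the three segment means). The pooled
  reading is the literal one and weights segments by their sample counts.
  Unavailable segments are left out of the pool.
- **Amplitudes** (mV, signed): max and min of the wave window minus the
  baseline; the excursion with larger absolute value wins, ties resolve
  to the positive one. The R amplitude window is the full QRS
  (onset → offset) so deep negative complexes are captured; this treats
  all three amplitudes uniformly.
- **Slopes** (mV/s): OLS slope (intercept included) over each of the nine
  segments, regressing on time in seconds so units are independent of the
  sampling rate. The TP segment runs to the next beat's P onset and is
  absent for the last beat.

Windows are inclusive of both endpoint samples.

## RR correction

Each span *y* follows *y* = *β*·RRᵅ + *ε* over beats; correction divides
by RRᵅ. The exponent is selected on the fixed grid {0, 0.1, …, 1.0}: for
each candidate *α*, *β* is fit by least squares **through the origin**
(the model has no intercept), and R² = 1 − SSE/SST is computed with SST
about the mean of *y*. No-intercept R² conventions vary; the mean-centered
convention is used deliberately so that fits are comparable across
exponents and R² = 0 means "no better than a constant". Ties resolve to
the smaller exponent (parsimony). Constant *y* has SST = 0 and raises a
degenerate-fit error instructing the caller to use *α* = 0.

Fitting uses healthy subjects' beats only, so disease-related distortions
cannot bend the correction law. The pipeline default applies the shipped
exponents (QT 0.5, PR 0.2, P span 0.1, T span 0.5, QRS span 0); refitting
is opt-in (`--refit-alpha`).

## Quantile features

Per subject, each of the 18 numeric variables is summarized by the sample
quantiles p1, p5, p10, p25, p75, p90, p95, p99 (144 features), each
variable using its own non-absent beats. The quantile definition is
linear interpolation of order statistics (position (n−1)·p/100 on the
0-based sorted vector, the common "type 7" convention) — fixed for
reproducibility. The median is deliberately absent from the set: when
most beats are normal in both groups, the information is in the tails.

The categorical T type is summarized as six per-beat proportions plus the
modal category. Proportions make the variable usable by all three
classifiers; the mode is retained for discriminant-analysis reports.
Subjects contribute all their beats pooled across records; subjects with
fewer than `min_beats` (default 30) are excluded with a logged reason,
because tail quantiles of a handful of beats are noise. Sporadically
absent features are imputed by the column median with the mask recorded.

## PCA

The 144 quantile features are standardized to unit variance (spans,
amplitudes and slopes are on incommensurate scales, so this is PCA of the
correlation structure) and decomposed; the default keeps 8 components,
with a cumulative-variance rule available. Test rows always reuse
training means/scales. Each loading column is oriented so its
largest-|value| entry is positive, making signs reproducible across
linear-algebra backends. The T-type proportions never enter the PCA; they
are appended to the classifier input afterwards.

## Discriminant classification

Stepwise selection works on Wilks' Λ = det(W)/det(T) over the candidate
subset (W within-group, T total SSCP). The partial F for adding one
variable to p included ones is F = (n−g−p)/(g−1) · (Λₚ/Λₚ₊₁ − 1) with
(g−1, n−g−p) degrees of freedom; removal uses the same statistic in
reverse. Entry requires p < `slentry`, removal p > `slstay`, both
defaulting to 0.15 (the customary stepwise-discriminant default; the
thresholds are configurable). Entry stops when the residual degrees of
freedom would drop below 2; repeated states terminate the loop. Collinear
candidates have partial F ≈ 0 and never enter.

Class covariance homogeneity is tested with Box's M (chi-square
approximation) at threshold 0.10: rejection switches from the pooled
covariance (linear rule, g₁ = 0) to per-class covariances with
g₁(t) = ln |Sₜ| (quadratic rule). When a class has too few subjects to
estimate its own covariance (n ≤ dimension) the pooled rule is kept
without testing. Equal priors are assumed throughout, so the prior term
g₂ is identically zero. Singular covariances receive a ridge of
10⁻⁸·trace/dim, logged.

With the pooled covariance and two classes the rule is algebraically the
closed-form linear discriminant; the tests assert that equivalence
against an independent implementation.

The SVM (RBF kernel, C and γ by grid search on training-set
cross-validation) and L1-penalized logistic regression (penalty by
cross-validated deviance) baselines delegate to scikit-learn, with seeded
folds. The comparison design also includes a "mean features" arm — the 18
per-variable means plus T-type proportions — as the classical summary the
quantile features are measured against. Disease is the positive class in
all reports: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

## Synthetic data generator

`simulate_beat_table` is the testbed's ground truth, not a waveform
physiology model. Per beat: RR is truncated-normal (lower bound 0.3 s, a
physiological floor); each span is *β*·RRᵅ·exp(ε) with ε ~ N(0, noise_cv)
— multiplicative lognormal noise keeps spans positive and matches the
ratio form of the corrections, a deliberate divergence from the additive
error of the correction model itself; amplitudes and slopes are
mean + Gaussian noise with sd = noise_cv·max(|mean|, floor), the floors
(0.05 mV, 2 mV/s) keeping zero-mean segments jittered; the T type is
categorical.

The disease mechanism is a two-component mixture: with probability
`abnormal_fraction` a beat receives a location shift on selected
variables and a fourfold variance inflation — the simplest mechanism
producing the heavy-tailed and bimodal per-subject distributions the
quantile features target, while moving means only by
fraction × shift.

Default study conditions: 20 subjects per group with 200 beats each
(beat counts of the order of a few minutes of recording). Healthy: RR
1.0 ± 0.1 s, span scales β = {PR 0.16, QT 0.40, P 0.10, QRS 0.09,
T 0.18} s with the shipped exponents as generating α, 5% noise, 90%
normal T waves. Disease: RR 0.9 ± 0.15 s, 8% noise, 15% abnormal beats
shifted in QT (+0.08 s), PR (+0.04 s), T span (+0.05 s), T and R
amplitudes (−0.4 / −0.5 mV) and the T slopes, and a T-type mix with only
50% normal. These values are chosen as physiologically plausible
magnitudes for a mixed disease group; the generator makes no claim to
reproduce any particular patient population, and real delineated data
differ in ways the generator does not emulate: autocorrelated RR series
(respiratory sinus arrhythmia), delineation error in the fiducials,
baseline wander, and correlated measurement errors across variables
within a beat. Passing tests therefore demonstrate the correctness and
internal consistency of the procedure, not clinical performance.

`simulate_waveform` renders piecewise-linear beats (triangular waves on a
constant baseline) whose spans, amplitudes and slopes are known exactly
on the sampling grid; every breakpoint lands on an integer sample, so the
measurement stage must recover the ground truth to numerical precision.
Connecting segments (PR, ST, TP) sit on the baseline with slope zero.

## Problem sizes in the shipped tests

Monte-Carlo checks use 100 replications (exponent recovery at n = 500
beats; planted-feature selection at n = 100 per class among 20 noise
features), 200 replications for Box's M calibration (n = 200 per class,
dimension 3), and 25 replicated cohorts at the default study conditions
for the end-to-end accuracy ordering (quantile ≥ mean, PCA ≥ none, for
the discriminant). These sizes give stable rates while keeping the suite
quick to run.

## Known limitations

- Delineation itself is out of scope: annotations are consumed, never
  produced.
- The WFDB support covers a deliberate subset (text header + format-16
  samples; rdann-style text annotation streams).
- Binary classification only; multiclass disease labels and multi-lead
  joint analysis are not implemented.
- Quantile set is fixed; per-variable optimal quantile selection is not
  attempted.
- With strongly non-Gaussian class distributions the discriminant's
  normal-theory F thresholds are approximations; the stepwise procedure
  is a heuristic, as always.
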