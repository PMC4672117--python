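# ecgquant

Quantile-based feature extraction and discriminant classification for
delineated ECG heartbeats.

## The problem

Screening for cardiac disease from single-lead ECG recordings usually
proceeds in three steps: delineate each heartbeat (onset, peak, offset of
the P wave, QRS complex and T wave), measure each beat, and classify the
subject from a summary of those measurements. The almost universal summary
is the per-subject **mean** of each measurement. But diseased hearts do not
shift the whole distribution: most beats look normal and a minority are
abnormal, so per-subject distributions of intervals, amplitudes and slopes
become skewed, heavy-tailed or multimodal — structure that a mean cannot
see. `ecgquant` summarizes each measurement's distribution by its tail
quantiles instead, and classifies subjects with a stepwise discriminant on
the (optionally PCA-reduced) quantile features.

The package is for researchers working with delineated ECG databases
(e.g. PhysioNet-style records annotated by ECGPUWAVE) and for
methodologists who want a fully synthetic, ground-truth-controlled testbed
of the whole procedure.

## The method

Per beat, 19 features are measured: the T-wave morphology class (6
categories), six time spans (RR, PR, QT and the P, QRS, T wave widths),
three baseline-referenced amplitudes (P, QRS, T), and nine segment slopes
by least squares (Up-P, Down-P, PR, Up-R, Down-R, ST, Up-T, Down-T, TP).

Time spans depend on the beat period, so each span *y* is corrected by a
power law

&nbsp;&nbsp;&nbsp;&nbsp;*y* = *β*·RR*ᵅ* + *ε*, &nbsp; *y*꜀ = *y* / RR*ᵅ*,

with *α* selected on the grid {0, 0.1, …, 1.0} by R² on healthy subjects'
beats. The shipped exponents are QT 0.5 (Bazett's correction), PR 0.2,
P span 0.1, T span 0.5, QRS span 0 (uncorrelated with RR).

Each subject's corrected per-beat distributions are then summarized by the
eight sample quantiles p1, p5, p10, p25, p75, p90, p95, p99 — 18 numeric
variables × 8 quantiles = **144 features** — plus the six T-type
proportions. Optionally the 144 features are standardized and PCA-reduced
(default: first 8 components), with the top-loading features of each
component reported as candidate biomarkers.

Classification is by **stepwise discriminant analysis**: variables enter
and leave by the partial F statistic derived from Wilks' Λ, and a subject
*x* is assigned to the class *t* minimizing the generalized squared
distance

&nbsp;&nbsp;&nbsp;&nbsp;*D*ₜ² = (*x* − *m*ₜ)ᵀ *S*⁻¹ (*x* − *m*ₜ) + *g*₁(*t*),

where *S* is pooled unless Box's M test rejects covariance homogeneity, in
which case each class uses its own *S*ₜ with *g*₁(*t*) = ln |*S*ₜ| (equal
priors throughout). RBF-kernel SVM and L1-penalized logistic regression
are included as baselines.

## Worked example

A fully synthetic cohort where the **only** group difference is in the
tails: diseased subjects are identical to healthy ones except that 6% of
their beats carry a +0.04 s QT shift and a steeper Down-T slope:

```sh
cat > subtle.yaml <<'YAML'
healthy: {n_subjects: 25, beats_per_subject: 120}
disease:
  n_subjects: 25
  beats_per_subject: 120
  rr_mean: 1.0
  rr_sd: 0.1
  noise_cv: 0.05
  abnormal_fraction: 0.06
  abnormal_shift: {QT: 0.04, "Down-T-slo": 3.0}
  ttype_probs: [0.90, 0.02, 0.02, 0.02, 0.02, 0.02]
YAML
ecgquant simulate --config subtle.yaml --seed 7 --out subtle
ecgquant run-all --beats subtle/beats.csv --seed 7 --out results.csv
```

prints (sensitivity/specificity/accuracy on the held-out half, disease
positive):

```
         mean + sda  sens 100.00%  spec  46.15%  acc  73.08%
     quantile + sda  sens 100.00%  spec 100.00%  acc 100.00%
```

(plus the remaining grid cells). Mean features barely register a 6%-beat
contamination — the mean QT moves by only ~2.4 ms — while the p95/p99
features move by an order of magnitude more, so the quantile-based
discriminant separates the groups perfectly here. With the shipped default
disease group (slower-varying rhythm, shifted intervals, altered T-wave
type mix) every arm reaches high accuracy; this subtle configuration is
the instructive edge case.

Refitting the correction exponents on the healthy half of a default cohort
recovers the generating law:

```
variable  alpha  beta      r_square  n_beats
PR        0.2    0.16014   0.131251  5000
QT        0.5    0.400322  0.516287  5000
Pspan     0.1    0.100189  0.041645  5000
QRSspan   0      0.0900667 0.000000  5000
Tspan     0.5    0.180319  0.510604  5000
```

The library mirrors the CLI one stage per module: `ecgquant.simulate`
(synthetic cohorts and piecewise-linear waveform fixtures), `ecgquant.io`
(beat tables, WFDB-style records, annotation streams),
`ecgquant.measurements`, `ecgquant.rr`, `ecgquant.features`,
`ecgquant.pca`, `ecgquant.classify`, `ecgquant.pipeline`.

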