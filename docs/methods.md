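# Methods

## The procedure

`homacut` estimates a population reference cutoff for HOMA-IR
(= FPI [mU/L] × FPG [mmol/L] / 22.5) when no gold-standard insulin-
sensitivity measurement is available. The chain of assumptions is:

1. Insulin resistance manifests as a *joint* elevation of graded
   cardiometabolic risk factors, so a two-cluster partition of the graded
   matrix recovers the resistant subpopulation (pseudo-labels).
2. HOMA-IR is a noisy marker of the same latent state, so the cutoff that
   best agrees with the pseudo-labels — by maximum Matthews correlation
   coefficient (MCC) — is a sensible population reference value.

Both steps are unsupervised: nothing is fitted against a clinical
diagnosis. What the method yields is a reproducible, population-specific
operating point, not a validated diagnostic threshold.

## Grading

Each variable is mapped to an ordinal grade 1, 2, … against fixed clinical
thresholds; a value equal to a boundary falls in the *worse* grade (the
"≥ 126 mg/dL" convention). Defaults, overridable by a YAML scheme file:

| variable | thresholds | grades | notes |
|---|---|---|---|
| BMI (kg/m²) | 25, 30, 35 | 1–4 | overweight / obese I / obese II+ |
| waist/hip ratio | F: 0.80, 0.85; M: 0.90, 0.95 | 1–3 | sex-specific |
| FPG (mg/dL) | 100, 126 | 1–3 | normal / prediabetes / diabetes |
| triglycerides (mg/dL) | 150, 200, 500 | 1–4 | |
| total cholesterol (mg/dL) | 200, 240 | 1–3 | |
| HDL cholesterol (mg/dL) | F: 50; M: 40 | 1–2 | protective: scale reversed |
| SBP (mmHg) | 120, 140, 160 | 1–4 | |
| DBP (mmHg) | 80, 90, 100 | 1–4 | |
| ALT, AST (U/L) | 40 | 1–2 | upper limit of normal |
| FPI (mU/L), optional | 12 | 1–2 | confirmation variant only |

Grade ranges are consistent in magnitude with the published per-cluster
mean grades, but the exact encodings used in the original study are not
public; the cutoff-scan acceptance checks deliberately do not depend on
them. Sex and age are not graded or clustered (no association with
HOMA-IR in the reference analysis). Subjects missing any scheme variable
are excluded from clustering, with a reported count — no imputation.

Glucose is stored in mg/dL and divided by 18.0 exactly once, inside the
HOMA-IR computation; insulin is assumed to be in mU/L (≡ µU/mL), and no
pmol/L conversion is attempted.

## Clustering

Lloyd's algorithm, k = 2, Euclidean distance on the raw integer grades.
The grades are deliberately *not* re-standardized: grading is already the
standardization, and rescaling would re-weight the ordinal risk scale.
Initialization samples two distinct subjects per restart; 50 restarts by
default, keeping the minimum-WCSS solution (the original analysis used a
single deterministic run of a statistical package; best-of-restarts is
more robust and is this package's own choice). An empty cluster is
reseeded at the point farthest from the surviving center. Iterations are
capped at 300; WCSS monotonicity is asserted every iteration. The cluster
with the larger mean per-subject grade sum is labeled resistant (tie →
higher mean FPG grade; an exact double tie raises). Per-attribute
diagnostics are one-way two-group ANOVAs on the grades — F with df
(1, n−2), identical to the squared pooled-variance t statistic; zero
within-group variance with unequal means is flagged as a degenerate
boundary case with p = 0.

## Cutoff scan

A subject is called positive when HOMA-IR **strictly exceeds** the cutoff
(consistent with the "high" band being values *above* the upper bound;
configurable to ≥). The coarse grid is 0.30–7.80 in 0.25 steps (31
points); a fine scan at 0.05 steps spans one coarse step either side of
the coarse optimum. MCC ties are broken toward the larger cutoff, which
favors specificity and avoids over-labeling. MCC with any zero marginal
is defined as 0. The ROC curve is the scan's (1−specificity, sensitivity)
points plus the (0,0) and (1,1) anchors, integrated by trapezoid. Band
fractions are reported at a conventional lower bound (default 2.60) and
the fitted cutoff; when a fit lands at or below the lower bound the band
report is undefined rather than an error.

## Re-verifying the published scan

The packaged published scan prints sensitivity and specificity to 3
decimals at group sizes 795/1059. At these sizes the rounding is almost
injective: each printed rate pins down a unique integer count, except
that the integer grid spacing at n = 1059 (≈ 0.00094) is finer than the
0.001 rounding bin, so one row (cutoff 6.05, specificity 0.907) admits
two TN candidates (960, 961). Reconstruction is strict by default —
ambiguity raises, listing candidates — and the table verifier resolves
that single row with the printed MCC column, which is part of the same
published table. All 31 recomputed MCCs then agree with the printed
column to 3 decimals, and the recomputed argmax is 3.80 (MCC 0.400).

## Supervised screening

The outcome for screening is a binarized HOMA-IR — median split by
default (prevalence-balanced labels stabilize both trainers), or a fixed
threshold via configuration; how the original analysis binarized it is
unknown. Features are standardized to zero mean / unit variance so
|weight| ranks variables. Two trainers:

- **Linear max-margin classifier** — L2-regularized hinge loss
  (liblinear), linear kernel only, C = 1.0 default.
- **Laplace-prior Bayesian logistic regression (MAP)** — the penalized
  objective is the logistic negative log-likelihood plus λ·Σ|β|
  (Laplace prior density λ/2·e^{−λ|β|} per coefficient; intercept
  unpenalized). Solved by cyclic coordinate descent: per coordinate, a
  Newton-like step using an upper bound on the logistic curvature within
  a per-coordinate trust region (start 1.0, updated to
  max(2|step|, Δ/2)), with a soft-threshold test at zero so coefficients
  become and stay exactly zero. Convergence when the largest coordinate
  update in a sweep is < 1e-6; sweep cap 10 000; the objective is
  verified non-increasing every sweep. λ default 1.0.

Performance is stratified k-fold (default 5) cross-validated AUROC,
computed as the Mann–Whitney rank statistic (ties 0.5). Selection rules:
nonzero weights, top-m, or a weight floor. The selection is advisory —
the clustering variable list comes from the grading scheme — so pipeline
results never depend on a stochastic screen.

## Synthetic cohorts

The generator draws a latent class ~ Bernoulli(prevalence 0.43 default,
echoing 795/1854), then continuous covariates from class-conditional
equicorrelated normals: per variable, the class shift is
effect_size × multiplier × sd with multiplier ±1 (−1 for HDL, 0 for
age), effect_size 1.5 default, within-class equicorrelation ρ = 0.2,
clipped to physiological bounds. FPI and FPG are class-conditional
lognormal (control medians 8 mU/L / 92 mg/dL; resistant 17 mU/L /
108 mg/dL), putting the control HOMA-IR median near 1.8 and the
resistant median near 4.5, so sample oracle cutoffs land around 2.8–3.3.

The ρ = 0.2 default is constrained by the intended separation: for p = 9
informative variables at 1.5 sd shift, the Bayes-optimal accuracy under
equicorrelation is Φ(1.5·√(p/(1−ρ+ρp))/2) — about 0.92 at ρ = 0.2 but
only 0.89 at ρ = 0.3, below the ≥ 0.9 pseudo-label agreement these study
conditions are designed to exhibit; grading discretization costs a
further point or two.

What the generator does *not* emulate: real marginal shapes and skew,
variable-specific correlation structure (a single equicorrelation factor
stands in), measurement error, missingness, household/family clustering,
or any attempt to match the original cohort's moments. Passing recovery
tests therefore shows the pipeline is correct and well-calibrated under
its own assumptions — not that it reproduces the original cohort's
numbers, which are only re-verified at the level of the published scan
table.

## Problem sizes and numerics

Default test/demonstration sizes: n = 2000 cohorts, 50 K-means restarts,
25-seed recovery sweeps, 200 label permutations for null calibration;
brute-force clustering oracles run on 6–10-point toys where every
2-partition can be enumerated. Grid arithmetic builds the cutoff grid by
integer index to avoid floating-step drift. Fractional confusion counts
are permitted only in reconstruction contexts; scans always produce
integer counts.

## Known limitations

- The derived cutoff inherits whatever bias the grading thresholds and
  the two-cluster assumption carry; it is population-specific by design
  and should not be transported across populations.
- Exact reproduction of a single deterministic K-means run of the
  original analysis is not possible without the original data; the
  best-of-restarts optimum is used instead.
- No confidence interval accompanies the cutoff (no bootstrap), matching
  the reference procedure.
- The fine-scan step (0.05) and the supervised binarization rule are this
  package's documented choices where the reference analysis is silent.
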