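# Methods

This document records the models, parameters, units, and numerical
conventions used by `airway4d`.  All lengths are in cm, areas in cm²,
volumes in cm³, grid spacings in mm, and entropies in nats.

## 1. Synthetic cohort generator

### Demographics

The default cohort has 90 participants: 84 analyzed (28 male, 56 female) and
6 excluded for suspected obstructive sleep apnea (screening score above
threshold).  Categorical sleep-symptom tables are planted exactly by
construction, not sampled:

- snoring by sex (never/occasionally/consistently): male 13/5/10,
  female 38/11/7
- nocturnal gasping by sex: male 20/5/3, female 54/1/1
- gasping participants are a subset of snorers; "symptomatic" means
  occasional-or-consistent snoring (33 of 84).

Continuous covariates (age, height, weight, BMI, neck circumference,
inter-molar distance change `delta_d`) are drawn from sex-conditional normal
distributions; BMI is derived from height and weight rather than drawn.

### Geometry and planted effects

Each participant in each mouth position (closed/open) gets an airway
centerline with five landmarks (hard palate, superior soft palate, velum
tip, epiglottic tip, epiglottic base).  Morphometric ground truth is
generated by a linear effect model per metric; the defaults plant

- total airway length: intercept 6.59 cm, +1.36 male, +0.92 symptomatic,
  +0.51 open-mouth
- retropalatal minimum CSA: 1.89 cm², −0.28 male-interaction terms,
  −0.29 symptomatic, −0.15 open (narrowing with mouth opening)
- retroglossal minimum CSA: 3.38 cm² +0.74 male
- a male area-scale factor (+17%) that drives the volume difference

plus participant- and position-level Gaussian variation (clipped at ±3 SD).
Cross-sectional area along the airway follows a shape-preserving monotone
spline (PCHIP) through control points at normalized stations
(0, 0.18, 0.35, 0.55, 0.85, 1).  The station-0.18 point is the retropalatal
notch; stations 0.35–0.85 form a flat retroglossal plateau so the sliding
11-slice window minimum equals the planted value.  Area tapers linearly to
15% at the region-of-interest margins.

### Dynamics and rasterization

Respiratory fluctuation modulates the local airway radius as
`1 + a(z)·sin(2π·frame/period − φ(z))`, with per-region amplitudes `a`
calibrated so the within-series coefficient of variation (CV) of each
metric matches its target (closed/open): global 0.03/0.04, retropalatal CSA
0.06/0.12, retroglossal CSA 0.04/0.07, epiglottic volume 0.06/0.08.
Radius amplitudes convert from area-CV targets as
`a = CV / (2·√(20/38)) = CV / 1.4504`: area scales with radius squared
(factor 2 for small `a`) and a sinusoid sampled at 20 frames has
SD/amplitude = √(20/38) with ddof = 1.  Round-trip measurement confirms
each CV target within ~10%.  Regional phase lags
(0, π/3, 2π/3) decorrelate the regional fluctuations so composite metrics
(total volume, mean CSA) land near the global CV target rather than the sum
of regional ones.

Frames rasterize to a 64×64×72 grid at 1.25×1.25×2.0 mm.  Labels:
0 background, 1 airway lumen, 2 epiglottis.  The epiglottic label covers the
lumen ventral to a per-slice chord at `cy + 0.3·r(z)` between the epiglottic
tip and base.  Intensity images place the lumen darker than tissue with
Gaussian noise (σ = 0.05 by default).

Round-trip accuracy (generate → rasterize → measure, 30 participants):
level CSAs within ~1% of planted values, CVs within ~10% of targets.
Note: total airway volume (~25 cm³ median) is what the stated
region-of-interest rule implies for these planted lengths and areas; a
smaller volume target would be inconsistent with that rule, so the rule
wins.

## 2. Fingerprint partition and roles

Each image's fingerprint is its median foreground intensity (foreground =
voxels above the image mean).  Participants are summarized by their median
fingerprint, decile-shuffled into five groups of 18, and accepted when a
Kruskal–Wallis test across groups gives p > 0.05 (up to 100 reshuffles;
identical fingerprints give p = 1 by convention).  Group 1 splits uniformly
at random into 14 initial-training and 4 fixed-validation participants
(surplus participants join the generation-2 pool wave); groups 2–4 are the
generation-2/3/4 pool waves; group 5 is the untouched hold-out.  With
2 positions × 20 frames this yields 3600 total images: 560 initial
training, 160 fixed validation, 720 hold-out, 2880 non-hold-out.

## 3. Active-learning campaign

Per-voxel uncertainty is Shannon entropy over the 3-class posterior, in
nats (max ln 3).  An image's score is the **median** entropy over all its
voxels (optionally masked).  Each generation: the candidate pool gains the
wave's images, every pool image is re-scored under the current model, and
images scoring strictly above mean + 1 SD (SD with ddof = 1) are selected.
Newly selected images are labeled exactly once (the annotation callback);
previously trained images gain one extra training copy per qualifying
generation (a multiset).  Isolation is asserted every generation:
validation and hold-out images can never enter the pool or training set.
Bookkeeping identity maintained and tested: total training count = unique
count + cumulative re-selections.

The reference backend is an atlas/intensity model: a voxel-wise label prior
(the atlas) combined with per-class intensity likelihoods.  Its posterior is
sharpened with training mass `W` (multiplicity-weighted similarity between
the query and training images, Gaussian kernel on median-intensity distance,
bandwidth 0.08) via exponent `1 + 7·(1 − e^{−0.15·W})`, then blended with
the uniform distribution with weight `ε = 0.3·e^{−0.1·W}`.  The blend
preserves the argmax (Dice unaffected) while making image entropy strictly
decreasing in training mass, so pool entropy anneals across generations and
a genuine mean + 1 SD selection tail exists — the behavior an uncertainty
method needs from any backend.

## 4. Morphometry

From each label frame: total airway length (superior soft palate to
epiglottic base, from landmarks; the label-2 extent is the fallback),
epiglottic length, total and epiglottic volumes (voxel counts × voxel
volume), retropalatal and retroglossal minimum CSA via an 11-slice sliding
window of per-slice areas (window minimum of windowed means), mean CSA, and
the within-series CV of each metric over the 20 frames (SD/mean, ddof = 1;
zero-mean series are flagged and give NaN).

## 5. Comparison battery

`route_and_compare` routes on Shapiro–Wilk normality (α = 0.05, per sample
for unpaired, on the differences for paired) and Levene variance equality:
Student t / Welch t / Mann–Whitney U unpaired, paired t / Wilcoxon
signed-rank paired.  Parametric tests report t-based CIs; rank tests report
percentile-bootstrap CIs (the Wilcoxon CI is a bootstrap of the mean paired
difference — a pragmatic deviation from the Hodges–Lehmann estimator, noted
in the routing trace).  The battery covers 12 metrics × (paired
open-vs-closed + sex and symptom contrasts in each position) = 60 rows.

`fisher_exact_rxc` enumerates all tables with the observed margins
(depth-first over free cells, log-factorial probabilities, ≤ 2×10⁷ tables)
and sums probabilities ≤ the observed table's (slack 1e-12); a Monte Carlo
fallback is available for larger tables.  It is validated against an
independent brute-force enumerator and the standard 2×2 exact test.

**Known discrepancy:** on the planted tables the exact test gives
p = 0.0430 (snoring by sex) and p = 0.0025 (gasping by sex).  The recorded
targets 0.047 and 0.005 are reproduced exactly by a likelihood-ratio (G)
chi-square test, not by any exact-enumeration convention we could construct
(the common alternative convention gives 0.0404/0.0026).  We keep the exact
test as specified; the corresponding acceptance test fails and is expected
to.

Bootstrap CIs are percentile intervals (simple, paired, or stratified
resampling), seeded through named RNG substreams for reproducibility.
Kruskal–Wallis + Dunn post hoc (pooled ranks, tie correction, Bonferroni)
and a normality-routed Pearson/Spearman correlation for `delta_d` round out
the battery.

## 6. Predictor regression

Outcomes (7 means + 5 CVs) are winsorized at P1/P99; CV outcomes are
log-transformed first (zeros floored to the smallest positive value, count
reported); everything is Z-standardized.  The design has 0/1 binaries
(mouth position, male sex, symptomatic) and five standardized continuous
covariates.  LASSO with 10-fold cross-validation selects predictors at the
penalty minimizing mean CV error; folds are stratified by participant so a
participant's two position rows never straddle a fold.  The selected set is
refit by OLS with CR1 cluster-robust standard errors clustered on
participant (equals HC1 when every cluster is a singleton — tested to
1e-8).  Diagnostics report hand-computed VIFs (flagged above 10),
Shapiro–Wilk on residuals, and a Breusch–Pagan test.

## 7. Numerical conventions

- Entropies in nats; ln 3 is the 3-class maximum.
- Sample SDs use ddof = 1 throughout.
- Selection uses strict `>` against mean + 1 SD (all-equal scores select
  nothing).
- RNG streams are named substreams of a single seed (`SeedSequence` with a
  hashed spawn key), so stages are independently reproducible.
- NIfTI volumes store labels as uint8 and intensities/probabilities as
  float32; probability maps are validated to sum to 1 (atol 1e-6).
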