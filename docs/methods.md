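# Methods

This note documents the models, the synthetic-data generator, the
numerical conventions, and the design decisions behind `respsig`, in the
spirit of a statistical package's model documentation. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The statistical chain

The pipeline estimates, from a two-arm mouse experiment and a paired
human cohort, whether a peripheral-blood expression signature of
antidepressant response transfers across species and whether it is
enriched for glucocorticoid-receptor (dexamethasone) responsive genes.

**Extreme-phenotype stratification.** Within the treated arm, animals are
ranked by forced-swim-test floating time (the depression-like readout of
the 5-minute assay); the k = ⌊fraction·n⌋ lowest become good responders
and the k highest poor responders, fraction defaulting to 0.20. Ties are
broken by stable animal-id order — the underlying behavioural scores are
continuous, so ties only arise in constructed data, but the rule must be
deterministic for reproducibility.

**Per-probe inference.** Expression (on the variance-stabilized scale) is
modelled probe-wise as ordinary least squares on a two-level group
indicator plus nuisance covariates: bead-chip id (categorical,
dummy-coded against a reference level) and drug concentration
(continuous, centred). The group term's t-test is identical to the
two-level ANOVA F-test, which is why the design enforces exactly two
levels. Probes with zero residual degrees of freedom or zero residual
variance are flagged degenerate and assigned p = 1. Benjamini–Hochberg
step-up q-values (q_(i) = min_{j≥i} p_(j)·n/j, capped at 1) control the
FDR; signatures are the probes below q < 0.1 (discovery) or q < 0.05
(stringent), ordered by ascending q then probe id.

Missing plasma drug concentrations are imputed from brain concentrations
by OLS on the animals with both measurements; the fit (intercept, slope,
r²) is logged. Imputation is exact on noiseless linear data and unbiased
on noisy linear data (a tested property).

**Cross-tissue comparison.** Signature probes measured in both blood and
brain are summarized by their two per-tissue group differences; rows are
ordered by agglomerative complete-linkage clustering on Euclidean
distances, and the blood–brain correlation of differences is reported.
With brain signal simulated independently of blood, this correlation is
null — the qualitative pattern the visualization is designed to expose.

**Signature transfer and classification.** Mouse probes map to mouse
genes, to human orthologue genes, to every human probe of those genes
that survives human QC; unmapped probes are dropped and counted. The
per-patient feature is |week12 − baseline| expression on the panel
(absolute by default; a signed mode exists). Patients split into
stratified halves (train gets the extra patient on odd n; class
proportions differ by at most one). The classifier is a soft-margin SVM
with RBF kernel k(u,v) = exp(−γ‖u−v‖²), γ = 0.001, C = 10, features
standardized with training-set statistics (zero-variance features are
dropped with a warning). Two nulls calibrate the observed test accuracy:

* label permutation — training labels shuffled m times, the classifier
  fully refit each time;
* random feature panels — k size-matched probe sets drawn uniformly
  without replacement from the post-QC universe, features rebuilt, the
  classifier retrained on the same split.

Both use the add-one estimator p = (b + 1)/(m + 1) with b the count of
null accuracies **greater than or equal to** the observed one. The
add-one form is never zero and is a valid p-value under exchangeability.

**Enrichment.** The common content is the exact intersection of the two
experiments' probe ids. With universe N, dex-regulated K, signature n and
overlap k, the 2×2 table (k, n−k, K−k, N−K−n+k) feeds three tests: a
Monte-Carlo null of m random size-n sets (exceedance **strictly
greater**, matching the convention of the emulated analysis, unlike the
classifier nulls' equal-or-better — both conventions are explicit
parameters), the exact hypergeometric upper tail P(X ≥ k), and an exact
binomial test on the count of sign-concordant overlap probes (two-sided
by default, one-sided available; probes with a zero effect sign on either
side are excluded with a logged count).

## The synthetic-data generator

Expression is generated directly on the post-transform scale as Gaussian
— the analysis operates entirely on transformed data, and raw-scale
intensities for testing the transform are produced by inverting the
generalized log. Defaults mirror the emulated study design: 12 good, 12
poor and 36 intermediate treated animals (so the 20 %-extremes rule
re-derives exactly the planted groups from a 60-animal arm) plus 12
vehicle controls; 86 patients with responder probability 63/86; 259
planted signal probes; brain/plasma concentration correlation 0.94; four
missing plasma values; dex margins emulating a 2,852-probe common content
with ~66 % regulated, an overlap boost of 0.09 on signature probes and a
72 % sign-concordance rate; orthology with ~1.07 mouse probes and ~1.2
human probes per gene at a 93 % mapping rate. Probe universes default to
5,000 (mouse) and 6,000 (human) — the scale of the post-QC inference
universes rather than raw arrays, which keeps simulation studies fast
without changing any statistical property of the methods.

Key structural choices:

* **Effects are standardized per measurement.** `effect_blood` and
  `effect_human` multiply the residual `noise_sd` (0.5 transform units by
  default). A planted blood effect of 2 therefore means a group-mean
  difference of 1.0 transform units. Note that for paired human features
  the baseline→week-12 *difference* has standard deviation √2·noise_sd,
  so a shift of e sd per measurement is e/√2 sd of the feature.
* **Batch and concentration enter additively**: a scalar per-chip offset
  (SD 0.2) shared across probes, and a linear concentration term for
  treated animals only (vehicle animals receive no drug and no
  bioavailability variance).
* **Floating times are drawn from non-overlapping ranges** per group
  (good 40–90 s, intermediate 95–175 s, poor 180–240 s), so stratification
  labels are unambiguous; `mixed_floating` draws all treated animals from
  one range to exercise tie and overlap handling.
* **Detection p-values are bimodal by construction**: detected probes get
  Beta(0.5, 10) values, a configurable fraction of probes get
  Uniform(0.3, 1) everywhere and can never pass a detection rule. Planted
  signal probes are always detectable, so the planted truth is
  recoverable downstream.
* **Responder status is Bernoulli** per patient; HDRS-17 scores are then
  generated so the ≥ 50 % improvement rule reproduces the drawn status
  exactly (responders: 55–90 % improvement, floored; nonresponders:
  −15–45 %, ceiled).
* **Per-stage sub-seeds** come from
  `SeedSequence([master_seed, crc32(stage_name)])`, so any generator can
  be re-run in isolation and the whole bundle is byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mean–variance coupling of raw bead intensities
(per-probe noise is homoscedastic, so the 5 % variance filter removes far
fewer probes than on real arrays), probe cross-correlation and pathway
structure, cell-type composition shifts, array spatial artifacts,
nonlinear batch effects, and attrition/QC failure of samples. Planted
effects are independent across probes, which makes classifier power
estimates optimistic relative to correlated real signatures.

## Reference fixtures

Deterministic constructed fixtures (in `respsig.fixtures`, labelled
synthetic) reproduce the translation cardinality chains (259 mouse probes
→ 241 human orthologue genes → 288 post-QC probes; 85 → 77 genes → 66 QC
genes → 92 probes) and the enrichment margins (2,852 / 1,882 / 179 / 134
with 96 concordant and 38 discordant signs). They exist to verify the
counting machinery against exact expected values, not to simulate data.

## Numerical and design conventions

* The generalized log uses c = median raw intensity by default; the
  transform is strictly monotone with closed-form inverse
  x = 2^y − c²/2^{y+2}, round-tripping to 1e−9 relative tolerance. The
  affine-calibrated arsinh of the original normalization method is not
  re-implemented: downstream statistics need only approximate variance
  stabilization.
* "Variance > 5 %" is read as the relative-SD slider of array-QC tools:
  retain probes with SD ≥ 5 % of the maximum probe SD of the **current**
  matrix. Because the reference point is matrix-dependent, pipeline order
  is fixed (detection → transform → variance) and contract-tested.
* The human detection sentence in the emulated protocol reads as removing
  well-detected probes; this is treated as a typo and implemented as
  *retain* probes detected at p < 0.01 in ≥ 10 % of samples, matching the
  mouse rule and standard practice.
* Batch adjustment is per-probe location/scale standardization (each
  batch centred to the probe's grand mean, variances matched to the
  pooled within-batch variance), not empirical-Bayes shrinkage; with the
  ≥ 10 samples per batch typical here the two agree closely and the
  simpler contract is exactly testable. Batches of one sample are an
  error.
* Phenotype outliers are values outside mean ± 1.96·SD of the
  observations (population SD), a tolerance-interval reading of a "95 %
  interval" — a literal confidence interval of the mean would exclude
  nearly everything at these group sizes.
* q = 0 is floored at the smallest positive double before −log10 for
  volcano output.
* The paroxetine-vs-vehicle contrast reuses the same OLS machinery with a
  different design; its variance-filter universe differs from the
  good-vs-poor one because filtering is applied per contrasted sample
  subset.
* The random-panel sampling universe defaults to the full post-QC human
  probe set (classification) and the common content (enrichment); both
  are parameters.
* The train/test split procedure and seed of the emulated analysis are
  unknown, so observed point accuracies are treated as non-reproducible;
  all validation is property-based (calibration under nulls, power under
  planted signal, determinism under fixed seeds).

## Problem sizes used in validation

The test suite exercises the chain at reduced Monte-Carlo depth chosen as
standard desk-scale working points: 100 null cohorts for calibration
checks, 20 seeds for power checks, m = 200 permutations / 200 random
panels per cohort, 5,000-probe mouse universes, and 100,000 draws for the
study-margin enrichment null. `scripts/acceptance.py` runs the full
pipeline at the analysis's own depths (10,000 / 1,000 / 100,000).

## Known limitations

* Classifier significance under small cohorts with very strong planted
  structure is conservative: label permutations that happen to align with
  the latent clusters still classify well, fattening the null's upper
  tail. This is a property of permutation tests on clustered data, not a
  bug; it disappears as signal strength drops to realistic levels.
* Probe-wise OLS with n = 24 uses exact t inference with no variance
  moderation (deliberately out of scope). At a planted standardized
  effect of 2 and 5,000 tests, BH recovery at q < 0.1 plateaus near ~84 %
  (computable from the noncentral-t tail; measured by the power check in
  the acceptance suite) — variance-shrinkage estimators would be needed
  to push sensitivity higher at these group sizes.
* The location/scale batch adjustment assumes batch effects are additive
  per probe; interaction-style batch effects are outside its contract.
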