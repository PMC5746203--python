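# respsig

Cross-species blood transcriptome signatures of antidepressant treatment
response: a tested, reusable implementation of the full discovery chain —
extreme-phenotype stratification of treated mice, covariate-adjusted
differential expression with FDR control, orthologue transfer of the
resulting probe signature to a human cohort, permutation-validated
SVM classification of human treatment response, and enrichment of the
signature for dexamethasone-regulated (glucocorticoid-receptor
responsive) genes.

The package is aimed at computational biologists who want to study or
stress-test this class of cross-species biomarker analyses. Because the
original microarray and clinical data are not publicly deposited, a
first-class synthetic-data module generates cohorts with the same
statistical structure (planted responder effects, batch offsets, drug
concentration covariates, paired human baseline/week-12 expression,
orthology maps, and a dexamethasone regulation table), so every stage is
testable end to end with no downloads.

## The analysis

1. **Stratification.** Treated mice are ranked by forced-swim-test
   floating time; the lowest 20 % are *good* and the highest 20 % *poor*
   responders (k = ⌊0.2 n⌋ per extreme).
2. **Preprocessing.** Probes must be detected (detection p < 0.05 in at
   least 4 samples; human arrays: p < 0.01 in at least 10 % of samples),
   intensities are variance-stabilized with a generalized log
   `glog(x) = log2((x + √(x² + c²))/2)`, and probes with standard
   deviation below 5 % of the largest probe SD are dropped.
3. **Differential expression.** Per probe, OLS of expression on the
   good/poor indicator plus nuisance covariates (bead chip, paroxetine
   plasma concentration — missing concentrations imputed by regressing
   plasma on brain concentration):
   `y = β₀ + β_g·group + Σ γ_j·cov_j + ε`. The two-sided t-test on β_g
   gives p; Benjamini–Hochberg step-up q-values define signatures at
   q < 0.1 and q < 0.05.
4. **Translation and classification.** Mouse signature probes map through
   orthologue genes to human array probes. Features are per-patient
   absolute baseline→week-12 expression changes |Δ|; responders are
   patients with ≥ 50 % HDRS-17 improvement. A soft-margin RBF SVM
   (γ = 0.001, C = 10) is trained on a stratified half split and scored
   on the other half. Significance comes from two nulls: 10,000
   training-label permutations and 1,000 size-matched random probe
   panels, with add-one p-values `p = (b + 1)/(m + 1)`.
5. **Enrichment.** Within the common probe content of the response and
   dexamethasone experiments, the signature/dex overlap k is referred to
   100,000 random size-matched probe sets (exceedance strictly greater),
   the exact hypergeometric upper tail P(X ≥ k), and an exact binomial
   test of sign concordance between the two contrasts.

## Worked example

```python
from respsig import SimulationConfig, simulate_cohort_bundle
from respsig.preprocess import MOUSE_DETECTION_RULE, detection_filter, variance_filter
from respsig.phenotype import stratify_extremes, impute_plasma_from_brain
from respsig.diffexpr import ProbewiseDE, DesignSpec

cfg = SimulationConfig(seed=1, n_probes_mouse=2000, n_probes_human=3000,
                       n_signal_probes=100)
bundle = simulate_cohort_bundle(cfg)

blood = detection_filter(bundle.mouse_blood, MOUSE_DETECTION_RULE)
ann = stratify_extremes(bundle.mouse_annotation, 0.20)
treated = impute_plasma_from_brain(ann[ann["arm"] == "paroxetine"])
gp = treated[treated["responder"].isin(["good", "poor"])]

model = ProbewiseDE(
    variance_filter(blood.subset_samples(gp["animal_id"]), 0.05), gp,
    DesignSpec("responder", ("poor", "good"),
               categorical_covariates=("chip_id",),
               continuous_covariates=("plasma_conc",)))
print(model.fit().summary())
```

```
Probewise differential expression (OLS, two-group contrast)
============================================================
contrast:        responder (good - poor)
covariates:      ['chip_id', 'plasma_conc']
probes tested:   1900
residual df:     17
degenerate:      0
q < 0.10:        87
q < 0.05:        74
min q:           9.67e-05
```

Of the 100 planted responder-associated probes, 87 are recovered at
q < 0.1 (74 at q < 0.05) from 12 good vs 12 poor responders after
detection and variance filtering (2000 → 1900 probes). Running the whole
chain instead:

```python
from respsig import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(
    master_seed=1, simulation=cfg, m_label=200, k_random=200, m_enrich=10_000))
```

yields (from `report.stages`): held-out classification accuracy 0.953 on
the q < 0.1 orthologue panel with label-permutation p = 0.005 and
random-panel p = 0.005 (null median accuracy 0.72, the majority-class
rate); signature/dex overlap 76 of 101 against a mean chance overlap of
66.9 (permutation p = 0.016, hypergeometric p = 0.029), with 56 of 76
shared probes regulated in the same direction (binomial p = 4.4e-05).

The same chain is scriptable:

```bash
respsig run --seed 1 --m-label 200 --k-random 200 --m-enrich 10000 --out runs/demo
respsig simulate --seed 1 --out data/bundle   # synthetic study as TSVs
```

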