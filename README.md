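# lumpsplit

Statistical support for **lumping vs splitting** decisions in syndrome
delineation: given two groups of patients with variants in the same gene,
should they be curated as one disease entity or two?

The package combines three lines of evidence used in modern
genotype–epigenotype–phenotype workup of rare neurodevelopmental
disorders:

1. **Facial phenotype descriptors.** Each frontal facial photo is
   represented (by a next-generation phenotyping model such as
   GestaltMatcher) as an ensemble of twelve 512-dimensional descriptors
   spanning a clinical face phenotype space.  Facial similarity between
   images *i* and *j* is the mean ensemble cosine distance

   d(i, j) = (1/12) Σₖ (1 − cos(xᵢₖ, xⱼₖ)),

   and the distance between cohorts C₁, C₂ is the mean of d(i, j) over
   all cross pairs.  A decision threshold *c* is calibrated by ROC/Youden
   analysis of two resampled control distributions (random two-way splits
   of single syndromes vs random group pairs from different syndromes)
   under syndrome-level five-fold cross-validation.  For a candidate
   cohort pair, 100 random subgroup pairs quantify decision uncertainty:
   if more than half of the subgroup distances exceed *c* the evidence
   favours **split**, and a positive predictive value is estimated from
   the pooled validation control distributions via
   PPV = sens·p / (sens·p + (1 − spec)(1 − p)) at pre-test probability
   p = 0.5.

2. **Clinical phenotype frequencies.** 2×2 affected/unaffected tables per
   clinical feature, tested with a two-tailed Fisher's exact test
   (sum of hypergeometric point probabilities ≤ that of the observed
   table) at a Bonferroni-corrected level α/m.  The published frequency
   table for 56 individuals with MN1 truncating variants (C-terminal vs
   N-terminal truncation groups) ships as a packaged fixture.

3. **DNA-methylation episignatures.** Probe-wise moderated-*t*
   differential methylation (empirical-Bayes variance shrinkage, BH FDR,
   covariate principal components) on beta matrices selects a signature
   (q ≤ 0.05, |Δβ| ≥ 0.05); a linear SVM with sigmoid-calibrated margins
   scores samples in [0, 1], classifying them as case-like above 0.5.

Because real descriptor and methylation datasets of this kind are
access-restricted, the package includes first-class synthetic generators:
directional syndrome/patient/image clusters on the unit 512-sphere and
beta matrices with planted differentially methylated probes plus latent
confounder structure.

## Worked example

```sh
lumpsplit simulate-cfps --seed 3 --out desc.tsv
lumpsplit calibrate --descriptors desc.tsv --seed 4 --out calib.json
# a.txt/b.txt: image ids of the two candidate cohorts, one per line
lumpsplit compare --descriptors desc.tsv --cohort-a a.txt --cohort-b b.txt \
    --calib calib.json --seed 5 --out decision.json
lumpsplit clinical --out report.csv
```

prints

```
wrote 240 images to desc.tsv
threshold c = 0.4478 (fold 0; validation sens 1.000, spec 1.000)
d = 0.9957 vs c = 0.4478; 100% of subgroup distances above threshold; verdict: split (PPV 97.75%)
8/25 features significant at alpha/m = 0.0028
```

Reading the output: calibration on the synthetic collection (40 syndromes,
3 patients × 2 images) finds the distance threshold *c* = 0.4478 separating
same-syndrome from different-syndrome control distances, with perfect
held-out sensitivity/specificity at this (well-separated) simulation
setting.  The two candidate cohorts — here, two different synthetic
syndromes — sit at ensemble distance 0.9957, every one of the 100 resampled
subgroup pairs stays above the threshold, so the method votes **split**
with an estimated 97.75% probability that the cohorts are truly distinct.
The clinical command reproduces the published MN1 phenotype table: 8 of 25
features differ between the C- and N-terminal truncation groups at the
Bonferroni level 0.05/18 = 0.0028.

The same steps are available as library calls (`lumpsplit.generate`,
`lumpsplit.calibrate` / `SplitThresholdCalibrator`, `compare_cohorts`,
`compare_phenotypes`, `differential_methylation`, `train_classifier`, …);
the estimators follow scikit-learn conventions (`fit`, `get_params`,
fitted attributes with trailing underscores).

## Documentation

`docs/methods.md` describes the statistical model, the synthetic data
generators and their limitations, parameter defaults, and numerical
conventions.
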