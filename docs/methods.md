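# Methods

## Ensemble cosine distance on facial phenotype descriptors

Each facial image *i* enters the analysis as twelve 512-dimensional
descriptor vectors x₍ᵢ,ₖ₎ (an ensemble produced by test-time augmentation
of a facial phenotyping network; the package consumes descriptors, it
never touches pixels).  The image distance is the mean of the twelve
per-slot cosine distances and lies in [0, 2]; the cohort distance
d(C₁, C₂) is the mean image distance over all |C₁||C₂| cross pairs.
Because both are cosine-based they are invariant to positive rescaling of
any descriptor; internally each slot is unit-normalised once and all
pairwise distances reduce to a single matrix product, which keeps full
pairwise matrices cheap at the cohort sizes involved (tens to a few
hundred images).  Applying the cross-pair formula literally, an image
present in both cohorts contributes zero-distance self pairs; callers that
need disjoint cohorts must enforce disjointness (the decision step does).

Gallery ranking sorts candidate images by ascending distance to a probe;
exact ties are broken lexicographically by image id so rankings are
deterministic.

## Threshold calibration

Two control distributions anchor the decision:

* **same-syndrome**: for each syndrome, its images are randomly divided
  into two nonempty groups (each image to a side with probability ½,
  resampled while a side is empty), 10 repetitions per syndrome;
* **different-syndrome**: for each unordered pair of syndromes, one group
  of uniform random size (1 … all images) is drawn from each side,
  5 repetitions per pair.

Duplicate comparisons — the same unordered pair of image-id sets — are
removed within each distribution.  Syndromes require at least two distinct
patients to enter calibration, and folds are formed at syndrome level
(5 folds, sizes differing by at most one syndrome) so that no patient's
images straddle the train/validation boundary.

Per fold, the threshold maximises the Youden index J(c) = sensitivity(c)
+ specificity(c) − 1 on the training distributions, where a
different-syndrome distance counts as detected when strictly above c and
a same-syndrome distance as correctly lumped when at or below c (a
distance exactly equal to the threshold therefore lumps — the
conservative reading of an open boundary).  Candidate thresholds are the
midpoints between consecutive distinct pooled distances plus sentinels
below and above all data, making the argmax well defined; Youden ties
break toward the smallest threshold, favouring sensitivity.  AUC is the
Mann–Whitney rank statistic.  The same sampling schemes are applied to
the held-out fold, and the fold with the highest validation Youden index
supplies the operational threshold.  Validation-side distributions from
*all* folds are pooled for downstream predictive-value estimation, since
predictive values should reflect held-out rather than training behaviour.

## Split decision, PPV and downsampling

For two disjoint candidate cohorts the pipeline computes d(C₁, C₂) and
draws 100 subgroup pairs: subgroup sizes are independent uniform draws on
[1, |C|] per cohort and images are sampled without replacement within a
draw (repeats across draws are allowed; the dedup rule applies only to
control-distribution construction).  The verdict is **split** when the
proportion of subgroup distances strictly above the threshold exceeds
50%.  The PPV of the observed subgroup-distance range [min, max] uses
range-based probabilities from the pooled validation controls —
sensitivity = fraction of different-syndrome distances inside the closed
range, specificity = fraction of same-syndrome distances outside it —
each clipped to [1/(n+1), n/(n+1)] so a finite sample never produces the
degenerate probabilities 0 or 1, then the Bayes formula at pre-test
probability 0.5 (no prior preference for lumping or splitting).  A
degenerate range (min = max) is a point query with the same clipping.

The downsampling analysis draws n patients per cohort (all images of a
sampled patient are included; with one image per patient this is
image-level sampling) for 1 ≤ n ≤ min cohort size, 100 draws per n, and
summarises median, IQR, standard deviation and the proportion of draws
above threshold.  Decisions where either cohort contains a single patient
are flagged low-confidence but still reported.

## Synthetic clinical face phenotype space

The generator emulates the syndrome → patient → image hierarchy as
directional clusters on the unit 512-sphere.  Syndrome mean directions
are uniform on the sphere — in 512 dimensions two random directions are
nearly orthogonal, so distinct syndromes sit at ensemble distance ≈ 1,
matching the scale real descriptor cohorts exhibit.  Patient means tilt
away from their syndrome mean by a tangent-space Gaussian perturbation,
and each image's twelve slots tilt away from the patient mean with an
additional independent per-slot jitter.  All spread parameters are
angular dispersions in radians: noise has per-coordinate standard
deviation spread/√512, so its expected norm — and hence the typical tilt
of a unit direction — equals the parameter.  Tangent-space Gaussian +
renormalisation was chosen over an exact directional distribution because
only relative separations matter under the cosine metric.  Defaults (40
syndromes, 3 patients × 2 images, within-syndrome spread 0.15, within-
patient spread 0.05, slot jitter 0.02) describe a strongly separated
benchmark: within-syndrome distances are two orders of magnitude below
between-syndrome distances.  What passing tests at these settings show is
that the statistical machinery is correct and well-calibrated when
cluster structure is present; they do not show how the method behaves at
the much smaller real-world separation between overlapping syndromes,
where the paper-scale distributions overlap and specificity is materially
below 1.  The generator makes no attempt to mimic the spectral statistics
of real network embeddings.

## Clinical contingency testing

The two-sided Fisher exact p-value is the sum of hypergeometric point
probabilities, at fixed margins, over all tables whose point probability
is at most that of the observed table times (1 + 1e-7) — the dominant
convention, implemented by direct enumeration of the support.  This
convention reproduces the published MN1 table at 4-decimal precision for
22 of 25 rows; the packaged fixture marks the three non-reproducible rows
(`verified=False`) and the test suite treats "<0.0001" rows as bounds.
Significance uses the Bonferroni level α/m with the published divisor
m = 18 as default; the row set behind that divisor is not recoverable
from the table itself, so m is a parameter.

## Episignature discovery and scoring

Beta matrices (probes × samples, values in [0, 1]) are compared probe-wise
between discovery cases and controls with the linear model
β ~ intercept + group + PC1 + PC2, where PC1/PC2 are principal-component
scores of the discovery samples over all probes — stand-ins for age, sex
and blood-cell-composition structure.  Residual variances s²_g on d
degrees of freedom are shrunk toward an empirical-Bayes prior:
s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d), with (d₀, s₀²) estimated by
moment-matching the log variances to a scaled F distribution (trigamma
inversion by Newton iteration; when the observed dispersion of
log-variances does not exceed chi-square sampling noise the prior df is
infinite and s₀² is the mean variance).  Moderated t uses the posterior
variance on d + d₀ degrees of freedom (capped at the pooled residual df);
two-sided p-values are Benjamini–Hochberg adjusted.  Constant probes
receive Δβ = 0 and t = 0 by convention.  Δβ is the raw case-minus-control
mean difference, deliberately unadjusted so the selection threshold
|Δβ| ≥ 0.05 refers to the observable methylation scale.

The signature is the probe set with q ≤ 0.05 and |Δβ| ≥ 0.05 (non-strict
inequalities; both thresholds configurable), ordered by ascending q then
descending |Δβ|.  The classifier is a linear soft-margin SVM on the
signature-site betas — linear is the convention for episignature
classifiers, and with tens of probes and tens of samples a more flexible
kernel would only invite overfitting — whose margins are mapped to [0, 1]
by a Platt-style logistic sigmoid fitted on the training margins.  Scores
above 0.5 classify as case-like, below as not-case; exactly 0.5 is
reported as indeterminate since the rule leaves the boundary undefined.

The beta-matrix generator plants `n_signature` probes with a +Δβ shift in
case samples on baselines drawn from (0.15, 0.75) (background baselines
from (0.1, 0.9)), Gaussian noise, and two latent sample-level confounder
factors (loading sd 0.02 per probe) that affect all samples independently
of group — this is the structure the covariate PCs are meant to absorb,
and without it the leading components would align with the group contrast
itself in small simulated matrices.  Values are clipped to [0, 1].
Samples carry discovery/validation/test roles; "test" samples are
case-labelled but signature-free, emulating a molecularly distinct
subgroup.  The generator draws all probes independently, so it does not
reproduce the genomic autocorrelation, beta-value bimodality, or
array-batch structure of real EPIC data; recovery results on it bound the
method's correctness, not its field performance.

## Problem sizes and numerical choices

Synthetic benchmarks use 40 syndromes × 3 patients × 2 images for
calibration (5 replicates), 20 replicates for decision operating
characteristics, 10 for downsampling and episignature recovery, and
2,000-probe matrices with 9 discovery cases vs 41 controls, 1 + 79
validation samples and 5 signature-free test samples — the design sizes
of the motivating study, with the probe count chosen so the full suite
runs in seconds.  All distances are computed in double precision;
repeated calls on identical inputs are bit-identical.  Every stochastic
step takes an explicit seed (NumPy `default_rng`); estimator classes
follow scikit-learn's `random_state` convention.

## Known limitations

* The calibrated threshold is only as good as the reference collection of
  curated syndromes; the package does not curate images or re-derive any
  training/validation split of a descriptor database.
* PPV estimates inherit the resolution of the pooled control
  distributions; with few validation syndromes the clipping constant
  1/(n+1) dominates.
* The episignature module assumes a pre-filtered, normalised beta matrix
  (probe QC, SNP/cross-reactive removal and normalisation are upstream);
  it does not parse IDATs or handle array manifests.
* Verdicts from single-patient cohorts are statistically meaningful under
  the model but flagged low-confidence, as inter-individual variation is
  then indistinguishable from inter-syndrome variation.
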