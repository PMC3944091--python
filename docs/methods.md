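# Methods

`prolifsig` implements a prognostic-comparison pipeline for lymph-node-negative
breast cancer: commercial-signature-derived risk groups (an Oncotype-DX-style
recurrence score and a MammaPrint-style classification) are compared against
direct proliferation markers (mitotic activity index MAI, phosphohistone-H3
counts PPH3, Ki67 percentage) on distant-metastasis-free survival (DMFS),
together with a supervised gene-selection / cross-validation stage and a
synthetic cohort generator that makes every stage testable without access to
patient data.

## Endpoint

DMFS is the time from diagnosis to distant metastasis or breast-cancer death.
Death from other causes, locoregional recurrence, second primaries and
contralateral disease censor at the last follow-up visit; a confirmed
metastasis without a recurrence date is counted as an event at the last
follow-up visit. `survival.encode_dmfs` accepts either an already-encoded
table (`follow_up`, `dmfs_event`) or an `event_type` column with these rules.

## Recurrence score

The 21-gene recurrence-score algorithm combines 16 cancer-related genes into
four group scores and three single-gene terms:

```
GRB7 group   = 0.9·GRB7 + 0.1·ERBB2
ER group     = (0.8·ESR1 + 1.2·PGR + BCL2 + SCUBE2) / 4
PROLIF group = mean(BIRC5, MKI67, MYBL2, CCNB1, AURKA)
INV group    = (CTSL2 + MMP11) / 2

RS_u = 0.47·GRB7g − 0.34·ERg + 1.04·PROLIFg + 0.10·INVg
       + 0.05·CD68 − 0.08·GSTM1 − 0.07·BAG1
```

The original assay computes these on reference-normalized qPCR ΔCt values
with floors (GRB7 group ≥ 8, proliferation group ≥ 6.5) and a 0–100 rescale.
Applied to microarray data the pipeline computes RS_u on per-gene z-scored
log2 expression; because risk groups are subsequently derived from ROC
cut-offs, only the ordering of RS_u matters, so the floors and rescale are
off by default (`apply_floors=True` restores the floors for qPCR-scale
input). RS_u is linear in the expression scale and strictly increasing in
the proliferation group and decreasing in the ER group — both properties are
asserted by tests.

## AGPP and two-cluster MammaPrint-style classification

Two alternative groupings over the MammaPrint-mapped genes are provided and
both are reported:

* **AGPP correlation**: the average gene-expression profile of patients with
  and without distant metastasis forms two centroids; each sample is assigned
  to the class whose centroid it correlates with more strongly (Pearson by
  default, Spearman with average ranks optional; exact ties go to the
  good-prognosis class, favouring the lower-treatment-intensity call).
  Because the centroids are computed from the cohort's own outcome labels,
  the resulting grouping is resubstitution-biased: its log-rank p-value is
  optimistic by construction. It is therefore shown in the report but
  excluded from the multivariate candidate set and from prognostic-ordering
  comparisons.
* **Two-cluster analysis**: agglomerative clustering of samples on the
  signature genes with 1 − correlation distance and average linkage (the
  convention of the dChip package that popularized this workflow; linkage
  configurable); the tree is cut into its two main clusters and the cluster
  with the higher observed event proportion is labelled high-risk. This
  grouping is outcome-blind up to the final cluster labelling and is the
  MammaPrint representative used in comparisons.

## ROC stratification

Scores are positively oriented; a sample is test-positive when its score is
at or above the threshold. The ROC curve enumerates one threshold at the
midpoint between every pair of adjacent distinct scores plus ±∞ sentinels,
so every achievable confusion table appears exactly once; AUC is computed by
the trapezoid rule over the staircase. Two cut-offs define three risk
groups:

* the **optimal cut-off** minimizes the Euclidean distance to the ideal ROC
  corner (FPR 0, TPR 1); the phrase "closest to 1" is ambiguous, so Youden's
  J is available as an alternative (`youden_cutoff`). Distance ties break
  toward higher specificity, then the lower threshold.
* the **second cut-off** is the most specific threshold in the highly
  sensitive part of the curve (sensitivity ≥ 0.9 by default; the bound is a
  parameter because no canonical value exists).

Group assignment is left-closed on the high side: score < cut_low → low,
cut_low ≤ score < cut_high → medium, score ≥ cut_high → high.

## Gene selection and cross-validation

Per-gene association with metastasis status uses classical equal-variance
two-group one-way ANOVA (F = t², p from the F(1, n−2) upper tail),
sign-agnostic so genes with opposing profiles are captured; selection keeps
p ≤ α (α = 0.01 by default) with no multiplicity correction, mirroring the
exploratory character of the original workflow. Leave-one-out
cross-validation reselects genes inside every fold, so the left-out sample
never influences its own gene list (a property asserted by a scrambling
test); prediction uses the AGPP-consistent centroid-correlation rule. Folds
whose selection returns fewer than two genes (correlation is undefined on a
single gene) fall back to the training-majority class, so confusion counts
always sum to n.

Two behaviours of this estimator are worth knowing:

* the centroid-correlation rule is location-invariant, so a uniform mean
  shift across all selected genes is invisible to it; discriminative signal
  must live in the *profile shape* across genes.
* under weak signal, LOOCV with per-fold reselection is pessimistically
  biased, sometimes strongly ("anti-learning"): excluding a sample shifts
  its own class centroid away from it, and the selection step amplifies the
  effect. On simulated 94-patient cohorts with the default weak planted
  effects the cross-validated accuracy routinely lands *below* the
  majority-class rate. This is a property of the procedure, not a bug; the
  permutation-null acceptance test verifies there is no optimistic bias,
  which is the failure mode that would matter.

## Survival analysis

Kaplan-Meier estimation is the standard product-limit estimator (censored
observations tied with an event time count as at risk at that time).
Log-rank testing delegates to `lifelines`. The Cox proportional-hazards
model is fit in-package by Newton-Raphson with step-halving on the partial
likelihood, Breslow tie handling by default and Efron optional; standard
errors come from the observed information, confidence intervals are
exp(coef ± 1.96·SE) and per-covariate p-values are Wald tests. Breslow was
chosen because it is the simplest exactly-specifiable convention; the
in-package fit agrees with `lifelines` on tie-free data (where the two tie
conventions coincide) and with a grid-search maximization of the literal
partial likelihood on small fixtures. A coefficient diverging past |β| > 30
or standard errors beyond 50 raise a separation error rather than returning
a meaningless fit. Stepwise selection (forward by smallest Wald p below
p_enter = 0.05, the common statistics-package default; backward by largest
p above it) records its inclusion trace; candidates whose single fits
separate are skipped rather than aborting the scan.

Event-free percentages are printed as integers with half-away-from-zero
rounding; "14-year" survival is evaluated at 168 months on the months time
axis.

## Synthetic cohort generator

The generator is first-class, tested code. It emulates a ~94-patient
node-negative cohort with ~24% DMFS events and a median follow-up near 127
months (range capped at 171 months). Two independent standard-normal
latents carry prognostic information:

* **z**, the proliferation score, drives the hazard with per-unit log-HR
  `prolif_effect` (default 0.71, so a median dichotomy of z is worth a
  hazard ratio near 3, the scale reported for PPH3 in such cohorts). The
  `PROLIF_*` module genes (50 by default, loading 1.0, noise SD 1.0)
  express z, and the tissue markers are monotone noisy transforms of z:
  latent z + Gaussian noise (SD 0.3–0.5) mapped through piecewise-linear
  quantile anchors chosen so the conventional clinical cut-offs (MAI 3 and
  10, PPH3 13, Ki67 10%) reproduce realistic group sizes (≈45/49 for PPH3,
  ≈60/34 for MAI, ≈39/53 for Ki67 out of 94).
* **s**, the planted signature score, drives the hazard with the weaker
  `signature_effect` (default 0.25) and is what the commercial-signature
  gene sets measure: the `MP_*` MammaPrint-like genes and the Oncotype
  proliferation-group genes load on s (loading 0.8). This makes the
  signature groupings genuinely but weakly prognostic, mirroring the
  reference cohort's pattern of strong marker effects and non-significant
  signature effects.

ER-group genes load on an ER latent and GRB7/ERBB2 on a HER2 latent; these
latents also generate the ER/PR/HER2 status columns but carry no hazard, so
they are structured noise. All remaining genes are pure noise around a
baseline of 7 (log2 scale). Survival is exponential
(hazard = b·exp(prolif_effect·z + signature_effect·s); a Weibull shape is
exposed as an option), with the baseline b solved by root-finding so the
expected event fraction matches `event_target_rate` given the censoring
scheme. Censoring is independent uniform on (0, follow_up_max] for a
`censor_rate` fraction of patients (default 0.65, calibrated so the median
follow-up of censored patients is near 127 months) and administrative at
follow_up_max for the rest. Identical configurations (including the seed)
produce bit-identical cohorts.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, normalization pipelines, gene-gene correlation beyond the
single-module / single-signature structure, non-proportional hazards, and
informative censoring. Passing tests therefore demonstrate correctness of
the analysis machinery and calibration under the stated model, not
performance on real microarray cohorts.

## Pipeline and problem sizes

`run_full_analysis` composes: ingest (or simulate) → per-gene z-scoring →
recurrence scores → ROC cut-offs → three-group assignment → AGPP and
two-cluster MammaPrint groupings → per-factor KM/log-rank and
univariate Cox rows (marker dichotomies MAI <10/≥10 and 0–2/3–9/≥10, PPH3
<13/≥13, Ki67 <10/≥10) → forward-Wald multivariate Cox over the univariately
significant factors (p < 0.05, configurable; the resubstitution-biased AGPP
grouping excluded as described above) → ANOVA gene selection and LOOCV. All
randomness flows through the single simulation seed recorded in `run.log`
alongside a config hash.

Simulation-backed checks run at deliberately moderate sizes chosen to give
stable Monte-Carlo answers quickly: 400 genes per simulated cohort for
pipeline-level replicates, 40 replicates for the prognostic-ordering
comparison, 100 replicates at n = 400 for hazard-ratio recovery, 500
replicates for log-rank null calibration, and 50 permutations for the
cross-validation null. The acceptance script reports, next to each value,
the problem size it was computed at.

## Known limitations

* The recurrence score on z-scored microarray data shares only its ordering
  with the qPCR-scale score; absolute RS values and the published 18/31
  cut-points are not comparable.
* The AGPP grouping's apparent prognostic strength is inflated by
  resubstitution and should not be compared against outcome-blind factors.
* The Cox implementation targets small-to-moderate cohorts (hundreds of
  samples, a handful of covariates); it is O(events × n) per Newton step
  and makes no attempt at the sparse/stratified generality of dedicated
  survival packages.
* Probe-to-gene collapsing keeps the probe with the highest mean expression;
  genuinely discordant probes are resolved silently by that rule.
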