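# prolifsig

Prognostic comparison of commercial gene-expression signatures against
direct proliferation markers in lymph-node-negative breast cancer.

Node-negative patients mostly do well, yet the majority receive adjuvant
therapy; the open question is which risk stratifier best identifies the
minority who will develop distant metastasis. This package implements, as
a tested and reusable pipeline, the comparison of:

* an **Oncotype-DX-style recurrence score** — the 21-gene algorithm's
  group-score combination
  `RS_u = 0.47·GRB7g − 0.34·ERg + 1.04·PROLIFg + 0.10·INVg + 0.05·CD68 −
  0.08·GSTM1 − 0.07·BAG1`, stratified into low/intermediate/high risk by
  ROC cut-off optimization against distant-metastasis-free survival (DMFS);
* a **MammaPrint-style classification** — both two-cluster hierarchical
  grouping (1 − correlation distance, average linkage) and nearest-centroid
  correlation to the average gene-expression profiles (AGPP) of patients
  with and without metastasis;
* the **proliferation markers** mitotic activity index (MAI),
  phosphohistone-H3 counts (PPH3, cut at 13) and Ki67 percentage (cut at
  10%);

on Kaplan-Meier / log-rank survival comparisons, univariate Cox hazard
ratios, and a forward-Wald multivariate Cox model — plus a supervised
per-gene ANOVA selection (p ≤ 0.01) with leave-one-out cross-validation
that reselects genes inside every fold. A synthetic cohort generator with
planted proliferation and signature effects emulates the statistical
structure of a ~94-patient node-negative cohort (≈24% event rate, median
follow-up ≈127 months), so the entire pipeline is testable without patient
data. See `docs/methods.md` for the model details and design choices.

Intended users: computational biologists and biostatisticians who want a
transparent, scriptable re-implementation of this classic
microarray-prognostics workflow, or a calibrated simulation harness for
studying its statistical behaviour (ROC cut-off optimism, LOOCV selection
bias, and so on).

## Worked example

Simulate a 94-patient cohort and run the full analysis:

```bash
prolifsig simulate --n-patients 94 --n-genes 400 --seed 1 --out demo/cohort
# wrote cohort: 94 patients, 28 events -> demo/cohort

prolifsig run-all \
    --expression demo/cohort/expression.tsv \
    --clinical   demo/cohort/clinical.csv \
    --signature  demo/cohort/signature_mammaprint_like.json \
    --seed 1 --out demo/analysis
# n=94 events=28 pph3 log-rank p=0.009538 -> demo/analysis
```

`demo/analysis/report.tsv` holds one row per risk-factor group with
events/at-risk counts, event-free percentage, log-rank p and the
univariate Cox hazard ratio against the factor's reference group. The
marker and signature rows of the run above:

```
factor              group  events  at_risk  event_free_pct  logrank_p    hr     95% CI
pph3                <13    9       46       80              0.0095
pph3                >=13   19      48       60              0.0095       2.75   1.24-6.09
mai10               <10    16      70       77              0.0112
mai10               >=10   12      24       50              0.0112       2.55   1.20-5.39
oncotype_rs         low    2       7        71              0.977
oncotype_rs         medium 8       28       71              0.977        0.93   0.20-4.37
oncotype_rs         high   18      59       69              0.977        1.01   0.23-4.38
mammaprint_cluster  good   12      50       76              0.290
mammaprint_cluster  bad    16      44       64              0.290        1.49   0.71-3.16
```

Read: the PPH3 dichotomy separates survival strongly (80% vs 60%
event-free, log-rank p ≈ 0.01, HR 2.7), while the signature-derived
groupings do not reach significance — the ordering the planted effects
encode (the proliferation latent carries a per-unit log-HR of 0.71, the
signature latent only 0.25). The forward-Wald multivariate model selects
only `pph3:>=13` (HR 2.75, Wald p = 0.013). The `mammaprint_agpp` rows
(not shown) look dramatically prognostic (p ≈ 7e-6) precisely because the
AGPP centroids are trained on the cohort's own outcome — the report keeps
them for completeness, but they are excluded from the multivariate
candidates; `docs/methods.md` discusses this resubstitution bias.

`results.json` additionally records the ROC cut-offs and group sizes, the
selected gene list, and the cross-validation confusion matrix;
`km_curves.tsv` exports every Kaplan-Meier step for plotting.

The same operations are available as a library:

```python
from prolifsig import (SimulationConfig, simulate_cohort, zscore_genes,
                       recurrence_scores, roc_curve, optimal_cutoff)

cohort = simulate_cohort(SimulationConfig(seed=1))
rs = recurrence_scores(zscore_genes(cohort.expression))
roc = roc_curve(rs, cohort.clinical["dmfs_event"])
print(round(roc.auc, 3), round(optimal_cutoff(roc), 3))
```

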