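# csfmet

Confidence-aware prediction of multiple-sclerosis phenotypes from CSF
metabolomics, as a tested, reusable pipeline.

Distinguishing relapsing-remitting MS (RRMS) from progressive MS (PMS) is a
clinical judgement that can lag the underlying biology by years.
Untargeted LC-MS metabolomics of cerebrospinal fluid can capture that
biology, but a single-number classifier score is hard to act on for an
individual patient.  This package implements a two-cohort analysis that
ends in *per-patient confidence*: a metabolite signature is selected in a
training cohort, validated in an independent cohort, and wrapped in a
conformal predictor whose p-values quantify how well each patient conforms
to each phenotype — including longitudinal monitoring of treated
progressive patients whose biochemistry drifts back toward the
relapsing-remitting distribution.

The intended audience is computational biologists building or stress-testing
biomarker pipelines: every stage is a library function with a CLI and a
synthetic-data generator that emulates the study design (two cohorts with
HC/RRMS/PMS groups, planted discriminatory features, age confounders,
batch shifts, run-order drift, QC/blank/dilution injections, missingness,
treated patients re-sampled at 3/6/12 months).

## Methods at the core

**Preprocessing & harmonization** (per cohort, then cross-cohort):
blank-ratio contaminant removal; keep features with a significant positive
Pearson correlation against a 2-fold dilution series (p < 0.05); log2;
QC-anchored LOESS run-order correction (span 0.2); QC CV < 0.20 on
de-logged values; one-to-one cross-cohort matching within ±2.5 ppm and
±5 s; intensity-consistency, age (Pearson in cohort-1 healthy controls,
p < 0.05), and 90 %-presence filters; mean imputation; within-cohort
centering.

**Signature selection.** Elastic-net logistic regression on cohort 1,

    min  (1/n)·Dev(β₀, β) + λ[ α‖β‖₁ + (1−α)/2 ‖β‖₂² ],   α = 0.5,

λ chosen by balanced 7-fold cross-validation (five patients per phenotype
per fold) with the one-standard-error rule; validation by ROC AUC on
cohort 2.

**Conformal prediction.** Transductive Mondrian (class-conditional) CP over
a probability-calibrated SVC.  For test sample x and hypothesized label ŷ,
the classifier is refit on the training set plus (x, ŷ); with margin
nonconformity α = 1 − P(y), the p-value ranks x among the class-ŷ examples:

    p(ŷ) = #{ j : y_j = ŷ, α_j ≥ α_x } / (n_ŷ + 1).

Prediction sets at significance ε contain the labels with p > ε (empty,
single, or double); Mondrian validity bounds the per-class error by ε.
Treated PMS patients are monitored leave-patient-out: the model is trained
on all baseline RRMS/PMS samples excluding every sample of the evaluated
patient, and the patient's baseline and follow-up p-values are tracked.

**Characterization.** PCA of the selected features with projection of the
validation cohort and follow-ups, ANOSIM with 999 permutations, paired
Wilcoxon tests on PC1, sex-adjusted log2 fold changes, Mann-Whitney
treatment checks, random-intercept multilevel models of clinical measures
(strength = sign(β)·−log10 p), and Spearman-distance hierarchical
clustering of association profiles.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (each is a thin driver over the library; outputs land in `results/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py --seed 1
python analysis/03_harmonize.py --seed 1
python analysis/04_select_signature.py --seed 1
python analysis/05_conformal.py --seed 1
python analysis/06_monitor.py --seed 1
```

which prints, stage by stage:

```
simulated 2 cohorts (600 shared features, 22 treated PMS patients) -> results/data
cohort 1: 660 -> 634 features ({'blank_filter': 26})
cohort 2: 660 -> 634 features ({'blank_filter': 26})
291 harmonized features over 179 samples; 0 false matches; age filter removed 58 features
selected 28 features at lambda_1se=0.1474; cohort-2 AUC 0.944 (best single feature 0.810)
chosen kernel rbf (C=0.55); peak single-label fraction at epsilon=0.028; at 6% significance: 63% correct single-label + 0% double-label
cohort-1 ANOSIM R=0.39 (p=0.001); median treated-PMS conformal p: baseline 0.60 -> month 12 0.06; Wilcoxon PC1 p at 12 months 4.8e-07
```

Reading the output: all 26 planted contaminants fall to the blank filter
and cross-cohort matching makes no false assignments; the elastic-net
signature built on cohort 1 generalizes to cohort 2 (AUC 0.944, well above
the best single feature); the hyperparameter search lands on the RBF
kernel; ANOSIM confirms the phenotype separation in PCA space (R = 0.39,
p = 0.001); and the treated progressive patients' conformal PMS p-value
collapses from 0.60 at baseline to 0.06 twelve months after treatment —
the signal the monitoring stage exists to detect.

The same stages are available as a console tool
(`csfmet simulate|preprocess|match|select|conformal|monitor`).

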