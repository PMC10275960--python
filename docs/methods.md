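# Methods notes

This note documents the models, parameter choices and numerical decisions
behind `csfmet`, and what the synthetic-data experiments do and do not
establish.

## Synthetic data model

The generator emulates a two-cohort CSF metabolomics case-control study
with a longitudinal treatment arm.  On the log2 scale, a study injection of
feature *f* is

    log2 I = μ_f + δ_f·1[PMS] + a_f·age + s_f·1[male] + c_f·1[cohort 2]
             + g_f(order) + ε,     ε ~ N(0, σ²),

with μ_f ~ U(14, 24), planted effects δ_f = ±0.6 on 10 of 600 features
(alternating sign, emulating up- and down-regulated metabolites),
age slopes a_f = ±0.03 log2/year on 10 % of features, sex effects ±0.3 on
5 %, per-feature cohort shifts c_f ~ N(0, 0.3²), sinusoidal run-order
drift g_f with amplitude U(0, 0.3) and period ~ one run, and residual
σ = 0.5.  Raw intensities are 2^log2 with 5 % missingness (MCAR) on study
cells.  Group sizes default to the study design: 49/39/35 (HC/RRMS/PMS) in
cohort 1 and 10/30/16 in cohort 2; patient ages are drawn from the
reported group means/SDs, healthy controls in cohort 1 uniformly over
18–74 years so the age filter has leverage.

Technical injections follow the acquisition layout: five lead QCs, two
blanks, a 2-fold dilution series (0.5–32 µL against a 10 µL study
injection volume), then a QC and a blank every 8th sample.  QC injections
measure the pool (σ_tech = 0.1); blanks sit ~10 log2 units below the pool
except for planted contaminants (4 % of features per cohort), which appear
at pool level in blanks and ignore the dilution volume.  30 % of
non-contaminant features are absent from blanks entirely.

Cross-cohort identity: m/z values sit on a 0.05 Da grid with ±0.005 Da
jitter, so distinct features are never within ±2.5 ppm of each other;
cohort-2 counterparts of genuine features are jittered within ±1.5 ppm /
±2.5 s, and decoy features (10 %) are pushed outside the window, half in
mass (6–20 ppm) and half in retention time (10–25 s).  This makes
"zero false matches" a property of the matcher, not of luck in the
catalog.

Treated cohort-1 PMS patients (22 by default) are re-sampled at 3, 6 and
12 months with the planted effect shrunk linearly toward RRMS:
δ_f·(1 − m/12) at month *m* (full convergence at a year by default).
Follow-ups emulate already drift-corrected re-injections — no new run-order
drift or missingness.  Eight clinical measures are linear combinations of
two planted metabolite levels each (coefficients ±1, recorded in truth)
plus a patient random intercept (SD 0.5) and noise (SD 0.5).

A single master seed spawns named sub-streams (catalog, subjects, values
per cohort, missingness, drift, longitudinal, clinical), so each component
is reproducible in isolation.

**What passing tests on these data do not show:** the generator is
Gaussian on the log scale with MCAR missingness, linear age/sex effects
and independent features; real LC-MS data have correlated features
(adducts, isotopes), intensity-dependent missingness, heavier tails and RT
warping.  Results here validate the *machinery* (filters, selection, CP
validity, monitoring), not field performance on any particular cohort.

## Preprocessing

Stage order is fixed: blank filter → dilution filter → log2 → LOESS → CV
filter.  The blank rule keeps a feature when mean QC intensity ≥ 10× mean
blank intensity (boundary kept); features absent from all blanks are kept.
The published upstream pipeline's exact blank criterion is not restated in
the methods we implement from, so this conventional background-ratio rule
stands in, with the threshold configurable.  The dilution filter requires
a *positive* Pearson r with volume at two-sided p < 0.05 — positivity
encodes "originating from the sample"; constant features are removed.

LOESS drift correction is fitted on QC injections only (degree-1 local
linear, robustness iterations off for determinism, span 0.2) and evaluated
at every injection's run order by interpolation with linear extrapolation
beyond the QC range; the fitted curve is subtracted and the QC mean added
back.  The effective span is floored so each local fit sees ≥ 3 points
when QCs are few.  Whether the original analysis fitted LOESS on QCs or
on all samples is ambiguous; the QC-anchored reading is the standard
drift-correction protocol and is directly testable (flat QCs afterwards).
Features with fewer than five QC values pass through unnormalized and are
flagged.  The QC CV filter works on de-logged values, strict `< 0.20`.
TIC outliers (|TIC − median| > 3 MAD; any deviation when MAD = 0) are
flagged, never removed.

## Harmonization

Matching is one-to-one within ±2.5 ppm / ±5 s and same ion mode, greedy by
the combined normalized distance |Δppm|/2.5 + |Δrt|/5 with deterministic
tie-breaks; greedy was chosen over optimal bipartite assignment for
simplicity and reproducibility, and at these tolerances the two coincide
on the synthetic catalogs.  The intensity-consistency rule is formalized
as: keep match *i* iff |d_i − mean(d)| < sd(d), where d is the mean log2
intensity difference over all candidate matches, computed once; sd = 0
keeps everything.  The age filter uses Pearson correlation over cohort-1
healthy controls only (patients would confound age with phenotype, since
PMS patients are systematically older); constant features are kept and
flagged.  Presence ≥ 90 % is evaluated over *study* samples per cohort
(QC/blank/dilution excluded, since downstream modeling uses study samples
only; boundary kept).  Mean imputation then within-cohort centering makes
imputed cells exactly 0.  The cohort-1 feature id is the canonical
identity; the pre-centering cohort-1 means are retained so later samples
(follow-ups) can be placed on the same centered scale.

## Signature selection

Objective: (1/n)·binomial deviance + λ[α‖β‖₁ + (1−α)/2‖β‖₂²], α = 0.5,
intercept unpenalized, features standardized to cohort-1 mean 0 / SD 1.
λ grid: 100 log-spaced values from the analytic λ_max
(2·max_j |x_jᵀ(y − ȳ)| / (n·α), the null-model KKT bound) down to
0.01·λ_max.  The solver is an in-package IRLS + coordinate-descent path
(soft-thresholding, active sets, warm starts) — the classic algorithm for
this problem — giving exact zeros and millisecond path fits; tests hold it
to within 1e-6 of a direct numerical minimizer and to the unpenalized
logistic fit as λ → 0.

Balanced folds: each fold gets exactly five subjects per phenotype where
the class divides evenly; remainders are dealt round-robin (≤ 1 extra per
fold per class), so 39 RRMS / 35 PMS yields four folds of 6 RRMS and three
of 5.  CV deviance SE is the across-fold SD divided by √k, and λ_1SE is
the largest λ whose mean deviance is within one SE *of the minimum* — the
standard reading of the 1-SE rule.  After CV the model is refit on all
cohort-1 subjects at λ_1SE (the alternative — reusing a CV-internal fit —
discards a seventh of the training data for no benefit).  AUC is
tie-corrected pair counting (equivalently the Mann-Whitney statistic);
per-feature AUCs are reported as-is, below 0.5 for anti-correlated
features.

## Conformal prediction

Mondrian transductive CP over an SVC with internal cross-validated sigmoid
probability calibration (seeded).  Margin nonconformity
α = 0.5 − (P(y) − max_{y'≠y} P(y'))/2, which for two classes is 1 − P(y).
P-values use the conservative non-strict tie count and include the test
sample in its hypothesized class, so p ≥ 1/(n+1) and p ∈ (0, 1].
Unsmoothed p-values are the default (deterministic); smoothed p-values
(ties weighted by a seeded uniform draw) are computed alongside for
uniformity diagnostics.  Class encoding is fixed throughout: RRMS = 0,
PMS = 1.

The ε grid for curves is 0.001–0.50 in steps of 0.001, fine enough to
resolve the 5–6 % significance region where single-label predictions peak.
The peak-single ε is the smallest ε attaining the maximum single fraction.
Hyperparameter search is two-stage by leave-one-out accuracy: a small
preset per kernel (linear C ∈ 2^{−3..3}; rbf/sigmoid C × γ presets;
polynomial degree 2–3) picks the kernel, then a 30 × 30 log-spaced
(C, γ) grid refines it; ties break toward smaller C, then smaller γ.
Leave-patient-out monitoring trains on all baseline RRMS/PMS samples of
both cohorts minus *every* sample of the evaluated patient (audited by
subject id) and evaluates the patient's baseline and follow-ups.

## Characterization statistics

PCA is SVD on the centered matrix (data are already within-cohort
centered; no rescaling), component signs fixed so the largest-|loading|
entry is positive.  ANOSIM uses Euclidean dissimilarities with average
rank ties, R = (r̄_between − r̄_within)/(n(n−1)/4) ∈ [−1, 1], and the
permutation p-value (hits + 1)/(n_perm + 1) with 999 permutations; the
dissimilarity is configurable since the original choice is unstated.
Paired Wilcoxon tests drop zero differences and use exhaustive sign-flip
enumeration up to n = 12 (exact even with tied |differences|), the
closed-form exact distribution to n = 25 without ties, and a tie-corrected
normal approximation beyond.  Mann-Whitney treatment checks are exact for
small samples without ties.  Sex-adjusted fold changes come from
`level ~ group + sex` least squares (the coefficient equals the
marginal-means contrast for a two-level factor).  Clinical associations
are random-intercept multilevel models
`level ~ clinical + time + sex + time:clinical + (1|patient)` fitted by
maximum likelihood, with residual-df t p-values (no Satterthwaite
correction — simpler, slightly conservative at these sizes) and strength
= sign(β)·(−log10 p); non-converged fits are flagged and excluded from
clustering.  Association profiles are clustered with distance
1 − Spearman ρ and average linkage; constant rows (undefined ρ) are placed
last.

## Problem sizes in tests and the acceptance run

The test suite runs the conformal validity study at n_train = 80 /
n_test = 200 over 50 seeded repetitions; elastic-net recovery at
10 planted / 500 features, n = 74, 50 seeds; matching fidelity over
50 seeds of 150-feature catalogs; and the longitudinal monitor over
50 seeds with 8 treated patients each (the median across patients is
stable from ~6 patients on, and the full trial arm of 22 adds nothing to
the property under test).  The acceptance script runs the complete
pipeline once at the full study design (600 features, both cohorts,
22 treated patients, full 30 × 30 grid search).

## Known limitations

- The transductive predictor refits the classifier 2× per evaluated
  sample; it is meant for cohort-scale evaluation, not streaming use.
- Mixed-model p-values rely on the residual-df t approximation; with very
  few patients they are approximate.
- The blank-contaminant rule is a documented stand-in for an upstream
  pipeline whose exact criterion is not restated here.
- Matching assumes retention times are already comparable across cohorts
  (no RT warping); the windows only absorb small offsets.
- Under strong planted signals the 1-SE elastic net still selects a dense
  model (the CV deviance minimum moves to small λ); sparsity comparable
  to weak-signal real data should not be expected from the generator's
  default effect sizes.
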