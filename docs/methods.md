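# Methods

This note documents the statistical model behind `hepamir`, the defaults it
ships with, the choices made where the design was genuinely open, and what
its synthetic data can and cannot certify.

## Relative quantification (2^−ΔΔCt)

The qPCR model assumes perfect doubling per cycle (efficiency 2.0), so one
threshold cycle equals one log2 unit of template abundance; no efficiency
correction is applied. For subject *s* and target assay *a*:

    ΔCt(s,a)  = Ct(s,a) − mean_r Ct(s,r)            r over reference assays
    ΔΔCt(s,a) = ΔCt(s,a) − mean_{c∈control} ΔCt(c,a)
    level(s,a) = 2^−ΔΔCt(s,a)

The arithmetic mean of reference Cts is the log2 of the geometric mean of
reference abundances, the standard normalizer for a multi-reference panel.
Referencing to the *arithmetic mean of control ΔCt* (equivalently the
geometric mean of control abundances) makes the control-group geometric mean
of levels exactly 1 per assay; mean-vs-median here was an open choice and the
mean follows common 2^−ΔΔCt practice. Two invariances are tested: adding a
constant to every Ct of a subject (a global efficiency/loading shift) leaves
all levels unchanged, and ΔΔCt = −1 gives exactly level 2.

**Detection QC.** A reaction is detected when Ct < 38 cycles (`max_ct`,
configurable). Target assays detected in fewer than 90% of subjects
(`min_detection`) are excluded; a *reference* assay failing detection is a
hard error, because silently losing the normalizer would corrupt every
level. Undetected targets become missing values, not values imputed at the
threshold — censoring-as-value inflates apparent down-regulation; an
`impute-at-threshold` sensitivity mode is deliberately *not* the default.
Subjects missing any reference Ct are dropped with a warning.

**geNorm stability.** With log2 expression = −Ct, the stability of assay *i*
is M_i = mean over partners j≠i of the SD across subjects of
(Ct_j − Ct_i), pairwise-complete over missing values; lower M is more
stable. The stepwise trace removes the highest-M assay and recomputes, down
to the final pair, as in the original scheme. M is permutation-equivariant
in assay order and invariant to per-assay additive offsets (both tested).

## Severity scores

Histology grades are ordinal: steatosis 0–3 (graded from the percentage of
steatotic hepatocytes at <5 / 5–33 / >33–66 / >66), ballooning 0–2, lobular
inflammation 0–2, fibrosis stage 0–4. NAS = steatosis + inflammation +
ballooning; SAF activity = ballooning + inflammation; "at risk" = activity
≥ 2; advanced fibrosis = stage 3 or 4. Inflammation is stored on the 0–2
scale; a grade of 3 (the wider NAS convention) is accepted with a warning.

The serum algorithms use their standard published formulas (they are
comparators here, with units: age years, AST/ALT IU/L, platelets 10³/µL,
albumin g/dL, glucose mg/dL, insulin µU/mL):

* FIB-4 = age·AST / (platelets·√ALT), cut-off 1.30
* APRI = 100·(AST/ULN)/platelets, ULN default 40 IU/L (configurable; the
  upper limit of normal is rarely reported with the score), cut-off 1
* BARD = [BMI ≥ 28] + 2·[AST/ALT ≥ 0.8] + [diabetes], cut-off ≥ 2
* NFS = −1.675 + 0.037·age + 0.094·BMI + 1.13·[IFG/diabetes] +
  0.99·AST/ALT − 0.013·platelets − 0.66·albumin, bins at −1.455 / −0.675 /
  0.676 (−1.455 is the published lower cut-off)
* HOMA-IR = glucose·insulin/405

Boundary ties follow the printed inequality conventions: a score exactly at
a "<c / >c" boundary goes to the lower bin (FIB-4, APRI, NFS); BARD is ≥ 2.
A `strict` flag flips the tie.

## Univariate statistics

The adaptive two-group policy: pooled-variance Student t when both samples
pass Shapiro-Wilk normality *and* an F-test of variance equality (both at
α = 0.05, configurable); otherwise Mann-Whitney U (exact for small untied
samples, tie-corrected normal approximation otherwise). Note the policy
sends normal-but-heteroscedastic data to the rank test, not to Welch's t —
Welch is noted as an alternative but is not the default, to keep the
pipeline's decisions reproducible against the adaptive rule as stated.
Multi-group comparisons use one-way ANOVA with Tukey HSD; qualitative
variables use Pearson chi-square without continuity correction; correlation
is Pearson when both margins look normal, Spearman otherwise. p values are
reported raw across the ~16-assay panel (an optional Benjamini-Hochberg
switch exists and is clearly non-default). Every result records which test
actually ran.

## Diagnostics

ROC curves are empirical: thresholds at observed marker values, tied scores
stepping diagonally, AUROC by trapezoid — equal to the Mann-Whitney U
statistic over n₁n₀ with ties counted half (asserted exhaustively for
n ≤ 8). Direction is auto-resolved so AUROC ≥ 0.5 and recorded. Cut-offs sit
at observed values (no midpoint interpolation) so reported cut-offs are
reproducible data points; the Youden maximizer breaks ties toward higher
sensitivity, then the lower cut-off. Subjects missing a marker are excluded
from that marker's evaluation (complete case).

Confidence intervals (the methods are a package choice; sources rarely state
them): Clopper-Pearson exact for proportions (one-sided at boundary cells),
Simel's log method for likelihood ratios, Hanley-McNeil for AUROC with
DeLong as an option. Degenerate confusion cells yield flagged NaN (or an
explicit +inf PLR at specificity 1), never exceptions. Every report is
checked against the Bayes identities (accuracy = sens·p + spec·(1−p); PPV
from sens/spec/prevalence).

`predictive_values` is the rate-based counterpart of the count-based panel:
it rebuilds PPV/NPV/PLR/NLR/accuracy from sensitivity, specificity and
prevalence alone, which is how the acceptance script re-derives published
panel cells from their printed inputs.

## PLS-DA with leave-one-out cross-validation

PLS1 NIPALS on autoscaled predictors (mean 0, SD 1 with ddof = 1;
zero-variance variables are rejected by name) against a centered {0,1}
class vector; deterministic, no randomness. Coefficients are kept per
component count, so one fit yields the whole LV path. With as many LVs as
the predictor rank the fit equals ordinary least squares (asserted at
1e-8), and predictions agree with an independent reference PLS
implementation at 1e-8.

Class coding {0,1} with a 0.5 decision midpoint was an open choice; a
Youden-threshold mode on the cross-validated scores is provided since
published operating points may derive from either.

Cross-validation is leave-one-out with *fold-internal* autoscaling and
median imputation (no leakage: corrupting a held-out sample cannot change
its fold's training model — tested metamorphically). A scale-once mode
exists for comparison with analyses that autoscale before CV. The LV count
is chosen to minimize total LOO misclassifications, ties to the fewest
components (default search up to 10).

One numerical subtlety: pooled LOO scores use the overall class prevalence
as intercept rather than each fold's training mean. The fold mean is
anti-correlated with the held-out label (a training set missing a positive
has a lower mean), which biases pooled null CV AUROC visibly below 0.5 at
n ≈ 40–90; the prevalence is a single constant and carries no subject-level
information. With this choice the permuted-label CV AUROC is 0.5 within
Monte-Carlo error (tested over 200 replicates).

**Panels.** Clinical panel: 16 laboratory/anthropometric variables (age,
BMI, glucose, triglycerides, total/HDL/LDL cholesterol, bilirubin, albumin,
platelets, ALT, AST, ɣ-GT, ALP, ferritin, hemoglobin). miRNA panel: the 16
detected assays plus 17 induced/repressed ratios — the 6×3 grid of induced
(34a, 27b, 22, 122, 192, 21) over repressed (30c, 16, 197) gives 18 pairs
and the exact published membership of the 17 is not enumerated anywhere, so
the default drops miR-21/16 (both constituents behave as general
liver-injury markers rather than NAFLD-specific ones); the membership is
configurable. Combined panel: the 49-variable union.

## Synthetic cohort generator

The generator emulates the study conditions of a three-group biopsy-proven
cohort: 17 normal-liver controls, 25 NAFL, 50 NASH, plus a 17-subject
drug-induced liver injury (DILI) group paired against the same controls.

* **Clinical variables**: independent normal draws per group from the
  published (mean, SD) pairs, redrawn at ≤ 0 for strictly positive
  quantities; sex Bernoulli from the published percentages; impaired
  fasting glucose / diabetes derived as glucose ≥ 100 mg/dL. No covariance
  structure is imposed (none is published); a correlation hook exists.
  Control-group fasting insulin is not reported and defaults to
  8 ± 4 µU/mL (normal fasting range) so HOMA-IR stays computable.
* **Histology**: independent categorical draws from the published per-group
  marginals, resampled until the diagnostic constraints hold — NASH
  requires steatosis ≥ 1, ballooning ≥ 1 and inflammation ≥ 1 (hence SAF
  activity ≥ 2); NAFL requires activity < 2; controls are all grade 0. The
  joint grade distribution is a modeling choice, not a reported fact.
* **Ct values**: Ct = base_ct − log2_effect(group) + N(0, σ), censored to
  missing at 38 cycles. Default effects are ±1 log2 units in NASH/DILI and
  ±0.3 in NAFL with the validated directions (NAFLD-induced: 34a, 27b, 22,
  122, 192, 21; repressed: 30c, 16, 197; DILI-induced: 34a, 122, 21, 451a,
  663a, 146b, 331, 197; DILI-repressed: 16). Magnitudes on the log2 scale
  are free parameters (publications report significance, not log2 effects);
  the defaults put simulated single-marker and cross-validated AUROCs in
  the published 0.7–0.85 band. Base Cts sit in the observed 28–37 serum
  band (miR-16/451a most abundant, miR-34a near the top of the range);
  σ = 1.0 cycles for targets and 0.5 for the two reference assays
  (references are chosen for low variability); two assays are generated at
  base Ct 39/39.5 so they censor out at QC, emulating candidates that fail
  to amplify.

Identical (spec, seed) gives bit-identical output, through serialization.

**What passing tests do not show.** The generator reproduces group
marginals and effect directions only. It has no clinical covariance, no
joint histology structure beyond the constraints, no plate/batch effects,
no hemolysis artifacts, and its lognormal level distribution is an
assumption. Green tests certify the statistical machinery, not clinical
realism, and synthetic AUROCs (especially for the clinical panel, whose
group means differ without the within-group overlap of real cohorts) run
higher than published ones.

## Problem sizes used by the test and acceptance suites

Simulation-backed checks use: 200 simulated cohorts for geNorm reference
ranking and for direction-recovery rates; 200 permuted-label replicates for
null CV AUROC calibration; 100 replicates for the combined-versus-miRNA
panel comparison with the LV count fixed at 2 (inside the published 1–4
range) rather than re-selected per replicate; 1000 random instances for the
Youden brute-force oracle; exhaustive labelings up to n = 8 for the
AUROC/Mann-Whitney identity. These sizes were chosen to keep Monte-Carlo
error well below the asserted margins while the full suite runs in minutes.

## Known limitations

* Direction-recovery power at the default conditions is ~0.91–0.96 per
  miRNA (severe-activity split): the observable contrast is diluted below
  1 log2 unit by the intermediate group's 0.3 shift, by reference noise and
  by censoring near the detection limit. Simultaneous recovery of all nine
  validated markers therefore happens in roughly half of replicates, not
  95%.
* The NFS, FIB-4, APRI and BARD formulas are implemented from their
  original publications; cohort-specific recalibrations are out of scope.
* No smoothed/binormal ROC fitting, no net-reclassification indices, no
  sparse or orthogonal PLS variants, no nested double cross-validation.
* The CLI writes plain TSV/JSON only; plotting is left to the caller.
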