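# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions behind `ponvkit`.

## Outcome model

PONV occurrence within 24 h of surgery is Bernoulli with

    logit P(occ=1) = β₀ + Σⱼ βⱼ xⱼ + β_G · G,

where x₁..x₈ are the risk-coded clinical covariates (female sex, age < 50,
non-smoking, no cannabis use, previous PONV history, visceral or
gynecological surgery, volatile anesthetics, > 19 mg oral-morphine-
equivalent perioperative opioid) and G is the genetic term.  Recurrence (a
second episode) is modelled by the same form, conditional on occurrence and
on being followed up.  Genetic terms enter as minor-allele dosage
(additive), carrier status (dominant), minor-homozygote status (recessive),
or a continuous CYP activity score.

Dichotomization boundaries are inclusive on the no-risk side: exactly 19 mg
codes 0 (the median split is ≤ 19 vs > 19) and exactly 50 years codes 0
(the age rule is strictly < 50).

## Synthetic cohort generator

The generator exists so every downstream stage (QC, activity scoring,
association, haplotype analysis, risk modelling) can be exercised and
validated on data whose ground truth is known.  Its defaults encode the
study conditions the package targets:

* **Covariates** are Bernoulli with the published cohort prevalences
  (female 0.526, age<50 0.577, non-smoking 0.681, no cannabis 0.937,
  history 0.238, visceral/gyn 0.408, volatile 0.875, high opioid 0.484).
  Dependence between covariate pairs is realized by a sequential
  conditional scheme: covariates are drawn in a fixed order, and a coupled
  covariate uses the two conditional probabilities implied by its marginal,
  the parent's marginal, and a user-specified odds ratio (unique root of
  the margin-constrained 2×2 quadratic).  Marginals are therefore preserved
  exactly.  The default profile couples history↔gender (OR ≈ 2.78, from
  "71% of history patients are women") and smoking↔age (OR ≈ 0.56, from
  "67% of smokers are under 50"); all other pairs are independent because
  no further dependence information is available.
* **Genotypes**: unblocked loci are two independent allele draws at the
  locus MAF (Hardy-Weinberg).  Loci in an LD block are drawn as two
  independent haplotypes from the block's haplotype frequency table and
  collapsed to unphased genotypes; the phased truth is retained for oracle
  tests.  The default panel carries the three serotonin-receptor blocks
  (HTR3B: rs3758987+rs45460698 and rs76124337+rs3782025; HTR3A:
  rs10160548+rs1176713) with the published haplotype frequencies, plus a
  spread of unblocked loci at their cohort MAFs.  The published HTR3A
  frequencies sum to 1.01; the wild-type haplotype is trimmed 0.62 → 0.61
  so the distribution is proper while both single-locus margins stay at
  their MAFs.  The triallelic ABCB1 locus rs2032582 is drawn by two nested
  biallelic draws (major vs non-major, then the rare T within non-major) so
  both printed minor-allele frequencies (0.38 and 0.016) are reproduced
  exactly.
* **Outcomes**: occurrence uses the published per-covariate odds ratios and
  a per-G-allele OR of 1.40 at rs3782025; recurrence uses the recurrence
  odds ratios (including the protective high-opioid OR 0.35 and marker OR
  0.66) conditional on occurrence, with an independent 86.7% follow-up
  flag.  Both intercepts are solved by exact enumeration of the joint
  covariate/genotype distribution (2⁸ covariate cells × HWE genotype
  classes; for recurrence the cell weights are tilted by the occurrence
  probability) with Brent root-finding, so the implied prevalences are
  43.9% (occurrence) and 68.6% (recurrence among followed cases) by
  construction, not by tuning.
* **Raw columns**: undichotomized columns (age in years, opioid mg, surgery
  type, …) are synthesized consistently with the coded flags, so
  re-dichotomizing them reproduces the codes exactly.  Opioid doses follow
  a lognormal matched to the cohort median (19 mg) and IQR (6–46 mg),
  drawn conditionally on the correct side of the median.  The
  postoperative-opioid flag used by the Apfel score is independent
  Bernoulli(0.80) — a typical postsurgical analgesia rate, chosen because
  no cohort value is published — and is deliberately distinct from the
  regression model's median-split opioid covariate.
* **Missingness**: 0.6% of calls are set missing by default (matching the
  >99% call rates of array genotyping) after outcomes are generated, so
  missingness only exercises the QC and listwise-deletion paths.

What the generator does *not* emulate: genotyping batch effects or
platform-specific error modes, population stratification and relatedness,
real LD decay outside the declared blocks, any dependence of genotype on
covariates, and treatment (dexamethasone) effects.  Passing tests therefore
demonstrate correctness of the estimators under the declared generating
process, not robustness to those real-data complications.

## Genotype QC

Call rates are non-missing fractions per axis.  MAF is the minor-allele
count over twice the non-missing sample count, after orientation
normalization (the minor allele is the less frequent in the data; ties keep
the declared orientation, making normalization idempotent).  Triallelic
variants are summarized on the primary allele pair with the third allele's
frequency reported separately.  Hardy-Weinberg uses the 1-df Pearson
chi-square or the exact conditional test on the heterozygote count (full
enumeration over same-parity heterozygote counts, summing probabilities not
exceeding the observed configuration's).  The default picks the exact test
below 100 minor alleles, chi-square otherwise — standard small-sample
practice.  HWE can be evaluated within cases and controls separately, since
QC exceptions in case-control panels are typically annotated by stratum.
Monomorphic variants return p = 1 with a warning.  Indels are treated as
biallelic presence/absence symbols; no liftover or strand flipping is
attempted because the panel is small and fixed.

## CYP activity scoring

Star alleles are defined in an editable TSV (gene, star allele, defining
variant, required allele, per-allele score).  The shipped table covers the
alleles needed for the six genes scored here with well-known tag rsIDs; it
is a pragmatic default, not a complete nomenclature, and users with a
different panel should override it.  Diplotype assignment enumerates all
allele pairs and keeps those whose joint requirements exactly explain the
observed dosage at every defining variant; ties resolve by table order
(default allele first), missing calls act as wildcards and mark the call
ambiguous, and inconsistent profiles yield an explicit no-call.

Scores: additive genes (CYP1A2, CYP2B6, CYP2C19) sum two per-allele values
(e.g. CYP2C19 \*1 = 1, \*17 = 2, \*2/\*3 = 0 per allele).  CYP2C9 counts
reduced-function alleles.  CYP2D6 adds per-allele values with copy-number
awareness: extra copies duplicate the higher-activity allele (the
conservative convention when the duplicated allele is unresolved); a single
copy counts only the lower-activity allele; copy number 0 with non-null
alleles is flagged inconsistent.  CYP3A is scored as a metabolizer group:
CYP3A5 expressor + fully functional CYP3A4 → EM, exactly one → IM, neither
→ PM, with a one-group increment (capped at EM) for CYP3A7\*1C carriers;
groups map PM/IM/EM → 0/1/2.  CYP1A2 induction by smoking multiplies the
genetic score by 1.5, applied at most once (double application raises), and
the result is never rounded.

## Logistic fitting

IRLS (Newton scoring) with step-halving, which makes the log-likelihood
non-decreasing.  Convergence: max |score| < 1e-8 or relative deviance
change < 1e-10, within 50 iterations.  Wald standard errors come from the
observed-information inverse; 95% CIs are exp(β ± 1.959964·SE).  Wald
inference (not likelihood-ratio) matches the OR/CI/p presentation
convention of genetic association tables.  Rank deficiency is detected up
front and the aliased column named; separation is detected by the
|β| > 15 heuristic and flagged rather than silently returned — plausible
here because some strata (cannabis use, 6.3%) are small.  Missing values
are handled by listwise deletion, mirroring the exclusion of incomplete
records rather than imputation.  Bonferroni correction uses p < α/m.
VIF is 1/(1−R²) from an ordinary least-squares regression of each
covariate on the others.  The confounding scan refits the clinical model
with each marker added and reports the relative change of every
significant clinical coefficient; |change| > 10% is flagged — the 10% cut
is this package's declared convention for "weak confounding".

## Haplotypes and LD

EM over the 2^L haplotype space (L ≤ 8): E-step phase posteriors
proportional to haplotype-frequency products (doubled for heterozygous
pairs), M-step posterior-weighted frequency updates, convergence when the
largest frequency change is below 1e-8.  Initialization is the
phase-ignorant allele-frequency product plus a small seeded jitter, which
avoids the flat-likelihood stall of all-heterozygote inputs while staying
deterministic.  Samples missing any block locus are excluded; both
coverage notions (non-missing, resolvable-phase) are reported and coincide
under this exclusion rule.

LD: D = p_AB − p_A·p_B on the minor alleles, D′ = |D|/D_max with the usual
sign-dependent D_max, r² = D²/(p_A q_A p_B q_B).  Blocks are found by
greedily merging adjacent loci with D′ ≥ 0.8.  The simple adjacent-D′ rule
(rather than a confidence-interval method) is deliberate: the regions
analyzed here are tiny fixed panels, the threshold is configurable, and
the expected three-block structure is validated as a property of the
calibrated simulation.

Haplotype association scores each haplotype's posterior-expected dosage
against the outcome with a 1-df score (trend) chi-square (the "STAT"),
plus an OR from a dosage logistic fit; a covariate-adjusted mode includes
the eight clinical covariates.  The unadjusted score test is the default
because that is the convention of standard haplotype association output;
both modes are available since the choice is not always documented in
published tables.  Haplotypes below 1% frequency are skipped.

## Risk modelling

The simplified Apfel score uses the postoperative-opioid flag, not the
regression median split, because the published score is defined on postoperative
opioid use.  The rs3782025 flag and the Model 1/2 genotyping policies are
as described in the README.  NNG is rounded to the nearest integer — the
only rounding rule consistent with all four published NNG values given
their printed inputs — and NNT is defined on the risk difference between
flagged and unflagged genotyped patients, the only definition consistent
with those NNGs.  The descriptive category adjustment shifts the genotyped
subset by ±1 category; classification metrics use the binary flag
directly, so the shift convention does not affect them.  Whole-cohort ROC
uses the adjusted category as an ordinal score with the ½ tie convention;
AUC is the Mann-Whitney statistic, with DeLong (default) or stratified
bootstrap (2000 resamples, seeded) intervals.

## Problem sizes and validation

The test suite validates the primitives against independent oracles:
closed-form 2×2 logistic solutions and statsmodels for IRLS; exhaustive
grid search over the haplotype simplex (5e-3 coarse pass, 1e-3 refinement)
for two-locus EM on ≤ 10-sample fixtures; exact rational enumeration for
the HWE test; brute-force pair counting for AUC.  Stochastic properties
use seeded replication at the study scale (n = 601): 200 replicates for
effect-size recovery (marker OR 1.40, activity OR 0.55, haplotype OR
1.49), 1000 replicates for Wald CI coverage (93–97% band), 400 for test
size, 200 for HWE rejection calibration, and n = 100 000 for generator
calibration (prevalence 43.9 ± 1.5%).  These sizes give Monte-Carlo error
comfortably inside each tolerance while keeping the default suite around
a minute.

## Known limitations

* Real-cohort estimates (the published per-SNP ORs and p-values, the AUCs
  0.633/0.648/0.668, the stratum-specific HWE failures) require the
  deposited patient data and are covered only as simulation-recovery
  properties, not reproduced numerically.
* The shipped allele-definition table is a small pragmatic default; exact
  panel definitions should be supplied by the user for real data.
* The generator draws genotypes independently of covariates, so
  gene-environment confounding cannot be simulated.
* No imputation, phasing-aware input, relatedness handling, or
  population-structure inference; the haplotype EM is exponential in locus
  count and restricted to ≤ 8 loci.
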