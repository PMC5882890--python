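# Methods

## Data model

All tables are tab-separated UTF-8 with fixed headers; genomic coordinates
are 1-based inclusive.  NPX is treated as an arbitrary continuous log-type
scale: all effects — covariate, genetic, medication, batch — are additive
in NPX, and values are comparable within a protein across samples, not
across proteins.  A per-assay limit of detection (LOD) left-censors the
scale; censored records carry a flag and are excluded from all estimation.

## Synthetic cohort generator

`generate_cohort` assembles, per individual *i* and protein *j*,

```
NPX_ij = a_j + z_i' B_j + d_i' G_j + m_i' delta_j + plate_ij + fam_ij + e_ij
```

with `z_i` the standardized covariate vector (13 canonical covariates: sex,
age, height, weight, smoking contrasts, lifestyle flag, blood pressure,
lipids, disease history), `d_i` allele dosages in [0,2] drawn under
Hardy–Weinberg equilibrium, `m_i` binary medication indicators, a plate
batch shift `plate_ij ~ N(0, batch_shift_sd²)` (plates of 90 samples nested
in the two sampling rounds), an optional block-exchangeable family effect
(off by default; kinship modelling is out of scope), and
`e_ij ~ N(0, noise_sd²)`.

Defaults are the study conditions the pipeline targets: a discovery
subcohort of 663 (round 2006) and a replication subcohort of 240 (round
2009); 441 proteins on five panels, 16 of them constructed low-abundance
(≈15% of values above LOD) so the 20% retention rule removes exactly 16;
noise_sd = 1 NPX, batch_shift_sd = 0.2 NPX, 3% censoring for ordinary
proteins.  Per-protein covariate effects are sparse (2–6 covariates) and
scaled so the combined covariate R² spans roughly 0.12–0.67.  About 30% of
proteins receive one pQTL with a target variance fraction of 0.10–0.60, 80%
of them cis (placed inside the encoding gene on a 22-chromosome toy
genome).  Thirteen drugs with ATC codes and prevalences patterned on common
cardiovascular-era medication (statins ~9.6% combined, platelet aggregation
inhibitors 13.6%, several antihypertensive classes at 2–6%) affect 1–25
proteins each with |delta| ≈ 0.15–0.8 NPX; use is drawn from a logistic
model on the covariates (weights 0.3–0.9 logit units per SD on age, lipids,
weight, blood pressure or infarction history), with the intercept
calibrated by bisection so the realized prevalence matches the nominal one.
The two statin substances share one class-level effect profile, so
substance groups are poolable by construction.

What the generator does **not** emulate: linkage disequilibrium, imputation
uncertainty (beyond a dosage-noise HWE exemption in QC), genuine kinship,
assay-specific heteroskedasticity, non-linear covariate effects, and
longitudinal sampling.  Passing tests therefore demonstrate correctness and
calibration under an additive, unrelated-sample model — not robustness to
those real-data features.

## Batch normalization and LOD filtering

Normalization is a median-of-group strategy: per protein, each (plate,
round) group is shifted so its median equals the median of the group
medians.  Using the median of group medians (rather than the pooled median)
as the target makes the operation exactly idempotent; it preserves
within-group rank order.  Censoring flags are set before normalization, the
shift is computed from non-censored values only, and censored values are
left unchanged; groups with fewer than 3 usable values are skipped with a
warning.  The group-center statistic is pluggable.

Proteins with strictly less than 20% of measurements above LOD are removed
entirely; for retained proteins the censored records are dropped from the
analysis set.

## Covariate modelling

Per protein, each covariate is fitted separately (Gaussian least squares;
Wald two-sided p for single-column covariates, model F-test for categorical
contrasts, reference level = most frequent) and all covariates are fitted
simultaneously.  The combined model's per-covariate contribution is a
sequential type-I decomposition in the user-supplied order, F-tested
against the full-model residual mean square — the behaviour of R's `anova`
on a fitted `glm`.  Collinear columns contribute zero degrees of freedom
and are reported.  Missing data are handled by listwise deletion per fit,
never by global row deletion, to maximize n per protein.

Variance explained is Cox & Snell's R² = 1 − exp((2/n)(ℓ₀ − ℓ₁)); for the
Gaussian family this is algebraically the classical R², which the tests
verify to 10⁻¹⁰.  Family-wise significance divides α by
(covariates × proteins).  Medication indicators for drugs with ≥ 10 users
enter the screen as covariates.  The covariates carried into the genetic
and medication stages are those passing the Bonferroni level in the
combined-model contribution test; the single-covariate screen is reported
alongside.

## Two-stage pQTL mapping

Variant QC: MAF (folded mean dosage / 2) must reach one chromosome in the
sample, 1/(2n); Hardy–Weinberg is tested on nearest-integer hard calls with
the exact conditional test, at α/(number of HWE-tested variants).  Variants
whose dosages sit far from integers for > 5% of individuals are treated as
imputation-uncertain and exempted from the HWE filter.

Each protein is residualized (OLS) on its significant covariates and
rank-inverse-normal transformed, Φ⁻¹((rank − ½)/n) with tie-averaged ranks,
within each analysis stage.  Association is per-variant linear regression
of the transformed residuals on dosage (two-sided t).  The sample is
modelled as unrelated; the kinship-aware mixed models used for genuinely
related cohorts are deliberately out of scope.

Selection: discovery hits need p < α/(number of analysed variants);
replication is tested only for discovery hits at α/k.  k is the protein's
own discovery hit count by default (a global-k mode is configurable) — with
per-protein families the replication burden matches each protein's
discovery multiplicity, which we consider the more defensible reading.
The combined stage pools both subcohorts with a subcohort indicator
covariate and is run for replicated proteins.

Cis/trans: a variant is cis if it lies on the encoding gene's chromosome
within a strict 35 kb window of the gene body (distance 0 inside the gene);
the window is measured from gene boundaries, not the TSS.  Top-marker
variance is the Cox & Snell R² of the **raw** (unadjusted, untransformed)
abundance on the top marker's dosage — i.e. the squared correlation.

## Medication transfer adjustment

For each drug with ≥ 10 users and each protein:

1. Candidate covariates = the protein's Bonferroni-significant covariates
   from the combined screen (other-drug indicators included; the drug's own
   indicator excluded) plus, when available, the protein's top genetic
   marker dosage.
2. Candidates are restricted to those significant **among the non-users**
   at the nominal 0.05 contribution level.  The candidates already passed
   the family-wise screen on the full cohort; re-imposing the Bonferroni
   level on the smaller non-user subset was measured to drop true
   confounders and leave residual confounding bias in the users.
3. The covariate model is fitted on non-users (≥ 30 required), and
   everyone's abundance is adjusted:
   `adjusted = observed − (prediction − non-user training mean)`,
   so users and non-users remain on a common scale.
4. Adjusted users and non-users are compared with a two-sided Wilcoxon
   rank-sum test: exact enumeration when min(n₁, n₂) ≤ 8 and the pooled
   sample has no ties, otherwise the normal approximation with tie and
   continuity corrections.  Benjamini–Hochberg q-values are computed across
   proteins within each drug (per-drug families match per-drug reporting; a
   global family is configurable).  The reported delta is the adjusted
   user-minus-non-user mean, and r²_medication the Cox & Snell R² of the
   adjusted abundance on the use indicator.

Stratified comparisons (e.g. by infarction history) rerun the adjusted test
within strata, skipping cells with fewer than 5 complete values.

### Known limitation: adjustment-estimation variance

The rank test treats adjusted values as data, but the adjustment is itself
estimated from the non-users: every user is shifted by the same realization
of (b − b̂)ᵀx, so the user/non-user contrast carries an extra variance term
Δx̄ᵀ Var(b̂) Δx̄ that the Wilcoxon reference distribution does not include.
For drugs with few users (≤ ~60 of 900) or mild confounding this term is
negligible and the procedure is calibrated (verified by simulation); for a
drug with ~120 users whose use is strongly covariate-dependent the adjusted
test is measurably anticonservative (per-family false-positive probability
≈ 0.1–0.25 instead of 0.05 in our null simulations), even though the delta
estimate itself is unbiased.  Propagating this uncertainty would require a
refit-per-permutation reference distribution, which is outside the
procedure implemented here; consumers should read small q-values for large,
heavily confounded drugs with this in mind.

## Clinical workflows

**Hypertension group**: union of (SBP > 140 **and** DBP > 90 mmHg — the
conjunctive reading of the clinical definition; an "either" mode is
configurable), self-reported diagnosis, and use of any configured
antihypertensive ATC class (defaults C03CA, C07AB, C08CA, C09AA, C09CA).
Cross-sectional data cannot express "repeated" elevation, so a single
measurement exceedance is used.  Regimen class is none/mono/combination by
the count of distinct antihypertensive codes.  Per class (including the
untreated hypertensive subgroup), transfer models are trained on
non-hypertensive controls — regardless of other medication, with other-drug
indicators eligible as covariates — applied to the class members, and
tested with per-class FDR; an overlap matrix summarises sharing of
significant proteins across classes.

**Statins**: HDL/LDL Wilcoxon comparisons of statin users against
non-users of any lipid-modifying drug (ATC C10*); a poolability check of
the two most-used statin substances on adjusted values (pooled unless any
protein differs at α/proteins); the pooled adjusted scan; a Spearman screen
of each FDR-significant protein against LDL in the controls (nominal
p < 0.05 flags the protein as inseparable from lipid levels — such proteins
are excluded from the headline list but still reported); and a sensitivity
rerun excluding antihypertensive users from both groups.

## Numerical choices

- All linear fits run through one least-squares core (QR/lstsq); rank
  deficiency is handled by pinv with aliased columns flagged.  Agreement
  with statsmodels OLS is tested to machine precision.
- Cox & Snell values are clamped to [0, 1); p-values from scans are floored
  at the smallest positive double so they remain in (0, 1].
- The HWE exact test enumerates heterozygote counts in log space
  (max-subtracted) for stability at large n.
- Rank transforms use average ranks for ties; a constant (or numerically
  constant, range ≤ 10⁻¹⁰ of the data range) residual vector is an error.
- Seeds: one global seed per generated cohort, with per-component
  sub-generators spawned deterministically (`SeedSequence.spawn`), so adding
  a component never perturbs the draws of another.

## Problem sizes

The default simulated cohort is 903 individuals × 441 proteins with a
2000-variant panel — a desk-scale stand-in for a genome-wide panel; all
genome-wide thresholds are computed from the analysed panel size.
Calibration and recovery simulations in the test suite use 200 replicates
at n = 900 with 1–10 proteins per replicate, and the two-stage null
calibration uses 10⁵ simulated null variants.
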