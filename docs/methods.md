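# Methods

## The interaction model and test

For a quantitative blood-pressure trait (SBP or DBP, mm Hg), sodium exposure
E (estimated daily sodium intake, mEq/day) and a coded genotype G, the scan
compares two nested Gaussian linear models per variant:

    model 1:  BP = β₀ + β_G·G + β_E·E + γ'C
    model 2:  BP = β₀ + β_G·G + β_E·E + β_GE·(G×E) + γ'C

where C are the adjustment covariates (by default 20 principal components,
age, sex and BMI; plus a study-site indicator in the combined analysis).
Both models are fit by ordinary least squares on complete cases, and the
interaction is tested by the Gaussian profile-likelihood ratio

    LRT = n · ln(RSS₁ / RSS₂)  ~  χ²₁  under β_GE = 0.

This is the standard maximum-likelihood form of the nested-OLS likelihood
ratio; the Wald statistic (β̂_GE/SE)² agrees with it asymptotically and the
suite checks agreement within 10% at n ≥ 1,000. A 2-df joint test of
(β_G, β_GE) is available behind the `joint_2df` flag but is not part of the
default pipeline, which targets interactions specifically.

Numerical notes: designs are solved by SVD-based least squares;
rank-deficient designs (e.g. constant exposure making G×E collinear with G)
and constant coded genotypes produce records flagged `untestable` rather
than exceptions; best-guess posterior ties are broken toward the lower
genotype count and flagged.

### Genotype codings

- *dosage* — expected effect-allele count `p₁ + 2p₂` from the genotype
  posterior;
- *additive* — best-guess allele count in {0, 1, 2};
- *dominant* — carrier indicator (≥ 1 effect allele);
- *recessive* — homozygote indicator. Either allele can be designated as the
  effect allele, so a contrast like "GG vs AG/AA" (recessive coding of the
  reference allele) is expressible.

### Genomic control and two-stage staging

λ = median(LRT) / 0.454936… (the χ²₁ median). Corrected statistics are
LRT/max(λ, 1): λ is floored at one because the correction exists to damp
inflation; deflating would be anti-conservative to that purpose. Staging
gates: suggestive if discovery P_GC < 1×10⁻⁵; replicated if additionally the
replication P < 0.05 with the same interaction sign; genome-wide if
additionally the site-adjusted combined P < 5×10⁻⁸. Replication and combined
p-values are not GC-corrected (correction applies to the genome-wide
discovery stage, where the candidate set is selected). A combined record
fitted without the site covariate caps the status at `replicated`.

## Variant QC

Call rate, MAF and the Hardy–Weinberg exact test are computed from hard
calls (exact-test counts must be integers, and this mirrors pre-imputation
array QC); imputation quality uses the per-variant R² metadata. Thresholds
printed as strict inequalities exclude, so equality passes: call rate ≥
0.95, HWE P ≥ 1×10⁻⁶, MAF ≥ 0.01, R² ≥ 0.8, and coded-genotype frequency ≥
0.01 for the dominant/recessive codings. The HWE exact test is the
conventional (not mid-p) two-sided test: conditional on allele counts, it
sums the probabilities of all heterozygote counts whose conditional
probability does not exceed the observed one. The distribution is built with
the ratio recurrence P(h+2)/P(h) = 4·n_AA·n_BB/((h+1)(h+2)) accumulated in
the log domain and normalised by the running maximum, so counts in the tens
of thousands neither overflow nor underflow; outcomes equal to the observed
probability up to a 1e-10 relative tolerance count as ties. The test suite
verifies exact agreement with a brute-force enumeration oracle for every
genotype triple with total ≤ 200.

## Phenotype preparation

BP is the mean of the available (one or two) readings; subjects on
antihypertensive medication get +10 mm Hg SBP and +5 mm Hg DBP to
approximate untreated pressure (disabled in the `measured_bp` sensitivity
mode). Hypertension is SBP ≥ 140, DBP ≥ 90, or medication. Daily sodium is
estimated from spot urine as

    Na24 = scale · (spot_Na / (10 · spot_Cr) · PRCr)^exponent,
    PRCr = −2.04·age + 14.89·weight + 16.14·height − 2244.45,

the Tanaka estimator (spot Na in mEq/L, spot Cr in mg/dL, PRCr the predicted
24-h creatinine excretion in mg/day). All coefficients are configuration
values (`SodiumFormulaCoefficients`), never hard-coded downstream; tests
exercise degenerate and round-trip coefficient sets. Unit conversions use
the nutrition convention of 23 mg sodium per mEq (mmol) with half-up
presentation rounding, which reproduces published cohort-table mg/day values
exactly (164.8 mEq/day ↔ 3,790 mg/day); the more precise atomic mass
22.9898 would round several of those values differently. Subjects missing
BMI, SBP, DBP or daily sodium are excluded with per-reason counts logged.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- Genotypes: true genotypes Binomial(2, MAF) under HWE. Imputation noise is
  a per-entry mixture: with probability R² (the target imputation quality)
  the posterior is degenerate on the true genotype; otherwise it collapses
  to the variant's HWE prior and the recorded call is redrawn from that
  prior. This keeps hard-call margins exactly HWE and gives
  dosage-vs-truth R² equal to the target in closed form — a deterministic
  "leak to adjacent classes" cannot lower R² at all, since it makes dosage an
  affine function of the true genotype. Dosage always equals the posterior
  expectation.
- Exposure and phenotype: E ~ Normal(164.8, 37.9) mEq/day; SBP follows the
  linear interaction model with Gaussian residual noise (default SD
  19.2 mm Hg, the discovery-population total SBP SD) plus optional
  covariate effects (defaulting to zero, since the source analysis adjusts
  for covariates without reporting their effect sizes); DBP follows its own
  sodium-only linear model. Two paired readings per trait carry 3 mm Hg
  within-visit measurement noise, and medicated subjects' recorded pressure
  is lower than the modelled untreated value by exactly the imputation
  constants, so preparation recovers the generated value. Medication status
  is assigned independently of genotype and BP (a simplification; real
  treatment is confounded with high BP).
- Sites: a replication block shifts age (+3.6 y), SBP (+3.3 mm Hg) and
  sodium (+11.8 mEq/day) means, matching the two emulated study populations.
- Spot urine: analytes are generated by inverting the sodium formula, with
  optional log-normal noise applied on the implied 24-h excretion scale;
  noise SD 0.3 yields an estimate-truth correlation near the estimator's
  published validation r = 0.54. (Noise applied to raw spot sodium would be
  damped by the 0.392 exponent and give r ≈ 0.87.)

What the generator does *not* emulate: linkage disequilibrium between
variants (each variant is independent), haplotype-level imputation error,
population stratification correlated with phenotype (PCs are pure noise),
or treatment assignment correlated with BP. Passing tests therefore
demonstrate the statistical machinery, not robustness to those real-data
features.

All generators are deterministic given (config, seed).

## Power simulation

One replicate draws E ~ Normal(μ_Na, σ_Na), G ~ Binomial(2, f) (additive)
or Bernoulli(f) (dominant/recessive), sets

    BP = β_E·E + β_GE·G·E + Normal(0, σ_resid),

fits the same nested models as the scan (including the main G term), and
records whether the interaction p-value falls below α = 1×10⁻⁵. Power is
the rejection fraction over 1,000 iterations (MC SE ≤ 1.6 points). The
analytic cross-check uses the exact noncentral χ²₁ power with

    NCP = n · β_GE² · Var(G) · σ_Na² / σ_resid²,

valid because with G ⊥ E the residual variance of G×E after projection on
(1, G, E) is exactly Var(G)·Var(E).

**Residual SD reconstruction.** The generative model describes residuals of
age-, sex- and BMI-*adjusted* BP, so σ_resid is the post-adjustment residual
SD — a quantity the source study does not publish. The raw phenotype SDs
(19.2/11.9 mm Hg) are not a valid stand-in: plugging them into the exact
power formula gives e.g. 49% where 67.5% is the published SBP-recessive
power. Inverting the exact power formula at the five published operating
points (`resid_sd_from_power`) yields σ ≈ 17.3 mm Hg for SBP and
≈ 10.9 mm Hg for DBP — a single value per trait fits all published points
within ~1 point, and implies covariate R² of about 0.19 (SBP) and 0.16
(DBP), realistic for age, sex and BMI. These are the trait defaults,
exposed as the `resid_sd` parameter. β_E defaults are 0.041426 (SBP) and
0.019897 (DBP) mm Hg per mEq/day. "Frequency" means effect-allele frequency
under the additive model and effect-genotype frequency (a 0/1 indicator)
under dominant/recessive, so the dominant and recessive cells coincide.

## Stratified post-hoc analyses

Sodium tertiles are assigned on the whole cohort before genotype
stratification, with boundary ties going to the lower tertile
(deterministic, consistent with strict-inequality boundary printing). Cells
report raw mean ± SD; the mean differences vs the low tertile and their
p-values come from an age-, sex-, BMI-adjusted linear model with tertile
indicators — the companion subgroup analyses are covariate-adjusted, and
reporting adjusted contrasts alongside raw summaries keeps the two
consistent. Subgroup sodium slopes are OLS of the trait on daily sodium
with the same covariates, per carrier group. The hypertension odds ratio
defaults to the unadjusted 2×2 cross-product with a Woolf log-SE 95% CI
(zero cells get the +0.5 Haldane correction with a warning); a
covariate-adjusted logistic path exists behind a flag. Sodium "low"/"high"
strata for the OR use the bottom/top whole-cohort tertile. Sensitivity
modes re-run the preparation stage (measured BP; medicated excluded;
hypertensives excluded) and emit the identical output schema for diffing.

## Problem sizes used in the test suite

The suite runs entire stages at reduced scale chosen for statistical
resolution per check: null calibration uses 10,000 single-variant refits and
a 10,000-variant null scan (λ bounds (0.9, 1.1)); parameter recovery uses
200 cohorts of n = 4,527; the end-to-end fixture is 500 subjects (300
discovery + 200 replication) × 200 variants with one planted recessive
interaction of β_GE = 0.5 — large enough that discovery, replication and
combined gates all pass with margin at that n. The HWE exact test is checked
exhaustively against enumeration for all genotype totals ≤ 200.

## Known limitations

- Genomic control on fewer than ~100 testable variants is noisy; the
  implementation warns.
- The LRT's ML form is mildly anti-conservative at very small n (the n vs
  n−p variance divisor); calibration checks run at n ≥ 300.
- The pipeline holds genotypes in memory; it targets desk-scale synthetic
  studies and method validation, not biobank-scale production scans.
- PCs are consumed as covariate columns; computing them is out of scope.
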