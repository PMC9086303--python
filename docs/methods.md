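# Methods

## Model

For offspring `i` in family `f`, the parent-of-origin model is

    y_i = β0 + β1·PD_i + β2·MD_i + γᵀz_i + b_i + ε_i

with `PD`/`MD` the number of minor alleles inherited from the father and
the mother, `z` the covariates (sex as a 0/1 indicator, age and birth year
centered), a family-structured random effect `b ~ N(0, C σ²_b)` and
independent residuals `ε ~ N(0, I σ²_ε)`. `C` is block diagonal over
families with unit diagonal and off-diagonal entries equal to twice the
kinship coefficient between offspring: 0.5 for full siblings and DZ twins,
1.0 for MZ twins, 0 across families. The origin-blind comparison model
replaces `(PD, MD)` by the dosage `G = PD + MD`.

Assumptions: nuclear families only (no half-sibs, loops or multiple
generations); biallelic autosomal SNPs coded on the minor allele; Gaussian
phenotypes after the rank-based inverse normal transform; parental origin
inferred from pedigree alone, never from population haplotypes.

The relatedness entries are twice the *kinship* coefficient. Reading them
as twice the *inbreeding* coefficient would zero the off-diagonals in an
outbred sample and remove the family structure entirely, so the kinship
reading is used and stated here prominently.

## Trio coding

With dosages (father, mother, offspring) ∈ {0,1,2}³, the coder enumerates
the parental transmissions consistent with the trio. A unique consistent
pair gives the exact (PD, MD); the one doubly-consistent cell — all three
heterozygous — is coded (0.5, 0.5) and retained in the regression (a flag
allows sensitivity reruns without those rows); the twelve impossible cells
are flagged as Mendelian errors. Inconsistencies and missing genotypes set
(PD, MD) missing for that offspring–SNP pair only, never family- or
scan-wide; counts are reported per SNP. No transmission imputation is
attempted when a parental genotype is missing — complete families are the
point of the design.

## Estimation

Writing V(λ) = λC + I with λ = σ²_b/σ²_ε, the REML criterion is profiled
over λ: the eigendecomposition C = U S Uᵀ is assembled block by block
(every family block has exchangeable correlation, and identical blocks
share one small `eigh` call), after which each candidate λ costs one
weighted least-squares solve on the rotated data. The scalar search runs
in log λ over [10⁻⁶, 10⁶] (bounded Brent, tolerance 1e-8), and the
boundary σ²_b = 0 is always evaluated explicitly and kept when it is at
least as good — so the no-family-variance case degrades exactly to
ordinary least squares. Decompositions are cached per offspring subset:
per-SNP missingness changes the subset and triggers (only then) a fresh
decomposition.

Fixed effects and their covariance come from GLS at the optimum,
`Cov(β̂) = σ̂²_ε (XᵀW⁻¹X)⁻¹`. Rank-deficient designs (e.g., PD ≡ MD at a
SNP monomorphic in fathers) raise an error naming the collinear columns;
the scan driver converts per-SNP failures to `untested` rows.

## Tests and classification

- β1 = 0 and β2 = 0: Wald statistics with the normal reference, two-sided,
  at the genome-wide level 5×10⁻⁸.
- β1 = β2: single-degree-of-freedom F statistic on the contrast with
  denominator df = n − p, at level 0.05. A flag switches to the chi-square
  reference; at n ≈ 2,000 the two are numerically indistinguishable.
- Confidence intervals are Wald intervals (normal quantiles for single
  coefficients, t quantiles for the contrast, matching the F reference).
- Classification uses strict inequalities and no multiple-testing
  correction beyond the fixed thresholds: a genome-wide significant β1
  with significant asymmetry ⇒ maternal imprinting; symmetrically for β2 ⇒
  paternal imprinting. The (never observed in practice) case of both is
  reported as a combined label plus a warning. Raising the genome-wide
  threshold can only enlarge the significant set.

## Phenotype transform

Each trait is mapped to Φ⁻¹((r − 0.375)/(n − 2·0.375 + 1)) of its mean-tie
rank r — the Blom variant of the rank-based inverse normal transform. The
offset is a parameter; 0.375 is the common default and results are
insensitive to it at study sample sizes. The transform is applied once
over the full filtered offspring set (not per family or per stratum). The
Spearman screen draws one offspring per family with a seeded generator so
sibling correlation cannot inflate the descriptive correlations.

## Synthetic data

The generator emulates the structure of the MCTFR behavioral-disinhibition
family sample: by default 621 twin families (half MZ), 377 full-sibling
families and 189 one-offspring families — 1,187 families, 2,185 offspring;
founder genotypes HWE at MAF 0.3; offspring age 17.8 ± 0.7, father
44.6 ± 5.4, mother 42.4 ± 4.9, sex Bernoulli(0.5), birth year derived from
age against a mid-1990s assessment year; β1 = 0.5, β2 = 0, σ²_b = 0.5,
σ²_ε = 1 at the causal SNP; covariate effects default to zero (tests that
exercise covariates set them explicitly). The family random effect is
drawn from the same per-family correlation blocks the analysis kinship
uses, so generator and model agree by construction. All five phenotype
columns share one linear predictor and receive independent family/residual
noise, which also yields mildly positively correlated traits.

True transmitted origins are recorded *before* missingness or genotyping
error is injected (errors perturb offspring dosages to a different value
in {0,1,2}), so the coder can be validated cell by cell: every Mendelian
flag must sit on a perturbed cell. Note the flagged rate is below the
injected rate at intermediate MAF — many perturbed trios remain Mendelian-
consistent — so rate checks are on the perturbation mask, not the flags.

What the generator does not emulate: linkage disequilibrium between SNPs
(the scan is marginal per SNP), ascertainment of the families, genotyping
error in parents, non-Gaussian phenotype noise, and any true covariate or
cohort structure. Passing tests therefore demonstrate correctness of the
machinery and calibration under the stated model, not robustness to those
real-data features.

## Validation and problem sizes

- The REML fit is checked against an independent dense grid-search oracle
  (λ grid on [0, 10], explicit V inverses) to 1e-4 in log-likelihood on
  40-offspring instances, and against statsmodels' random-intercept
  MixedLM on the MZ-only special case where the two models coincide.
- Effect recovery: 200 simulated replicates at the full 1,187-family mix
  recover mean β̂1 and β̂2 within 3 Monte-Carlo SEs of (0.5, 0).
- Calibration: 1,000 null replicates at the same scale give an F-test
  rejection rate within 2 binomial SEs of 0.05 and Wald p-values passing a
  Kolmogorov–Smirnov uniformity check at α = 0.01.
- Power ordering: with a one-parent effect β1 = 0.3 (chosen so neither
  test saturates at power 1), the PD Wald test rejects at 5×10⁻⁸ at least
  as often as the origin-blind genotype test over 200 paired replicates on
  identical data.

These replicate counts and instance sizes are the package's standing test
configuration; the block-diagonal decomposition cache makes a study-scale
fit cost milliseconds, so the full simulation suite runs in a few minutes.

## Known limitations

- Pedigree-defined relatedness only; no marker-estimated kinship.
- Quantitative traits only; no binary-trait (GLMM) variant.
- The twin label requires zygosity flags (MZ/DZ) and equal birth years;
  zygosity-unknown twin pairs are treated as full siblings (conservative,
  affects only the C matrix).
- Multi-allelic markers are collapsed to minor-vs-rest at load time.
- Wald/F inference; no likelihood-ratio or permutation alternatives.
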