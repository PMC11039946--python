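# Methods

## The analysis this package implements

`mrkit` implements a two-sample Mendelian randomization (MR) workflow for
GWAS summary statistics: genetic variants strongly associated with an
exposure (e.g. a circulating hormone level) serve as instrumental variables
for estimating the causal effect of that exposure on an outcome (e.g. an
inflammatory bowel disease diagnosis), with the exposure and outcome
associations drawn from two independent, non-overlapping GWAS.

The chain for one exposure–outcome pair is:

1. **Instrument selection.** Keep SNPs with exposure p < 5×10⁻⁸; greedily
   LD-clump (r² < 0.001 within a 10,000 kb window, most significant SNP of
   each linked group kept); if fewer than two SNPs survive, restart from the
   full table at the relaxed threshold 5×10⁻⁶. Finally require instrument
   strength F = β²/SE² strictly greater than 10. The F filter is applied
   after clumping; the per-SNP audit trail records every disposition so the
   order can be inspected.
2. **Harmonization.** Align outcome records to the exposure's effect
   allele: swapped allele pairs get their outcome beta negated; palindromic
   SNPs (A/T, C/G) are excluded unconditionally, with no frequency-based
   strand inference; SNPs absent from the outcome GWAS are dropped without
   proxy lookup.
3. **Estimation.** Three estimators on the harmonized pairs
   (x = β_exposure, y = β_outcome, weights w = 1/SE²_outcome):
   - *Random-effects IVW* (primary): weighted regression of y on x through
     the origin, β̂ = Σwxy / Σwx². The SE is the fixed-effect SE
     √(1/Σwx²) inflated by √(Q/(n−1)) when Cochran's Q exceeds its degrees
     of freedom, and never deflated (multiplicative overdispersion floored
     at 1).
   - *MR-Egger*: the same regression with an unconstrained intercept, each
     SNP first oriented so x ≥ 0. The slope is a pleiotropy-adjusted causal
     estimate under the InSIDE assumption; the intercept estimates the mean
     directional pleiotropic effect. SEs use the same dispersion floor with
     n−2 degrees of freedom.
   - *Weighted median*: the interpolated weighted median of per-SNP Wald
     ratios y/x with inverse-variance weights (x/SE_outcome)², consistent
     when valid instruments carry ≥50% of the weight. Its SE is the SD of
     1000 parametric-bootstrap replicates (betas resampled from normals
     centred on the observed values with their reported SEs, fixed seed).
   All inference is z-based: p = 2(1−Φ(|β/SE|)), CI = β ± 1.96·SE; binary
   outcomes are additionally reported as OR = exp(β) with exponentiated CI
   bounds, so the OR is always the geometric mean of its CI.
4. **Sensitivity.** Cochran's Q (n ≥ 2), the Egger intercept test (n ≥ 3),
   and MR-PRESSO (n ≥ 4): a parametric-simulation test on the weighted
   residual sum of squares of the IVW regression, with each SNP's residual
   taken against a leave-one-out slope. Per-SNP outlier p-values are
   Bonferroni-corrected; flagged SNPs are removed and the IVW re-fitted
   (outlier-corrected estimate); the distortion test compares the percent
   change of the estimate against the distribution from removing the same
   number of SNPs at random. Tests whose preconditions fail are reported
   as unavailable with a reason, not as errors. Heterogeneity never
   invalidates a result by itself — the random-effects IVW absorbs it — it
   only annotates the report.
5. **Verdict.** A finding is *robust* iff the IVW p < 0.05 **and** all
   available methods agree on the sign of the estimate. When a method is
   unavailable (too few instruments) the comparison runs over the available
   ones and is flagged as reduced. No multiple-testing correction is applied
   across an exposure–outcome grid; a Bonferroni column is emitted as
   opt-in annotation.

Forward (trait → disease, OR scale) and reverse (disease → trait, beta
scale) analyses of the same pair are fully independent runs, including
instrument selection. Sex-stratified analyses are ordinary manifest entries
whose input GWAS tables are themselves stratified; no special machinery
exists beyond the stratum label.

## The synthetic data generator

Real hormone/IBD-scale GWAS cannot be bundled, so every pipeline stage is
validated against simulated two-sample summary statistics with known ground
truth (`mrkit.simulate`). For SNP j:

- MAF_j ~ Uniform(maf_range), default (0.05, 0.5);
- instrument effect γ_j: zero with probability 0.8, else N(0, 0.05²)
  (per-allele effect on a standardized trait);
- SE formula: SE = 1/√(2·n·MAF·(1−MAF)), the standard asymptotic for a
  standardized continuous trait; binary outcomes reuse it as a log-odds
  approximation;
- observed exposure beta ~ N(γ_j, SE²_exp,j) with n_exp = 300,000
  (biobank-scale hormone GWAS);
- horizontal pleiotropy α_j = 0 for valid SNPs, else N(μ_α, σ_α²)
  (a π_invalid fraction);
- observed outcome beta ~ N(θ·γ_j + α_j, SE²_out,j) with n_out = 35,000
  (IBD case-control scale), independent of the exposure noise (two-sample
  assumption);
- optional LD blocks: members share the lead SNP's signal scaled by the
  block correlation r, exposure sampling errors get constant within-block
  correlation r, and the implied block-diagonal r matrix is exported for
  the clumper — no genotype reference panel anywhere;
- realism corruption the harmonizer must survive: 5% palindromic allele
  pairs, 5% of outcome rows emitted with swapped alleles / negated beta /
  complemented EAF.

With the defaults (m = 2000 candidates, ≈400 true signals) roughly 300
instruments survive selection — deliberately on the generous end so that
estimator calibration is measured in a strong-instrument regime.

What the generator does **not** emulate: case-control ascertainment and the
binary-trait likelihood (outcome betas are Gaussian around θγ), ancestry
structure and stratification, sample overlap between the two GWAS,
MAF-dependent effect-size architecture, and realistic genome-wide LD (only
explicit constant-correlation blocks). Passing tests therefore demonstrate
correctness of the statistical machinery under the stated structural model,
not robustness to every pathology of real consortium data.

## Numerical and design choices

- **Dispersion floor.** The multiplicative random-effects SE never drops
  below the fixed-effect SE (dispersion floored at 1), matching the default
  behaviour of the standard summary-data MR toolchain. Cochran's Q and the
  IVW dispersion share one implementation, so the heterogeneity test and
  the SE inflation can never disagree.
- **First-order Wald weights.** Exposure-side uncertainty is ignored in
  the IVW/median weights (w = x²/SE²_out); this is the common first-order
  convention. Second-order weights are out of scope.
- **z- not t-inference.** Printed OR/CI/P triples in the MR literature are
  mutually consistent under the normal reporting model (verified in the
  acceptance suite to ±0.002 on p), so z-quantiles are used throughout,
  with the conventional 1.96 for the 95% CI.
- **Clumping determinism.** Greedy selection orders by (p-value, chromosome,
  position, snp_id), making the result independent of input row order and
  idempotent. SNPs missing from the LD matrix are treated as unlinked with
  a logged warning.
- **Boundary semantics.** p-thresholds are strict (<), the F filter is
  strict (>10), SNPs *within* the window are candidates for removal.
- **MR-PRESSO.** n_sim = 1000 with (1+exceedances)/(n_sim+1) smoothing, so
  Monte-Carlo p-values are never exactly 0; outlier threshold is the
  Bonferroni-corrected 0.05. Simulated outcome betas are centred on
  θ̂₋j times the *jittered* exposure beta — the coherent parametric
  bootstrap, and measurably better calibrated at nonzero slope than
  centring on the observed beta. The distortion null removes |outliers|
  SNPs uniformly at random from the full set. If every SNP is flagged, no
  corrected estimate is reported and an error is logged.
- **Single-instrument degradation.** IVW with one SNP degrades to the Wald
  ratio with a logged note; Egger and the weighted median are skipped with
  a recorded reason below 3 instruments, MR-PRESSO below 4.
- **Recovery checks are coverage checks.** Parameter-recovery assertions
  compare the mean estimate over 200 seeded replicates to the truth within
  two *per-replicate* SDs. A stricter SEM-of-the-mean criterion is
  unattainable in principle: selecting instruments at genome-wide
  significance from the exposure GWAS induces winner's-curse/regression-
  dilution attenuation of order 1% of θ (measured ≈0.002 at θ = 0.3),
  small against any single analysis's SE but many SEMs at 200 replicates.
  The same applies to the weighted median's finite-sample shift under
  one-sided invalid instruments.

## Known limitations

- The weighted median's parametric bootstrap SE (resampling around the
  observed betas, per the standard recipe) is structurally conservative at
  the null: the bootstrap ratios carry roughly twice the sampling scatter
  of the truth, inflating the SE by ~15–20% in the strong-instrument
  regime. Measured null rejection is ≈0.02–0.03 at nominal 0.05 (IVW 0.044,
  Egger 0.056 are nominal). The fixed-weight bootstrap variant does not
  change this. The acceptance suite documents this as a failing calibration
  check rather than silently widening the band.
- LD handling is matrix-based and synthetic-facing; clumping against a
  genotype reference panel, proxy-SNP lookup, Steiger direction filtering
  and multivariable MR are out of scope.
- Continuous-trait betas are assumed already standardized; no unit
  conversion is attempted.

## Problem sizes

Default test and acceptance workloads: 500 replicates for null calibration,
200 for parameter recovery and MR-PRESSO null uniformity, 100 seeded runs
for planted-outlier detection, m = 2000 candidate SNPs per replicate
(m = 300 for the invalid-instrument scenario so that ~15 instruments
survive), 1000 bootstrap/simulation draws per analysis. These sizes keep
Monte-Carlo error well below the tolerances being asserted.
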