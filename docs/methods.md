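# Methods

## Statistical model

### pQTL scan

Protein abundances are prepared in the order the association model assumes:

1. Proteins with fewer than 200 measurements above the assay's limit of
   detection are excluded; retained columns are rank-inverse-normal
   transformed with the Blom offset, Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks
   for ties. The offset is a package choice; any standard offset changes
   scores by O(1/n).
2. Stage 1 removes measured covariates by ordinary least squares (intercept
   added; rank-deficient covariate matrices are rejected naming the collinear
   columns).
3. Stage 2 fits the one-GRM variance-component model y = μ + g + e,
   g ~ N(0, σ²_g K), e ~ N(0, σ²_e I) by REML, profiled over
   h² = σ²_g/(σ²_g+σ²_e) in the GRM eigenbasis (bounded scalar
   minimization; non-convergence raises with the last bracket). The
   association response is the *environmental* residual e = σ²_e V⁻¹(y − μ̂),
   i.e. the phenotype minus the genetic BLUP — the GRAMMAR idea. The "+"
   rescaling of the original GRAMMAR+ procedure is not reproduced: the
   subsequent transform is rank-based, so a monotone rescaling has no effect
   on anything downstream. Residuals with |z| > 4 are removed and the
   remainder rank-inverse-normal transformed.
   With K = I the variance split is unidentifiable; the contract returns
   h² = 0 and the z-scored input.
4. Stage 3 is vectorized per-SNP simple linear regression on dosage with
   normal-approximation p-values (a t option exists; at n ≈ 1000 the
   difference is negligible). Monomorphic variants are emitted flagged
   (`undefined=True`), never dropped, so genome-wide scans cannot abort.

Because stage 2 shrinks and stage 3's response is re-standardized, reported
effect sizes are in standard deviations of the *transformed residual*, not of
the raw protein — the same caveat the real design carries.

### Clumping, replication, instruments

Greedy clumping: the smallest-p unassigned variant with p ≤ 5×10⁻⁸ founds a
clump and absorbs every unassigned variant within ±5 Mb with r² > 0.2
(PLINK semantics: non-significant variants may be absorbed but never found).
Ties in p break by position then rsid, for determinism. Variant pairs missing
from the LD source count as r² = 0 with a logged warning (configurable to
hard-error). Replication: p below 0.05 / (number of significant discovery
leads) with sign agreement. Instruments: per protein, the replicated local
(gene ± 150 kb, inclusive, position-based and therefore invariant to allele
labelling) lead with the lowest discovery p, requiring MAF > 1% and info
> 0.95 in both cohorts; further qualifying leads are kept as independent
sensitivity instruments (clump leads are mutually un-clumpable by
construction, so their pairwise r² ≤ 0.2).

### Delta-method MR

β̂_YX = (β̂_YZ/β̂_XZ)(1 + se²_XZ/β̂²_XZ), the second-order Taylor expansion of
the ratio of expectations; se_YX is first order. The published rendering of
the standard-error formula omits a radical; dimensional analysis forces
se_YX = √(se²_YZ/β²_XZ + β²_YZ se²_XZ/β⁴_XZ), which is what is implemented
(and what reproduces the printed example results). Exposure statistics must
come from the replication cohort; the screen raises on discovery-cohort
exposure unless explicitly overridden (winner's-curse guard). Harmonization
aligns the outcome record's effect allele to the exposure's, flipping the
outcome beta for swapped allele order and complementing non-palindromic
records across strands; A/T and C/G pairs are retained but flagged
`ambiguous_palindrome` (no frequency-based resolution is attempted, matching
the source design); unresolvable allele sets produce exclusion records.
Benjamini–Hochberg FDR (statsmodels backend, cross-checked against the
step-up definition in tests) runs separately within each outcome source
group. Binary-outcome effects stay on the scale the outcome study provides
(e.g. log OR); no conversion is attempted.

### HEIDI

For the selected sub-locus the per-variant estimate is the first-order ratio
b_i = β̂_YZi/β̂_XZi (the second-order correction is reserved for the headline
top-SNP estimate, matching the cited method), d_i = b_i − b_top, and the
covariance of d follows from first-order propagation with
cov(β̂_i, β̂_j) = r_ij se_i se_j within each trait and independence across
traits. T = Σ z²_{d_i} is referred to Σ λ_k χ²₁ with λ the eigenvalues of the
correlation matrix of d, by Imhof numerical integration (equal eigenvalues
short-circuit to an exact scaled chi-square; the extreme tail and any
integration failure fall back to the Satterthwaite moment match; a singular
d-covariance is ridge-regularized with a logged epsilon). Selection: window
2000 kb, at most 20 variants used (top included), MAF > 0.01 and
info > 0.95. Constants the headline study does not state are taken from the
cited SMR software and are config values: exposure-significance gate
p < 1.57×10⁻³, r²-with-top within [0.05, 0.9] (near-duplicates above the
upper bound pruned keeping the more exposure-significant), and a minimum of
3 partners, below which the result is `insufficient_snps` with no p-value.
Small p means heterogeneity — evidence against a single shared causal
variant.

### CLPP

Per trait the locus z-vector is modelled as N(0, R + s²R_c R_cᵀ) given causal
configuration c (the marginalized single-effect-per-causal-variant model),
with binomial prior γ^{|c|}(1−γ)^{m−|c|}, γ = 0.01. Because R_c = R E_c,
Woodbury reduces each configuration's Bayes factor to a |c|×|c| solve, so
exhaustive enumeration over |c| ≤ 2 on the 101-variant locus (50 variants
either side of the instrument, inclusive) costs milliseconds; the reference
analysis's max of 5 causal variants is available behind an explicit
enumeration budget. The prior effect scale s = 5.2 follows the cited
software's convention (the study does not report its value). Empirical LD is
PSD-repaired by eigenvalue clipping at 1e-6, logged. CLPP at the instrument
is the product of the exposure and outcome posterior inclusion
probabilities; > 1% is the colocalization call.

## The synthetic world

The generator emulates the design's statistical structure, not human
genomes:

* **Genotypes** are Gaussian-copula haplotypes: latent MVN thresholded at
  allele-frequency quantiles, dosage = sum of two haplotypes. The latent
  correlation is calibrated per variant pair (bivariate-normal CDF
  root-find) so that the *dosage* correlation equals the requested target;
  within a block, allele frequencies scatter around a shared base with a
  spread shrinking in the block's maximum |r| (strongly linked variants
  carry similar frequencies, and the attainable point correlation of
  thresholded indicators is frequency-bounded). Blocks are independent and
  live on separate chromosomes by default.
* **Proteins** are Σ β_XZ · (standardized dosage) + covariate effects (age,
  sex; defaults 0.1 sd each) + polygenic N(0, h²·GRM) + noise on a
  unit-variance scale. The GRM is computed from a separate set of 500
  independent background markers — in real data a single locus is a
  negligible fraction of a 300k-marker GRM, and building it from the scan
  variants would let the BLUP absorb the pQTL signal.
* **Outcome GWAS** are generated at the summary-statistic level:
  z ~ MVN(√n·R·b, R), β̂ = z/√n, se = 1/√n, where b holds the direct effects
  of the scenario — `causal`: β_YX·β_XZ at the protein's causal variants
  (a causal chain); `linkage`: an independent effect at a distinct variant
  in LD (r² ≈ 0.6 by default) with the pQTL; `null`: zero.
* **Defaults** follow the emulated design where it states values: cohort
  sizes 909/998, 5×10⁻⁸ / Bonferroni / ±150 kb / MAF & info filters, HEIDI
  2000 kb & 20 SNPs, CLPP 50-SNP flanks & 1%. Where it does not, the
  package fixes one realistic value and documents it: pQTL variance
  explained 20% (a strong local Olink-scale pQTL; the study does not report
  its distribution, and it is an exposed parameter), causal effect
  β_YX = 0.3 sd/sd, outcome GWAS n = 100,000, polygenic h² = 0.1, AR(0.9)
  block LD over 21 variants per protein locus.

What a green test does *not* establish: the generator has no allele-frequency
spectrum realism, no X chromosome, no missing genotypes, no imputation error
beyond an optional info-score degradation knob, and cross-cohort LD
differences only through an explicit mismatch knob (default 0). Error-rate
calibration results therefore speak to the statistics, not to robustness
against real-data artifacts. Notably, in the end-to-end cohort run the
exposure scan's *empirical* LD differs from the analytic reference LD by
sampling noise (~n^-1/2), which inflates HEIDI rejections of genuinely causal
pairs above the summary-level type-I rate — the same false-positive mechanism
the emulated study reports for its own HEIDI step.

## Numerical choices

* REML: bounded scalar minimization of the profiled criterion on
  h² ∈ [1e-6, 1−1e-6], xatol 1e-8.
* Latent-correlation calibration: Brent root-find, xtol 1e-6, with a cache
  keyed on (r, f₁, f₂); unattainable targets raise naming the attainable
  range; calibrated latent matrices are eigenvalue-clipped to PSD.
* Imhof integration: QAGI on [0, ∞) with limit 500; its error estimate is
  pessimistic for oscillatory integrands, so accuracy is validated in tests
  against exact chi-square cases and Monte Carlo rather than gated on the
  estimate.
* Ties: clump founding order and instrument selection break ties by (p,
  position, rsid); BH uses the standard step-up.
* Degenerate inputs: monomorphic variants flagged; GRM = I returns the
  h² = 0 contract; empty lead sets return empty frames rather than dividing
  by zero; p-values are clipped away from exact 0.

## Scale-downs

The default end-to-end world (30 proteins × 21 variants, 900 MR pairs) is a
desk-scale stand-in for the emulated 249-protein genome-wide design; the
counting logic is identical and the acceptance script re-runs the whole
pipeline in ~25 s. Replicate counts in the acceptance suite follow the
stated protocol sizes (10⁶ Monte-Carlo draws, 500–1000 replicates for
recovery/calibration, 200 per arm for colocalization discrimination).
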