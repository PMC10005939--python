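# Methods

`sfactor` compares two definitions of a "suicidality" trait built from four
item-level GWAS of suicidal thoughts and behaviors — *thought life not worth
living* (TLNWL), *thoughts of self-harm* (TSH), *actual self-harm* (ASH), and
*attempted suicide* — either as a phenotypic 0–4 aggregate score, or as a
latent common factor ("S-factor") estimated from the items' genetic
covariance by genomic structural equation modeling.  This note records the
models, the numerical choices, and what the synthetic validation does and
does not establish.

## Item aggregation

The ordinal suicidality score counts endorsed items: all-no scores 0, each
"yes" adds 1, up to 4 (most severe).  Any missing item makes the aggregate
missing rather than deflating the count; the analysis population is complete
responders.  Over independent items with endorsement probability p the score
is exactly Binomial(4, p), which the tests verify by enumerating all 16
response patterns.

## LD-score regression

Univariate heritability comes from the weighted regression
E[χ²_j] = 1 + N·a + (N·h²/M)·ℓ_j, cross-trait genetic covariance from
E[z1_j z2_j] = c + (√(N₁N₂)·ρ_g/M)·ℓ_j, with the cross-trait intercept c
absorbing sample overlap.  Weights are the standard two-step LDSC scheme
(1/[ℓ_j (1 + N h² ℓ_j/M)²], first pass unweighted); cross-trait weights
reuse the step-one slopes so that the rg of a trait with itself is exactly 1.
Standard errors are delete-a-block jackknives over 200 contiguous variant
blocks; the multivariable sampling matrix V is the joint jackknife covariance
of all k(k+1)/2 estimates on shared blocks, so sampling dependence between
elements of S is retained.  Negative point estimates are reported, never
floored — downstream difference tests need the unbiased values.

Two deliberate departures from common practice:

- **No χ² cap by default.**  The conventional regression-SNP cap
  max(80, 0.001·N) is available (`chi2_max="ldsc"`) but off by default.  At
  desk scale a sparse architecture (e.g. 100 causal SNPs carrying h² = 7.6%
  over M = 2×10⁴) puts genuine signal at χ² of several hundred; truncating it
  biases h² downward by roughly a third.  The cap is an outlier-robustness
  device for real data, not part of the estimator.
- **Heterogeneous LD panel.**  `simulate_ld_panel` mixes AR(1) segments
  (default quarters with block size/ρ of 1/0, 10/0.5, 50/0.9, 100/0.95,
  ℓ ∈ [1, 19.4]).  With a homogeneous panel, LD-score variation exists only
  within blocks and the regression slope is essentially unidentified
  conditional on a sparse architecture draw (the oracle conditional slope has
  sd ≈ 0.05 around a truth of 0.07); the between-segment spread, which is
  what real panels provide, restores identification (conditional sd ≈ 0.016).
  LD scores are computed exactly from the generating correlation matrices,
  never estimated from genotypes.

Stratified (partitioned) heritability regresses χ² on per-annotation LD
scores; enrichment of category c is (h²_c/h²)/(M_c/M) with h²_c assembled
from the annotation overlap matrix, jackknife SEs on the ratio, and a
two-sided p against enrichment = 1.  The base annotation has enrichment
exactly 1 by construction.  The MHC interval (chr6:25–34 Mb by default) is
excluded when positions are available.

## Common-factor model

The one-factor model Σ(θ) = φ λλ′ + diag(θ) is fitted to (S, V) by
diagonally weighted least squares — minimize (s − σ(θ))′ diag(V)⁻¹
(s − σ(θ)) over the vech — identified by fixing the marker indicator's
loading to 1 (TSH, the most strongly loading item, in the canonical
configuration) and estimating the factor variance.  Optimization is L-BFGS-B
with analytic gradients from starts λ = 0.5, θ = 0.5·diag(S), plus five
perturbed restarts.  Parameter SEs use the sandwich estimator with the full
V.  Promax rotation is the identity for a single factor and is applied as an
explicit no-op.  If the unconstrained optimum has a negative residual
variance (Heywood case), the model is refitted with θ ≥ 0 and flagged.

Fit statistics: the model χ² is the quadratic form of the moment residuals
against the pseudo-inverse of (I−P) V (I−P)′, where P is the linearized DWLS
projection — the correct asymptotic covariance of DWLS residuals, so exact
fits give 0 and data generated under the model give E[χ²] = df (measured
mean 2.02 over 50 replicates at df = 2; the naive r′V⁻¹r form runs ~50%
hot because DWLS is not the efficient weighting).  df = k(k+1)/2 − n_free
with n_free = 2k; AIC = χ² + 2·n_free; CFI compares against an independence
model that estimates only the k genetic variances; SRMR is the RMS residual
between correlation-standardized observed and implied matrices over unique
elements.  A model is declared superior only if it dominates on lower AIC,
lower SRMR, and higher CFI; otherwise the comparison is returned as
indeterminate with per-criterion winners.  (A note on df: a saturated
three-indicator one-factor model has df = 0 by this counting; the df
reported for such models elsewhere in the literature on this comparison is
not reproducible from the formula, and this package always reports its own
formula's value.)

The per-SNP factor GWAS holds the fitted measurement structure and estimates
the SNP→factor effect by one-parameter DWLS, which reduces to the weighted
proportionality solution β_F = Σ_t λ_t b_t/SE_t² / Σ_t λ_t²/SE_t² with
SE = (Σ_t λ_t²/SE_t²)^{-1/2}.  The output's per-SNP effective N is the sum
of indicator sample sizes weighted by squared standardized loadings, so LDSC
on the factor output reads heritability on the factor's own scale.  Output
is emitted in the munged dialect (SNP A1 A2 Z N) and feeds back into every
downstream stage unchanged.

## Effect-size mixture and projections

Filtered Z-scores are modeled as
z_j ~ (1−π_c)·N(0, α) + π_c·N(0, α + N_j σ² ℓ_j): π_c the proportion of
susceptibility SNPs, σ² the non-null effect variance, α residual inflation.
LD enters only through ℓ_j — an independent-SNP composite likelihood; the
full LD-window convolution of the original estimator is out of scope, and
accordingly the mixture is validated on LD-free panels (under strong LD the
marginal model mis-attributes causal neighbors to π_c; this is a documented
fidelity gap).  Optimization runs in (logit π_c, log σ², log α) with
analytic gradients from a grid of π_c starts, within domain bounds π_c ≤ ½,
σ² ≤ 1, α ∈ [e⁻⁵, e⁵]; SEs come from the inverse observed information in
natural parameters, and fits at any bound are flagged.

Because the upstream QC protocol removes SNPs with Z² > 80, the likelihood
conditions each observation on surviving that truncation (`z2_max`, default
80; None recovers the plain form).  Without conditioning, the clipped
non-null tail reads as smaller σ² and larger π_c as soon as causal
chi-squares cross the boundary; with it, recovery is unbiased up to ~15%
tail loss.  Beyond roughly half the causal mass clipped the model is no
longer identified (the σ² bound then catches a degenerate uniform-component
optimum and the fit is flagged).

Expected genome-wide-significant discoveries at sample size N use the exact
marginal: Z ~ N(0, α + Nσ²) for non-null SNPs, so
E[#GWS] = m·[π_c·2Φ̄(z_c/√(α+Nσ²)) + (1−π_c)·2Φ̄(z_c/√α)] at the
P < 5×10⁻⁸ threshold.  Gauss–Hermite quadrature over β is retained as an
alternative method, with the caveat that the integrand sharpens as N grows
and fixed node counts degrade.  Projection CIs are equal-tailed quantiles
over parameter vectors drawn from the asymptotic normal, truncated to the
valid domain, and always bracket the point estimate.

## QC filter

Sequential: variant allowlist (HapMap3-style) → drop Z² strictly greater
than 80 (the boundary is kept) → drop N below 0.67 × the 90th percentile of
N, the percentile computed on the post-allowlist set (the ordering is a
documented choice; the stages are reported separately and reconcile exactly
with the row counts).  The 90th percentile uses linear interpolation.

## Polygenic scores

Scores are Σ_j w_j·dosage_ij over weight-table variants harmonized to the
cohort (A1/A2 swaps negate w; irreconcilable pairs dropped and counted),
restricted to minor allele frequency > 5% computed in the target cohort
itself, with per-variant mean imputation of missing dosages and mean-centered
output.  Associations use the covariate model age, age², sex×age, sex×age²
and ten principal components: logistic regression with the incremental
Nagelkerke R² (R²_CS max-rescaled) for binary items, linear regression with
incremental adjusted R² for the ordinal 0–4 score and for continuous traits.
Continuous-shrinkage weighting of the training effects is out of scope;
weights are raw effect sizes (a documented fidelity gap versus shrinkage
methods).

## Synthetic-data generator

The generator's canonical study: four items loading (0.9, 1.0, 0.7, 0.5) on
one latent factor with factor h² = 7.6% (the aggregate-trait scale reported
for this phenotype), per-item residual h² = 1%, point-normal causal effects
with π_c = 0.005, M = 2×10⁴ variants, N = 10⁵, full sample overlap with
phenotypic item correlation 0.4 (the overlap and item correlation are not
published quantities; they are free parameters with these defaults).  Factor
and residual effect vectors are rescaled so realized Σβ² equals the target
heritability.  Z-scores are √N(Rβ) plus noise correlated R within LD blocks
and overlap×pheno-corr across traits — the cross-trait LDSC-intercept
structure of shared samples, produced without simulating individuals.  The
mixture stage uses an LD-free panel at M = 2×10⁵, N = 1.2×10⁵ (≈1000 causal
SNPs at π_c = 0.005): large enough for ML asymptotics, small enough to run
in seconds; the target cohort (binomial dosages, thresholded liabilities
sharing a factor, independent covariates) defaults to n = 256, the scale of
the smallest published target group.  All randomness descends from one
integer seed through named substreams; identical seeds give bit-identical
output.

What passing tests show: the estimators recover the parameters of their own
generating model at desk scale, with calibrated standard errors and null
behavior.  What they do not show: robustness to real LD structure (the AR(1)
panel has no long-range LD and the mixture is validated LD-free), to
uncorrected stratification, to allele-frequency-dependent architectures, or
to real phenotype measurement; and desk-scale M means per-SNP effects are
orders of magnitude larger than in a biobank GWAS.

## Known limitations

- Difference tests assume independent estimates; aggregate- and factor-based
  definitions built from the same samples make them anti-conservative.  An
  optional covariance term in `zdiff_test` lets callers correct this.
- The factor GWAS treats SNPs one at a time; no heterogeneity (Q-type)
  statistic is computed.
- rg is a ratio estimate; when either heritability estimate is non-positive
  the result is returned flagged as undefined rather than as a number.
- With an active Heywood bound the projected χ² can understate misfit (the
  residual is no longer orthogonal to the constrained tangent space).
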