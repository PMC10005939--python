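# sfactor

Tools for comparing a phenotypically aggregated ordinal "suicidality" trait
with a latent genetic factor ("S-factor") built from the same four item-level
GWAS of suicidal thoughts and behaviors — thought life not worth living,
thoughts of self-harm, actual self-harm, and attempted suicide.  The package
is aimed at statistical geneticists who work from GWAS summary statistics and
want the whole comparison pipeline — and a synthetic-data generator that
makes every stage testable without any data download.

## What it computes

- **LD-score regression** (`sfactor.ldsc`): SNP-heritability
  E[χ²_j] = 1 + N·a + (N·h²/M)·ℓ_j, genetic correlation r_g = ρ_g/√(h²₁h²₂),
  the multivariable genetic covariance matrix **S** with the joint
  block-jackknife sampling matrix **V**, and stratified annotation
  enrichment (h²_c/h²)/(M_c/M).
- **Common-factor genomic SEM** (`sfactor.factor`): DWLS fit of
  Σ = φλλ′ + Θ to (S, V) with a marker loading fixed to 1, χ²/df/AIC/CFI/SRMR
  fit indices, Heywood-case correction by bound-constrained refit, a
  dominance rule for model comparison, and a per-SNP common-factor GWAS whose
  output feeds back into every summary-statistic analysis.
- **Effect-size distribution** (`sfactor.mixture`): the two-component model
  z_j ~ (1−π_c)·N(0, α) + π_c·N(0, α + N σ² ℓ_j) — π_c the proportion of
  susceptibility SNPs, σ² their effect variance, α residual inflation — with
  truncation-aware likelihood behind the Z² ≤ 80 QC filter, and projected
  genome-wide-significant discovery counts at future sample sizes
  (P < 5×10⁻⁸).
- **Comparison layer** (`sfactor.report`): z difference tests,
  Benjamini–Hochberg FDR, Bonferroni thresholds, concordance regression of
  genetic-correlation profiles, and a self-describing report bundle.
- **Polygenic scoring** (`sfactor.pgs`): dosage scoring with target-cohort
  MAF > 5% filtering, the age/age²/sex-interaction/10-PC covariate model,
  Nagelkerke pseudo-R² for binary items, and cross-score Pearson correlation.
- **Synthetic data** (`sfactor.synthetic`): block-AR(1) LD references with
  exact LD scores, factor-structured multi-trait summary statistics with
  sample-overlap intercept structure, individual-level target cohorts under
  a liability-threshold model, and the 0–4 item aggregation rule.

## Worked example

```python
import numpy as np
from sfactor import synthetic, ldsc, factor

ld = synthetic.simulate_ld_panel(20_000, seed=0)
model = synthetic.TrueModel(
    n_snps=20_000,
    loadings=np.array([0.9, 1.0, 0.7, 0.5]),
    residual_h2=np.array([0.01] * 4),
    factor_h2=0.076,
    pi_c=0.005,
    seed=0,
)
items = synthetic.simulate_sumstats(model, ld, n_per_trait=100_000,
                                    overlap_fraction=1.0)
cov = ldsc.genetic_covariance(items, ld,
                              names=["tlnwl", "tsh", "ash", "attempt"])
fit = factor.fit_common_factor(cov, marker_indicator="tsh")
print("h2 (tsh):     %.4f" % cov.S[1, 1])
print("loadings:     " + " ".join(f"{x:.3f}" for x in fit.loadings))
print("chi2=%.3f df=%d AIC=%.3f CFI=%.3f SRMR=%.4f"
      % (fit.fit.chi2, fit.fit.df, fit.fit.aic, fit.fit.cfi, fit.fit.srmr))

fgwas, _ = factor.factor_gwas(cov, items, fit)
h2f = ldsc.estimate_h2(fgwas, ld)
print("S-factor h2:  %.4f (SE %.4f)" % (h2f.h2, h2f.se))
```

prints

```
h2 (tsh):     0.0917
loadings:     0.956 1.000 0.696 0.472
chi2=0.943 df=2 AIC=16.943 CFI=1.000 SRMR=0.0051
S-factor h2:  0.0682 (SE 0.0157)
```

Reading it: multivariable LDSC estimates the TSH item's SNP-heritability at
9.2% on this synthetic study; the one-factor model recovers the generating
loadings (0.9, 1.0, 0.7, 0.5) up to sampling noise with an excellent fit
(χ² ≈ df would be ~2 on average, CFI 1.0, SRMR 0.005); AIC is χ² plus twice
the 8 free parameters; and LDSC on the factor GWAS output reads the latent
factor's heritability (truth 7.6%) back within one standard error.

A thin CLI covers the same pipeline on files:

```bash
sfactor simulate --out study/ --seed 1
sfactor compare --artifacts study/ --out report/ --seed 1
```

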