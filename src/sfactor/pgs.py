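"""Polygenic scoring of a target cohort and association with its phenotypes.

Scores are weighted sums of allele dosages using summary-statistic effect
weights, restricted to variants with minor allele frequency above a cutoff in
the target cohort itself.  Associations follow the covariate model age, age^2,
sex x age, sex x age^2 and ten principal components: logistic regression with
an incremental Nagelkerke pseudo-R^2 for binary items, linear regression with
incremental adjusted R^2 for the ordinal 0-4 aggregate and for continuous
traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic import Cohort, ParameterError


@dataclass
class ScoreAccounting:
    n_variants_scored: int
    n_variants_dropped_maf: int
    n_variants_dropped_allele: int


def compute_pgs(
    cohort: Cohort, weights: pd.DataFrame, maf_min: float = 0.05
) -> tuple[np.ndarray, ScoreAccounting]:
    """Score every individual from a per-variant effect-weight table.

    ``weights`` needs SNP, A1, A2 and a BETA (effect per A1 allele) column.
    Variants are matched to the cohort by id; an A1/A2 swap negates the
    weight; irreconcilable allele pairs are dropped and counted.  The minor
    allele frequency filter (> ``maf_min``) is computed from the target
    cohort's own dosages.  Missing dosages are mean-imputed per variant and
    the returned scores are mean-centered.
    """
    if "BETA" not in weights.columns:
        raise ParameterError("weights table requires a BETA column")
    cv = cohort.variants.reset_index(drop=True)
    idx_of = {snp: i for i, snp in enumerate(cv["SNP"])}
    w_list, col_list = [], []
    n_allele_dropped = 0
    for snp, a1, a2, beta in zip(
        weights["SNP"], weights["A1"], weights["A2"], weights["BETA"]
    ):
        i = idx_of.get(snp)
        if i is None:
            n_allele_dropped += 1
            continue
        ca1, ca2 = cv.loc[i, "A1"], cv.loc[i, "A2"]
        if (a1, a2) == (ca1, ca2):
            w_list.append(beta)
        elif (a1, a2) == (ca2, ca1):
            w_list.append(-beta)
        else:
            n_allele_dropped += 1
            continue
        col_list.append(i)

    if not col_list:
        raise ParameterError("no variants could be matched for scoring")
    cols = np.array(col_list)
    w = np.array(w_list, dtype=float)

    dos = cohort.dosages[:, cols].astype(float)
    col_mean = np.nanmean(dos, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(dos))
    dos[nan_r, nan_c] = col_mean[nan_c]

    freq = dos.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    pass_maf = maf > maf_min
    n_maf_dropped = int((~pass_maf).sum())
    if not pass_maf.any():
        raise ParameterError("no variants pass the MAF filter")

    scores = dos[:, pass_maf] @ w[pass_maf]
    scores = scores - scores.mean()
    acct = ScoreAccounting(
        n_variants_scored=int(pass_maf.sum()),
        n_variants_dropped_maf=n_maf_dropped,
        n_variants_dropped_allele=n_allele_dropped,
    )
    return scores, acct


def nagelkerke_r2(loglik_null: float, loglik_full: float, n: int) -> float:
    """Max-rescaled Cox-Snell pseudo-R^2.

    R2_CS = 1 - exp(2(ll_null - ll_full)/n), rescaled by its attainable
    maximum 1 - exp(2 ll_null / n).
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    if loglik_full < loglik_null - 1e-9:
        raise ParameterError("full-model log-likelihood below the null's")
    r2_cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    if max_cs <= 0:
        raise ParameterError("degenerate null model: Nagelkerke R^2 undefined")
    return float(min(r2_cs / max_cs, 1.0))


def default_covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Covariate design: age, age^2, sex x age, sex x age^2, PC1-PC10."""
    age, sex = covariates["age"], covariates["sex"]
    design = pd.DataFrame(
        {
            "age": age,
            "age2": age**2,
            "sex_age": sex * age,
            "sex_age2": sex * age**2,
        }
    )
    for c in covariates.columns:
        if c.startswith("PC"):
            design[c] = covariates[c]
    return design


@dataclass
class PGSAssociation:
    effect: float
    se: float
    p: float
    r2: float  # Nagelkerke (binary) or incremental adjusted R^2 (linear)
    r2_kind: str
    n: int


def pgs_association(
    scores: np.ndarray,
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    kind: str = "auto",
) -> PGSAssociation:
    """Associate a polygenic score with one phenotype under the covariate model.

    Binary phenotypes use logistic regression, reporting the Nagelkerke R^2
    increment of adding the score to the covariate-only model; ordinal or
    continuous phenotypes use a linear model, reporting incremental adjusted
    R^2.  Listwise deletion handles missing phenotype values.
    """
    y = pd.Series(phenotype).astype(float)
    complete = y.notna().to_numpy()
    y = y[complete].to_numpy()
    x_cov = default_covariate_design(covariates).loc[complete].to_numpy()
    s = np.asarray(scores, dtype=float)[complete]
    n = len(y)

    if kind == "auto":
        kind = "binary" if set(np.unique(y)) <= {0.0, 1.0} else "linear"

    design_null = sm.add_constant(x_cov)
    design_full = np.column_stack([design_null, s])
    if np.linalg.matrix_rank(design_full) < design_full.shape[1]:
        raise ParameterError("rank-deficient design (collinear covariates or score)")

    if kind == "binary":
        null = sm.Logit(y, design_null).fit(disp=0, maxiter=200)
        full = sm.Logit(y, design_full).fit(disp=0, maxiter=200)
        r2 = nagelkerke_r2(null.llf, full.llf, n) - nagelkerke_r2(
            null.llf, null.llf, n
        )
        r2_kind = "nagelkerke"
    elif kind == "linear":
        null = sm.OLS(y, design_null).fit()
        full = sm.OLS(y, design_full).fit()
        r2 = full.rsquared_adj - null.rsquared_adj
        r2_kind = "incremental_adj_r2"
    else:
        raise ParameterError(f"unknown model kind {kind!r}")
    return PGSAssociation(
        effect=float(full.params[-1]),
        se=float(full.bse[-1]),
        p=float(full.pvalues[-1]),
        r2=float(r2),
        r2_kind=r2_kind,
        n=n,
    )


def score_correlation(scores_a, scores_b) -> tuple[float, float]:
    """Pearson correlation between two polygenic scores with a two-sided p."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ParameterError("need equal-length score vectors with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ParameterError("zero variance in a score vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
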