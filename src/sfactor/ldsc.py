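"""LD-score regression: heritability, genetic correlation, the multivariable
genetic covariance structure, and stratified annotation enrichment.

The regression model is E[chi2_j] = 1 + N*a + (N*h2/M) * l_j for a single
trait and E[z1_j z2_j] = c + (sqrt(N1 N2) * rho_g / M) * l_j across traits,
fitted by weighted least squares with the standard two-step LDSC weighting
(heteroskedasticity x over-counting) and standard errors from a
delete-a-block jackknife over contiguous variant blocks.  Negative point
estimates are reported, never floored: difference tests downstream need the
unbiased estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import LDReference, ParameterError


@dataclass
class H2Estimate:
    h2: float
    se: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    p: float
    n_blocks: int = 200


@dataclass
class RgEstimate:
    rg: float
    se: float
    p: float
    rho_g: float
    cross_intercept: float
    defined: bool = True  # False when either h2 estimate is non-positive


@dataclass
class CovStruct:
    """Genetic covariance matrix S with the sampling covariance V of vech(S).

    ``vech`` stacks the lower triangle of S in ``np.tril_indices`` (row-major)
    order; V is the k(k+1)/2-square block-jackknife covariance of those
    estimates, computed jointly on shared blocks.
    """

    names: list[str]
    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray = field(default=None)

    @property
    def k(self) -> int:
        return len(self.names)

    def vech(self) -> np.ndarray:
        i, j = np.tril_indices(self.k)
        return self.S[i, j]

    def to_json_dict(self) -> dict:
        return {
            "names": list(self.names),
            "S": self.S.tolist(),
            "V": self.V.tolist(),
            "intercepts": None if self.intercepts is None else self.intercepts.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CovStruct":
        icpt = d.get("intercepts")
        return cls(
            names=list(d["names"]),
            S=np.asarray(d["S"], dtype=float),
            V=np.asarray(d["V"], dtype=float),
            intercepts=None if icpt is None else np.asarray(icpt, dtype=float),
        )


def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    """Contiguous block boundaries; reduces the block count if m is small."""
    if m < 2 * n_blocks:
        n_blocks = max(2, m // 2)
        warnings.warn(f"fewer variants than blocks; using {n_blocks} blocks")
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _wls_jackknife(x: np.ndarray, y: np.ndarray, w: np.ndarray, bounds: np.ndarray):
    """WLS of y on [1, x] with delete-a-block jackknife.

    Returns (coef, jk_se, jk_coefs) with coef = (intercept, slope); the
    leave-one-block-out fits reuse per-block sufficient statistics, so the
    jackknife costs O(n_blocks) solves.
    """
    design = np.column_stack([np.ones_like(x), x])
    wx = design * w[:, None]
    nb = len(bounds) - 1
    a_blocks = np.empty((nb, 2, 2))
    c_blocks = np.empty((nb, 2))
    for b in range(nb):
        s = slice(bounds[b], bounds[b + 1])
        a_blocks[b] = wx[s].T @ design[s]
        c_blocks[b] = wx[s].T @ y[s]
    a_tot, c_tot = a_blocks.sum(axis=0), c_blocks.sum(axis=0)
    coef = np.linalg.solve(a_tot, c_tot)
    jk = np.linalg.solve(a_tot[None] - a_blocks, (c_tot[None] - c_blocks)[..., None])
    jk = jk[..., 0]
    se = np.sqrt((nb - 1) / nb * ((jk - jk.mean(axis=0)) ** 2).sum(axis=0))
    return coef, se, jk


def _align(s: pd.DataFrame, ld: LDReference) -> pd.DataFrame:
    merged = s.merge(ld.table[["SNP", "L2"]], on="SNP", how="inner")
    if len(merged) == 0:
        raise ParameterError("no variants shared with the LD reference")
    # keep reference order for block contiguity
    order = {snp: i for i, snp in enumerate(ld.snp)}
    return merged.sort_values("SNP", key=lambda s: s.map(order)).reset_index(drop=True)


def _resolve_cap(chi2_max, n: np.ndarray) -> float:
    """Regression-SNP chi2 cap.  None (default) keeps every SNP: truncation
    biases the slope downward whenever a sparse architecture puts real signal
    into very large chi2 values.  'ldsc' applies the conventional
    max(80, 0.001*N) robustness cap for real-data outliers."""
    if chi2_max is None:
        return np.inf
    if chi2_max == "ldsc":
        return max(80.0, 0.001 * float(np.median(n)))
    return float(chi2_max)


def _h2_weights(ell: np.ndarray, n: np.ndarray, m: int, h2: float) -> np.ndarray:
    ellc = np.maximum(ell, 1.0)
    h2c = min(max(h2, 0.0), 1.0)
    return 1.0 / (ellc * (1.0 + n * h2c * ellc / m) ** 2)


def estimate_h2(
    s: pd.DataFrame, ld: LDReference, n_blocks: int = 200, chi2_max=None
) -> H2Estimate:
    """Univariate LDSC SNP-heritability with block-jackknife standard errors.

    Variants are matched to the reference by id; M is the reference variant
    count.  ``chi2_max`` optionally excludes large-chi2 SNPs from the
    regression only ('ldsc' for the conventional max(80, 0.001*N) cap).  The
    two-sided p tests h2 = 0 against the jackknife SE.
    """
    df = _align(s, ld)
    m = ld.n_snps
    chi2 = df["Z"].to_numpy() ** 2
    n = df["N"].to_numpy(dtype=float)
    ell = df["L2"].to_numpy()
    if np.ptp(ell) == 0:
        raise ParameterError("zero variance in LD scores: singular design")
    keep = chi2 <= _resolve_cap(chi2_max, n)
    chi2, n, ell = chi2[keep], n[keep], ell[keep]

    x = n * ell / m
    bounds = _block_bounds(len(x), n_blocks)
    coef0, _, _ = _wls_jackknife(x, chi2, np.ones_like(x), bounds)
    w = _h2_weights(ell, n, m, coef0[1])
    coef, se, _ = _wls_jackknife(x, chi2, w, bounds)
    h2, h2_se = coef[1], se[1]
    p = 2 * stats.norm.sf(abs(h2) / h2_se) if h2_se > 0 else np.nan
    return H2Estimate(
        h2=float(h2),
        se=float(h2_se),
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        mean_chi2=float(chi2.mean()),
        p=float(max(p, np.finfo(float).tiny)),
        n_blocks=len(bounds) - 1,
    )


def _pairwise_stats(
    traits: list[pd.DataFrame], ld: LDReference, n_blocks: int, chi2_max=None
):
    """Shared machinery: aligned arrays, block bounds, and slope jackknives
    for every diagonal (h2) and off-diagonal (rho_g) element."""
    aligned = [_align(t, ld) for t in traits]
    snp0 = aligned[0]["SNP"]
    for a in aligned[1:]:
        if not a["SNP"].equals(snp0):
            raise ParameterError("traits must be harmonized to a shared variant set")
    m = ld.n_snps
    ell = aligned[0]["L2"].to_numpy()
    z = np.column_stack([a["Z"].to_numpy() for a in aligned])
    n = np.column_stack([a["N"].to_numpy(dtype=float) for a in aligned])
    # joint regression-SNP cap: one shared variant set keeps every diagonal
    # and cross-trait slope, and the joint jackknife, on identical blocks
    keep = np.ones(len(ell), dtype=bool)
    for t in range(z.shape[1]):
        keep &= z[:, t] ** 2 <= _resolve_cap(chi2_max, n[:, t])
    ell, z, n = ell[keep], z[keep], n[keep]
    bounds = _block_bounds(len(ell), n_blocks)
    if len(bounds) - 1 < 2:
        raise ParameterError("fewer than 2 jackknife blocks of shared variants")

    k = len(traits)
    icpt = np.empty(k)
    h2_step1 = np.empty(k)
    diag_fits = []
    for t in range(k):
        x = n[:, t] * ell / m
        coef0, _, _ = _wls_jackknife(x, z[:, t] ** 2, np.ones_like(x), bounds)
        h2_step1[t] = coef0[1]
        w = _h2_weights(ell, n[:, t], m, coef0[1])
        coef, se, jk = _wls_jackknife(x, z[:, t] ** 2, w, bounds)
        icpt[t] = coef[0]
        diag_fits.append({"coef": coef, "se": se, "jk": jk})

    # cross weights reuse the step-1 slopes so the i == j limit reproduces
    # the univariate weighting exactly (rg of a trait with itself is 1)
    ellc = np.maximum(ell, 1.0)
    cross_fits = {}
    for i in range(k):
        for j in range(i):
            x = np.sqrt(n[:, i] * n[:, j]) * ell / m
            w = 1.0 / (
                ellc
                * (1.0 + n[:, i] * min(max(h2_step1[i], 0.0), 1.0) * ellc / m)
                * (1.0 + n[:, j] * min(max(h2_step1[j], 0.0), 1.0) * ellc / m)
            )
            coef, se, jk = _wls_jackknife(x, z[:, i] * z[:, j], w, bounds)
            cross_fits[(i, j)] = {"coef": coef, "se": se, "jk": jk}
    return diag_fits, cross_fits, icpt, bounds


def estimate_rg(
    s1: pd.DataFrame, s2: pd.DataFrame, ld: LDReference, n_blocks: int = 200,
    chi2_max=None,
) -> RgEstimate:
    """Bivariate LDSC genetic correlation.

    The cross-trait intercept absorbs sample overlap; rg = rho_g /
    sqrt(h2_1 * h2_2) with a jackknife SE over the ratio.  When either
    heritability estimate is non-positive, rg is undefined and the result is
    flagged rather than returned as a silent NaN.
    """
    diag, cross, _, _ = _pairwise_stats([s1, s2], ld, n_blocks, chi2_max)
    h1, h2_ = diag[0]["coef"][1], diag[1]["coef"][1]
    rho = cross[(1, 0)]["coef"][1]
    cross_icpt = cross[(1, 0)]["coef"][0]
    if h1 <= 0 or h2_ <= 0:
        return RgEstimate(
            rg=np.nan, se=np.nan, p=np.nan, rho_g=float(rho),
            cross_intercept=float(cross_icpt), defined=False,
        )
    rg = rho / np.sqrt(h1 * h2_)
    jk_rg = cross[(1, 0)]["jk"][:, 1] / np.sqrt(
        np.clip(diag[0]["jk"][:, 1], 1e-12, None)
        * np.clip(diag[1]["jk"][:, 1], 1e-12, None)
    )
    nb = len(jk_rg)
    se = float(np.sqrt((nb - 1) / nb * ((jk_rg - jk_rg.mean()) ** 2).sum()))
    p = 2 * stats.norm.sf(abs(rg) / se) if se > 0 else np.nan
    return RgEstimate(
        rg=float(rg),
        se=se,
        p=float(max(p, np.finfo(float).tiny)),
        rho_g=float(rho),
        cross_intercept=float(cross_icpt),
    )


def genetic_covariance(
    traits: list[pd.DataFrame],
    ld: LDReference,
    n_blocks: int = 200,
    names: list[str] | None = None,
    chi2_max=None,
) -> CovStruct:
    """Multivariable LDSC: genetic covariance matrix S and sampling matrix V.

    Diagonal elements are the univariate h2 slopes, off-diagonals the
    pairwise genetic covariances; V is the joint delete-a-block jackknife
    covariance of all k(k+1)/2 estimates computed on shared blocks, so the
    sampling dependence between elements (shared variants, shared samples) is
    captured.
    """
    if len(traits) < 2:
        raise ParameterError("at least two traits required")
    k = len(traits)
    names = names or [f"trait{i + 1}" for i in range(k)]
    diag, cross, icpt, bounds = _pairwise_stats(traits, ld, n_blocks, chi2_max)

    S = np.zeros((k, k))
    for t in range(k):
        S[t, t] = diag[t]["coef"][1]
    for (i, j), fit in cross.items():
        S[i, j] = S[j, i] = fit["coef"][1]

    rows, cols = np.tril_indices(k)
    nb = len(bounds) - 1
    jk = np.empty((nb, len(rows)))
    for q, (i, j) in enumerate(zip(rows, cols)):
        jk[:, q] = diag[i]["jk"][:, 1] if i == j else cross[(i, j)]["jk"][:, 1]
    centered = jk - jk.mean(axis=0)
    V = (nb - 1) / nb * centered.T @ centered
    return CovStruct(names=names, S=S, V=V, intercepts=icpt)


@dataclass
class EnrichmentTable:
    """Per-annotation partitioned-heritability enrichment."""

    table: pd.DataFrame  # annotation, prop_snps, prop_h2, enrichment, se, p
    h2_total: float

    def __getitem__(self, annotation: str) -> pd.Series:
        return self.table.set_index("annotation").loc[annotation]


def stratified_h2(
    s: pd.DataFrame,
    ld: LDReference,
    n_blocks: int = 200,
    exclude_mhc: bool = True,
    chi2_max=None,
) -> EnrichmentTable:
    """Stratified LDSC over the reference's annotation categories.

    Multiple WLS regression of chi2 on the per-annotation LD scores gives
    per-SNP coefficients tau_c; annotation heritability is
    h2_c = sum_{j in c} sum_b tau_b a_jb and enrichment = (h2_c / h2) /
    (M_c / M), with delete-a-block jackknife SEs and a two-sided p against
    enrichment = 1.  The base (all-SNPs) annotation has enrichment exactly 1
    by construction.  Variants in the MHC interval are excluded when CHR/BP
    are available.
    """
    if ld.annotations is None or ld.annot_ld is None:
        raise ParameterError("reference carries no annotation LD scores")
    df = s.merge(ld.annot_ld, on="SNP", how="inner")
    order = {snp: i for i, snp in enumerate(ld.snp)}
    df = df.sort_values("SNP", key=lambda c: c.map(order)).reset_index(drop=True)
    if exclude_mhc and {"CHR", "BP"} <= set(df.columns):
        from .sumstats import MHC_REGION

        chrom, start, end = MHC_REGION
        inside = (df["CHR"] == chrom) & (df["BP"] >= start) & (df["BP"] <= end)
        df = df.loc[~inside].reset_index(drop=True)

    annot_names = [c for c in ld.annotations.columns if c != "SNP"]
    a_mat = ld.annotations[annot_names].to_numpy(dtype=float)
    in_ref = ld.snp.isin(df["SNP"]).to_numpy()
    ld_cols = [f"{c}L2" for c in annot_names]
    ells = df[ld_cols].to_numpy()
    chi2 = df["Z"].to_numpy() ** 2
    n = df["N"].to_numpy(dtype=float)
    m = ld.n_snps
    keep = chi2 <= _resolve_cap(chi2_max, n)
    chi2, n, ells = chi2[keep], n[keep], ells[keep]

    design = np.column_stack([np.ones(len(chi2)), n[:, None] * ells])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(ells, rowvar=False)
        bad = [
            annot_names[j]
            for j in range(1, len(annot_names))
            for i in range(j)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ParameterError(f"collinear annotation columns: {sorted(set(bad))}")

    total_ell = np.maximum(ells[:, 0], 1.0)
    coef0 = np.linalg.lstsq(design, chi2, rcond=None)[0]
    h2_guess = float(np.clip(coef0[1:] @ a_mat.sum(axis=0), 0.0, 1.0))
    w = 1.0 / (total_ell * (1.0 + n * h2_guess * total_ell / m) ** 2)

    bounds = _block_bounds(len(chi2), n_blocks)
    nb = len(bounds) - 1
    wx = design * w[:, None]
    p_dim = design.shape[1]
    a_blocks = np.empty((nb, p_dim, p_dim))
    c_blocks = np.empty((nb, p_dim))
    for b in range(nb):
        sl = slice(bounds[b], bounds[b + 1])
        a_blocks[b] = wx[sl].T @ design[sl]
        c_blocks[b] = wx[sl].T @ chi2[sl]
    a_tot, c_tot = a_blocks.sum(axis=0), c_blocks.sum(axis=0)
    tau = np.linalg.solve(a_tot, c_tot)[1:]
    jk_tau = np.linalg.solve(
        a_tot[None] - a_blocks, (c_tot[None] - c_blocks)[..., None]
    )[..., 1:, 0]

    # h2 per category from the annotation overlap matrix over reference SNPs
    gram = a_mat.T @ a_mat  # (A, A): G[a,b] = sum_j a_ja a_jb
    m_per = a_mat.sum(axis=0)
    prop_snps = m_per / m

    def enrich(t: np.ndarray) -> np.ndarray:
        h2_cat = gram @ t
        h2_tot = h2_cat[0]  # base annotation covers all SNPs
        return (h2_cat / h2_tot) / prop_snps

    e = enrich(tau)
    jk_e = np.apply_along_axis(enrich, 1, jk_tau)
    centered = jk_e - jk_e.mean(axis=0)
    se = np.sqrt((nb - 1) / nb * (centered**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2 * stats.norm.sf(np.abs(e - 1.0) / se)
    pvals = np.where(se > 0, pvals, 1.0)
    pvals[0] = 1.0  # base: enrichment 1 by construction

    h2_total = float((gram @ tau)[0])
    table = pd.DataFrame(
        {
            "annotation": annot_names,
            "prop_snps": prop_snps,
            "prop_h2": (gram @ tau) / h2_total if h2_total != 0 else np.nan,
            "enrichment": e,
            "se": se,
            "p": np.clip(pvals, np.finfo(float).tiny, 1.0),
        }
    )
    return EnrichmentTable(table=table, h2_total=h2_total)
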