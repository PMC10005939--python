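"""Common-factor genomic SEM on an LDSC genetic covariance structure.

A single latent factor is fitted to the k x k genetic covariance matrix S by
diagonally weighted least squares: minimize
(vech(S) - vech(Sigma))' diag(V)^-1 (vech(S) - vech(Sigma)) with
Sigma = phi * lambda lambda' + diag(theta), identified by constraining one
marker indicator's loading to 1 and estimating the factor variance phi.
Fit is summarized by the chi-square from the full-V weighted quadratic form,
AIC = chi2 + 2 * n_free, CFI against an uncorrelated-indicators independence
model, and SRMR on the correlation-standardized matrices.  Inadmissible
(Heywood) solutions with a negative residual variance are corrected by a
bound-constrained refit at theta >= 0.

Promax rotation, listed in the method lineage, is the identity for a single
factor; it is applied as an explicit no-op so the pipeline stays faithful.

The per-SNP common-factor GWAS treats each variant independently: the SNP ->
factor effect is the one-parameter DWLS solution given the fitted measurement
structure, which reduces to a weighted proportionality estimate across the
indicator effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldsc import CovStruct
from .synthetic import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class FitStatistics:
    chi2: float
    df: int
    p_chi2: float
    aic: float
    cfi: float
    srmr: float


@dataclass
class FactorFit:
    """A fitted single-common-factor model."""

    names: list[str]
    marker: str
    loadings: np.ndarray  # unstandardized, marker fixed to 1
    loading_se: np.ndarray
    residuals: np.ndarray  # theta, diagonal
    residual_se: np.ndarray
    factor_variance: float
    std_loadings: np.ndarray
    std_loading_se: np.ndarray
    fit: FitStatistics | None = None
    heywood_corrected: bool = False
    converged: bool = True
    objective: float = np.nan
    n_free: int = 0

    @property
    def k(self) -> int:
        return len(self.names)

    def implied_cov(self) -> np.ndarray:
        lam = self.loadings
        return self.factor_variance * np.outer(lam, lam) + np.diag(self.residuals)

    def to_json_dict(self) -> dict:
        d = {
            "names": self.names,
            "marker": self.marker,
            "loadings": self.loadings.tolist(),
            "loading_se": self.loading_se.tolist(),
            "residuals": self.residuals.tolist(),
            "residual_se": self.residual_se.tolist(),
            "factor_variance": self.factor_variance,
            "std_loadings": self.std_loadings.tolist(),
            "std_loading_se": self.std_loading_se.tolist(),
            "heywood_corrected": self.heywood_corrected,
            "converged": self.converged,
            "n_free": self.n_free,
        }
        if self.fit is not None:
            d["fit"] = vars(self.fit)
        return d


def _vech(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0])
    return mat[i, j]


def _unpack(x: np.ndarray, k: int, marker_idx: int):
    lam = np.empty(k)
    lam[marker_idx] = 1.0
    free = [i for i in range(k) if i != marker_idx]
    lam[free] = x[: k - 1]
    phi = x[k - 1]
    theta = x[k:]
    return lam, phi, theta


def _implied(lam: np.ndarray, phi: float, theta: np.ndarray) -> np.ndarray:
    return phi * np.outer(lam, lam) + np.diag(theta)


def _jacobian(lam: np.ndarray, phi: float, k: int, marker_idx: int) -> np.ndarray:
    """d vech(Sigma) / d x, columns in (free loadings, phi, theta) order."""
    rows, cols = np.tril_indices(k)
    q = len(rows)
    free = [i for i in range(k) if i != marker_idx]
    jac = np.zeros((q, 2 * k))
    for c, a in enumerate(free):
        jac[:, c] = phi * ((rows == a) * lam[cols] + (cols == a) * lam[rows])
    jac[:, k - 1] = lam[rows] * lam[cols]
    for a in range(k):
        jac[:, k + a] = (rows == a) & (cols == a)
    return jac


def fit_common_factor(
    cov: CovStruct,
    marker_indicator: str | None = None,
    bound_residuals: bool = True,
    n_restarts: int = 5,
    seed: int = 0,
) -> FactorFit:
    """Fit the one-factor model to (S, V) by DWLS.

    The marker indicator's loading is fixed to 1 (default: the first trait)
    and the factor variance is estimated.  Parameter standard errors use the
    sandwich estimator with the full sampling matrix V.  If the unconstrained
    optimum has any negative residual variance and ``bound_residuals`` is
    set, the model is refitted with theta >= 0 and flagged as
    Heywood-corrected.
    """
    k = cov.k
    if k < 3:
        raise ParameterError("at least 3 indicators required")
    q = k * (k + 1) // 2
    n_free = 2 * k  # (k-1) loadings + factor variance + k residuals
    if q < n_free:
        raise ParameterError(f"under-identified: {n_free} free parameters, {q} moments")
    marker = marker_indicator or cov.names[0]
    if marker not in cov.names:
        raise ParameterError(f"marker indicator {marker!r} not among traits")
    marker_idx = cov.names.index(marker)

    s_vec = _vech(cov.S)
    d = np.diag(cov.V).copy()
    if np.any(d <= 0):
        raise ParameterError("V diagonal must be strictly positive for DWLS")
    w = 1.0 / d

    def objective(x):
        lam, phi, theta = _unpack(x, k, marker_idx)
        r = s_vec - _vech(_implied(lam, phi, theta))
        jac = _jacobian(lam, phi, k, marker_idx)
        return float(r @ (w * r)), -2.0 * (jac.T @ (w * r))

    diag_s = np.clip(np.diag(cov.S), 1e-8, None)
    base = np.concatenate(
        [np.full(k - 1, 0.5), [0.5 * diag_s[marker_idx]], 0.5 * diag_s]
    )
    # loadings on the marker's scale: scale the free-loading starts accordingly
    rng = np.random.default_rng(seed)

    def solve(x0, bound):
        bounds = [(None, None)] * (k - 1) + [(1e-12, None)]
        bounds += [(0.0, None) if bound else (None, None)] * k
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12},
        )
        return res

    def multistart(bound):
        best = solve(base, bound)
        for _ in range(n_restarts):
            x0 = base * (1 + 0.3 * rng.standard_normal(base.shape))
            x0[k - 1 :] = np.abs(x0[k - 1 :]) if bound else x0[k - 1 :]
            x0[k - 1] = abs(x0[k - 1]) + 1e-6
            res = solve(x0, bound)
            if res.fun < best.fun:
                best = res
        return best

    res = multistart(bound=False)
    lam, phi, theta = _unpack(res.x, k, marker_idx)
    heywood = False
    if bound_residuals and np.any(theta < 0):
        res = multistart(bound=True)
        lam, phi, theta = _unpack(res.x, k, marker_idx)
        theta = np.clip(theta, 0.0, None)
        heywood = True
    if not res.success and res.fun > 1e-6:
        raise RuntimeError(
            f"factor model failed to converge (best objective {res.fun:.3g})"
        )

    # sandwich SEs: (J'WJ)^-1 J'W V W J (J'WJ)^-1
    jac = _jacobian(lam, phi, k, marker_idx)
    bread = np.linalg.pinv(jac.T @ (w[:, None] * jac))
    meat = (jac * w[:, None]).T @ cov.V @ (jac * w[:, None])
    param_cov = bread @ meat @ bread
    param_se = np.sqrt(np.clip(np.diag(param_cov), 0.0, None))

    free = [i for i in range(k) if i != marker_idx]
    loading_se = np.zeros(k)
    loading_se[free] = param_se[: k - 1]
    residual_se = param_se[k:]

    implied = _implied(lam, phi, theta)
    diag_imp = np.clip(np.diag(implied), 1e-12, None)
    std_lam = lam * np.sqrt(phi) / np.sqrt(diag_imp)

    def std_of(x):
        lam_, phi_, theta_ = _unpack(x, k, marker_idx)
        imp = np.clip(np.diag(_implied(lam_, phi_, theta_)), 1e-12, None)
        return lam_ * np.sqrt(max(phi_, 1e-12)) / np.sqrt(imp)

    grad = np.empty((k, 2 * k))
    h = 1e-6
    for p in range(2 * k):
        xp, xm = res.x.copy(), res.x.copy()
        xp[p] += h
        xm[p] -= h
        grad[:, p] = (std_of(xp) - std_of(xm)) / (2 * h)
    std_se = np.sqrt(np.clip(np.einsum("ip,pq,iq->i", grad, param_cov, grad), 0, None))

    logger.debug("promax rotation: identity for a single factor (no-op)")
    fit = FactorFit(
        names=list(cov.names),
        marker=marker,
        loadings=lam,
        loading_se=loading_se,
        residuals=theta,
        residual_se=residual_se,
        factor_variance=float(phi),
        std_loadings=std_lam,
        std_loading_se=std_se,
        heywood_corrected=heywood,
        converged=True,
        objective=float(res.fun),
        n_free=n_free,
    )
    fit.fit = compute_fit_statistics(fit, cov)
    return fit


def _chi2_projected(
    resid: np.ndarray, jac: np.ndarray, v: np.ndarray, w: np.ndarray, k: int
) -> float:
    """Moment-residual test statistic weighted by the full sampling matrix.

    The DWLS residual is r = (I - P) s with P the (linearized) DWLS
    projection, so r has covariance (I - P) V (I - P)'; the quadratic form
    against the pseudo-inverse of that matrix is asymptotically chi-square
    with df = q - n_free for any weight matrix.  An exact fit gives 0.
    """
    if np.linalg.matrix_rank(v, tol=1e-12) < k:
        return np.nan
    proj = jac @ np.linalg.pinv(jac.T @ (w[:, None] * jac)) @ (jac * w[:, None]).T
    eye = np.eye(len(w))
    v_resid = (eye - proj) @ v @ (eye - proj).T
    return float(resid @ np.linalg.pinv(v_resid, rcond=1e-10) @ resid)


def compute_fit_statistics(fit: FactorFit, cov: CovStruct) -> FitStatistics:
    """Chi-square, df, p, AIC, CFI and SRMR for a fitted factor model.

    chi2 is the full-V weighted quadratic form of the moment residuals
    (projection-adjusted for the DWLS estimation, so exact fits give 0 and
    one-factor-consistent data give E[chi2] = df) with df = k(k+1)/2 -
    n_free; AIC = chi2 + 2*n_free.  CFI compares against an independence
    model that estimates only the k genetic variances (all indicators
    heritable but uncorrelated).  SRMR is the root mean square of the
    residuals between correlation-standardized observed and implied matrices
    over the unique elements.
    """
    k = cov.k
    q = k * (k + 1) // 2
    s_vec = _vech(cov.S)
    implied = fit.implied_cov()
    resid = s_vec - _vech(implied)
    w = 1.0 / np.diag(cov.V)
    marker_idx = cov.names.index(fit.marker)
    jac = _jacobian(fit.loadings, fit.factor_variance, k, marker_idx)
    df = q - fit.n_free
    if df <= 0:  # saturated model: no testable restrictions
        chi2 = 0.0
    else:
        chi2 = _chi2_projected(resid, jac, cov.V, w, k)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    aic = chi2 + 2 * fit.n_free

    # independence model: variances only, off-diagonal moments at zero
    indep = np.diag(np.diag(cov.S))
    resid_ind = s_vec - _vech(indep)
    rows, cols = np.tril_indices(k)
    jac_ind = np.zeros((q, k))
    for a in range(k):
        jac_ind[:, a] = (rows == a) & (cols == a)
    chi2_ind = _chi2_projected(resid_ind, jac_ind, cov.V, w, k)
    df_ind = q - k
    num = max(chi2 - df, 0.0)
    den = max(chi2_ind - df_ind, chi2 - df, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0

    ds = np.sqrt(np.clip(np.diag(cov.S), 1e-12, None))
    di = np.sqrt(np.clip(np.diag(implied), 1e-12, None))
    corr_s = cov.S / np.outer(ds, ds)
    corr_i = implied / np.outer(di, di)
    srmr = float(np.sqrt(np.mean(_vech(corr_s - corr_i) ** 2)))
    return FitStatistics(
        chi2=float(chi2), df=int(df), p_chi2=p, aic=float(aic), cfi=float(cfi),
        srmr=srmr,
    )


@dataclass
class ModelComparison:
    """Outcome of the dominance rule: lower AIC, lower SRMR, higher CFI."""

    best: int | None  # index of the dominating fit, None if indeterminate
    winners: dict = field(default_factory=dict)  # criterion -> index

    @property
    def indeterminate(self) -> bool:
        return self.best is None


def compare_models(fits: list[FactorFit]) -> ModelComparison:
    """Rank candidate models; a model wins only by dominating on all of
    lower AIC, lower SRMR, and higher CFI."""
    if len(fits) < 2:
        raise ParameterError("at least two fits required")
    aic = np.array([f.fit.aic for f in fits])
    srmr = np.array([f.fit.srmr for f in fits])
    cfi = np.array([f.fit.cfi for f in fits])
    winners = {
        "aic": int(np.argmin(aic)),
        "srmr": int(np.argmin(srmr)),
        "cfi": int(np.argmax(cfi)),
    }
    for i in range(len(fits)):
        if (
            np.all(np.delete(aic, i) > aic[i])
            and np.all(np.delete(srmr, i) > srmr[i])
            and np.all(np.delete(cfi, i) < cfi[i])
        ):
            return ModelComparison(best=i, winners=winners)
    return ModelComparison(best=None, winners=winners)


def factor_effective_n(fit: FactorFit, n_per_trait: np.ndarray) -> float:
    """Per-SNP effective N for the factor GWAS output.

    Sum of the indicator sample sizes weighted by squared standardized
    loadings: the factor statistic pools its indicators, so its chi-square
    scales with roughly this many observations, and LDSC on the factor
    output recovers heritability on the factor's own scale.
    """
    w = fit.std_loadings**2
    return float(np.sum(w * np.asarray(n_per_trait, dtype=float)))


def factor_gwas(
    cov: CovStruct,
    per_snp: list[pd.DataFrame],
    fit: FactorFit,
) -> tuple[pd.DataFrame, int]:
    """Per-SNP common-factor GWAS from harmonized indicator statistics.

    For each variant the SNP -> factor effect is estimated by DWLS with the
    measurement structure held at the fitted optimum; with per-trait effects
    b_t and sampling variances SE_t^2 this is the weighted proportionality
    solution  beta_F = sum_t lambda_t b_t / SE_t^2 / sum_t lambda_t^2 / SE_t^2
    with SE(beta_F) = (sum_t lambda_t^2 / SE_t^2)^(-1/2).  Variants missing
    in any trait are skipped and counted.  Returns (table, n_skipped); the
    table is in the munged dialect (SNP A1 A2 Z N) plus BETA/SE/P so it can
    feed straight back into LDSC and the mixture model.
    """
    if len(per_snp) != cov.k:
        raise ParameterError("one per-SNP table per indicator required")
    lam = fit.loadings
    common = per_snp[0][["SNP", "A1", "A2"]]
    betas, ses, ns = [], [], []
    snp_sets = [set(t["SNP"]) for t in per_snp]
    shared = set.intersection(*snp_sets)
    n_skipped = len(set.union(*snp_sets)) - len(shared)
    mask = common["SNP"].isin(shared).to_numpy()
    snp_order = common.loc[mask, "SNP"]
    for t in per_snp:
        sub = t.set_index("SNP").loc[snp_order].reset_index()
        if "BETA" in sub.columns and "SE" in sub.columns:
            b, se = sub["BETA"].to_numpy(), sub["SE"].to_numpy()
        else:
            n = sub["N"].to_numpy(dtype=float)
            b, se = sub["Z"].to_numpy() / np.sqrt(n), 1.0 / np.sqrt(n)
        betas.append(b)
        ses.append(se)
        ns.append(sub["N"].to_numpy(dtype=float))
    betas, ses, ns = np.array(betas), np.array(ses), np.array(ns)

    w = 1.0 / ses**2
    denom = np.sum(w * lam[:, None] ** 2, axis=0)
    beta_f = np.sum(w * lam[:, None] * betas, axis=0) / denom
    se_f = 1.0 / np.sqrt(denom)
    z = beta_f / se_f
    p = 2 * stats.norm.sf(np.abs(z))
    n_eff = factor_effective_n(fit, ns.mean(axis=1))

    out = common.loc[mask].reset_index(drop=True).copy()
    out["Z"] = z
    out["N"] = n_eff
    out["BETA"] = beta_f
    out["SE"] = se_f
    out["P"] = np.clip(p, np.finfo(float).tiny, 1.0)
    return out, n_skipped
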