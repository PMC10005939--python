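"""Two-component polygenic effect-size distribution and discovery projection.

A filtered GWAS Z-score panel is modeled as a mixture of null and
susceptibility SNPs,

    z_j ~ (1 - pi_c) * Normal(0, alpha) + pi_c * Normal(0, alpha + N_j sigma2 l_j),

in variance parameterization: ``pi_c`` is the proportion of susceptibility
SNPs, ``sigma2`` the per-SNP effect-size variance of the non-null component,
and ``alpha`` the residual inflation of the null variance (population
stratification, deflation, uncaptured tiny effects).  LD enters the non-null
variance only through the LD score l_j — an independent-SNP composite
likelihood.  Fitted parameters feed a projection of the expected number of
genome-wide-significant discoveries at future sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .synthetic import LDReference, ParameterError

_PI_GRID = (1e-4, 1e-3, 1e-2, 1e-1)


@dataclass
class MixtureFit:
    pi_c: float
    sigma2: float
    alpha: float
    pi_c_se: float
    sigma2_se: float
    alpha_se: float
    param_cov: np.ndarray  # 3x3, (pi_c, sigma2, alpha) order
    loglik: float
    n_snps_used: int
    boundary: bool = False  # pi_c at the edge of its domain: SE unreliable

    def to_json_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "param_cov"}
        d["param_cov"] = self.param_cov.tolist()
        return d


@dataclass
class ProjectionCurve:
    n_grid: np.ndarray
    expected: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": self.n_grid,
                "expected_gws": self.expected,
                "lo95": self.lo95,
                "hi95": self.hi95,
            }
        )


def _keep_prob(v, c: float):
    """P(|z| <= c) for z ~ Normal(0, v), and its derivative in v."""
    u = c / np.sqrt(2.0 * v)
    g = special.erf(u)
    dg_dv = -u * np.exp(-(u**2)) / (np.sqrt(np.pi) * v)
    return g, dg_dv


def _neg_loglik(x: np.ndarray, z2: np.ndarray, nl: np.ndarray, z2_max=None) -> float:
    return _neg_loglik_grad(x, z2, nl, z2_max)[0]


def _neg_loglik_grad(x: np.ndarray, z2: np.ndarray, nl: np.ndarray, z2_max=None):
    """(value, gradient) of the negative log-likelihood in transformed coords.

    When ``z2_max`` is given, each observation is conditioned on having
    survived the |z| <= sqrt(z2_max) QC truncation — without this the
    truncated non-null tail masquerades as a smaller sigma2 and a larger
    pi_c whenever causal chi-squares cross the filter boundary.
    """
    pi_c = np.clip(special.expit(x[0]), 1e-12, 1 - 1e-12)
    sigma2 = np.exp(x[1])
    alpha = np.exp(x[2])
    v0 = alpha
    v1 = alpha + nl * sigma2
    log_null = -0.5 * (np.log(2 * np.pi * v0) + z2 / v0)
    log_alt = -0.5 * (np.log(2 * np.pi * v1) + z2 / v1)
    a = np.log1p(-pi_c) + log_null
    b = np.log(pi_c) + log_alt
    lse = np.logaddexp(a, b)
    r1 = np.exp(b - lse)  # responsibility of the non-null component
    r0 = 1.0 - r1
    # d log phi(z;0,v) / dv = (z^2 - v) / (2 v^2)
    dl0_dv = (z2 - v0) / (2 * v0**2)
    dl1_dv = (z2 - v1) / (2 * v1**2)
    g_pi = (r1 / pi_c - r0 / (1 - pi_c)) * pi_c * (1 - pi_c)
    g_s2 = r1 * dl1_dv * nl * sigma2
    g_al = (r0 * dl0_dv + r1 * dl1_dv) * alpha

    value = -lse.sum()
    grad = -np.array([g_pi.sum(), g_s2.sum(), g_al.sum()])
    if z2_max is not None:
        c = np.sqrt(z2_max)
        k0, dk0 = _keep_prob(v0, c)
        k1, dk1 = _keep_prob(v1, c)
        denom = (1 - pi_c) * k0 + pi_c * k1
        value += np.log(denom).sum()
        d_pi = ((k1 - k0) / denom) * pi_c * (1 - pi_c)
        d_s2 = (pi_c * dk1 * nl / denom) * sigma2
        d_al = (((1 - pi_c) * dk0 + pi_c * dk1) / denom) * alpha
        grad += np.array([d_pi.sum(), d_s2.sum(), d_al.sum()])
    return float(value), grad


def _loglik_natural(
    theta: np.ndarray, z2: np.ndarray, nl: np.ndarray, z2_max=None
) -> float:
    pi_c, sigma2, alpha = theta
    if not (0 < pi_c < 1) or sigma2 <= 0 or alpha <= 0:
        return -np.inf
    x = np.array([special.logit(pi_c), np.log(sigma2), np.log(alpha)])
    return -_neg_loglik(x, z2, nl, z2_max)


def fit_mixture(
    s: pd.DataFrame,
    ld: LDReference,
    pi_grid: tuple = _PI_GRID,
    z2_max: float | None = 80.0,
) -> MixtureFit:
    """Maximize the two-component composite likelihood over (pi_c, sigma2, alpha).

    Expects QC-filtered summary statistics (allowlist, Z^2 and effective-N
    rules already applied) with a per-SNP N column.  Optimization runs in
    transformed coordinates (logit pi_c, log sigma2, log alpha) from multiple
    starts over a pi_c grid; standard errors come from the inverse observed
    information of the natural parameters.  A fit with pi_c at the boundary
    is flagged (SEs unreliable there).

    ``z2_max`` must echo the Z^2 cutoff of the upstream QC filter (None if
    no cutoff was applied): the likelihood conditions every observation on
    surviving that truncation, which keeps sigma2 and pi_c consistent when
    causal chi-squares cross the filter boundary.
    """
    df = s.merge(ld.table[["SNP", "L2"]], on="SNP", how="inner")
    if len(df) == 0:
        raise ParameterError("no variants shared with the LD reference")
    z2 = df["Z"].to_numpy() ** 2
    nl = df["N"].to_numpy(dtype=float) * df["L2"].to_numpy()

    best = None
    for pi0 in pi_grid:
        sigma0 = max(z2.mean() - 1.0, 0.01) / (pi0 * nl.mean())
        x0 = np.array([special.logit(pi0), np.log(sigma0), 0.0])
        # domain bounds: susceptibility SNPs are a minority (pi_c <= 0.5),
        # per-SNP effect variance cannot exceed total trait variance
        # (sigma2 <= 1), and alpha stays within e^+-5 of the unit null.
        # The sigma2 bound also removes a degenerate optimum of the
        # truncation-conditioned likelihood in which an enormous sigma2
        # turns the non-null component into a uniform over the kept window.
        res = optimize.minimize(
            _neg_loglik_grad,
            x0,
            args=(z2, nl, z2_max),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-30.0, 0.0), (None, 0.0), (-5.0, 5.0)],
            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("mixture likelihood did not converge to a finite optimum")

    pi_c = float(special.expit(best.x[0]))
    sigma2 = float(np.exp(best.x[1]))
    alpha = float(np.exp(best.x[2]))
    theta = np.array([pi_c, sigma2, alpha])
    boundary = (
        pi_c < 1e-6
        or pi_c > 0.499
        or sigma2 > 0.99  # optimizer ran into a domain bound
        or not 0.01 < alpha < 100.0
    )

    # observed information in natural parameters by central differences
    steps = np.maximum(np.abs(theta) * 1e-4, 1e-10)
    hess = np.empty((3, 3))
    f0 = _loglik_natural(theta, z2, nl, z2_max)
    for i in range(3):
        for j in range(i + 1):
            ei = np.eye(3)[i] * steps[i]
            ej = np.eye(3)[j] * steps[j]
            fpp = _loglik_natural(theta + ei + ej, z2, nl, z2_max)
            fpm = _loglik_natural(theta + ei - ej, z2, nl, z2_max)
            fmp = _loglik_natural(theta - ei + ej, z2, nl, z2_max)
            fmm = _loglik_natural(theta - ei - ej, z2, nl, z2_max)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                4 * steps[i] * steps[j]
            )
    with np.errstate(all="ignore"):
        info = -hess
        try:
            pcov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            pcov = np.linalg.pinv(info)
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    if not np.all(np.isfinite(ses)):
        ses = np.where(np.isfinite(ses), ses, 0.0)
        boundary = True

    return MixtureFit(
        pi_c=pi_c,
        sigma2=sigma2,
        alpha=alpha,
        pi_c_se=float(ses[0]),
        sigma2_se=float(ses[1]),
        alpha_se=float(ses[2]),
        param_cov=pcov,
        loglik=float(f0),
        n_snps_used=len(z2),
        boundary=boundary,
    )


def expected_discoveries(
    pi_c: float,
    sigma2: float,
    alpha: float,
    n: float,
    m_total: int,
    threshold: float = 5e-8,
    method: str = "analytic",
    gh_nodes: int = 256,
) -> float:
    """Expected genome-wide-significant SNP count at sample size n.

    E[#GWS] = m * [ pi_c * E_beta P(|Z| > z_c) + (1 - pi_c) * P0 ] with
    Z ~ Normal(sqrt(n) beta, sqrt(alpha)) and beta ~ Normal(0, sigma2).

    ``method='analytic'`` (default) integrates the non-null power exactly:
    marginally Z ~ Normal(0, alpha + n*sigma2), so
    E_beta P(|Z| > z_c) = 2 * Phi_bar(z_c / sqrt(alpha + n*sigma2)).
    ``method='gauss-hermite'`` evaluates the same integral by Gauss-Hermite
    quadrature in beta; note the integrand sharpens as n grows, so the node
    count must grow with n for the quadrature to track the exact value.
    """
    if not 0 < threshold < 1:
        raise ParameterError("threshold must be in (0, 1)")
    z_c = stats.norm.isf(threshold / 2)
    sd = np.sqrt(alpha)
    if method == "analytic":
        e_power = 2 * stats.norm.sf(z_c / np.sqrt(alpha + n * sigma2))
    elif method == "gauss-hermite":
        nodes, weights = np.polynomial.hermite.hermgauss(gh_nodes)
        beta = np.sqrt(2 * sigma2) * nodes
        mean = np.sqrt(n) * beta
        power = stats.norm.sf((z_c - mean) / sd) + stats.norm.sf((z_c + mean) / sd)
        e_power = float(np.sum(weights * power) / np.sqrt(np.pi))
    else:
        raise ParameterError(f"unknown integration method {method!r}")
    p_null = 2 * stats.norm.sf(z_c / sd)
    return m_total * (pi_c * e_power + (1 - pi_c) * p_null)


def project_discoveries(
    fit: MixtureFit,
    n_grid,
    m_total: int,
    threshold: float = 5e-8,
    n_draws: int = 1000,
    seed: int = 0,
) -> ProjectionCurve:
    """Project expected GWS discoveries over a grid of future sample sizes.

    The 95% CI at each N comes from ``n_draws`` parameter vectors sampled
    from the asymptotic normal of (pi_c, sigma2, alpha), truncated to the
    valid domain, with equal-tailed quantiles of the resulting curves.
    """
    n_grid = np.asarray(n_grid, dtype=float)
    point = np.array(
        [
            expected_discoveries(
                fit.pi_c, fit.sigma2, fit.alpha, n, m_total, threshold
            )
            for n in n_grid
        ]
    )
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        [fit.pi_c, fit.sigma2, fit.alpha], fit.param_cov, size=n_draws,
        method="svd",
    )
    draws[:, 0] = np.clip(draws[:, 0], 0.0, 1.0)
    draws[:, 1] = np.clip(draws[:, 1], 0.0, None)
    draws[:, 2] = np.clip(draws[:, 2], 1e-8, None)
    curves = np.empty((n_draws, len(n_grid)))
    for d in range(n_draws):
        pi_d, s2_d, a_d = draws[d]
        curves[d] = [
            expected_discoveries(pi_d, s2_d, a_d, n, m_total, threshold)
            for n in n_grid
        ]
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    return ProjectionCurve(
        n_grid=n_grid, expected=point, lo95=lo, hi95=hi, threshold=threshold
    )


def compare_pi(fit_a: MixtureFit, fit_b: MixtureFit) -> tuple[float, float]:
    """Two-sided z-test for a difference in the proportion of susceptibility
    SNPs between two independent fits."""
    se = np.hypot(fit_a.pi_c_se, fit_b.pi_c_se)
    if se == 0:
        raise ParameterError("zero standard errors: difference test undefined")
    z = (fit_a.pi_c - fit_b.pi_c) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(max(p, np.finfo(float).tiny))
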