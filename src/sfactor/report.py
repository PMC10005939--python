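"""Head-to-head comparison layer: difference tests, FDR, concordance of
genetic-correlation profiles, and the assembled comparison report.

All difference tests assume the two estimates are independent.  When the two
trait definitions are built from overlapping samples (as aggregate and
factor-based definitions of the same items necessarily are) this is
anti-conservative; a user-supplied covariance term can correct it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import ParameterError


def zdiff_test(
    est1: float, se1: float, est2: float, se2: float, cov: float = 0.0
) -> tuple[float, float]:
    """Two-sided z-test for a difference between two estimates.

    z = (est1 - est2) / sqrt(se1^2 + se2^2 - 2*cov); ``cov`` defaults to 0
    (independent estimates).
    """
    if se1 <= 0 or se2 <= 0:
        raise ParameterError("standard errors must be strictly positive")
    var = se1**2 + se2**2 - 2 * cov
    if var <= 0:
        raise ParameterError("non-positive variance of the difference")
    z = (est1 - est2) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(max(p, np.finfo(float).tiny))


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level q.

    Returns (reject flags, adjusted p-values); adjusted p-values are monotone
    non-decreasing in the raw-p rank.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    reject, adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, adj


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ParameterError("m must be at least 1")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    return alpha / m


def concordance_regression(
    rg_vec1, rg_vec2
) -> tuple[float, float, float]:
    """OLS concordance of two genetic-correlation profiles.

    Regresses ``rg_vec2`` on ``rg_vec1`` with an intercept and returns
    (slope, adjusted R^2, slope p-value); adjusted R^2 uses the
    single-predictor formula 1 - (1 - R^2)(n - 1)/(n - 2).
    """
    x = np.asarray(rg_vec1, dtype=float)
    y = np.asarray(rg_vec2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ParameterError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ParameterError("zero variance in the predictor profile")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(x)
    adj_r2 = 1 - (1 - model.rsquared) * (n - 1) / (n - 2)
    return float(model.params[1]), float(adj_r2), float(model.pvalues[1])


@dataclass
class ComparisonReport:
    """Self-describing bundle of every suicidality-vs-factor comparison.

    Components are stored under fixed keys (h2, rg, rg_profiles, enrichment,
    mixture, projections, pgs); anything not supplied is listed in
    ``missing`` rather than silently absent.
    """

    components: dict = field(default_factory=dict)
    seed: int | None = None
    EXPECTED = ("h2", "rg", "rg_profiles", "enrichment", "mixture", "projections", "pgs")

    @property
    def missing(self) -> list[str]:
        return [k for k in self.EXPECTED if k not in self.components]

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "seed": self.seed,
            "missing": self.missing,
            "components": _jsonable(self.components),
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# Suicidality vs S-factor comparison", ""]
        if self.seed is not None:
            lines.append(f"Seed: {self.seed}")
            lines.append("")
        for key in self.EXPECTED:
            if key not in self.components:
                continue
            lines.append(f"## {key}")
            lines.append("")
            lines.append("```json")
            lines.append(json.dumps(_jsonable(self.components[key]), indent=2,
                                    sort_keys=True))
            lines.append("```")
            lines.append("")
        if self.missing:
            lines.append("## missing")
            lines.append("")
            for key in self.missing:
                lines.append(f"- {key}")
            lines.append("")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if hasattr(obj, "to_json_dict"):
        return _jsonable(obj.to_json_dict())
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(vars(obj))
    return obj


def build_report(seed: int | None = None, **components) -> ComparisonReport:
    """Assemble the final comparison bundle from completed components.

    Accepts any subset of the expected component keys; omissions are recorded
    in the report's ``missing`` section.  Two runs on identical inputs render
    byte-identical JSON/markdown.
    """
    unknown = set(components) - set(ComparisonReport.EXPECTED)
    if unknown:
        raise ParameterError(f"unknown report components: {sorted(unknown)}")
    return ComparisonReport(components=components, seed=seed)
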