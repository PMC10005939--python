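"""Synthetic GWAS data with a latent-factor architecture.

Generates everything the downstream pipeline consumes: an LD reference with
exactly known LD scores (block AR(1) correlation), per-trait causal effects
driven by a single heritable factor plus trait-specific residual effects
(point-normal mixtures), multi-trait Z-score summary statistics with
LDSC-intercept-style error correlation from sample overlap, and a small
individual-level cohort with four binary items and an ordinal 0-4 aggregate
phenotype for polygenic-score analyses.

All randomness flows from a single integer seed; each operation derives its
substream deterministically, so identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Non-complementary allele pairs: harmonization keeps these unambiguously.
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]


class ParameterError(ValueError):
    """An operation was called with parameters outside its valid domain."""


@dataclass
class TrueModel:
    """Generating model for a multi-trait GWAS with one latent genetic factor.

    Parameters
    ----------
    n_snps
        Number of variants M in the reference.
    loadings
        Unstandardized loading of each trait on the latent factor.
    residual_h2
        Trait-specific (non-factor) SNP-heritability per trait.
    factor_h2
        SNP-heritability of the latent factor itself.
    pi_c
        Proportion of causal SNPs in each point-normal component.
    seed
        Top-level seed; every substream is derived from it.
    """

    n_snps: int
    loadings: np.ndarray
    residual_h2: np.ndarray
    factor_h2: float
    pi_c: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.residual_h2 = np.asarray(self.residual_h2, dtype=float)
        if self.loadings.shape != self.residual_h2.shape:
            raise ParameterError("loadings and residual_h2 must have equal length")
        if not 0.0 <= self.pi_c <= 1.0:
            raise ParameterError(f"pi_c must be in [0, 1], got {self.pi_c}")
        if not 0.0 <= self.factor_h2 <= 1.0:
            raise ParameterError("factor_h2 must be in [0, 1]")
        if np.any(self.residual_h2 < 0) or np.any(self.residual_h2 > 1):
            raise ParameterError("residual_h2 entries must be in [0, 1]")
        total = self.loadings**2 * self.factor_h2 + self.residual_h2
        if np.any(total > 1.0 + 1e-12):
            raise ParameterError(
                "per-trait genetic variance lambda^2*h2_F + residual_h2 exceeds 1"
            )

    @property
    def n_traits(self) -> int:
        return len(self.loadings)

    @property
    def sigma2_beta(self) -> float:
        """Per-causal-SNP effect variance of the factor component."""
        n_causal = self.n_snps * self.pi_c
        return self.factor_h2 / n_causal if n_causal > 0 else 0.0


@dataclass
class LDReference:
    """Per-variant LD scores plus optional functional annotations.

    ``table`` holds CHR, SNP, BP, A1, A2 and the total LD score L2; the LD
    scores are computed exactly from the generating block-AR(1) correlation
    matrix, not estimated from genotypes.  ``annotations`` (variants x
    categories, 0/1 or continuous) and the matching per-annotation LD scores
    ``annot_ld`` support stratified LD-score regression.
    """

    table: pd.DataFrame
    block_size: int = 1
    rho: float = 0.0
    annotations: pd.DataFrame | None = None
    annot_ld: pd.DataFrame | None = None
    segments: list[tuple[int, int, float]] | None = None

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp(self) -> pd.Series:
        return self.table["SNP"]

    @property
    def ld_score(self) -> np.ndarray:
        return self.table["L2"].to_numpy()

    def segment_spec(self) -> list[tuple[int, int, float]]:
        """(n_snps, block_size, rho) per homogeneous stretch of the panel."""
        if self.segments is not None:
            return self.segments
        return [(self.n_snps, self.block_size, self.rho)]

    def block_correlation(self, block_size: int | None = None, rho: float | None = None
                          ) -> np.ndarray:
        """The AR(1) correlation matrix shared by every block of a segment."""
        b = self.block_size if block_size is None else block_size
        r = self.rho if rho is None else rho
        idx = np.arange(b)
        return r ** np.abs(idx[:, None] - idx[None, :])

    @property
    def m_per_annotation(self) -> pd.Series:
        if self.annotations is None:
            raise ValueError("reference carries no annotations")
        return self.annotations.drop(columns="SNP").sum(axis=0)


@dataclass
class Cohort:
    """A small individual-level cohort for polygenic scoring.

    Dosages are additive allele counts in [0, 2]; the four binary items are
    floats with NaN for missing (never coded 0); covariates are age, sex and
    ten principal components.
    """

    dosages: np.ndarray
    variants: pd.DataFrame  # SNP, A1, A2, MAF (generating frequency)
    items: pd.DataFrame  # four 0/1 columns, NaN = missing
    covariates: pd.DataFrame
    liability_factor: np.ndarray = field(repr=False, default=None)
    # generating truth, for validation: standardized-dosage weights of the
    # genetic score underlying the liability factor (zero for non-causal)
    causal_weights: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def suicidality(self) -> pd.Series:
        """Ordinal 0-4 aggregate of the four items (NaN if any item missing)."""
        return aggregate_suicidality_frame(self.items)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: child generator of ``seed`` keyed by ``key``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_ld_blocks(
    n_snps: int, block_size: int, rho: float, seed: int = 0
) -> LDReference:
    """Build an LD reference of independent AR(1) blocks.

    Within a block, the correlation between variants at distance d is
    ``rho**d``; blocks are mutually uncorrelated.  LD scores are the exact row
    sums of the squared block correlation matrix (so every ``l_j >= 1``, the
    self-correlation).  ``seed`` only randomizes allele assignment.
    """
    if not 0.0 <= rho < 1.0:
        raise ParameterError(f"rho must be in [0, 1), got {rho}")
    if block_size < 1 or n_snps % block_size != 0:
        raise ParameterError("n_snps must divide into blocks of block_size")
    idx = np.arange(block_size)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    ell_block = (corr**2).sum(axis=1)
    ell = np.tile(ell_block, n_snps // block_size)

    rng = _rng(seed, 0)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    flip = rng.random(n_snps) < 0.5
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    a1, a2 = np.where(flip, a2, a1), np.where(flip, a1, a2)

    table = pd.DataFrame(
        {
            "CHR": 1,
            "SNP": [f"rs{i + 1}" for i in range(n_snps)],
            "BP": np.arange(1, n_snps + 1) * 1000,
            "A1": a1,
            "A2": a2,
            "L2": ell,
        }
    )
    return LDReference(table=table, block_size=block_size, rho=rho)


DEFAULT_PANEL = ((0.25, 1, 0.0), (0.25, 10, 0.5), (0.25, 50, 0.9), (0.25, 100, 0.95))


def simulate_ld_panel(
    n_snps: int,
    segments: tuple = DEFAULT_PANEL,
    seed: int = 0,
) -> LDReference:
    """Build a heterogeneous LD panel from AR(1) segments.

    ``segments`` lists (fraction of variants, block_size, rho) stretches; the
    default mixes LD-free, weak, strong and very strong regions so LD scores
    spread over an order of magnitude, as in real reference panels — the
    between-segment spread is what gives LD-score regression its leverage.
    """
    fracs = np.array([s[0] for s in segments], dtype=float)
    if not np.isclose(fracs.sum(), 1.0):
        raise ParameterError("segment fractions must sum to 1")
    counts = [int(frac * n_snps / block) * block for frac, block, _ in segments]
    remainder = n_snps - sum(counts)
    if remainder:
        # absorb the rounding remainder into an LD-free stretch
        block_one = [i for i, s in enumerate(segments) if s[1] == 1]
        if not block_one:
            raise ParameterError(
                "n_snps incompatible with the segment layout (no block-1 "
                "segment to absorb the remainder)"
            )
        counts[block_one[0]] += remainder

    tables, spec = [], []
    for i, ((_, block, rho), c) in enumerate(zip(segments, counts)):
        if c == 0:
            continue
        part = simulate_ld_blocks(c, block, rho, seed=seed + i)
        tables.append(part.table)
        spec.append((c, block, rho))
    table = pd.concat(tables, ignore_index=True)
    table["SNP"] = [f"rs{i + 1}" for i in range(n_snps)]
    table["BP"] = np.arange(1, n_snps + 1) * 1000
    return LDReference(table=table, segments=spec)


def attach_annotations(
    ld: LDReference, annotations: pd.DataFrame, base_name: str = "base"
) -> LDReference:
    """Attach an annotation matrix and compute exact per-annotation LD scores.

    ``annotations`` has one row per reference variant (same order) and one 0/1
    or continuous column per category; a ``base`` column of ones is prepended
    when absent.  Per-annotation LD scores are l_{j,a} = sum_k r_jk^2 a_k,
    evaluated block-exactly from the generating correlation matrix.
    """
    annot = annotations.copy()
    if "SNP" in annot.columns:
        if not annot["SNP"].tolist() == ld.snp.tolist():
            raise ParameterError("annotation SNP order must match the reference")
        annot = annot.drop(columns="SNP")
    if base_name not in annot.columns:
        annot.insert(0, base_name, 1.0)
    if len(annot) != ld.n_snps:
        raise ParameterError("annotation rows must match the reference variants")

    a_full = annot.to_numpy(dtype=float)
    parts, off = [], 0
    for c, block, rho in ld.segment_spec():
        r2 = ld.block_correlation(block, rho) ** 2
        a = a_full[off : off + c].reshape(-1, block, annot.shape[1])
        parts.append(np.einsum("ij,njk->nik", r2, a).reshape(-1, annot.shape[1]))
        off += c
    scores = np.concatenate(parts, axis=0)
    annot_ld = pd.DataFrame(scores, columns=[f"{c}L2" for c in annot.columns])
    annot_ld.insert(0, "SNP", ld.snp.to_numpy())
    out_annot = annot.copy()
    out_annot.insert(0, "SNP", ld.snp.to_numpy())
    return LDReference(
        table=ld.table,
        block_size=ld.block_size,
        rho=ld.rho,
        annotations=out_annot,
        annot_ld=annot_ld,
        segments=ld.segments,
    )


def simulate_factor_architecture(
    model: TrueModel, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-trait causal effect vectors from the one-factor architecture.

    Factor effects are point-normal: zero with probability 1 - pi_c, otherwise
    Gaussian, rescaled so the realized factor heritability sum(beta_F^2) equals
    ``factor_h2``.  Trait t receives ``loadings[t] * beta_F`` plus an
    independent point-normal residual vector rescaled to ``residual_h2[t]``.

    Returns ``(betas, beta_factor)`` with ``betas`` of shape (n_traits, M).
    """
    rng = _rng(model.seed if seed is None else seed, 1)
    m, k = model.n_snps, model.n_traits

    def point_normal(h2: float) -> np.ndarray:
        mask = rng.random(m) < model.pi_c
        draws = rng.standard_normal(m)  # always consume m draws: stable streams
        if h2 == 0.0:
            return np.zeros(m)
        if model.pi_c == 0.0 or not mask.any():
            raise ParameterError(
                f"h2={h2} unattainable: no causal SNPs at pi_c={model.pi_c}, M={m}"
            )
        beta = np.where(mask, draws, 0.0)
        return beta * np.sqrt(h2 / np.sum(beta**2))

    beta_factor = point_normal(model.factor_h2)
    betas = np.empty((k, m))
    for t in range(k):
        betas[t] = model.loadings[t] * beta_factor + point_normal(model.residual_h2[t])
    return betas, beta_factor


def simulate_sumstats(
    model: TrueModel,
    ld: LDReference,
    n_per_trait: int | np.ndarray,
    overlap_fraction: float = 0.0,
    pheno_corr: float = 0.4,
    seed: int | None = None,
    effects: np.ndarray | None = None,
) -> list[pd.DataFrame]:
    """Simulate munged-style summary statistics for every trait in the model.

    Marginal Z scores follow Z_j ~ Normal(sqrt(N_t) * (R beta_t)_j, 1) with
    errors correlated R across variants within an LD block and, across traits,
    by ``overlap_fraction * pheno_corr`` — the cross-trait LDSC-intercept
    structure produced by shared samples.  Each returned frame carries SNP,
    A1, A2, Z, N plus BETA = Z/sqrt(N) and SE = 1/sqrt(N).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ParameterError("overlap_fraction must be in [0, 1]")
    if effects is None:
        effects, _ = simulate_factor_architecture(model, seed=seed)
    k, m = effects.shape
    if m != ld.n_snps:
        raise ParameterError("effect vectors do not match the LD reference")
    n_per_trait = np.broadcast_to(np.asarray(n_per_trait, dtype=float), (k,))

    rng = _rng(model.seed if seed is None else seed, 2)
    trait_corr = np.full((k, k), overlap_fraction * pheno_corr)
    np.fill_diagonal(trait_corr, 1.0)
    chol_trait = np.linalg.cholesky(trait_corr)

    mean_parts, eps_parts, off = [], [], 0
    for c, b, rho in ld.segment_spec():
        corr = ld.block_correlation(b, rho)
        chol_snp = np.linalg.cholesky(corr)
        n_blocks = c // b
        # mean: per block R @ beta; noise: L_R @ G @ L_C' per block
        beta_blocks = effects[:, off : off + c].reshape(k, n_blocks, b)
        mean_parts.append(np.einsum("ij,knj->kni", corr, beta_blocks).reshape(k, c))
        g = rng.standard_normal((n_blocks, b, k))
        eps = np.einsum("ij,njk,lk->nil", chol_snp, g, chol_trait)
        eps_parts.append(eps.reshape(c, k).T)
        off += c
    mean = np.concatenate(mean_parts, axis=1)
    eps = np.concatenate(eps_parts, axis=1)

    out = []
    for t in range(k):
        n_t = n_per_trait[t]
        z = np.sqrt(n_t) * mean[t] + eps[t]
        df = pd.DataFrame(
            {
                "SNP": ld.snp.to_numpy(),
                "A1": ld.table["A1"].to_numpy(),
                "A2": ld.table["A2"].to_numpy(),
                "Z": z,
                "N": np.full(m, n_t),
                "BETA": z / np.sqrt(n_t),
                "SE": np.full(m, 1.0 / np.sqrt(n_t)),
            }
        )
        out.append(df)
    return out


def simulate_target_cohort(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    factor_h2_liability: float = 0.3,
    thresholds: np.ndarray = (1.0, 1.2, 1.5, 1.8),
    loadings: np.ndarray = (0.9, 0.95, 0.7, 0.6),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> Cohort:
    """Simulate an individual-level target cohort under a liability model.

    Dosages are Binomial(2, maf).  A latent factor is built from a genetic
    score over a random subset of variants (scaled to ``factor_h2_liability``
    of the factor's unit variance) plus environmental noise; each binary item
    thresholds its own liability ``lambda_t * F + sqrt(1 - lambda_t^2) * e_t``
    at the given standard-normal cutoffs.  Covariates (age, sex, ten PCs) are
    independent of genotype.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    if thresholds.shape != (4,) or np.any(np.isnan(thresholds)):
        raise ParameterError("thresholds must be four real liability cutoffs")
    if not 0.0 <= factor_h2_liability <= 1.0:
        raise ParameterError("factor_h2_liability must be in [0, 1]")
    if np.any(np.abs(loadings) > 1.0):
        raise ParameterError("standardized item loadings must lie in [-1, 1]")

    rng = _rng(seed, 3)
    maf = rng.uniform(*maf_range, size=m)
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)

    # genetic score on standardized dosages over a causal subset
    n_causal = max(1, m // 10)
    causal = rng.choice(m, size=n_causal, replace=False)
    w = rng.standard_normal(n_causal)
    std = np.sqrt(2 * maf[causal] * (1 - maf[causal]))
    gscore = (dosages[:, causal] - 2 * maf[causal]) / std @ w
    gsd = gscore.std()
    gscore = gscore / gsd if gsd > 0 else gscore

    f = np.sqrt(factor_h2_liability) * gscore + np.sqrt(
        1 - factor_h2_liability
    ) * rng.standard_normal(n)
    items = {}
    names = ["tlnwl", "tsh", "ash", "attempt"]
    for t, name in enumerate(names):
        lam = loadings[t]
        liab = lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        col = (liab > thresholds[t]).astype(float)
        if missing_rate > 0:
            col[rng.random(n) < missing_rate] = np.nan
        items[name] = col

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(m)],
            "A1": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "A2": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "MAF": maf,
        }
    )
    age = rng.uniform(40, 70, size=n)
    covs = {"age": age, "sex": rng.integers(0, 2, size=n).astype(float)}
    for i in range(10):
        covs[f"PC{i + 1}"] = rng.standard_normal(n)
    w_full = np.zeros(m)
    if gsd > 0:
        w_full[causal] = w / std / gsd
    return Cohort(
        dosages=dosages,
        variants=variants,
        items=pd.DataFrame(items),
        covariates=pd.DataFrame(covs),
        liability_factor=f,
        causal_weights=w_full,
    )


_YES = {"yes", 1, 1.0, True}
_NO = {"no", 0, 0.0, False}


def aggregate_suicidality(items) -> float:
    """Aggregate four yes/no/missing item responses into an ordinal 0-4 score.

    The score counts endorsed ("yes") items: all-no scores 0, all-yes scores 4
    (most severe).  Any missing item makes the aggregate missing (NaN) rather
    than deflating the count.
    """
    if len(items) != 4:
        raise ParameterError(f"exactly four items required, got {len(items)}")
    score = 0
    for v in items:
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "missing":
            return float("nan")
        if isinstance(v, str):
            v = v.lower()
        if v in _YES:
            score += 1
        elif v in _NO:
            continue
        else:
            raise ParameterError(f"item value {v!r} not in {{yes, no, missing}}")
    return float(score)


def aggregate_suicidality_frame(items: pd.DataFrame) -> pd.Series:
    """Vectorized aggregation of a four-column 0/1/NaN item frame."""
    if items.shape[1] != 4:
        raise ParameterError("item frame must have exactly four columns")
    vals = items.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | (vals == 0) | (vals == 1))
    if bad.any():
        raise ParameterError("item values must be 0, 1 or NaN")
    score = vals.sum(axis=1)
    score[np.isnan(vals).any(axis=1)] = np.nan
    return pd.Series(score, index=items.index, name="suicidality")
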