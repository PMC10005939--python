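"""Reading, writing, harmonizing and quality-filtering GWAS summary statistics.

Summary statistics live in pandas DataFrames with the munged-sumstats column
convention (SNP, A1, A2, Z, N, optionally BETA/SE/CHR/BP/FREQ); LD scores in
CHR SNP BP L2 tables.  Gzip is handled transparently by pandas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import LDReference, ParameterError

REQUIRED_COLUMNS = ("SNP", "A1", "A2", "Z", "N")
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
VALID_ALLELES = {"A", "C", "G", "T"}

# MHC interval (chr6, Mb), excludable when positions are available; the build
# is a configuration concern, the default matches common GRCh37 usage.
MHC_REGION = (6, 25_000_000, 34_000_000)


class SchemaError(ValueError):
    """A required column is missing or malformed."""


@dataclass
class FilterReport:
    """Accounting of the sequential QC filter (allowlist -> Z^2 -> Neff)."""

    n_input: int
    n_removed_not_in_allowlist: int
    n_removed_z2: int
    n_removed_neff: int
    n_output: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_not_in_allowlist + self.n_removed_z2 + self.n_removed_neff
        )
        assert self.n_output == self.n_input - removed, "filter counts do not reconcile"


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check the summary-statistics invariants, returning the frame unchanged.

    Requires the munged columns; enforces se > 0, a1 != a2, alleles in
    {A,C,G,T}, and |Z - BETA/SE| < 1e-6 whenever BETA and SE are present.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing")
    if len(df) == 0:
        return df
    if not np.issubdtype(df["Z"].dtype, np.number):
        bad = df.index[pd.to_numeric(df["Z"], errors="coerce").isna()]
        raise SchemaError(f"non-numeric Z at line {bad[0] + 2}")  # +2: header, 1-based
    if (df["A1"] == df["A2"]).any():
        raise SchemaError("a1 == a2 for some variants")
    alleles = set(df["A1"]).union(df["A2"])
    if not alleles <= VALID_ALLELES:
        raise SchemaError(f"alleles outside {{A,C,G,T}}: {alleles - VALID_ALLELES}")
    if "SE" in df.columns:
        if (df["SE"] <= 0).any():
            raise SchemaError("SE must be strictly positive")
        if "BETA" in df.columns:
            dev = np.abs(df["Z"] - df["BETA"] / df["SE"]).max()
            if dev >= 1e-6:
                raise SchemaError(f"Z inconsistent with BETA/SE (max dev {dev:.2e})")
    return df


def read_sumstats(path, dialect: str = "munged", column_map: dict | None = None):
    """Read summary statistics from a whitespace/TSV file.

    ``dialect='munged'`` expects at least SNP A1 A2 Z N; ``dialect='generic'``
    renames columns through ``column_map`` ({file column -> canonical name})
    first.  Unknown columns are preserved untouched.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if dialect == "generic" and column_map:
        df = df.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing in {path}")
    if not np.issubdtype(df["Z"].dtype, np.number):
        coerced = pd.to_numeric(df["Z"], errors="coerce")
        bad = df.index[coerced.isna() & df["Z"].notna()]
        if len(bad):
            raise SchemaError(f"non-numeric Z at line {bad[0] + 2} of {path}")
        df["Z"] = coerced
    return validate_sumstats(df)


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write munged-dialect summary statistics (tab-separated, gzip by suffix)."""
    validate_sumstats(df)
    df.to_csv(path, sep="\t", index=False)


def read_ld_scores(path) -> pd.DataFrame:
    """Read a CHR SNP BP L2 [+ per-annotation L2] table."""
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("SNP", "L2"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing in {path}")
    return df


def write_ld_scores(ld: LDReference, path, annot_path=None) -> None:
    ld.table.to_csv(path, sep="\t", index=False)
    if annot_path is not None and ld.annotations is not None:
        ld.annotations.to_csv(annot_path, sep="\t", index=False)


def _ambiguous(a1: pd.Series, a2: pd.Series) -> np.ndarray:
    pairs = list(zip(a1, a2))
    return np.array([p in AMBIGUOUS_PAIRS for p in pairs])


def harmonize(
    traits: list[pd.DataFrame], reference: LDReference | pd.DataFrame
) -> list[pd.DataFrame]:
    """Align several traits' summary statistics to a reference variant set.

    Variants are restricted to the intersection of every trait with the
    reference; allele order is matched to the reference (Z and BETA signs flip
    on an A1/A2 swap); strand-ambiguous variants (A/T, C/G) are removed;
    variants whose alleles cannot be reconciled with the reference are dropped
    and counted, not fatal.  Every output frame has the same variants in the
    same (reference) order.
    """
    if len(traits) == 0:
        raise ParameterError("at least one trait required")
    ref = reference.table if isinstance(reference, LDReference) else reference
    ref = ref.set_index("SNP")
    have_ref_alleles = {"A1", "A2"} <= set(ref.columns)
    if not have_ref_alleles:  # first trait defines the allele orientation
        ref = ref.join(traits[0].set_index("SNP")[["A1", "A2"]], how="inner")

    keep: set[str] | None = None
    for df in traits:
        validate_sumstats(df)
        ids = set(df.loc[~_ambiguous(df["A1"], df["A2"]), "SNP"])
        keep = ids if keep is None else keep & ids
    keep &= set(ref.index)

    snp_order = [s for s in ref.index if s in keep]
    ref_a1 = ref.loc[snp_order, "A1"].to_numpy()
    ref_a2 = ref.loc[snp_order, "A2"].to_numpy()

    aligned, drop_everywhere = [], np.zeros(len(snp_order), dtype=bool)
    for df in traits:
        sub = df.set_index("SNP").loc[snp_order].reset_index()
        same = (sub["A1"].to_numpy() == ref_a1) & (sub["A2"].to_numpy() == ref_a2)
        swapped = (sub["A1"].to_numpy() == ref_a2) & (sub["A2"].to_numpy() == ref_a1)
        drop_everywhere |= ~(same | swapped)
        sub.loc[swapped, "Z"] = -sub.loc[swapped, "Z"]
        if "BETA" in sub.columns:
            sub.loc[swapped, "BETA"] = -sub.loc[swapped, "BETA"]
        sub.loc[swapped, ["A1", "A2"]] = np.column_stack(
            [ref_a1[swapped], ref_a2[swapped]]
        )
        aligned.append(sub)
    out = [df.loc[~drop_everywhere].reset_index(drop=True) for df in aligned]
    return out


def qc_filter(
    df: pd.DataFrame,
    allowlist: set | None = None,
    z2_max: float = 80.0,
    neff_factor: float = 0.67,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the three-stage summary-statistics QC filter.

    Sequentially (1) restrict to the variant allowlist (HapMap3-style), (2)
    drop variants with Z^2 strictly greater than ``z2_max`` (the boundary is
    kept), and (3) drop variants with N below ``neff_factor`` times the 90th
    percentile of N, that percentile being computed on the post-allowlist set.
    Returns the filtered frame plus a per-stage removal report.
    """
    validate_sumstats(df)
    n_input = len(df)
    if allowlist is not None:
        in_allow = df["SNP"].isin(allowlist)
    else:
        in_allow = pd.Series(True, index=df.index)
    n_allow_removed = int((~in_allow).sum())
    df1 = df.loc[in_allow]

    z2_ok = df1["Z"] ** 2 <= z2_max
    n_z2_removed = int((~z2_ok).sum())
    df2 = df1.loc[z2_ok]

    if len(df1):
        threshold = neff_factor * np.percentile(df1["N"].to_numpy(), 90)
        neff_ok = df2["N"] >= threshold
    else:
        neff_ok = pd.Series(True, index=df2.index)
    n_neff_removed = int((~neff_ok).sum())
    out = df2.loc[neff_ok].reset_index(drop=True)

    report = FilterReport(
        n_input=n_input,
        n_removed_not_in_allowlist=n_allow_removed,
        n_removed_z2=n_z2_removed,
        n_removed_neff=n_neff_removed,
        n_output=len(out),
    )
    return out, report


def exclude_mhc(
    df: pd.DataFrame, region: tuple[int, int, int] = MHC_REGION
) -> pd.DataFrame:
    """Drop variants in the MHC interval (requires CHR/BP columns)."""
    if not {"CHR", "BP"} <= set(df.columns):
        raise SchemaError("CHR and BP columns required for interval exclusion")
    chrom, start, end = region
    inside = (df["CHR"] == chrom) & (df["BP"] >= start) & (df["BP"] <= end)
    return df.loc[~inside].reset_index(drop=True)
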