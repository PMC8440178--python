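"""GWAS summary-statistic handling and a desk-scale LD-score regression.

The genetic side of the pipeline estimates, for each disorder pair, the
genetic correlation rg of common-variant effects from GWAS summary
statistics. Inputs follow the munge-style layout (whitespace/tab-delimited
columns SNP, CHR, BP, A1, A2, Z (or BETA+SE / OR+SE), N, INFO, MAF).
Filtering mirrors standard practice: drop markers with INFO < 0.90, drop
the MHC region (hg19 chr6:25-35 Mb, inclusive), and keep only markers
present in a high-quality reference panel with reference MAF >= 5%.

The regression itself is a deliberately simplified LD-score regression:
z^2 (univariate) or z1*z2 (bivariate) regressed on a single LD-score
component with a free intercept and fixed weights 1/max(l, 1); the slope
times M/N (M/sqrt(N1*N2)) estimates h^2 (genetic covariance), and standard
errors come from a delete-one-block jackknife over contiguous
position-sorted SNP blocks (200 by default). There is no iterative
reweighting, partitioning, constrained intercept or liability-scale
conversion; the free bivariate intercept absorbs sample overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .concordance import pair_key

__all__ = [
    "read_sumstats",
    "read_ld_scores",
    "read_reference_maf",
    "filter_sumstats",
    "FilterLog",
    "ldsc_h2",
    "ldsc_rg",
    "H2Result",
    "GeneticCorrelationEntry",
    "load_rg_table",
    "write_rg_table",
    "MHC_CHROM",
    "MHC_START",
    "MHC_END",
    "SumstatsError",
]

logger = logging.getLogger(__name__)

# hg19 MHC locus, inclusive at both ends
MHC_CHROM = 6
MHC_START = 25_000_000
MHC_END = 35_000_000

INFO_MIN = 0.90
REF_MAF_MIN = 0.05

#: case-insensitive header aliases -> canonical column names
COLUMN_ALIASES: dict[str, str] = {
    "snp": "SNP", "rsid": "SNP", "markername": "SNP", "snpid": "SNP",
    "chr": "CHR", "chromosome": "CHR",
    "bp": "BP", "pos": "BP", "position": "BP",
    "a1": "A1", "allele1": "A1", "effect_allele": "A1",
    "a2": "A2", "allele2": "A2", "other_allele": "A2",
    "z": "Z", "zscore": "Z",
    "beta": "BETA", "b": "BETA", "effect": "BETA",
    "se": "SE", "stderr": "SE",
    "or": "OR",
    "n": "N", "nobs": "N", "neff": "N",
    "info": "INFO",
    "maf": "MAF", "frq": "MAF", "freq": "MAF",
}

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SumstatsError(ValueError):
    """Summary-statistics table violates a contract."""


def _canonicalize_columns(df: pd.DataFrame, aliases: Mapping[str, str] | None) -> pd.DataFrame:
    table = dict(COLUMN_ALIASES)
    if aliases:
        table.update({k.lower(): v for k, v in aliases.items()})
    return df.rename(columns=lambda c: table.get(c.strip().lower(), c.strip().upper()))


def read_sumstats(
    path: str | Path,
    n: float | None = None,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read munge-style GWAS summary statistics into a canonical DataFrame.

    Accepts Z directly or derives it from BETA+SE (z = beta/se) or OR+SE
    (z = ln(OR)/se). ``n`` supplies a constant sample size when the file
    has no N column. Returns columns SNP, CHR, BP, A1, A2, Z, N and, when
    present, INFO and MAF (folded to the minor-allele side).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str})
    df = _canonicalize_columns(df, aliases)
    if "Z" not in df.columns:
        if {"BETA", "SE"} <= set(df.columns):
            df["Z"] = df["BETA"].astype(float) / df["SE"].astype(float)
        elif {"OR", "SE"} <= set(df.columns):
            df["Z"] = np.log(df["OR"].astype(float)) / df["SE"].astype(float)
        else:
            raise SumstatsError(f"{path}: no Z column and no BETA+SE / OR+SE to derive it")
    if "N" not in df.columns:
        if n is None:
            raise SumstatsError(f"{path}: no N column; pass n= explicitly")
        df["N"] = float(n)
    missing = {"SNP", "CHR", "BP", "A1", "A2"} - set(df.columns)
    if missing:
        raise SumstatsError(f"{path}: missing columns {sorted(missing)}")
    df = df.copy()
    df["SNP"] = df["SNP"].astype(str)
    df["CHR"] = df["CHR"].astype(int)
    df["BP"] = df["BP"].astype(int)
    df["A1"] = df["A1"].astype(str).str.upper()
    df["A2"] = df["A2"].astype(str).str.upper()
    df["Z"] = df["Z"].astype(float)
    df["N"] = df["N"].astype(float)
    if "MAF" in df.columns:
        maf = df["MAF"].astype(float)
        df["MAF"] = np.minimum(maf, 1.0 - maf)
    validate_sumstats(df, name=str(path))
    keep = [c for c in ("SNP", "CHR", "BP", "A1", "A2", "Z", "N", "INFO", "MAF") if c in df.columns]
    return df[keep]


def validate_sumstats(df: pd.DataFrame, name: str = "sumstats") -> None:
    if df["SNP"].duplicated().any():
        dups = df.loc[df["SNP"].duplicated(), "SNP"].head(3).tolist()
        raise SumstatsError(f"{name}: duplicate SNP ids, e.g. {dups}")
    if not np.isfinite(df["Z"]).all():
        raise SumstatsError(f"{name}: non-finite z statistics")
    if (df["N"] <= 0).any():
        raise SumstatsError(f"{name}: non-positive sample sizes")


def read_ld_scores(path: str | Path) -> pd.DataFrame:
    """Read an LD-score table: tab-delimited CHR, SNP, BP, L2."""
    df = pd.read_csv(path, sep=r"\s+")
    df = df.rename(columns=lambda c: c.strip().upper())
    missing = {"CHR", "SNP", "BP", "L2"} - set(df.columns)
    if missing:
        raise SumstatsError(f"{path}: LD-score file missing columns {sorted(missing)}")
    df["SNP"] = df["SNP"].astype(str)
    if (df["L2"] <= 0).any():
        raise SumstatsError(f"{path}: non-positive LD scores")
    if df["SNP"].duplicated().any():
        raise SumstatsError(f"{path}: duplicate SNP ids in LD scores")
    return df[["CHR", "SNP", "BP", "L2"]]


def read_reference_maf(path: str | Path) -> pd.Series:
    """Read a reference-panel MAF table (SNP, MAF) into a SNP-indexed Series."""
    df = pd.read_csv(path, sep=r"\s+")
    df = df.rename(columns=lambda c: c.strip().upper())
    if missing := {"SNP", "MAF"} - set(df.columns):
        raise SumstatsError(f"{path}: reference MAF file missing columns {sorted(missing)}")
    return pd.Series(df["MAF"].astype(float).values, index=df["SNP"].astype(str))


@dataclass(frozen=True)
class FilterLog:
    """Per-rule drop counts from :func:`filter_sumstats`."""

    n_input: int
    n_dropped_info: int
    n_missing_info_kept: int
    n_dropped_mhc: int
    n_dropped_not_in_reference: int
    n_dropped_reference_maf: int
    n_output: int


def filter_sumstats(
    sumstats: pd.DataFrame, reference_maf: Mapping[str, float] | pd.Series
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the standard pre-LDSC marker filters, with per-rule accounting.

    Rules, applied in order: INFO < 0.90 dropped (markers with no INFO are
    kept and counted); MHC (chr6:25-35 Mb inclusive) dropped; markers absent
    from the reference panel dropped; reference MAF < 5% dropped.
    """
    ref = pd.Series(reference_maf) if not isinstance(reference_maf, pd.Series) else reference_maf
    if len(ref) == 0:
        raise SumstatsError("reference MAF mapping is empty")
    df = sumstats
    n_input = len(df)

    if "INFO" in df.columns:
        has_info = df["INFO"].notna()
        ok_info = ~has_info | (df["INFO"] >= INFO_MIN)
        n_missing_info = int((~has_info).sum())
        if n_missing_info:
            logger.info("%d markers lack INFO; kept", n_missing_info)
    else:
        ok_info = pd.Series(True, index=df.index)
        n_missing_info = n_input
        logger.info("no INFO column; all %d markers pass the INFO filter", n_input)
    n_dropped_info = int((~ok_info).sum())
    df = df[ok_info]

    in_mhc = (df["CHR"] == MHC_CHROM) & df["BP"].between(MHC_START, MHC_END, inclusive="both")
    n_dropped_mhc = int(in_mhc.sum())
    df = df[~in_mhc]

    in_ref = df["SNP"].isin(ref.index)
    n_dropped_absent = int((~in_ref).sum())
    df = df[in_ref]

    ref_maf = df["SNP"].map(ref)
    ok_maf = ref_maf >= REF_MAF_MIN
    n_dropped_maf = int((~ok_maf).sum())
    df = df[ok_maf]

    if df.empty:
        raise SumstatsError("no markers survive filtering; nothing to regress")
    log = FilterLog(
        n_input=n_input,
        n_dropped_info=n_dropped_info,
        n_missing_info_kept=n_missing_info,
        n_dropped_mhc=n_dropped_mhc,
        n_dropped_not_in_reference=n_dropped_absent,
        n_dropped_reference_maf=n_dropped_maf,
        n_output=len(df),
    )
    return df.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# LD-score regression


def _block_boundaries(m: int, n_blocks: int) -> np.ndarray:
    """Labels assigning m position-sorted SNPs to n_blocks contiguous blocks."""
    return np.repeat(np.arange(n_blocks), np.diff(np.linspace(0, m, n_blocks + 1).astype(int)))


def _wls_with_jackknife(
    ell: np.ndarray, y: np.ndarray, n_blocks: int
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted regression of y on [1, ell] plus leave-one-block-out refits.

    Weights are 1/max(ell, 1). Returns (coef, loo_coefs) where coef is
    (intercept, slope) and loo_coefs has one row per deleted block. Uses
    per-block partial normal equations, so the jackknife is exact and O(m).
    """
    m = len(ell)
    if np.ptp(ell) == 0:
        raise SumstatsError("constant LD scores: regression slope undefined")
    w = 1.0 / np.maximum(ell, 1.0)
    x = np.column_stack([np.ones(m), ell])
    labels = _block_boundaries(m, n_blocks)
    xw = x * w[:, None]
    # per-block sums of X'WX (flattened 2x2) and X'Wy
    a_flat = np.stack([xw[:, 0] * x[:, 0], xw[:, 0] * x[:, 1],
                       xw[:, 1] * x[:, 0], xw[:, 1] * x[:, 1]], axis=1)
    b_cols = xw * y[:, None]
    a_blocks = np.zeros((n_blocks, 4))
    b_blocks = np.zeros((n_blocks, 2))
    np.add.at(a_blocks, labels, a_flat)
    np.add.at(b_blocks, labels, b_cols)
    a_total = a_blocks.sum(axis=0).reshape(2, 2)
    b_total = b_blocks.sum(axis=0)
    coef = np.linalg.solve(a_total, b_total)
    loo = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        loo[b] = np.linalg.solve(a_total - a_blocks[b].reshape(2, 2), b_total - b_blocks[b])
    return coef, loo


def _jackknife_se(theta_loo: np.ndarray) -> float:
    """Delete-one(-block) jackknife SE from leave-out estimates."""
    b = len(theta_loo)
    return float(np.sqrt((b - 1) / b * ((theta_loo - theta_loo.mean()) ** 2).sum()))


@dataclass(frozen=True)
class H2Result:
    """SNP heritability estimate from univariate LD-score regression."""

    h2: float
    se: float
    intercept: float
    intercept_se: float
    m_snps: int
    mean_n: float
    n_blocks: int


def _merge_ld(sumstats: pd.DataFrame, ld: pd.DataFrame) -> pd.DataFrame:
    merged = sumstats.merge(ld[["SNP", "L2"]], on="SNP", how="inner")
    # jackknife blocks are contiguous in genome order
    return merged.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)


def _check_size(m: int, n_blocks: int) -> None:
    if n_blocks < 2:
        raise ValueError(f"n_blocks must be >= 2, got {n_blocks}")
    if m < 2 * n_blocks:
        raise SumstatsError(
            f"only {m} overlapping SNPs; need at least 2*n_blocks = {2 * n_blocks}"
        )


def ldsc_h2(sumstats: pd.DataFrame, ld: pd.DataFrame, n_blocks: int = 200) -> H2Result:
    """Estimate SNP heritability by regressing z^2 on LD scores.

    E[z_j^2] = 1 + N h2 l_j / M under the polygenic model, so the fitted
    slope times M / mean(N) estimates h2; the free intercept absorbs
    confounding. SE by delete-one-block jackknife.
    """
    merged = _merge_ld(sumstats, ld)
    m = len(merged)
    _check_size(m, n_blocks)
    ell = merged["L2"].to_numpy(float)
    y = merged["Z"].to_numpy(float) ** 2
    mean_n = float(merged["N"].mean())
    coef, loo = _wls_with_jackknife(ell, y, n_blocks)
    scale = m / mean_n
    return H2Result(
        h2=float(coef[1] * scale),
        se=_jackknife_se(loo[:, 1] * scale),
        intercept=float(coef[0]),
        intercept_se=_jackknife_se(loo[:, 0]),
        m_snps=m,
        mean_n=mean_n,
        n_blocks=n_blocks,
    )


@dataclass(frozen=True)
class GeneticCorrelationEntry:
    """One disorder pair's genetic correlation."""

    pair: tuple[str, str]
    rg: float
    se_rg: float
    h2_1: float | None = None
    h2_2: float | None = None
    gcov: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    m_snps: int | None = None


def _align_alleles(s1: pd.DataFrame, s2: pd.DataFrame) -> pd.DataFrame:
    """Merge two sumstats tables on SNP, harmonizing z2 to s1's allele coding.

    Strand-ambiguous (A/T, C/G) markers and allele mismatches are dropped.
    """
    merged = s1.merge(s2[["SNP", "A1", "A2", "Z", "N"]], on="SNP", suffixes=("", "_2"))
    ambiguous = [
        (a1, a2) in AMBIGUOUS_PAIRS for a1, a2 in zip(merged["A1"], merged["A2"])
    ]
    merged = merged[~np.array(ambiguous, dtype=bool)]
    same = (merged["A1"] == merged["A1_2"]) & (merged["A2"] == merged["A2_2"])
    flipped = (merged["A1"] == merged["A2_2"]) & (merged["A2"] == merged["A1_2"])
    n_mismatch = int((~(same | flipped)).sum())
    if n_mismatch:
        logger.info("dropping %d markers with irreconcilable alleles", n_mismatch)
    merged = merged[same | flipped].copy()
    merged.loc[flipped[same | flipped], "Z_2"] *= -1.0
    return merged


def ldsc_rg(
    s1: pd.DataFrame,
    s2: pd.DataFrame,
    ld: pd.DataFrame,
    n_blocks: int = 200,
    pair: tuple[str, str] = ("trait1", "trait2"),
) -> GeneticCorrelationEntry:
    """Estimate the genetic correlation of two traits by cross-trait LDSC.

    On the three-way SNP intersection (alleles harmonized, ambiguous
    markers dropped): z1*z2 regressed on LD scores gives the genetic
    covariance slope*M/sqrt(N1*N2); dividing by sqrt(h2_1*h2_2) — each
    estimated on the same SNP set — gives rg. The jackknife recomputes the
    full ratio per deleted block, so the SE reflects all three regressions.
    """
    merged = _align_alleles(s1, s2)
    merged = _merge_ld(merged, ld)
    m = len(merged)
    _check_size(m, n_blocks)
    ell = merged["L2"].to_numpy(float)
    z1 = merged["Z"].to_numpy(float)
    z2 = merged["Z_2"].to_numpy(float)
    n1 = float(merged["N"].mean())
    n2 = float(merged["N_2"].mean())

    coef1, loo1 = _wls_with_jackknife(ell, z1 ** 2, n_blocks)
    coef2, loo2 = _wls_with_jackknife(ell, z2 ** 2, n_blocks)
    coefx, loox = _wls_with_jackknife(ell, z1 * z2, n_blocks)

    h2_1 = float(coef1[1] * m / n1)
    h2_2 = float(coef2[1] * m / n2)
    gcov = float(coefx[1] * m / np.sqrt(n1 * n2))
    if h2_1 <= 0 or h2_2 <= 0:
        raise SumstatsError(
            f"non-positive heritability estimate (h2_1={h2_1:.4g}, h2_2={h2_2:.4g}); rg undefined"
        )
    rg = gcov / np.sqrt(h2_1 * h2_2)

    h2_1_loo = loo1[:, 1] * m / n1
    h2_2_loo = loo2[:, 1] * m / n2
    gcov_loo = loox[:, 1] * m / np.sqrt(n1 * n2)
    valid = (h2_1_loo > 0) & (h2_2_loo > 0)
    if not valid.all():
        logger.info("%d jackknife blocks dropped (non-positive h2)", int((~valid).sum()))
    rg_loo = gcov_loo[valid] / np.sqrt(h2_1_loo[valid] * h2_2_loo[valid])
    se_rg = _jackknife_se(rg_loo)

    if abs(rg) > 1.25:
        warnings.warn(f"rg estimate {rg:.3f} out of bounds (|rg| > 1.25)", stacklevel=2)
    return GeneticCorrelationEntry(
        pair=pair_key(*pair),
        rg=float(rg),
        se_rg=se_rg,
        h2_1=h2_1,
        h2_2=h2_2,
        gcov=gcov,
        intercept=float(coefx[0]),
        intercept_se=_jackknife_se(loox[:, 0]),
        m_snps=m,
    )


def load_rg_table(path: str | Path) -> list[GeneticCorrelationEntry]:
    """Load precomputed genetic correlations from TSV (disorder1 disorder2 rg se)."""
    df = pd.read_csv(path, sep="\t")
    if missing := {"disorder1", "disorder2", "rg", "se"} - set(df.columns):
        raise SumstatsError(f"{path}: rg table missing columns {sorted(missing)}")
    entries: list[GeneticCorrelationEntry] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = pair_key(str(row.disorder1), str(row.disorder2))
        if key in seen:
            raise SumstatsError(f"{path}: duplicate pair {key}")
        seen.add(key)
        rg = float(row.rg)
        if abs(rg) > 1.25:
            raise SumstatsError(f"{path}: |rg|={abs(rg):.3g} > 1.25 for pair {key}")
        entries.append(GeneticCorrelationEntry(pair=key, rg=rg, se_rg=float(row.se)))
    return entries


def write_rg_table(entries: list[GeneticCorrelationEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"disorder1": e.pair[0], "disorder2": e.pair[1], "rg": e.rg, "se": e.se_rg}
            for e in entries
        ]
    ).to_csv(path, sep="\t", index=False)
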