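"""Per-phenotype cross-disorder statistics.

For each brain phenotype the panel provides one Cohen's d per disorder
(where present). Two questions are asked of that small vector: do the
disorders agree on the *direction* of the case-control difference more
often than a fair coin would (exact binomial sign test), and is the
*magnitude* more variable than sampling error alone predicts (Cochran's Q,
inverse-variance weighted, chi-square with k-1 df under homogeneity)?

Q needs each d's sampling variance, computed with the standard large-sample
SMD formula v = (n1+n2)/(n1*n2) + d^2/(2*(n1+n2)) from the measure-specific
case/control counts; phenotypes whose counts are unknown are skipped and
logged, never silently defaulted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .profiles import DisorderPanel, EffectSizeProfile
from .registry import PhenotypeKey

__all__ = [
    "SignTestResult",
    "HeterogeneityResult",
    "ProfileSummary",
    "sign_test",
    "d_sampling_variance",
    "cochran_q",
    "profile_summary",
    "sign_test_table",
    "heterogeneity_table",
    "profile_summary_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignTestResult:
    n_negative: int
    n_positive: int
    n_zero: int
    p: float
    phenotype: PhenotypeKey | None = None


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    p: float
    phenotype: PhenotypeKey | None = None


@dataclass(frozen=True)
class ProfileSummary:
    disorder: str
    mean_d: float
    se_mean: float
    n_phenotypes: int


def sign_test(
    d_values: Sequence[float], phenotype: PhenotypeKey | None = None
) -> SignTestResult:
    """Exact two-sided binomial sign test on effect directions.

    Zeros are excluded from the trial count (reported as ``n_zero``). The
    two-sided p is the doubled smaller tail at success probability 0.5,
    capped at 1 — exact, since k never exceeds the disorder count.
    """
    d = np.asarray(d_values, dtype=float)
    n_neg = int((d < 0).sum())
    n_pos = int((d > 0).sum())
    n_zero = int((d == 0).sum())
    n = n_neg + n_pos
    if n < 2:
        raise ValueError(f"sign test needs >= 2 nonzero values, got {n}")
    p = min(1.0, 2.0 * float(stats.binom.cdf(min(n_neg, n_pos), n, 0.5)))
    return SignTestResult(n_negative=n_neg, n_positive=n_pos, n_zero=n_zero, p=p, phenotype=phenotype)


def d_sampling_variance(d: float, n_cases: int, n_controls: int) -> float:
    """Large-sample sampling variance of a Cohen's d from a two-group design.

    v = (n1 + n2)/(n1*n2) + d^2 / (2*(n1 + n2))
    """
    if n_cases < 2 or n_controls < 2:
        raise ValueError(f"group sizes must be >= 2, got ({n_cases}, {n_controls})")
    n = n_cases + n_controls
    return n / (n_cases * n_controls) + d * d / (2.0 * n)


def cochran_q(
    d_values: Sequence[float],
    variances: Sequence[float],
    phenotype: PhenotypeKey | None = None,
) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test across k effect estimates.

    Q = sum w_i (d_i - dbar_w)^2 with w_i = 1/v_i and dbar_w the
    inverse-variance-weighted mean; p from the chi-square upper tail at
    k - 1 df.
    """
    d = np.asarray(d_values, dtype=float)
    v = np.asarray(variances, dtype=float)
    if d.shape != v.shape:
        raise ValueError(f"d and variance sequences misaligned: {d.shape} vs {v.shape}")
    if len(d) < 2:
        raise ValueError(f"Q needs >= 2 estimates, got {len(d)}")
    if (v <= 0).any():
        raise ValueError("all variances must be positive")
    w = 1.0 / v
    dbar = float((w * d).sum() / w.sum())
    q = float((w * (d - dbar) ** 2).sum())
    df = len(d) - 1
    return HeterogeneityResult(Q=q, df=df, p=float(stats.chi2.sf(q, df)), phenotype=phenotype)


def profile_summary(profile: EffectSizeProfile) -> ProfileSummary:
    """Mean Cohen's d across a disorder's present phenotypes, with sd/sqrt(n)."""
    d = profile.vector()
    if len(d) < 2:
        raise ValueError(f"{profile.disorder}: summary needs >= 2 phenotypes")
    return ProfileSummary(
        disorder=profile.disorder,
        mean_d=float(d.mean()),
        se_mean=float(d.std(ddof=1) / np.sqrt(len(d))),
        n_phenotypes=len(d),
    )


def _phenotype_column(panel: DisorderPanel, key: PhenotypeKey):
    """(disorder, d) pairs for one phenotype across the panel."""
    return [(p.disorder, p.values[key]) for p in panel.profiles if key in p.values]


def sign_test_table(panel: DisorderPanel) -> list[SignTestResult]:
    """Sign tests for every phenotype present in >= 2 disorders (nonzero d)."""
    out = []
    for key in panel.registry.phenotypes:
        col = _phenotype_column(panel, key)
        d = [v for _, v in col]
        if sum(1 for v in d if v != 0) < 2:
            logger.info("sign test skipped for %s: < 2 nonzero values", key)
            continue
        out.append(sign_test(d, phenotype=key))
    return out


def heterogeneity_table(panel: DisorderPanel) -> list[HeterogeneityResult]:
    """Cochran's Q for every phenotype with >= 2 disorders carrying counts.

    Disorders lacking measure-specific case/control counts are dropped from
    that phenotype's test (logged); phenotypes left with < 2 usable
    estimates are skipped entirely.
    """
    out = []
    for key in panel.registry.phenotypes:
        d_vals, variances = [], []
        for profile in panel.profiles:
            if key not in profile.values:
                continue
            counts = profile.counts_for(key)
            if counts is None:
                logger.info("Q: %s dropped for %s (no sample sizes)", profile.disorder, key)
                continue
            d = profile.values[key]
            d_vals.append(d)
            variances.append(d_sampling_variance(d, *counts))
        if len(d_vals) < 2:
            logger.info("Q skipped for %s: < 2 estimates with sample sizes", key)
            continue
        out.append(cochran_q(d_vals, variances, phenotype=key))
    return out


def profile_summary_table(panel: DisorderPanel) -> list[ProfileSummary]:
    return [profile_summary(p) for p in panel.profiles]
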