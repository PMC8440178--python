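"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`gen_effect_panel` — per-disorder Cohen's d profiles drawn, one
  brain phenotype at a time, from a multivariate normal with a target
  cross-disorder correlation matrix, per-disorder location/scale, and
  missing-phenotype masks (e.g. an epilepsy-like disorder with no
  surface-area measures).
* :func:`gen_gwas_pair` — a pair of GWAS summary-statistic tables whose
  z statistics follow the LD-score regression expectation model:
  var(z_i) = 1 + N_i h2_i l/M and cov(z1, z2) = sqrt(N1 N2) rg
  sqrt(h2_1 h2_2) l/M, with SNPs independent given their LD score. This
  matches the regression's estimand without simulating realized LD, which
  is exactly what makes h2/rg recovery a sharp test of the estimator.
* :func:`gen_joint_scenario` — couples the two: builds a panel correlation
  target whose off-diagonal entries are a noisy monotone transform of a
  given genetic-correlation vector, calibrated so the population Spearman
  correlation between the two similarity structures equals a requested
  coupling (via the bivariate-normal grade-correlation identity
  rho_s = (6/pi) asin(rho_p / 2)).

The default panel scenario mirrors the shape of the real cross-disorder
study: 7 disorders, 75 phenotypes, shared-phenotype counts {75, 74, 41},
profile means from -0.22 (schizophrenia-like) to -0.018 (depression-like),
and measure-specific case/control counts at published magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import pair_key
from .profiles import DisorderPanel, EffectSizeProfile, ValidationError
from .registry import (
    SURFACE_AREA,
    SUBCORTICAL_VOLUME,
    THICKNESS,
    PhenotypeKey,
    PhenotypeRegistry,
    default_registry,
)

__all__ = [
    "PanelScenario",
    "GwasScenario",
    "SpikeIns",
    "JointScenarioInfo",
    "gen_effect_panel",
    "gen_gwas_pair",
    "gen_joint_scenario",
    "psd_project",
    "default_panel_scenario",
    "DEFAULT_DISORDERS",
    "DEFAULT_RG",
]

DEFAULT_DISORDERS = ("ADHD", "ASD", "BD", "Epilepsy", "MDD", "OCD", "SCZ")

#: Plausible cross-disorder genetic correlations (published magnitudes:
#: high for the two psychotic disorders, near zero for epilepsy vs the
#: psychiatric disorders). Used as the default rg vector in joint scenarios.
DEFAULT_RG: dict[tuple[str, str], float] = {
    ("ADHD", "ASD"): 0.36, ("ADHD", "BD"): 0.13, ("ADHD", "Epilepsy"): 0.04,
    ("ADHD", "MDD"): 0.42, ("ADHD", "OCD"): -0.10, ("ADHD", "SCZ"): 0.12,
    ("ASD", "BD"): 0.16, ("ASD", "Epilepsy"): 0.02, ("ASD", "MDD"): 0.41,
    ("ASD", "OCD"): 0.11, ("ASD", "SCZ"): 0.21, ("BD", "Epilepsy"): 0.05,
    ("BD", "MDD"): 0.35, ("BD", "OCD"): 0.31, ("BD", "SCZ"): 0.68,
    ("Epilepsy", "MDD"): 0.09, ("Epilepsy", "OCD"): 0.01, ("Epilepsy", "SCZ"): 0.03,
    ("MDD", "OCD"): 0.22, ("MDD", "SCZ"): 0.34, ("OCD", "SCZ"): 0.33,
}

#: Observed cross-disorder imaging correlations (the Table-2-style pattern)
#: used as the default panel correlation target (PSD-projected at build).
_DEFAULT_IMAGING_R: dict[tuple[str, str], float] = {
    ("ADHD", "ASD"): -0.06, ("ADHD", "BD"): -0.53, ("ADHD", "Epilepsy"): -0.36,
    ("ADHD", "MDD"): -0.33, ("ADHD", "OCD"): -0.10, ("ADHD", "SCZ"): -0.32,
    ("ASD", "BD"): 0.38, ("ASD", "Epilepsy"): 0.02, ("ASD", "MDD"): 0.26,
    ("ASD", "OCD"): 0.00, ("ASD", "SCZ"): 0.36, ("BD", "Epilepsy"): 0.17,
    ("BD", "MDD"): 0.69, ("BD", "OCD"): 0.50, ("BD", "SCZ"): 0.81,
    ("Epilepsy", "MDD"): -0.37, ("Epilepsy", "OCD"): -0.19, ("Epilepsy", "SCZ"): -0.03,
    ("MDD", "OCD"): 0.46, ("MDD", "SCZ"): 0.58, ("OCD", "SCZ"): 0.65,
}

#: Profile means/scales at published magnitudes (most-affected: SCZ-like;
#: least: MDD-like).
_DEFAULT_MEANS = {
    "ADHD": -0.05, "ASD": -0.04, "BD": -0.097, "Epilepsy": -0.12,
    "MDD": -0.018, "OCD": -0.04, "SCZ": -0.22,
}
_DEFAULT_SCALES = {
    "ADHD": 0.08, "ASD": 0.07, "BD": 0.095, "Epilepsy": 0.11,
    "MDD": 0.05, "OCD": 0.06, "SCZ": 0.12,
}

#: Measure-specific (cases, controls) counts at published magnitudes.
_DEFAULT_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "ADHD": {THICKNESS: (2246, 1934), SURFACE_AREA: (2246, 1934), SUBCORTICAL_VOLUME: (1713, 1529)},
    "ASD": {THICKNESS: (1571, 1651), SURFACE_AREA: (1571, 1651), SUBCORTICAL_VOLUME: (1571, 1651)},
    "BD": {THICKNESS: (1837, 2582), SURFACE_AREA: (1820, 2582), SUBCORTICAL_VOLUME: (1710, 2594)},
    "Epilepsy": {THICKNESS: (2149, 1727), SUBCORTICAL_VOLUME: (2149, 1727)},
    "MDD": {THICKNESS: (1911, 7663), SURFACE_AREA: (1902, 7658), SUBCORTICAL_VOLUME: (1728, 7199)},
    "OCD": {THICKNESS: (1498, 1435), SURFACE_AREA: (1497, 1433), SUBCORTICAL_VOLUME: (1495, 1472)},
    "SCZ": {THICKNESS: (4474, 5098), SURFACE_AREA: (4434, 5073), SUBCORTICAL_VOLUME: (2028, 2540)},
}


def psd_project(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Nearest-ish PSD correlation matrix: clip eigenvalues, rescale diagonal."""
    corr = np.asarray(corr, dtype=float)
    sym = (corr + corr.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    fixed = (vecs * np.maximum(vals, eps)) @ vecs.T
    scale = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(scale, scale)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass
class PanelScenario:
    """Ground truth for an effect-size panel simulation."""

    disorders: tuple[str, ...]
    target_corr: np.ndarray
    means: dict[str, float]
    scales: dict[str, float]
    masks: dict[str, frozenset[PhenotypeKey]] = field(default_factory=dict)
    n_cases: dict[str, dict[str, int]] = field(default_factory=dict)
    n_controls: dict[str, dict[str, int]] = field(default_factory=dict)
    registry: PhenotypeRegistry = field(default_factory=default_registry, repr=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.disorders = tuple(self.disorders)
        d = len(self.disorders)
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        if self.target_corr.shape != (d, d):
            raise ValidationError(f"target_corr must be {d}x{d}")
        if not np.allclose(self.target_corr, self.target_corr.T, atol=1e-10):
            raise ValidationError("target_corr must be symmetric")
        if not np.allclose(np.diag(self.target_corr), 1.0, atol=1e-10):
            raise ValidationError("target_corr must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(self.target_corr).min())
        if eigmin < -1e-8:
            raise ValidationError(
                f"target_corr not positive semidefinite (smallest eigenvalue {eigmin:.3g})"
            )
        for name in self.disorders:
            if name not in self.means or name not in self.scales:
                raise ValidationError(f"missing mean/scale for {name}")
            if self.scales[name] <= 0:
                raise ValidationError(f"scale for {name} must be > 0")
        for a_i in range(d):
            for b_i in range(a_i + 1, d):
                a, b = self.disorders[a_i], self.disorders[b_i]
                if len(self._present(a) & self._present(b)) < 3:
                    raise ValidationError(f"masks leave < 3 shared phenotypes for {a}/{b}")

    def _present(self, disorder: str) -> set[PhenotypeKey]:
        missing = self.masks.get(disorder, frozenset())
        return set(self.registry.phenotypes) - set(missing)


def default_panel_scenario(seed: int | None = None) -> PanelScenario:
    """Seven-disorder scenario mirroring the real study's shape.

    Correlation target: the observed cross-disorder imaging pattern (PSD
    projected). Masks: the epilepsy-like disorder lacks all surface-area
    phenotypes (41 present) and the OCD-like disorder lacks one
    surface-area phenotype (74 present), so pairwise overlaps reproduce the
    {75, 74, 41} shared-phenotype counts.
    """
    registry = default_registry()
    corr = pairs_to_matrix(DEFAULT_DISORDERS, _DEFAULT_IMAGING_R)
    corr = psd_project(corr)
    sa_all = frozenset(k for k in registry.phenotypes if k.measure == SURFACE_AREA)
    masks = {
        "Epilepsy": sa_all,
        "OCD": frozenset({PhenotypeKey("bankssts", SURFACE_AREA)}),
    }
    return PanelScenario(
        disorders=DEFAULT_DISORDERS,
        target_corr=corr,
        means=dict(_DEFAULT_MEANS),
        scales=dict(_DEFAULT_SCALES),
        masks=masks,
        n_cases={d: {m: c[0] for m, c in per.items()} for d, per in _DEFAULT_COUNTS.items()},
        n_controls={d: {m: c[1] for m, c in per.items()} for d, per in _DEFAULT_COUNTS.items()},
        registry=registry,
        seed=seed,
    )


def pairs_to_matrix(
    disorders: tuple[str, ...], values: Mapping[tuple[str, str], float]
) -> np.ndarray:
    """Assemble a symmetric unit-diagonal matrix from a pair -> value mapping."""
    d = len(disorders)
    index = {name: i for i, name in enumerate(disorders)}
    mat = np.eye(d)
    for (a, b), v in values.items():
        mat[index[a], index[b]] = mat[index[b], index[a]] = v
    return mat


def matrix_to_pairs(
    disorders: tuple[str, ...], mat: np.ndarray
) -> dict[tuple[str, str], float]:
    d = len(disorders)
    return {
        pair_key(disorders[i], disorders[j]): float(mat[i, j])
        for i in range(d)
        for j in range(i + 1, d)
    }


def gen_effect_panel(scenario: PanelScenario, seed: int | None = None) -> DisorderPanel:
    """Draw a disorder panel from the scenario's multivariate-normal model.

    Each phenotype contributes one independent D-vector draw with the
    scenario's cross-disorder correlation; disorder i's value is
    mean_i + scale_i * z_i. Masked phenotypes are then removed per
    disorder. Deterministic given the seed (falls back to scenario.seed).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    d = len(scenario.disorders)
    n_phen = scenario.registry.n_phenotypes
    # square-root factor via eigendecomposition so singular targets
    # (e.g. a perfectly correlated pair) are admissible
    vals, vecs = np.linalg.eigh(scenario.target_corr)
    root = vecs * np.sqrt(np.maximum(vals, 0.0))
    z = rng.standard_normal(size=(n_phen, d)) @ root.T

    profiles = []
    for i, name in enumerate(scenario.disorders):
        missing = scenario.masks.get(name, frozenset())
        values = {
            key: float(scenario.means[name] + scenario.scales[name] * z[j, i])
            for j, key in enumerate(scenario.registry.phenotypes)
            if key not in missing
        }
        profiles.append(
            EffectSizeProfile(
                disorder=name,
                values=values,
                n_cases=dict(scenario.n_cases.get(name, {})),
                n_controls=dict(scenario.n_controls.get(name, {})),
                provenance="synthetic:gen_effect_panel",
                registry=scenario.registry,
            )
        )
    return DisorderPanel(profiles=tuple(profiles))


@dataclass
class GwasScenario:
    """Ground truth for a simulated GWAS summary-statistic pair."""

    m_snps: int = 20_000
    n1: float = 50_000
    n2: float = 50_000
    h2_1: float = 0.3
    h2_2: float = 0.3
    rg: float = 0.0
    ld_shape: float = 2.0
    ld_scale: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m_snps < 1000:
            raise ValidationError(f"m_snps must be >= 1000, got {self.m_snps}")
        for h2 in (self.h2_1, self.h2_2):
            if not 0.0 <= h2 <= 1.0:
                raise ValidationError(f"h2 must be in [0, 1], got {h2}")
        if abs(self.rg) > 1.0:
            raise ValidationError(f"|rg| must be <= 1, got {self.rg}")
        if self.ld_shape <= 0 or self.ld_scale <= 0:
            raise ValidationError("LD-score distribution parameters must be positive")


@dataclass(frozen=True)
class SpikeIns:
    """Extra records constructed to fail each marker filter, for testing."""

    n_low_info: int = 0
    n_mhc: int = 0
    n_missing_reference: int = 0
    n_low_reference_maf: int = 0


def gen_gwas_pair(
    scenario: GwasScenario,
    seed: int | None = None,
    spike_ins: SpikeIns | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a pair of sumstats tables plus LD scores and reference MAFs.

    LD scores are 1 + Gamma(shape, scale). Given its LD score l_j, SNP j's
    (z1, z2) are bivariate normal with variances 1 + N_i h2_i l_j / M and
    covariance sqrt(N1 N2) rg sqrt(h2_1 h2_2) l_j / M — the cross-trait
    LD-score regression model with no realized inter-SNP correlation.
    Positions are laid out contiguously over 22 autosomes; all core SNPs
    have INFO = 1 and reference MAF uniform on [0.05, 0.5].
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    m = sc.m_snps
    ell = 1.0 + rng.gamma(sc.ld_shape, sc.ld_scale, size=m)

    var1 = 1.0 + sc.n1 * sc.h2_1 * ell / m
    var2 = 1.0 + sc.n2 * sc.h2_2 * ell / m
    cov = math.sqrt(sc.n1 * sc.n2) * sc.rg * math.sqrt(sc.h2_1 * sc.h2_2) * ell / m
    if (cov * cov > var1 * var2 + 1e-12).any():
        raise ValidationError("per-SNP z covariance matrix not positive semidefinite")
    u1 = rng.standard_normal(m)
    u2 = rng.standard_normal(m)
    z1 = np.sqrt(var1) * u1
    z2 = (cov / np.sqrt(var1)) * u1 + np.sqrt(np.maximum(var2 - cov * cov / var1, 0.0)) * u2

    chrom = (np.arange(m) * 22) // m + 1
    # restart positions on each chromosome, clear of the MHC window
    bp = np.zeros(m, dtype=int)
    for c in range(1, 23):
        idx = np.flatnonzero(chrom == c)
        bp[idx] = 1_000_000 + np.arange(len(idx)) * 1_000
    snp = np.array([f"rs{j}" for j in range(m)])

    def table(z: np.ndarray, n: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": snp, "CHR": chrom, "BP": bp, "A1": "A", "A2": "G",
                "Z": z, "N": float(n), "INFO": 1.0,
            }
        )

    s1, s2 = table(z1, sc.n1), table(z2, sc.n2)
    ld = pd.DataFrame({"CHR": chrom, "SNP": snp, "BP": bp, "L2": ell})
    ref_maf = pd.Series(rng.uniform(0.05, 0.5, size=m), index=snp)

    if spike_ins is not None:
        s1, s2, ld, ref_maf = _add_spikes(s1, s2, ld, ref_maf, spike_ins, rng)
    return s1, s2, ld, ref_maf


def _add_spikes(s1, s2, ld, ref_maf, spikes: SpikeIns, rng):
    """Append records engineered to trip each filter rule exactly once each."""
    rows1, rows2, ld_rows, maf_extra = [], [], [], {}
    counter = 0

    def new_record(snp_id, chrom, bp, info):
        z = rng.standard_normal(2)
        base = {"SNP": snp_id, "CHR": chrom, "BP": bp, "A1": "A", "A2": "G", "INFO": info}
        rows1.append({**base, "Z": z[0], "N": float(s1["N"].iloc[0])})
        rows2.append({**base, "Z": z[1], "N": float(s2["N"].iloc[0])})
        ld_rows.append({"CHR": chrom, "SNP": snp_id, "BP": bp, "L2": 1.0 + rng.gamma(2.0, 15.0)})

    for _ in range(spikes.n_low_info):
        sid = f"spike_info{counter}"; counter += 1
        new_record(sid, 1, 500 + counter, info=0.5)
        maf_extra[sid] = 0.25
    for _ in range(spikes.n_mhc):
        sid = f"spike_mhc{counter}"; counter += 1
        new_record(sid, MHC_CHROM_SPIKE, 30_000_000 + counter, info=1.0)
        maf_extra[sid] = 0.25
    for _ in range(spikes.n_missing_reference):
        sid = f"spike_noref{counter}"; counter += 1
        new_record(sid, 2, 500 + counter, info=1.0)  # deliberately absent from ref_maf
    for _ in range(spikes.n_low_reference_maf):
        sid = f"spike_rare{counter}"; counter += 1
        new_record(sid, 3, 500 + counter, info=1.0)
        maf_extra[sid] = 0.01

    s1 = pd.concat([s1, pd.DataFrame(rows1)], ignore_index=True) if rows1 else s1
    s2 = pd.concat([s2, pd.DataFrame(rows2)], ignore_index=True) if rows2 else s2
    ld = pd.concat([ld, pd.DataFrame(ld_rows)], ignore_index=True) if ld_rows else ld
    if maf_extra:
        ref_maf = pd.concat([ref_maf, pd.Series(maf_extra)])
    return s1, s2, ld, ref_maf


MHC_CHROM_SPIKE = 6


@dataclass(frozen=True)
class JointScenarioInfo:
    """Diagnostics for a coupled imaging/genetic scenario."""

    requested_coupling: float
    pre_projection_coupling: float
    post_projection_coupling: float


def gen_joint_scenario(
    rg_vector: Mapping[tuple[str, str], float] | None = None,
    coupling: float = 0.44,
    seed: int | None = None,
    means: Mapping[str, float] | None = None,
    scales: Mapping[str, float] | None = None,
    use_default_masks: bool = True,
) -> tuple[PanelScenario, dict[tuple[str, str], float], JointScenarioInfo]:
    """Build a panel scenario whose similarity structure tracks an rg vector.

    The target correlation entries are a strictly monotone squashing of
    latent values c* = rho_p g + sqrt(1 - rho_p^2) e, where g are normal
    scores of the rg ranks, e is seeded standard-normal rank noise and
    rho_p = 2 sin(pi * coupling / 6) — the Pearson correlation whose
    bivariate-normal grade (Spearman) correlation equals ``coupling``. The
    matrix is then PSD-projected; both the pre- and post-projection
    Spearman couplings with rg are reported. An error is raised if the
    projection destroys the requested ordering (monotone agreement between
    pre- and post-projection entries below 0.8).
    """
    if abs(coupling) > 1.0:
        raise ValidationError(f"|coupling| must be <= 1, got {coupling}")
    rg = {pair_key(*k): float(v) for k, v in (rg_vector or DEFAULT_RG).items()}
    disorders = tuple(sorted({d for k in rg for d in k}))
    n_pairs = len(disorders) * (len(disorders) - 1) // 2
    if len(rg) != n_pairs:
        raise ValidationError(
            f"rg vector has {len(rg)} pairs; {n_pairs} required for {len(disorders)} disorders"
        )
    pairs = sorted(rg)
    rg_arr = np.array([rg[k] for k in pairs])

    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(rg_arr, method="average")
    g = stats.norm.ppf((ranks - 0.375) / (len(ranks) + 0.25))  # Blom normal scores
    g = (g - g.mean()) / g.std(ddof=0)
    rho_p = 2.0 * math.sin(math.pi * coupling / 6.0)
    latent = rho_p * g + math.sqrt(1.0 - rho_p ** 2) * rng.standard_normal(len(g))
    # strictly monotone squash into a plausible correlation range
    c = 0.2 + 0.65 * np.tanh(latent / 2.0)

    from .concordance import correlate  # local import to avoid cycle at module load

    pre = correlate(c, rg_arr, method="spearman")
    corr = pairs_to_matrix(disorders, dict(zip(pairs, c)))
    corr_psd = psd_project(corr)
    c_post = np.array([corr_psd[disorders.index(a), disorders.index(b)] for a, b in pairs])
    post = correlate(c_post, rg_arr, method="spearman")
    agreement = correlate(c, c_post, method="spearman")
    if agreement < 0.8:
        raise ValidationError(
            f"PSD projection destroyed the requested coupling (pre/post rank agreement "
            f"{agreement:.2f}); achievable coupling about {post:.2f} vs requested {coupling:.2f}"
        )

    registry = default_registry()
    if use_default_masks and set(disorders) == set(DEFAULT_DISORDERS):
        base = default_panel_scenario()
        masks, n_cases, n_controls = base.masks, base.n_cases, base.n_controls
        default_means, default_scales = base.means, base.scales
    else:
        masks, n_cases, n_controls = {}, {}, {}
        default_means = {d: -0.1 for d in disorders}
        default_scales = {d: 0.1 for d in disorders}
    scenario = PanelScenario(
        disorders=disorders,
        target_corr=corr_psd,
        means=dict(means or default_means),
        scales=dict(scales or default_scales),
        masks=masks,
        n_cases=n_cases,
        n_controls=n_controls,
        registry=registry,
        seed=None if seed is None else int(np.random.SeedSequence([seed, 1]).generate_state(1)[0] % (2**31)),
    )
    info = JointScenarioInfo(
        requested_coupling=float(coupling),
        pre_projection_coupling=float(pre),
        post_projection_coupling=float(post),
    )
    return scenario, rg, info
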