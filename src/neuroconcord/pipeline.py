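"""End-to-end orchestration: panel -> pairwise table -> region stats ->
genetic correlations -> correlation of correlations -> report bundle.

The run is fully deterministic given the config (seed included); rerunning
with the same config produces byte-identical TSV outputs. Figures (a
correlation heatmap and the imaging-vs-genetic scatter) are best-effort
vector graphics excluded from the bit-exactness guarantee.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    ConcordanceResult,
    PairwiseResult,
    correlation_of_correlations,
    pair_key,
    pairwise_table,
)
from .genetics import (
    GeneticCorrelationEntry,
    filter_sumstats,
    ldsc_rg,
    load_rg_table,
    read_ld_scores,
    read_reference_maf,
    read_sumstats,
    write_rg_table,
)
from .profiles import DisorderPanel, ValidationError, load_effect_table, write_effect_table
from .region_stats import heterogeneity_table, profile_summary_table, sign_test_table
from .simulate import default_panel_scenario, gen_effect_panel

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_report", "StageError"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and context."""


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    effect_table: str | None = None  # path; None -> simulate the default scenario
    rg_table: str | None = None  # precomputed rg TSV; bypasses LDSC
    sumstats: dict[str, str] = field(default_factory=dict)  # disorder -> path
    ld_scores: str | None = None
    reference_maf: str | None = None
    method: Literal["pearson", "spearman"] = "pearson"
    concordance_method: Literal["pearson", "spearman"] = "spearman"
    n_perm: int = 10_000
    bonferroni_m: int | None = None  # None -> number of pairs
    n_blocks: int = 200
    seed: int = 0
    output_dir: str = "neuroconcord_run"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError(f"n_perm must be >= 1, got {self.n_perm}")
        if self.seed is None:
            raise ValidationError("seed must be set: runs are deterministic by contract")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(raw) - known:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All artifacts of one pipeline run."""

    config: RunConfig
    panel: DisorderPanel
    pairwise: list[PairwiseResult]
    sign_tests: list
    heterogeneity: list
    summaries: list
    rg: list[GeneticCorrelationEntry]
    concordance: ConcordanceResult | None


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate with stage context, keep traceback
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute every stage and return the report bundle."""
    if cfg.effect_table:
        panel = _stage("effect_size_io")(load_effect_table, cfg.effect_table)
    else:
        logger.info("no effect table given; simulating the default scenario")
        scenario = default_panel_scenario(seed=cfg.seed)
        panel = _stage("synthetic_data")(gen_effect_panel, scenario)

    pairwise = _stage("concordance")(
        pairwise_table,
        panel,
        method=cfg.method,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        bonferroni_m=cfg.bonferroni_m,
    )
    sign_tests = _stage("region_stats")(sign_test_table, panel)
    heterogeneity = _stage("region_stats")(heterogeneity_table, panel)
    summaries = _stage("region_stats")(profile_summary_table, panel)

    rg_entries = _stage("genetics")(_genetic_stage, cfg, panel)

    concordance = None
    if rg_entries:
        imaging = {row.pair: row.r for row in pairwise}
        genetic = {e.pair: e.rg for e in rg_entries}
        concordance = _stage("concordance_of_correlations")(
            correlation_of_correlations,
            imaging,
            genetic,
            method=cfg.concordance_method,
        )
    return ReportBundle(
        config=cfg,
        panel=panel,
        pairwise=pairwise,
        sign_tests=sign_tests,
        heterogeneity=heterogeneity,
        summaries=summaries,
        rg=rg_entries,
        concordance=concordance,
    )


def _genetic_stage(cfg: RunConfig, panel: DisorderPanel) -> list[GeneticCorrelationEntry]:
    if cfg.rg_table:
        return load_rg_table(cfg.rg_table)
    if not cfg.sumstats:
        logger.info("no genetic inputs configured; skipping the genetics stage")
        return []
    if not (cfg.ld_scores and cfg.reference_maf):
        raise ValidationError("sumstats given but ld_scores/reference_maf missing")
    ld = read_ld_scores(cfg.ld_scores)
    ref = read_reference_maf(cfg.reference_maf)
    filtered: dict[str, pd.DataFrame] = {}
    for disorder, path in cfg.sumstats.items():
        table = read_sumstats(path)
        table, log = filter_sumstats(table, ref)
        logger.info("%s: %s", disorder, log)
        filtered[disorder] = table
    names = sorted(filtered)
    entries = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            entries.append(
                ldsc_rg(filtered[a], filtered[b], ld, n_blocks=cfg.n_blocks, pair=(a, b))
            )
    return entries


def _sci(p: float) -> str:
    """Scientific notation with 3 significant digits for p-value columns."""
    return f"{p:.2E}"


def pairwise_frame(rows: list[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "disorder1": [r.pair[0] for r in rows],
            "disorder2": [r.pair[1] for r in rows],
            "r": [round(r.r, 6) for r in rows],
            "df": [r.df for r in rows],
            "se": [round(r.se, 6) for r in rows],
            "p": [_sci(r.p) for r in rows],
            "p_precise": [repr(r.p) for r in rows],
            "p_bonf": [_sci(r.p_bonf) for r in rows],
            "p_perm": [_sci(r.p_perm) for r in rows],
            "n_perm": [r.n_perm for r in rows],
            "method": [r.method for r in rows],
        }
    )


def write_report(bundle: ReportBundle, directory: str | Path, figures: bool = True) -> list[Path]:
    """Write the TSV tables, manifest and figures; returns the file list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(frame: pd.DataFrame, name: str) -> None:
        path = directory / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    emit(pairwise_frame(bundle.pairwise), "pairwise.tsv")

    emit(
        pd.DataFrame(
            {
                "phenotype": [str(t.phenotype) for t in bundle.sign_tests],
                "n_neg": [t.n_negative for t in bundle.sign_tests],
                "n_pos": [t.n_positive for t in bundle.sign_tests],
                "n_zero": [t.n_zero for t in bundle.sign_tests],
                "p_sign": [_sci(t.p) for t in bundle.sign_tests],
            }
        ),
        "regions_sign.tsv",
    )
    if bundle.heterogeneity:
        emit(
            pd.DataFrame(
                {
                    "phenotype": [str(t.phenotype) for t in bundle.heterogeneity],
                    "Q": [round(t.Q, 6) for t in bundle.heterogeneity],
                    "df": [t.df for t in bundle.heterogeneity],
                    "p_q": [_sci(t.p) for t in bundle.heterogeneity],
                }
            ),
            "regions_q.tsv",
        )
    else:
        logger.info("no heterogeneity results (no sample sizes); regions_q.tsv omitted")
    emit(
        pd.DataFrame(
            {
                "disorder": [s.disorder for s in bundle.summaries],
                "mean_d": [round(s.mean_d, 6) for s in bundle.summaries],
                "se_mean": [round(s.se_mean, 6) for s in bundle.summaries],
                "n_phenotypes": [s.n_phenotypes for s in bundle.summaries],
            }
        ),
        "profiles.tsv",
    )
    if bundle.rg:
        path = directory / "rg.tsv"
        write_rg_table(bundle.rg, path)
        written.append(path)
    if bundle.concordance is not None:
        c = bundle.concordance
        emit(
            pd.DataFrame(
                {
                    "statistic": ["rho", "p", "n_pairs", "loo_min", "loo_max"],
                    "value": [round(c.rho, 6), _sci(c.p), c.n_pairs,
                              round(c.loo_min, 6), round(c.loo_max, 6)],
                }
            ),
            "concordance.tsv",
        )
        emit(
            pd.DataFrame(
                {
                    "excluded_disorder1": [k[0] for k in sorted(c.loo)],
                    "excluded_disorder2": [k[1] for k in sorted(c.loo)],
                    "rho": [round(c.loo[k], 6) for k in sorted(c.loo)],
                }
            ),
            "concordance_loo.tsv",
        )

    effect_path = directory / "effect_table.tsv"
    write_effect_table(bundle.panel, effect_path)
    written.append(effect_path)

    manifest = {
        "package": "neuroconcord",
        "version": __version__,
        "seed": bundle.config.seed,
        "config": dataclasses.asdict(bundle.config),
        "config_digest": bundle.config.digest(),
        "files": sorted(p.name for p in written),
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)

    if figures:
        written.extend(_figures(bundle, directory))
    return written


def _figures(bundle: ReportBundle, directory: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    out: list[Path] = []
    disorders = list(bundle.panel.disorders)
    mat = np.full((len(disorders), len(disorders)), np.nan)
    np.fill_diagonal(mat, 1.0)
    for row in bundle.pairwise:
        i, j = disorders.index(row.pair[0]), disorders.index(row.pair[1])
        mat[i, j] = mat[j, i] = row.r
    fig, ax = plt.subplots(figsize=(6, 5))
    sns.heatmap(
        pd.DataFrame(mat, index=disorders, columns=disorders),
        annot=True, fmt=".2f", cmap="RdBu_r", vmin=-1, vmax=1, ax=ax,
    )
    ax.set_title("Cross-disorder sMRI correlations")
    fig.tight_layout()
    heatmap_path = directory / "heatmap.svg"
    fig.savefig(heatmap_path)
    plt.close(fig)
    out.append(heatmap_path)

    if bundle.concordance is not None and bundle.rg:
        imaging = {r.pair: r.r for r in bundle.pairwise}
        rg_map = {e.pair: (e.rg, e.se_rg) for e in bundle.rg}
        keys = sorted(imaging)
        x = np.array([rg_map[k][0] for k in keys])
        xerr = np.array([rg_map[k][1] for k in keys])
        y = np.array([imaging[k] for k in keys])
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.errorbar(x, y, xerr=xerr, fmt="o", capsize=2)
        slope, intercept = np.polyfit(x, y, 1)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, slope * grid + intercept, ls="--", color="grey")
        ax.set_xlabel("genetic correlation (rg)")
        ax.set_ylabel("sMRI effect-size correlation")
        c = bundle.concordance
        ax.text(0.02, 0.95, f"Spearman rho = {c.rho:.2f}, p = {c.p:.3f}",
                transform=ax.transAxes, va="top")
        fig.tight_layout()
        scatter_path = directory / "scatter.svg"
        fig.savefig(scatter_path)
        plt.close(fig)
        out.append(scatter_path)
    return out
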