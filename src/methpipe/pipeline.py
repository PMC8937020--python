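"""End-to-end orchestration: simulate/load -> call sites -> map genes ->
classify -> associate -> screen, with a machine-readable JSON report.

The report is the single source of truth for downstream checks; it carries
per-stage counts, the config echo, and the package version, but no
timestamps, so identical configs produce identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .differential import AGGREGATION_POLICIES, call_differential_sites, drop_all_zero_sites
from .errors import ConfigurationError, DataFormatError, DegenerateStatisticsError, MethpipeError
from .expression import (
    CLASS_SPECS,
    UNIVERSES,
    association_report,
    call_de_genes,
    compute_rpkm,
)
from .gene_mapping import assign_sites_to_genes, build_profiles
from .instability import (
    RANKING_KEYS,
    classify_genes,
    per_chromosome_site_counts,
    rank_unstable_genes,
    updown_correlation,
    venn_counts,
)
from .instability import biotype_composition
from .io_formats import (
    MARKS,
    read_counts,
    read_gene_annotation,
    read_sample_sheet,
    read_site_scores,
    read_survival,
    write_differential_sites,
    write_json,
)
from .survival import screen_genes, select_tsg_candidates
from .synthetic import SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with paper-default thresholds."""

    # inputs (ignored when a `simulate` section is present)
    genes: str | None = None
    sites_5mC: str | None = None
    sites_6mA: str | None = None
    sample_sheet: str | None = None
    counts: str | None = None
    survival: str | None = None
    simulate: SimulationConfig | None = None
    # thresholds and policies
    fold: float = 2.0
    zero_rescue: float = 0.6
    de_fold: float = 2.0
    de_pseudocount: float = 0.01
    alpha: float = 0.05
    top_n: int = 100
    aggregation_policy: str = "mean_by_condition"
    class_spec: str = "mark_both_updown"
    universe: str = "annotated_genes"
    ranking_key: str = "total"
    flank: int = 0
    yates: bool = False
    seed: int | None = None

    def __post_init__(self):
        for name in ("fold", "zero_rescue", "de_fold", "alpha"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.top_n < 1:
            raise ConfigurationError(f"top_n must be >= 1, got {self.top_n}")
        if self.aggregation_policy not in AGGREGATION_POLICIES:
            raise ConfigurationError(
                f"aggregation_policy must be one of {AGGREGATION_POLICIES}"
            )
        if self.class_spec not in CLASS_SPECS:
            raise ConfigurationError(f"class_spec must be one of {CLASS_SPECS}")
        if self.universe not in UNIVERSES:
            raise ConfigurationError(f"universe must be one of {UNIVERSES}")
        if self.ranking_key not in RANKING_KEYS:
            raise ConfigurationError(f"ranking_key must be one of {RANKING_KEYS}")
        if self.flank < 0:
            raise ConfigurationError("flank must be >= 0")


def validate_config(path) -> PipelineConfig:
    """Load and normalize a pipeline YAML; unknown keys are rejected with
    their key path, and an empty file yields all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    sim = raw.pop("simulate", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    sim_cfg = None
    if sim is not None:
        if not isinstance(sim, dict):
            raise ConfigurationError("config key 'simulate': must be a mapping")
        try:
            sim_cfg = SimulationConfig.from_dict(sim)
        except ConfigurationError as exc:
            raise ConfigurationError(f"simulate: {exc}") from exc
    try:
        cfg = PipelineConfig(simulate=sim_cfg, **raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    if cfg.seed is not None and cfg.simulate is not None:
        cfg.simulate = dataclasses.replace(cfg.simulate, seed=cfg.seed)
    return cfg


def _config_echo(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.simulate is not None:
        d["simulate"] = dataclasses.asdict(cfg.simulate)
    return d


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write all outputs plus ``report.json`` into
    *outdir*. Returns the report dict. A stage failure raises with the stage
    name; the partial report is kept as ``report.partial.json``."""
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"version": __version__, "config": _config_echo(config)}
    stage = "setup"
    try:
        # ----- inputs -------------------------------------------------
        stage = "inputs"
        survival_df = None
        if config.simulate is not None:
            cohort = simulate_cohort(config.simulate)
            paths = write_cohort(cohort, os.path.join(outdir, "cohort"))
            # relative paths keep the report identical across output dirs
            report["cohort_paths"] = {
                k: os.path.relpath(p, outdir) for k, p in paths.items()
            }
            genes = cohort.genes
            tables = cohort.site_tables
            samples = cohort.samples
            counts = cohort.counts
            survival_df = cohort.survival
            report["seed"] = config.simulate.seed
        else:
            if not (config.genes and config.sites_5mC and config.sites_6mA and config.sample_sheet):
                raise ConfigurationError(
                    "genes, sites_5mC, sites_6mA and sample_sheet are required "
                    "when no simulate section is given"
                )
            genes = read_gene_annotation(config.genes)
            samples = read_sample_sheet(config.sample_sheet)
            tables = {
                "5mC": read_site_scores(config.sites_5mC, "5mC", samples),
                "6mA": read_site_scores(config.sites_6mA, "6mA", samples),
            }
            counts = read_counts(config.counts) if config.counts else None
            if config.survival:
                survival_df = read_survival(config.survival)
            report["seed"] = config.seed

        # ----- differential sites ------------------------------------
        stage = "call_sites"
        diff_frames = []
        site_stats = {}
        for mark in MARKS:
            table = tables[mark]
            retained = drop_all_zero_sites(table)
            diff = call_differential_sites(
                table,
                policy=config.aggregation_policy,
                fold_threshold=config.fold,
                zero_rescue_threshold=config.zero_rescue,
            )
            write_differential_sites(diff, os.path.join(outdir, f"diff_{mark}.tsv"))
            site_stats[mark] = {
                "n_input_sites": len(table),
                "n_after_zero_drop": len(retained),
                "n_dropped_all_zero": len(table) - len(retained),
                "n_up": int((diff["direction"] == "up").sum()),
                "n_down": int((diff["direction"] == "down").sum()),
            }
            diff_frames.append(diff)
        diff_all = (
            pd.concat(diff_frames, ignore_index=True)
            if any(len(d) for d in diff_frames)
            else diff_frames[0]
        )
        report["differential_sites"] = site_stats
        report["per_chromosome_sites"] = per_chromosome_site_counts(diff_all).to_dict(
            orient="records"
        )

        # ----- gene mapping -------------------------------------------
        stage = "map_genes"
        assigned = assign_sites_to_genes(diff_all, genes, flank=config.flank)
        profiles = build_profiles(assigned)
        profiles = profiles.merge(genes[["gene_id", "biotype"]], on="gene_id", how="left")
        profiles[
            ["gene_id", "biotype", "n_up_5mC", "n_down_5mC", "n_up_6mA", "n_down_6mA", "total"]
        ].to_csv(os.path.join(outdir, "profiles.tsv"), sep="\t", index=False)
        n_assigned_sites = (
            assigned[["chrom", "pos0", "mark"]].drop_duplicates().shape[0] if len(assigned) else 0
        )
        report["gene_mapping"] = {
            "n_assignments": len(assigned),
            "n_genes_with_sites": len(profiles),
            "n_intergenic_sites": int(len(diff_all) - n_assigned_sites),
        }

        # ----- classification & instability stats ---------------------
        stage = "classify"
        labels = classify_genes(profiles)
        labels.to_csv(os.path.join(outdir, "labels.tsv"), sep="\t", index=False)
        unstable_ids = labels.loc[labels["unstable"], "gene_id"].tolist()
        stats: dict = {
            "n_genes_classified": len(labels),
            "n_unstable": len(unstable_ids),
            "venn": venn_counts(labels),
        }
        if unstable_ids:
            comp = biotype_composition(unstable_ids, genes)
            stats["biotype_composition"] = {
                b: {
                    "set_fraction": float(r.set_fraction),
                    "background_fraction": float(r.background_fraction),
                }
                for b, r in comp.iterrows()
            }
        for mark in MARKS:
            try:
                r, n_used = updown_correlation(profiles, mark)
                stats[f"updown_pearson_{mark}"] = {"r": r, "n_genes": n_used}
            except DegenerateStatisticsError as exc:
                stats[f"updown_pearson_{mark}"] = {"error": str(exc)}
        top = rank_unstable_genes(labels=labels, profiles=profiles, n=config.top_n, key=config.ranking_key)
        stats["top_unstable_genes"] = top
        report["instability"] = stats

        # ----- expression association ---------------------------------
        stage = "associate"
        de_results = None
        if counts is not None:
            rpkm = compute_rpkm(counts)
            de_results = call_de_genes(
                rpkm,
                samples,
                fold_threshold=config.de_fold,
                pseudocount=config.de_pseudocount,
            )
            de_results.to_csv(
                os.path.join(outdir, "de.tsv"), sep="\t", index=False, float_format="%.10g"
            )
            universe = (
                genes["gene_id"]
                if config.universe == "annotated_genes"
                else profiles["gene_id"]
            )
            report["association"] = association_report(
                labels, de_results, universe, yates=config.yates
            )
            report["association"]["universe"] = config.universe
            report["association"]["n_de"] = int(de_results["de"].sum())
        else:
            report["association"] = {"skipped": "no counts table provided"}

        # ----- survival screen ----------------------------------------
        stage = "screen"
        if survival_df is not None:
            screenable = [g for g in top if g in survival_df.columns]
            screen = screen_genes(survival_df, screenable, alpha=config.alpha)
            screen.to_csv(
                os.path.join(outdir, "screen.tsv"), sep="\t", index=False, float_format="%.10g"
            )
            entry = {
                "n_screened": len(screen),
                "n_selected": int(screen["selected"].sum()) if len(screen) else 0,
                "selected_genes": screen.loc[screen["selected"], "gene_id"].tolist()
                if len(screen)
                else [],
            }
            if de_results is not None and len(screen):
                entry["tsg_candidates"] = select_tsg_candidates(screen, de_results)
            report["survival_screen"] = entry
        else:
            report["survival_screen"] = {"skipped": "no survival table provided"}

        stage = "report"
        write_json(report, os.path.join(outdir, "report.json"))
        return report
    except Exception as exc:
        write_json(report, os.path.join(outdir, "report.partial.json"))
        if isinstance(exc, MethpipeError):
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        raise MethpipeError(f"[stage {stage}] {exc}") from exc
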