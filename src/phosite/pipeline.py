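"""End-to-end pipeline: FASTA + PSM table in, all result tables out.

Stages: parse -> map to protein coordinates -> coverage per
(condition, replicate) -> phospho-site evidence -> filter/classify ->
motif annotation -> interactome fold-change matrix. The run report
accounts for every parsed PSM exactly once (mapped / ambiguous /
unmatched / other-protein) and records row counts at every stage, so two
runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from phosite import digest, enrichment, motifs as motifs_mod, sites as sites_mod
from phosite.io import (
    ExperimentDesign,
    ProteinRecord,
    read_fasta,
    read_psm_table,
    write_table,
)
from phosite.sites import FilterConfig

logger = logging.getLogger("phosite")

COLOR_HEX = {"gray": "#9e9e9e", "blue": "#4878cf", "coral": "#f08070"}


class ConfigError(ValueError):
    """Invalid pipeline configuration (bad path, unknown accession...)."""


@dataclass
class PipelineConfig:
    fasta_path: Path
    psm_path: Path
    out_dir: Path
    design: ExperimentDesign
    target_accession: str
    filters: FilterConfig = field(default_factory=FilterConfig)
    motif_config_path: Path | None = None
    depth_over_covered_only: bool = True
    write_plots: bool = False


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    n_parsed: int = 0
    n_target_protein: int = 0
    n_other_protein: int = 0
    n_mapped: int = 0
    n_ambiguous: int = 0
    n_unmatched: int = 0
    n_site_evidence: int = 0
    n_detected_sites: int = 0
    site_counts: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run every stage and write all result tables under ``cfg.out_dir``.

    Writes: ``site_table.tsv``, ``site_counts.tsv``, ``coverage_<cond>.tsv``
    and ``coverage_summary.tsv``, ``fold_change_matrix.tsv``,
    ``run_report.json`` (and ``tracks.png`` when ``write_plots``).
    """
    if not cfg.fasta_path.exists():
        raise ConfigError(f"FASTA not found: {cfg.fasta_path}")
    if not cfg.psm_path.exists():
        raise ConfigError(f"PSM table not found: {cfg.psm_path}")
    proteins = {p.accession: p for p in read_fasta(cfg.fasta_path)}
    if cfg.target_accession not in proteins:
        raise ConfigError(
            f"target accession {cfg.target_accession!r} not in FASTA "
            f"(has {sorted(proteins)})"
        )
    target = proteins[cfg.target_accession]
    cfg.out_dir.mkdir(parents=True, exist_ok=True)

    report = RunReport(
        config={
            "fasta": str(cfg.fasta_path),
            "psm_table": str(cfg.psm_path),
            "target": cfg.target_accession,
            "conditions": list(cfg.design.conditions),
            "reference": cfg.design.reference,
            "replicates": cfg.design.replicates_per_condition,
            "confidence_threshold": cfg.filters.confidence_threshold,
            "min_phospho_psms": cfg.filters.min_phospho_psms,
        }
    )

    psms = read_psm_table(cfg.psm_path, cfg.design)
    report.n_parsed = len(psms)
    logger.info("parsed %d PSMs", len(psms))

    target_psms = [p for p in psms if p.protein_accession == cfg.target_accession]
    report.n_target_protein = len(target_psms)
    report.n_other_protein = len(psms) - len(target_psms)

    mapped: list[digest.MappedPsm] = []
    for psm in target_psms:
        result = digest.map_psm(psm, target)
        if isinstance(result, digest.MappedPsm):
            mapped.append(result)
        elif result.status == "ambiguous":
            report.n_ambiguous += 1
        else:
            report.n_unmatched += 1
    report.n_mapped = len(mapped)
    logger.info(
        "mapped %d / ambiguous %d / unmatched %d",
        report.n_mapped, report.n_ambiguous, report.n_unmatched,
    )

    # coverage per condition, averaged over replicates
    coverage_rows = []
    for cond in cfg.design.conditions:
        profiles = []
        for rep in cfg.design.replicates:
            rep_mapped = [
                m for m in mapped
                if m.psm.condition == cond and m.psm.replicate == rep
            ]
            profiles.append(digest.coverage_profile(rep_mapped, target))
        percent, depth = digest.average_coverage(
            profiles, covered_only=cfg.depth_over_covered_only
        )
        report.coverage[cond] = {"percent_coverage": percent, "mean_depth": depth}
        coverage_rows.append(
            {"condition": cond, "percent_coverage": percent, "mean_depth": depth}
        )
        mean_depth_track = sum(p.depth for p in profiles) / len(profiles)
        _write(
            pd.DataFrame(
                {
                    "position": range(1, target.length + 1),
                    "depth": mean_depth_track,
                }
            ),
            cfg.out_dir / f"coverage_{cond}.tsv",
            report,
        )
    _write(pd.DataFrame(coverage_rows), cfg.out_dir / "coverage_summary.tsv", report)

    evidence = sites_mod.collect_site_evidence(mapped, cfg.design)
    report.n_site_evidence = len(evidence)
    summaries = sites_mod.detect_and_classify(evidence, cfg.design, cfg.filters)
    report.n_detected_sites = len(summaries)

    patterns = (
        motifs_mod.load_motif_config(cfg.motif_config_path)
        if cfg.motif_config_path
        else motifs_mod.default_patterns()
    )
    annotations = motifs_mod.scan_motifs(target, patterns)
    summaries = motifs_mod.annotate_sites(summaries, annotations)

    site_frame = sites_mod.summaries_to_frame(summaries, cfg.design)
    _write(site_frame, cfg.out_dir / "site_table.tsv", report)

    counts = sites_mod.site_count_report(summaries, cfg.design)
    report.site_counts = counts
    count_rows = [
        {"metric": f"n_sites_{cond}", "value": n}
        for cond, n in counts["per_condition"].items()
    ] + [
        {"metric": k, "value": counts[k]}
        for k in ("union", "shared_all", "mitotic_shared", "unique_starred", "other")
    ]
    _write(pd.DataFrame(count_rows), cfg.out_dir / "site_counts.tsv", report)

    protein_counts = enrichment.count_psms_per_protein(psms, cfg.design)
    matrix = enrichment.build_matrix(protein_counts, cfg.design)
    _write(matrix.to_frame(), cfg.out_dir / "fold_change_matrix.tsv", report)

    if cfg.write_plots:
        try:
            coverage_tracks = {
                cond: pd.read_csv(cfg.out_dir / f"coverage_{cond}.tsv", sep="\t")["depth"]
                for cond in cfg.design.conditions
            }
            fig_path = cfg.out_dir / "tracks.png"
            render_tracks(summaries, coverage_tracks, target, cfg.design, fig_path)
            report.outputs.append(fig_path.name)
        except Exception as exc:  # plotting is presentational only
            logger.warning("plot rendering failed: %s", exc)

    (cfg.out_dir / "run_report.json").write_text(report.to_json() + "\n")
    if report.n_parsed == 0:
        logger.warning("PSM table contained no rows; outputs are header-only")
    return report


def _write(frame: pd.DataFrame, path: Path, report: RunReport) -> None:
    write_table(frame, path)
    report.outputs.append(path.name)


def render_tracks(
    summaries: Sequence[sites_mod.SiteSummary],
    coverage_by_condition: dict[str, "pd.Series"],
    protein: ProteinRecord,
    design: ExperimentDesign,
    path: Path,
) -> None:
    """Linear per-condition site tracks (colored by abundance bin, starred
    when condition-unique) above an aligned coverage track."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows = len(design.conditions) + 1
    fig, axes = plt.subplots(
        n_rows, 1, figsize=(10, 1.0 * n_rows), sharex=True,
        gridspec_kw={"height_ratios": [1] * len(design.conditions) + [2]},
    )
    for ax, cond in zip(axes[:-1], design.conditions):
        ax.hlines(0.5, 1, protein.length, color="0.8", lw=3)
        for s in summaries:
            if not s.detected_in(cond):
                continue
            ax.vlines(
                s.position, 0.2, 0.8,
                color=COLOR_HEX[s.color_bin_for(cond)], lw=1.5,
            )
            if s.category == "unique_starred":
                ax.plot(s.position, 0.92, marker="*", ms=6, color="black")
        ax.set_ylim(0, 1.1)
        ax.set_yticks([])
        ax.set_ylabel(cond, rotation=0, ha="right", va="center", fontsize=8)
    cov_ax = axes[-1]
    for cond in design.conditions:
        cov_ax.plot(
            range(1, protein.length + 1),
            coverage_by_condition[cond],
            lw=0.8, label=cond,
        )
    cov_ax.set_xlabel("residue position")
    cov_ax.set_ylabel("PSM depth", fontsize=8)
    cov_ax.legend(fontsize=6, ncol=len(design.conditions))
    cov_ax.set_xlim(1, protein.length)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
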