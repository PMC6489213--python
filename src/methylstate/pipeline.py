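"""End-to-end orchestration: run every stage on one input bundle.

``run_all`` consumes a :class:`PipelineConfig` (typically loaded from
YAML), executes QC, differential calling, metagene profiling, expression
and histone integration and the cross-cell-type specificity stage, and
writes one TSV per figure/table-like data product plus a manifest.  No
stage mutates its inputs, so reruns are idempotent.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffmeth, expression as expr_mod, histone, preprocess, profiles, specificity
from .io import (
    RegionSet,
    SampleDesign,
    ValidationError,
    read_beta_matrix,
    read_expression_table,
    read_gene_models,
    read_regions_bed,
    read_sample_design,
    write_table,
)

log = logging.getLogger("methylstate")


@dataclass
class PipelineConfig:
    """Input paths, thresholds and output location for a full run."""

    beta: str
    detection_p: str
    annotation: str
    design: str
    genes: str
    expression: str
    outdir: str
    peaks_increased: str | None = None
    peaks_decreased: str | None = None
    chrom_sizes: str | None = None
    other_beta: str | None = None
    expression_panel: str | None = None

    condition_a: str = "non_decidualized"
    condition_b: str = "decidualized"

    p_cutoff: float = 0.05
    delta_cutoffs: tuple[float, ...] = (0.15, 0.30)
    fold_cutoff: float = 1.5
    silent_cutoff: float = 0.01
    beta_cutoff: float = 0.2
    specificity_delta: float = 0.3
    promoter_window: tuple[int, int] = (-300, 700)
    association_window: tuple[int, int] = (-1500, 4000)
    upstream_bp: int = 1500
    downstream_bp: int = 1000
    body_bins: int = 40
    flank_bin_bp: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("delta_cutoffs", "promoter_window", "association_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("beta", "annotation", "design", "genes", "expression"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValidationError(f"input file for {name!r} not found: {p}")
        for name in ("detection_p", "peaks_increased", "peaks_decreased",
                     "chrom_sizes", "other_beta", "expression_panel"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input file for {name!r} not found: {p}")
        if not (0 < self.p_cutoff < 1):
            raise ValidationError("p_cutoff must be in (0, 1)")
        for c in self.delta_cutoffs:
            if not (0 < c < 1):
                raise ValidationError("delta cutoffs must be in (0, 1)")


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the manifest of written outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        write_table(frame, path)
        manifest[name] = path

    stage = "load"
    try:
        matrix, annotation = read_beta_matrix(config.beta, config.annotation,
                                              config.detection_p)
        design = read_sample_design(config.design)
        design.validate_against(matrix)
        genes = read_gene_models(config.genes)
        expr_table = read_expression_table(config.expression)

        stage = "preprocess"
        log.info("filtering %d probes (detection p <= %s in all samples, chrY dropped)",
                 matrix.shape[0], config.p_cutoff)
        matrix, report = preprocess.filter_probes(matrix, annotation, config.p_cutoff)
        annotation = annotation.subset(matrix.probes)
        emit("qc_report", report.to_frame())
        dist_rows = []
        for cond in (config.condition_a, config.condition_b):
            s = preprocess.summarize_beta_distribution(matrix, design, condition=cond)
            dist_rows.append({"condition": cond, **dataclasses.asdict(s)})
        emit("beta_distribution", pd.DataFrame(dist_rows))

        stage = "diffmeth"
        log.info("calling differential CpGs at cutoffs %s", list(config.delta_cutoffs))
        results = diffmeth.call_differential(
            matrix, design, config.condition_a, config.condition_b,
            cutoffs=list(config.delta_cutoffs),
        )
        summary_rows = []
        for cutoff, (calls, summary) in results.items():
            summary_rows.append({
                "cutoff": cutoff,
                "n_valid_cpgs": summary.n_valid_cpgs,
                "n_total_differential": summary.n_total_differential,
                "n_hypo": summary.n_hypo,
                "n_hyper": summary.n_hyper,
                "percent_of_all_cpgs": round(summary.fraction_of_all_cpgs, 4),
            })
        emit("differential_summary", pd.DataFrame(summary_rows))
        strictest = max(config.delta_cutoffs)
        calls, _ = results[strictest]
        emit("differential_calls",
             calls[calls["direction"] != "unchanged"])
        diffmeth.export_scatter(matrix, design, config.condition_a,
                                config.condition_b, outdir / "scatter.tsv")
        manifest["scatter"] = outdir / "scatter.tsv"
        assoc = diffmeth.associate_cpgs_with_genes(
            calls, genes, annotation, window=config.association_window)
        stage = "expression"
        classes = expr_mod.classify_expression(
            expr_table, config.fold_cutoff, config.silent_cutoff)
        gene_table = assoc.merge(
            classes.reset_index()[["gene_id", "fold_change", "label"]],
            on="gene_id", how="left")
        emit("differential_gene_table", gene_table)

        stage = "profiles"
        log.info("building metagene profiles (%d body bins, %d bp flank bins)",
                 config.body_bins, config.flank_bin_bp)
        assignments = profiles.assign_cpgs(
            genes, annotation, config.upstream_bp, config.downstream_bp)
        prof_frames = []
        for cond in (config.condition_a, config.condition_b):
            prof = profiles.metagene_profile(
                assignments, matrix, design, cond,
                body_bins=config.body_bins, flank_bin_bp=config.flank_bin_bp,
                upstream_bp=config.upstream_bp, downstream_bp=config.downstream_bp)
            frame = prof.bins.copy()
            frame.insert(0, "condition", cond)
            prof_frames.append(frame)
        emit("metagene_profile", pd.concat(prof_frames, ignore_index=True))

        subset_frames = []
        for label in ("up", "down", "silent"):
            subset = set(classes.index[classes["label"] == label])
            for cond in (config.condition_a, config.condition_b):
                prof = profiles.tss_profile(
                    genes, annotation, matrix, design, cond,
                    gene_subset=subset, window=config.association_window,
                    bin_bp=config.flank_bin_bp)
                prof.insert(0, "condition", cond)
                prof.insert(0, "gene_class", label)
                subset_frames.append(prof)
        emit("tss_profiles_by_class", pd.concat(subset_frames, ignore_index=True))

        promoter_means = {
            cond: profiles.tss_window_mean(genes, annotation, matrix, design,
                                           cond, window=config.promoter_window)
            for cond in (config.condition_a, config.condition_b)
        }
        pm_frame = pd.DataFrame(promoter_means)
        emit("promoter_means", pm_frame.reset_index())
        comparison = expr_mod.compare_promoter_methylation(classes, promoter_means)
        emit("promoter_methylation_groups", comparison.groups)
        emit("promoter_methylation_tests", comparison.pairwise)

        if config.peaks_increased and config.peaks_decreased:
            stage = "histone"
            peaks_inc = read_regions_bed(config.peaks_increased, "peaks_increased")
            peaks_dec = read_regions_bed(config.peaks_decreased, "peaks_decreased")
            conds = (config.condition_a, config.condition_b)
            frames = [
                histone.region_methylation(rs, annotation, matrix, design, conds).to_frame()
                for rs in (peaks_inc, peaks_dec)
            ]
            if config.chrom_sizes:
                sizes = pd.read_csv(config.chrom_sizes, sep="\t")
                space = RegionSet("analysis_space",
                                  [(r.chrom, 0, int(r.size)) for r in sizes.itertuples()])
                markfree = histone.markfree_complement(peaks_inc, peaks_dec, space)
                frames.append(
                    histone.region_methylation(
                        markfree, annotation, matrix, design, conds).to_frame())
            emit("region_methylation", pd.concat(frames, ignore_index=True))

        if config.other_beta:
            stage = "specificity"
            other, other_ann = read_beta_matrix(config.other_beta, config.annotation)
            other = other.subset_probes(other.probes.intersection(matrix.probes))
            other_design = SampleDesign({s: s for s in other.samples})
            other_pm = pd.DataFrame({
                ct: profiles.tss_window_mean(genes, other_ann, other, other_design,
                                             ct, window=config.promoter_window)
                for ct in other.samples
            })
            candidates = specificity.select_candidate_genes(
                promoter_means, classes, config.beta_cutoff)
            esc_pm = pm_frame.mean(axis=1)
            tier_frames = []
            for label, gene_list in candidates.items():
                calls_s = specificity.classify_specificity(
                    gene_list, esc_pm, other_pm, config.specificity_delta)
                calls_s.insert(0, "gene_class", label)
                tier_frames.append(calls_s.reset_index())
            emit("specificity_tiers", pd.concat(tier_frames, ignore_index=True))

            if config.expression_panel:
                panel = pd.read_csv(config.expression_panel, sep="\t", index_col=0)
                tiers_all = pd.concat(tier_frames, ignore_index=True)
                spec_up = tiers_all.loc[
                    (tiers_all["gene_class"] == "up")
                    & (tiers_all["tier"] == "esc_specific"), "gene_id"].tolist()
                if len(spec_up) >= 2:
                    z, comp = specificity.zscore_expression(
                        panel, spec_up, reference=config.condition_b)
                    emit("specific_gene_expression_z", z.reset_index())
                    emit("specific_gene_expression_tests", comp.pairwise)

        emit("manifest", pd.DataFrame(
            {"output": list(manifest), "path": [str(p) for p in manifest.values()]}))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return manifest
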