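"""Synthetic methylome bundles with recorded ground truth.

The generator emits every input the pipeline consumes — beta and
detection-p matrices with probe annotation, gene models, a two-condition
FPKM table, differential histone-peak BEDs, a panel of other-cell-type
methylomes and a cross-cell-type expression matrix — while recording the
planted effects, so each pipeline stage can be validated closed-loop.

Statistical structure emulated:

* a trimodal beta-value mixture (defaults 39% hypomethylated < 0.2,
  21% intermediate, 40% hypermethylated > 0.7), each component truncated
  to its bin so the planted bin counts are exact;
* TSS-proximal hypomethylation dips: promoter CpGs (-300..+700 bp) of
  expressed genes are drawn from the hypomethylated component;
* a planted set of differential CpGs with a stated beta shift applied to
  the second condition;
* log-scale FPKM expression with planted fold changes above the 1.5
  cutoff and a silent (FPKM < 0.01) gene class;
* histone-peak regions placed over hypomethylated promoters;
* other-cell-type methylomes with planted promoter hypermethylation per
  specificity tier (cell-specific / partial / nonspecific), plus an
  expression panel in which cell-specific genes are expressed only in
  the stromal cells.

Per-sample measurement noise is additive Gaussian on the logit scale
(default sd 0.1), small enough that threshold-based calls behave as in
the noise-free analysis; set ``noise_sd=0`` for exactly noise-free data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from .io import (
    BetaMatrix,
    ExpressionTable,
    GeneModel,
    ProbeAnnotation,
    RegionSet,
    SampleDesign,
    ValidationError,
    write_beta_matrix,
    write_expression_table,
    write_gene_models,
    write_probe_annotation,
    write_regions_bed,
    write_sample_design,
    write_table,
)

_EPS = 1e-9


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; the defaults are the study conditions
    at laptop scale (100k CpGs, 5k genes, two samples per condition, an
    8-cell-type methylation panel)."""

    seed: int
    n_cpgs: int = 100_000
    n_genes: int = 5_000
    n_chroms: int = 4
    samples_per_condition: int = 2
    condition_a: str = "non_decidualized"
    condition_b: str = "decidualized"

    # beta mixture (bin-truncated components)
    fraction_hypo: float = 0.39
    fraction_mid: float = 0.21
    fraction_hyper: float = 0.40
    hypo_shape: tuple[float, float] = (1.5, 20.0)
    mid_shape: tuple[float, float] = (4.0, 4.0)
    hyper_shape: tuple[float, float] = (20.0, 1.5)

    # promoter structure
    cpgs_per_promoter: int = 6
    promoter_window: tuple[int, int] = (-300, 700)

    # planted differential CpGs (condition B minus condition A)
    n_differential_hyper: int = 15
    n_differential_hypo: int = 8
    differential_delta: float = 0.5

    # expression model
    n_up: int = 800
    n_down: int = 700
    n_silent: int = 1000
    planted_fold: float = 2.0
    log2_fpkm_mean: float = 3.0
    log2_fpkm_sd: float = 1.5

    # histone peaks (placed over promoters of up/down genes)
    n_peaks_increased: int = 346
    n_peaks_decreased: int = 284

    # cross-cell-type specificity panel
    n_other_celltypes: int = 8
    n_specific_up: int = 63
    n_partial_up: int = 318
    n_specific_down: int = 43
    n_partial_down: int = 279
    specificity_delta: float = 0.5
    expression_celltypes: tuple[str, ...] = ("brain", "liver", "pancreas", "spleen", "saliva")

    # noise & QC probes
    noise_sd: float = 0.1
    detection_fail_fraction: float = 0.001
    chry_fraction: float = 0.002

    def validate(self) -> None:
        fr = self.fraction_hypo + self.fraction_mid + self.fraction_hyper
        if abs(fr - 1.0) > 1e-9:
            raise ValidationError(f"mixture fractions sum to {fr}, not 1")
        if self.n_genes * self.cpgs_per_promoter >= self.n_cpgs:
            raise ValidationError("promoter CpGs would exceed the CpG budget")
        n_expressed = self.n_genes - self.n_silent
        forced_hypo = n_expressed * self.cpgs_per_promoter
        if forced_hypo > round(self.fraction_hypo * self.n_cpgs):
            raise ValidationError(
                "promoter CpGs of expressed genes exceed the hypomethylated "
                "component budget; raise fraction_hypo or n_cpgs"
            )
        if self.n_up + self.n_down + self.n_silent > self.n_genes:
            raise ValidationError("expression class counts exceed n_genes")
        if self.n_specific_up + self.n_partial_up > self.n_up:
            raise ValidationError("planted up-gene specificity tiers exceed n_up")
        if self.n_specific_down + self.n_partial_down > self.n_down:
            raise ValidationError("planted down-gene specificity tiers exceed n_down")
        if self.n_peaks_increased > self.n_up or self.n_peaks_decreased > self.n_down:
            raise ValidationError("more peak regions than genes of the matching class")
        n_diff = self.n_differential_hyper + self.n_differential_hypo
        if n_diff > self.n_cpgs - self.n_genes * self.cpgs_per_promoter:
            raise ValidationError("more planted differential CpGs than background CpGs")
        if not (0.0 < self.differential_delta <= 1.0):
            raise ValidationError("differential_delta must be in (0, 1]")
        if self.samples_per_condition < 1 or self.n_other_celltypes < 1:
            raise ValidationError("need >= 1 sample per condition and >= 1 other cell type")
        if (self.n_partial_up or self.n_partial_down) and self.n_other_celltypes < 2:
            raise ValidationError("partial specificity tiers need >= 2 other cell types")


@dataclass
class GroundTruth:
    """The planted effects, keyed exactly as the emitted files are."""

    differential: pd.DataFrame       # probe_id, direction (hyper/hypo), delta
    expression_labels: pd.Series     # gene_id -> up/down/silent/unchanged
    specificity: pd.DataFrame        # gene_id, class (up/down), tier, hyper celltypes
    peak_genes: dict[str, list[str]]  # region-set name -> gene ids under peaks


@dataclass
class SimulatedBundle:
    """In-memory simulation outputs mirroring the on-disk layout."""

    config: SimulationConfig
    matrix: BetaMatrix
    annotation: ProbeAnnotation
    design: SampleDesign
    genes: list[GeneModel]
    expression: ExpressionTable
    peaks_increased: RegionSet
    peaks_decreased: RegionSet
    other_matrix: BetaMatrix          # one sample column per other cell type
    expression_panel: pd.DataFrame    # genes x (cond_a, cond_b, *expression_celltypes)
    chrom_sizes: dict[str, int]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every input file the pipeline consumes, plus ground truth."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "beta": out / "beta.tsv",
            "detection_p": out / "detection_p.tsv",
            "annotation": out / "annotation.tsv",
            "design": out / "design.tsv",
            "genes": out / "genes.tsv",
            "expression": out / "expression.tsv",
            "peaks_increased": out / "peaks_increased.bed",
            "peaks_decreased": out / "peaks_decreased.bed",
            "other_beta": out / "other_celltypes_beta.tsv",
            "expression_panel": out / "expression_panel.tsv",
            "chrom_sizes": out / "chrom_sizes.tsv",
            "truth_differential": out / "truth_differential.tsv",
            "truth_expression": out / "truth_expression.tsv",
            "truth_specificity": out / "truth_specificity.tsv",
        }
        write_beta_matrix(self.matrix, paths["beta"], paths["detection_p"])
        write_probe_annotation(self.annotation, paths["annotation"])
        write_sample_design(self.design, paths["design"])
        write_gene_models(self.genes, paths["genes"])
        write_expression_table(self.expression, paths["expression"])
        write_regions_bed(self.peaks_increased, paths["peaks_increased"])
        write_regions_bed(self.peaks_decreased, paths["peaks_decreased"])
        write_beta_matrix(self.other_matrix, paths["other_beta"])
        self.expression_panel.to_csv(paths["expression_panel"], sep="\t",
                                     index=True, index_label="gene_id")
        write_table(
            pd.DataFrame({"chrom": list(self.chrom_sizes),
                          "size": list(self.chrom_sizes.values())}),
            paths["chrom_sizes"],
        )
        write_table(self.truth.differential, paths["truth_differential"])
        write_table(
            self.truth.expression_labels.rename("label").reset_index(),
            paths["truth_expression"],
        )
        write_table(self.truth.specificity.reset_index(), paths["truth_specificity"])
        return paths


def default_paper_like_config(seed: int) -> SimulationConfig:
    """The default study-like config: runs end-to-end in minutes on one core."""
    cfg = SimulationConfig(seed=seed)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------


def _truncated_beta(rng: np.random.Generator, shape: tuple[float, float],
                    lo: float, hi: float, size: int) -> np.ndarray:
    """Inverse-CDF sample of a Beta distribution truncated to [lo, hi]."""
    a, b = shape
    p_lo, p_hi = beta_dist.cdf([lo, hi], a, b)
    u = rng.uniform(size=size)
    return np.clip(beta_dist.ppf(p_lo + u * (p_hi - p_lo), a, b), lo, hi)


def _component_betas(rng: np.random.Generator, cfg: SimulationConfig,
                     components: np.ndarray) -> np.ndarray:
    """Draw baseline betas per component label (0=hypo, 1=mid, 2=hyper)."""
    out = np.empty(components.size, dtype=float)
    for comp, (shape, lo, hi) in enumerate(
        [
            (cfg.hypo_shape, 0.0, 0.2 - _EPS),
            (None, 0.2, 0.7),  # mid: rescaled Beta into [0.2, 0.7]
            (cfg.hyper_shape, 0.7 + _EPS, 1.0),
        ]
    ):
        mask = components == comp
        n = int(mask.sum())
        if n == 0:
            continue
        if comp == 1:
            a, b = cfg.mid_shape
            out[mask] = 0.2 + 0.5 * rng.beta(a, b, size=n)
        else:
            out[mask] = _truncated_beta(rng, shape, lo, hi, n)
    return out


def _noisy_samples(rng: np.random.Generator, base: np.ndarray,
                   n_samples: int, sd: float) -> np.ndarray:
    """Per-sample betas: logit-scale Gaussian noise around the base values."""
    if sd == 0.0:
        return np.tile(base[:, None], (1, n_samples))
    z = logit(np.clip(base, 1e-4, 1 - 1e-4))
    noise = rng.normal(0.0, sd, size=(base.size, n_samples))
    return expit(z[:, None] + noise)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate(config: SimulationConfig) -> SimulatedBundle:
    """Build a fully reproducible synthetic bundle from the config seed."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- gene layout: fixed slots on a few synthetic autosomes -------------
    slot = 20_000
    genes_per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    chrom_sizes = {f"chr{i + 1}": genes_per_chrom * slot + slot
                   for i in range(cfg.n_chroms)}
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    lengths = rng.integers(2_000, 10_001, size=cfg.n_genes)
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        chrom = f"chr{i % cfg.n_chroms + 1}"
        slot_start = (i // cfg.n_chroms) * slot
        anchor = slot_start + 4_000  # leaves room for flanks inside the slot
        if strands[i] == "+":
            tss, tes = anchor, anchor + int(lengths[i])
        else:
            tss, tes = anchor + int(lengths[i]), anchor
        genes.append(GeneModel(f"gene{i:05d}", chrom, strands[i], tss, tes))

    # --- expression classes -------------------------------------------------
    gene_ids = np.array([g.gene_id for g in genes])
    order = rng.permutation(cfg.n_genes)
    up_idx = order[: cfg.n_up]
    down_idx = order[cfg.n_up: cfg.n_up + cfg.n_down]
    silent_idx = order[cfg.n_up + cfg.n_down: cfg.n_up + cfg.n_down + cfg.n_silent]
    labels = np.full(cfg.n_genes, "unchanged", dtype=object)
    labels[up_idx] = "up"
    labels[down_idx] = "down"
    labels[silent_idx] = "silent"

    base_fpkm = np.maximum(
        2.0 ** rng.normal(cfg.log2_fpkm_mean, cfg.log2_fpkm_sd, size=cfg.n_genes), 0.02
    )
    fpkm_a = base_fpkm.copy()
    fpkm_b = base_fpkm.copy()
    fpkm_b[up_idx] = fpkm_a[up_idx] * cfg.planted_fold
    fpkm_b[down_idx] = fpkm_a[down_idx] / cfg.planted_fold
    unchanged = labels == "unchanged"
    fpkm_b[unchanged] = fpkm_a[unchanged] * rng.uniform(0.75, 4.0 / 3.0, int(unchanged.sum()))
    fpkm_a[silent_idx] = rng.uniform(0.0, 0.009, cfg.n_silent)
    fpkm_b[silent_idx] = rng.uniform(0.0, 0.009, cfg.n_silent)
    expression = ExpressionTable(
        pd.DataFrame({"fpkm_a": fpkm_a, "fpkm_b": fpkm_b},
                     index=pd.Index(gene_ids, name="gene_id"))
    )

    # --- CpG placement ------------------------------------------------------
    lo_w, hi_w = cfg.promoter_window
    n_prom = cfg.n_genes * cfg.cpgs_per_promoter
    n_bg = cfg.n_cpgs - n_prom

    prom_chrom = np.empty(n_prom, dtype=object)
    prom_pos = np.empty(n_prom, dtype=int)
    prom_gene_idx = np.repeat(np.arange(cfg.n_genes), cfg.cpgs_per_promoter)
    offsets = rng.integers(lo_w, hi_w, size=n_prom)  # signed TSS distances
    for k, gi in enumerate(prom_gene_idx):
        g = genes[gi]
        prom_chrom[k] = g.chrom
        prom_pos[k] = g.tss + offsets[k] if g.strand == "+" else g.tss - offsets[k]

    # background CpGs: uniform, rejected out of all promoter windows so that
    # promoter means are governed by the planted promoter CpGs alone
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in genes:
        if g.strand == "+":
            forbidden[g.chrom].append((g.tss + lo_w, g.tss + hi_w))
        else:
            forbidden[g.chrom].append((g.tss - hi_w + 1, g.tss - lo_w + 1))
    forb_sorted = {}
    for chrom, ivs in forbidden.items():
        ivs.sort()
        forb_sorted[chrom] = (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))

    chrom_names = list(chrom_sizes)
    bg_chrom = np.array(chrom_names, dtype=object)[rng.integers(0, cfg.n_chroms, n_bg)]
    bg_pos = np.empty(n_bg, dtype=int)
    for chrom in chrom_names:
        mask = bg_chrom == chrom
        need = int(mask.sum())
        starts, ends = forb_sorted[chrom]
        got: list[np.ndarray] = []
        while need > 0:
            cand = rng.integers(0, chrom_sizes[chrom], size=max(need * 2, 16))
            if starts.size:
                idx = np.searchsorted(starts, cand, side="right") - 1
                inside = (idx >= 0) & (cand < ends[np.clip(idx, 0, len(ends) - 1)])
                cand = cand[~inside]
            cand = cand[:need]
            got.append(cand)
            need -= cand.size
        bg_pos[mask] = np.concatenate(got)

    probe_ids = np.array([f"cg{i:08d}" for i in range(cfg.n_cpgs)], dtype=object)
    chroms_all = np.concatenate([prom_chrom, bg_chrom])
    pos_all = np.concatenate([prom_pos, bg_pos])

    # --- baseline component assignment (exact planted bin counts) ----------
    n_hypo_t = int(round(cfg.fraction_hypo * cfg.n_cpgs))
    n_mid_t = int(round(cfg.fraction_mid * cfg.n_cpgs))
    n_hyper_t = cfg.n_cpgs - n_hypo_t - n_mid_t
    components = np.empty(cfg.n_cpgs, dtype=int)
    expressed_gene = labels != "silent"
    prom_forced = expressed_gene[prom_gene_idx]          # promoter CpGs of expressed genes
    components[:n_prom][prom_forced] = 0
    n_forced = int(prom_forced.sum())
    free_slots = np.concatenate([np.flatnonzero(~prom_forced),
                                 np.arange(n_prom, cfg.n_cpgs)])
    pool = np.concatenate([
        np.zeros(n_hypo_t - n_forced, dtype=int),
        np.ones(n_mid_t, dtype=int),
        np.full(n_hyper_t, 2, dtype=int),
    ])
    components[free_slots] = rng.permutation(pool)
    base = _component_betas(rng, cfg, components)

    # --- planted differential CpGs (background only) ------------------------
    bg_idx = np.arange(n_prom, cfg.n_cpgs)
    bg_hypo = bg_idx[components[bg_idx] == 0]
    bg_hyper = bg_idx[components[bg_idx] == 2]
    hyper_dir = rng.choice(bg_hypo, size=cfg.n_differential_hyper, replace=False)
    hypo_dir = rng.choice(np.setdiff1d(bg_hyper, hyper_dir),
                          size=cfg.n_differential_hypo, replace=False)
    delta = np.zeros(cfg.n_cpgs)
    delta[hyper_dir] = cfg.differential_delta
    delta[hypo_dir] = -cfg.differential_delta
    base_b = np.clip(base + delta, 0.0, 1.0)

    # --- ESC beta matrix with QC-bait probes --------------------------------
    nspc = cfg.samples_per_condition
    samples_a = [f"{cfg.condition_a}_{i + 1}" for i in range(nspc)]
    samples_b = [f"{cfg.condition_b}_{i + 1}" for i in range(nspc)]
    beta_a = _noisy_samples(rng, base, nspc, cfg.noise_sd)
    beta_b = _noisy_samples(rng, base_b, nspc, cfg.noise_sd)
    beta = np.hstack([beta_a, beta_b])

    n_fail = int(round(cfg.detection_fail_fraction * cfg.n_cpgs))
    n_chry = int(round(cfg.chry_fraction * cfg.n_cpgs))
    extra_ids = np.array(
        [f"cgF{i:07d}" for i in range(n_fail)] + [f"cgY{i:07d}" for i in range(n_chry)],
        dtype=object,
    )
    n_extra = n_fail + n_chry
    if n_extra:
        extra_comp = rng.integers(0, 3, size=n_extra)
        extra_base = _component_betas(rng, cfg, extra_comp)
        extra_beta = _noisy_samples(rng, extra_base, 2 * nspc, cfg.noise_sd)
        beta = np.vstack([beta, extra_beta])
        extra_chrom = np.concatenate([
            np.array(chrom_names, dtype=object)[rng.integers(0, cfg.n_chroms, n_fail)],
            np.full(n_chry, "chrY", dtype=object),
        ])
        extra_pos = rng.integers(0, min(chrom_sizes.values()), size=n_extra)
        chroms_all = np.concatenate([chroms_all, extra_chrom])
        pos_all = np.concatenate([pos_all, extra_pos])
        probe_ids = np.concatenate([probe_ids, extra_ids])

    all_samples = samples_a + samples_b
    detp = rng.uniform(0.0, 0.01, size=beta.shape)
    if n_fail:
        fail_rows = np.arange(cfg.n_cpgs, cfg.n_cpgs + n_fail)
        fail_col = rng.integers(0, len(all_samples), size=n_fail)
        detp[fail_rows, fail_col] = rng.uniform(0.06, 0.5, size=n_fail)

    index = pd.Index(probe_ids, name="probe_id")
    matrix = BetaMatrix(
        pd.DataFrame(beta, index=index, columns=all_samples),
        pd.DataFrame(detp, index=index, columns=all_samples),
    )
    annotation = ProbeAnnotation(
        pd.DataFrame({"chrom": chroms_all, "pos": pos_all}, index=index)
    )
    design = SampleDesign(
        {**{s: cfg.condition_a for s in samples_a},
         **{s: cfg.condition_b for s in samples_b}}
    )

    # --- histone peaks over promoters of differentially expressed genes ----
    def promoter_interval(g: GeneModel) -> tuple[str, int, int]:
        if g.strand == "+":
            return (g.chrom, g.tss + lo_w, g.tss + hi_w)
        return (g.chrom, g.tss - hi_w + 1, g.tss - lo_w + 1)

    inc_genes = rng.choice(up_idx, size=cfg.n_peaks_increased, replace=False)
    dec_genes = rng.choice(down_idx, size=cfg.n_peaks_decreased, replace=False)
    peaks_increased = RegionSet("peaks_increased",
                               [promoter_interval(genes[i]) for i in inc_genes])
    peaks_decreased = RegionSet("peaks_decreased",
                               [promoter_interval(genes[i]) for i in dec_genes])

    # --- other-cell-type methylomes with planted specificity tiers ---------
    celltypes = [f"celltype_{i + 1}" for i in range(cfg.n_other_celltypes)]
    tiers = np.full(cfg.n_genes, "", dtype=object)
    hyper_sets: dict[int, set[str]] = {}

    def plant(idx_pool: np.ndarray, n_spec: int, n_part: int) -> None:
        chosen = rng.choice(idx_pool, size=n_spec + n_part, replace=False)
        for j, gi in enumerate(chosen):
            if j < n_spec:
                tiers[gi] = "esc_specific"
                hyper_sets[gi] = set(celltypes)
            else:
                tiers[gi] = "partial"
                k = int(rng.integers(1, cfg.n_other_celltypes))
                hyper_sets[gi] = set(rng.choice(celltypes, size=k, replace=False))
        for gi in idx_pool:
            if tiers[gi] == "":
                tiers[gi] = "nonspecific"
                hyper_sets[gi] = set()

    plant(up_idx, cfg.n_specific_up, cfg.n_partial_up)
    plant(down_idx, cfg.n_specific_down, cfg.n_partial_down)

    other_cols = {}
    for ct in celltypes:
        shift = np.zeros(cfg.n_cpgs + n_extra)
        for gi, cts in hyper_sets.items():
            if ct in cts:
                sl = slice(gi * cfg.cpgs_per_promoter, (gi + 1) * cfg.cpgs_per_promoter)
                shift[sl] = cfg.specificity_delta
        ct_base = np.clip(np.concatenate([base, extra_base]) if n_extra else base, 0, 1)
        ct_base = np.clip(ct_base + shift, 0.0, 1.0)
        other_cols[ct] = _noisy_samples(rng, ct_base, 1, cfg.noise_sd)[:, 0]
    other_matrix = BetaMatrix(pd.DataFrame(other_cols, index=index))

    # --- expression panel (stromal conditions + other cell types) ----------
    panel = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    panel[cfg.condition_a] = fpkm_a
    panel[cfg.condition_b] = fpkm_b
    specific = np.array([tiers[i] == "esc_specific" for i in range(cfg.n_genes)])
    for ct in cfg.expression_celltypes:
        vals = np.maximum(
            2.0 ** rng.normal(cfg.log2_fpkm_mean, cfg.log2_fpkm_sd, cfg.n_genes), 0.02
        )
        vals[specific] = 2.0 ** rng.normal(-3.0, 0.5, int(specific.sum()))
        panel[ct] = vals

    truth = GroundTruth(
        differential=pd.DataFrame(
            {
                "probe_id": probe_ids[np.concatenate([hyper_dir, hypo_dir])],
                "direction": ["hyper"] * cfg.n_differential_hyper
                + ["hypo"] * cfg.n_differential_hypo,
                "delta": delta[np.concatenate([hyper_dir, hypo_dir])],
            }
        ),
        expression_labels=pd.Series(labels, index=pd.Index(gene_ids, name="gene_id")),
        specificity=pd.DataFrame(
            {
                "class": labels[np.concatenate([up_idx, down_idx])],
                "tier": tiers[np.concatenate([up_idx, down_idx])],
                "n_hyper_celltypes": [len(hyper_sets[i])
                                      for i in np.concatenate([up_idx, down_idx])],
            },
            index=pd.Index(gene_ids[np.concatenate([up_idx, down_idx])], name="gene_id"),
        ),
        peak_genes={
            "peaks_increased": list(gene_ids[inc_genes]),
            "peaks_decreased": list(gene_ids[dec_genes]),
        },
    )

    return SimulatedBundle(
        config=cfg,
        matrix=matrix,
        annotation=annotation,
        design=design,
        genes=genes,
        expression=expression,
        peaks_increased=peaks_increased,
        peaks_decreased=peaks_decreased,
        other_matrix=other_matrix,
        expression_panel=panel,
        chrom_sizes={**chrom_sizes, "chrY": min(chrom_sizes.values())},
        truth=truth,
    )


def small_config(seed: int, **overrides) -> SimulationConfig:
    """A miniature config for fast unit tests (seconds, not minutes)."""
    defaults = dict(
        n_cpgs=6_000,
        n_genes=400,
        n_up=80,
        n_down=70,
        n_silent=80,
        n_peaks_increased=30,
        n_peaks_decreased=25,
        n_specific_up=10,
        n_partial_up=25,
        n_specific_down=6,
        n_partial_down=15,
        n_differential_hyper=8,
        n_differential_hypo=5,
    )
    defaults.update(overrides)
    cfg = SimulationConfig(seed=seed, **defaults)
    cfg.validate()
    return cfg
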