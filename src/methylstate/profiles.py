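"""Strand-aware CpG-to-gene-structure assignment and metagene profiles.

Each gene contributes three spans: an upstream flank (default 1500 bp
before the TSS), the gene body (TSS to TES, rescaled to [0, 1]) and a
downstream flank (default 1000 bp past the TES).  All distance
arithmetic is strand-aware through :func:`signed_tss_distance`: negative
values are upstream of the TSS regardless of strand.  Profiles report
per-bin 25/50/75% quantiles of condition-mean beta, the standard way
aggregate methylation is displayed along a composite gene axis.

Boundary conventions (the field's figures rarely state them): upstream
covers signed distances [-upstream_bp, 0), the body [0, length] with the
TSS mapping to rescaled position 0 and the TES to 1 exactly, and the
downstream flank (length, length + downstream_bp].  The promoter window
used for per-gene summaries is half-open, [-300, +700) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, GeneModel, ProbeAnnotation, SampleDesign, ValidationError


def signed_tss_distance(gene: GeneModel, chrom: str, position: int) -> int | None:
    """Signed bp from the gene's TSS to ``position``; None if on another chromosome.

    Negative means upstream (promoter side), positive downstream into the
    gene, for both strands: on the minus strand coordinates greater than
    the TSS are upstream.
    """
    if chrom != gene.chrom:
        return None
    if gene.strand == "+":
        return position - gene.tss
    return gene.tss - position


class _ChromIndex:
    """Per-chromosome sorted probe positions for fast interval queries."""

    def __init__(self, annotation: ProbeAnnotation):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tab = annotation.table
        for chrom, sub in tab.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            order = np.argsort(pos, kind="stable")
            self.by_chrom[str(chrom)] = (pos[order], sub.index.to_numpy()[order])

    def query(self, chrom: str, left: int, right: int) -> tuple[np.ndarray, np.ndarray]:
        """Probes with left <= pos <= right (closed interval in genomic bp)."""
        if chrom not in self.by_chrom:
            return np.empty(0, dtype=int), np.empty(0, dtype=object)
        pos, ids = self.by_chrom[chrom]
        lo = np.searchsorted(pos, left, side="left")
        hi = np.searchsorted(pos, right, side="right")
        return pos[lo:hi], ids[lo:hi]


def assign_cpgs(
    genes: list[GeneModel],
    annotation: ProbeAnnotation,
    upstream_bp: int = 1500,
    downstream_bp: int = 1000,
) -> pd.DataFrame:
    """Assign every CpG to the gene regions whose span contains it.

    Returns one row per (gene, CpG, region) hit with columns probe_id,
    gene_id, region ('upstream'|'body'|'downstream') and rel_position
    (signed bp for flanks, rescaled fraction in [0, 1] for the body).
    A CpG inside several genes' spans yields several rows.
    """
    if not genes:
        raise ValidationError("assign_cpgs requires a non-empty gene list")
    index = _ChromIndex(annotation)
    rows: list[tuple] = []
    for gene in genes:
        length = gene.length
        if length == 0:
            warnings.warn(f"gene {gene.gene_id!r} has tss == tes; skipped "
                          "(body rescaling undefined)")
            continue
        if gene.strand == "+":
            left, right = gene.tss - upstream_bp, gene.tes + downstream_bp
        else:
            left, right = gene.tes - downstream_bp, gene.tss + upstream_bp
        pos, ids = index.query(gene.chrom, left, right)
        if pos.size == 0:
            continue
        d = (pos - gene.tss) if gene.strand == "+" else (gene.tss - pos)
        up = (d >= -upstream_bp) & (d < 0)
        body = (d >= 0) & (d <= length)
        down = (d > length) & (d <= length + downstream_bp)
        for pid, di in zip(ids[up], d[up]):
            rows.append((pid, gene.gene_id, "upstream", float(di)))
        for pid, di in zip(ids[body], d[body]):
            rows.append((pid, gene.gene_id, "body", float(di) / length))
        for pid, di in zip(ids[down], d[down]):
            rows.append((pid, gene.gene_id, "downstream", float(di - length)))
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "region", "rel_position"])


@dataclass(frozen=True)
class MetageneProfile:
    """Per-bin beta quantiles along the composite upstream/body/downstream axis.

    ``bins`` has columns region, bin_start, bin_end (bp for flanks,
    fraction for body), n, q25, q50, q75; empty bins carry NaN quantiles.
    """

    bins: pd.DataFrame
    upstream_bp: int
    downstream_bp: int
    body_bins: int
    flank_bin_bp: int


def _quantile_rows(values_per_bin: list[np.ndarray]) -> list[tuple]:
    rows = []
    for vals in values_per_bin:
        if vals.size == 0:
            rows.append((0, np.nan, np.nan, np.nan))
        else:
            q25, q50, q75 = np.quantile(vals, [0.25, 0.5, 0.75])  # linear interpolation
            rows.append((int(vals.size), q25, q50, q75))
    return rows


def metagene_profile(
    assignments: pd.DataFrame,
    matrix: BetaMatrix,
    design: SampleDesign,
    condition: str,
    gene_subset: set[str] | None = None,
    body_bins: int = 40,
    flank_bin_bp: int = 100,
    upstream_bp: int = 1500,
    downstream_bp: int = 1000,
) -> MetageneProfile:
    """Quantile profile of condition-mean beta over the three-region axis."""
    betas = matrix.condition_mean(design, condition)
    a = assignments
    if gene_subset is not None:
        a = a[a["gene_id"].isin(gene_subset)]
    a = a[a["probe_id"].isin(betas.index)]
    vals = betas.loc[a["probe_id"]].to_numpy()
    region = a["region"].to_numpy()
    rel = a["rel_position"].to_numpy(dtype=float)

    n_up = upstream_bp // flank_bin_bp
    n_down = downstream_bp // flank_bin_bp
    records: list[tuple] = []

    # upstream: [-upstream_bp, 0) in flank_bin_bp steps
    up_vals = vals[region == "upstream"]
    up_rel = rel[region == "upstream"]
    up_edges = np.linspace(-upstream_bp, 0, n_up + 1)
    idx = np.clip(np.digitize(up_rel, up_edges) - 1, 0, n_up - 1)
    per_bin = [up_vals[idx == i] for i in range(n_up)]
    for i, stats in enumerate(_quantile_rows(per_bin)):
        records.append(("upstream", up_edges[i], up_edges[i + 1], *stats))

    # body: fraction [0, 1]; last bin right-closed so rel == 1 is included
    b_vals = vals[region == "body"]
    b_rel = rel[region == "body"]
    b_edges = np.linspace(0.0, 1.0, body_bins + 1)
    idx = np.clip(np.digitize(b_rel, b_edges, right=False) - 1, 0, body_bins - 1)
    per_bin = [b_vals[idx == i] for i in range(body_bins)]
    for i, stats in enumerate(_quantile_rows(per_bin)):
        records.append(("body", b_edges[i], b_edges[i + 1], *stats))

    # downstream: (0, downstream_bp] beyond the TES
    d_vals = vals[region == "downstream"]
    d_rel = rel[region == "downstream"]
    d_edges = np.linspace(0, downstream_bp, n_down + 1)
    idx = np.clip(np.ceil(d_rel / flank_bin_bp).astype(int) - 1, 0, n_down - 1)
    per_bin = [d_vals[idx == i] for i in range(n_down)]
    for i, stats in enumerate(_quantile_rows(per_bin)):
        records.append(("downstream", d_edges[i], d_edges[i + 1], *stats))

    bins = pd.DataFrame(
        records, columns=["region", "bin_start", "bin_end", "n", "q25", "q50", "q75"]
    )
    return MetageneProfile(bins, upstream_bp, downstream_bp, body_bins, flank_bin_bp)


def tss_profile(
    genes: list[GeneModel],
    annotation: ProbeAnnotation,
    matrix: BetaMatrix,
    design: SampleDesign,
    condition: str,
    gene_subset: set[str] | None = None,
    window: tuple[int, int] = (-1500, 4000),
    bin_bp: int = 100,
) -> pd.DataFrame:
    """Quantile profile on a literal TSS-relative bp window (no body rescaling).

    Used for promoter-centred views where the profiled span is a fixed
    signed window around every TSS, truncated nowhere.
    """
    betas = matrix.condition_mean(design, condition)
    lo, hi = window
    index = _ChromIndex(annotation.subset(annotation.probe_ids.intersection(betas.index)))
    dists: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for gene in genes:
        if gene_subset is not None and gene.gene_id not in gene_subset:
            continue
        if gene.strand == "+":
            left, right = gene.tss + lo, gene.tss + hi
        else:
            left, right = gene.tss - hi, gene.tss - lo
        pos, ids = index.query(gene.chrom, left, right)
        if pos.size == 0:
            continue
        d = (pos - gene.tss) if gene.strand == "+" else (gene.tss - pos)
        keep = (d >= lo) & (d < hi)
        dists.append(d[keep])
        vals.append(betas.loc[ids[keep]].to_numpy())
    if dists:
        d_all = np.concatenate(dists)
        v_all = np.concatenate(vals)
    else:
        d_all = np.empty(0)
        v_all = np.empty(0)
    edges = np.arange(lo, hi + bin_bp, bin_bp)
    idx = np.clip(np.digitize(d_all, edges) - 1, 0, len(edges) - 2)
    per_bin = [v_all[idx == i] for i in range(len(edges) - 1)]
    records = [
        (edges[i], edges[i + 1], *stats)
        for i, stats in enumerate(_quantile_rows(per_bin))
    ]
    return pd.DataFrame(records, columns=["bin_start", "bin_end", "n", "q25", "q50", "q75"])


def tss_window_mean(
    genes: list[GeneModel],
    annotation: ProbeAnnotation,
    matrix: BetaMatrix,
    design: SampleDesign,
    condition: str,
    window: tuple[int, int] = (-300, 700),
) -> pd.Series:
    """Per-gene mean beta over a signed TSS-relative window (half-open).

    The promoter summary behind gene-level methylation filters: the mean
    of condition-mean betas of CpGs with signed TSS distance in
    [window[0], window[1]).  Genes with no CpG in the window get NaN
    (absent, not zero).
    """
    betas = matrix.condition_mean(design, condition)
    lo, hi = window
    index = _ChromIndex(annotation.subset(annotation.probe_ids.intersection(betas.index)))
    out: dict[str, float] = {}
    for gene in genes:
        if gene.strand == "+":
            left, right = gene.tss + lo, gene.tss + hi
        else:
            left, right = gene.tss - hi, gene.tss - lo
        pos, ids = index.query(gene.chrom, left, right)
        if pos.size == 0:
            out[gene.gene_id] = np.nan
            continue
        d = (pos - gene.tss) if gene.strand == "+" else (gene.tss - pos)
        keep = (d >= lo) & (d < hi)
        if not keep.any():
            out[gene.gene_id] = np.nan
        else:
            out[gene.gene_id] = float(betas.loc[ids[keep]].mean())
    s = pd.Series(out, name=f"promoter_beta_{condition}")
    s.index.name = "gene_id"
    return s
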