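"""Threshold-based differential CpG calling and CpG-to-gene association.

The differential statistic is the per-CpG difference of condition-mean
beta-values, delta = beta_b - beta_a (condition A is the untreated /
non-decidualized reference).  A CpG is called differentially methylated
when |delta| strictly exceeds a cutoff (0.15 and 0.30 are the
conventional grids); "hypomethylated" means beta decreased from A to B.
No moderated statistics are involved: thresholding on delta is the
method.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BetaMatrix, GeneModel, ProbeAnnotation, SampleDesign, ValidationError, write_table
from .profiles import signed_tss_distance


@dataclass(frozen=True)
class DifferentialSummary:
    """Per-cutoff tally of differential CpGs."""

    cutoff: float
    n_valid_cpgs: int
    n_total_differential: int
    n_hypo: int
    n_hyper: int

    @property
    def fraction_of_all_cpgs(self) -> float:
        """Percent of retained CpGs that are differential (4-decimal convention)."""
        return 100.0 * self.n_total_differential / self.n_valid_cpgs


def call_differential(
    matrix: BetaMatrix,
    design: SampleDesign,
    condition_a: str,
    condition_b: str,
    cutoffs: list[float] = (0.15, 0.30),
) -> dict[float, tuple[pd.DataFrame, DifferentialSummary]]:
    """Call differential CpGs at each |delta| cutoff.

    Returns, per cutoff, a calls table with one row per retained CpG
    (columns probe_id, beta_a, beta_b, delta, direction) and a summary.
    Direction is ``hyper`` for delta > cutoff, ``hypo`` for
    delta < -cutoff, else ``unchanged`` (strict inequalities).
    """
    for c in cutoffs:
        if not (0.0 < c < 1.0):
            raise ValidationError(f"cutoff must be in (0, 1); got {c}")
    beta_a = matrix.condition_mean(design, condition_a)
    beta_b = matrix.condition_mean(design, condition_b)
    delta = beta_b - beta_a

    out: dict[float, tuple[pd.DataFrame, DifferentialSummary]] = {}
    d = np.round(delta.to_numpy(), 12)  # boundary tie-break, see classify_deltas
    for cutoff in cutoffs:
        direction = np.where(d > cutoff, "hyper",
                             np.where(d < -cutoff, "hypo", "unchanged"))
        calls = pd.DataFrame(
            {
                "probe_id": matrix.probes,
                "beta_a": beta_a.values,
                "beta_b": beta_b.values,
                "delta": delta.values,
                "direction": direction,
            }
        )
        n_hypo = int((direction == "hypo").sum())
        n_hyper = int((direction == "hyper").sum())
        summary = DifferentialSummary(
            cutoff=cutoff,
            n_valid_cpgs=len(calls),
            n_total_differential=n_hypo + n_hyper,
            n_hypo=n_hypo,
            n_hyper=n_hyper,
        )
        out[cutoff] = (calls, summary)
    return out


def classify_deltas(beta_a, beta_b, cutoff: float = 0.30) -> pd.DataFrame:
    """Classify pre-computed beta pairs by the |delta| > cutoff rule.

    Convenience for worked examples where condition-mean betas are given
    directly (e.g. a published table of beta pairs) rather than derived
    from a matrix.
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    delta = b - a
    # round before comparing so boundary-equal deltas (up to float
    # representation) stay unchanged under the strict inequality
    d = np.round(delta, 12)
    direction = np.where(d > cutoff, "hyper",
                         np.where(d < -cutoff, "hypo", "unchanged"))
    return pd.DataFrame({"beta_a": a, "beta_b": b, "delta": delta, "direction": direction})


def export_scatter(
    matrix: BetaMatrix,
    design: SampleDesign,
    condition_a: str,
    condition_b: str,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-CpG (beta_a, beta_b) table backing the two-condition scatter plot."""
    table = pd.DataFrame(
        {
            "probe_id": matrix.probes,
            "beta_a": matrix.condition_mean(design, condition_a).values,
            "beta_b": matrix.condition_mean(design, condition_b).values,
        }
    )
    if path is not None:
        table_out = table.copy()
        table_out[["beta_a", "beta_b"]] = table_out[["beta_a", "beta_b"]].round(6)
        write_table(table_out, path)
    return table


def associate_cpgs_with_genes(
    calls: pd.DataFrame,
    genes: list[GeneModel],
    annotation: ProbeAnnotation,
    window: tuple[int, int] = (-1500, 4000),
) -> pd.DataFrame:
    """Associate differential CpGs with genes by a TSS-relative window.

    A CpG associates with every gene whose signed TSS distance window
    ``[window[0], window[1]]`` contains it (multiplicity allowed); CpGs
    in no window are reported with gene_id NA.  Only rows of ``calls``
    with direction != 'unchanged' are considered.
    """
    lo, hi = window
    diff = calls[calls["direction"] != "unchanged"]
    rows = []
    ann = annotation.table
    for row in diff.itertuples(index=False):
        chrom = ann.at[row.probe_id, "chrom"]
        pos = int(ann.at[row.probe_id, "pos"])
        hit = False
        for gene in genes:
            d = signed_tss_distance(gene, chrom, pos)
            if d is not None and lo <= d <= hi:
                rows.append(
                    {"probe_id": row.probe_id, "gene_id": gene.gene_id,
                     "delta": row.delta, "tss_distance": d}
                )
                hit = True
        if not hit:
            rows.append({"probe_id": row.probe_id, "gene_id": pd.NA,
                         "delta": row.delta, "tss_distance": pd.NA})
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "delta", "tss_distance"])
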