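"""Cross-cell-type hypomethylation-specificity classification.

Candidate genes are those whose stromal-cell promoter (mean beta over
the -300..+700 bp TSS window) is hypomethylated (< 0.2) and whose
expression changes during decidualization.  Each candidate is then
compared against a panel of other cell types: a cell type counts as
hypermethylated for the gene when its promoter beta exceeds the stromal
value by more than 0.3.  Tiers:

* ``esc_specific`` — hypermethylated in every other cell type (the gene
  is less methylated in stromal cells than anywhere else on the panel);
* ``partial`` — hypermethylated in at least one but not all;
* ``nonspecific`` — hypermethylated in none.

A z-score comparison of expression across cell types (genes jointly
scaled, sample-SD convention) supports checking whether specifically
hypomethylated genes are also specifically expressed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .expression import GroupComparison, compare_groups
from .io import ValidationError


def select_candidate_genes(
    promoter_means_esc: dict[str, pd.Series],
    classes: pd.DataFrame,
    beta_cutoff: float = 0.2,
    rule: str = "pooled_mean",
) -> dict[str, list[str]]:
    """Split promoter-hypomethylated, differentially expressed genes by label.

    ``promoter_means_esc`` maps the two stromal conditions to per-gene
    promoter-mean betas.  A gene qualifies when its stromal promoter beta
    is below ``beta_cutoff`` — under ``rule='pooled_mean'`` the mean of
    the two condition values, under ``rule='both'`` both values
    individually — and its expression label is ``up`` or ``down``.
    """
    if rule not in ("pooled_mean", "both"):
        raise ValidationError(f"unknown selection rule {rule!r}")
    pm = pd.DataFrame(promoter_means_esc)
    if rule == "pooled_mean":
        hypo = pm.mean(axis=1) < beta_cutoff
    else:
        hypo = (pm < beta_cutoff).all(axis=1)
    hypo_genes = set(pm.index[hypo & pm.notna().all(axis=1)])
    out: dict[str, list[str]] = {}
    for label in ("up", "down"):
        genes = classes.index[classes["label"] == label]
        out[label] = [g for g in genes if g in hypo_genes]
    return out


def classify_specificity(
    candidates: list[str],
    esc_promoter_mean: pd.Series,
    other_promoter_means: pd.DataFrame,
    delta_cutoff: float = 0.3,
) -> pd.DataFrame:
    """Tier candidate genes by how many other cell types are hypermethylated.

    ``other_promoter_means`` is genes x cell types.  A cell type is
    hypermethylated for a gene when (other - stromal) strictly exceeds
    ``delta_cutoff``.  Genes missing a promoter mean in any cell type are
    tiered ``unclassifiable`` rather than silently dropped.
    """
    if other_promoter_means.shape[1] == 0:
        raise ValidationError("need at least one other cell type")
    n_types = other_promoter_means.shape[1]
    rows = []
    for gene in candidates:
        esc = esc_promoter_mean.get(gene, np.nan)
        others = (other_promoter_means.loc[gene]
                  if gene in other_promoter_means.index
                  else pd.Series(np.nan, index=other_promoter_means.columns))
        if np.isnan(esc) or others.isna().any():
            tier, n_hyper = "unclassifiable", pd.NA
        else:
            # deltas rounded to 12 decimals so a difference that is exactly
            # the cutoff up to float representation does not count as hyper
            n_hyper = int((np.round(others - esc, 12) > delta_cutoff).sum())
            if n_hyper == n_types:
                tier = "esc_specific"
            elif n_hyper >= 1:
                tier = "partial"
            else:
                tier = "nonspecific"
        rows.append({"gene_id": gene, "esc_promoter_beta": esc,
                     "n_hyper_in_others": n_hyper, "tier": tier})
    return pd.DataFrame(rows).set_index("gene_id")


def tier_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Counts per tier plus the nested 'hypomethylated vs at least one' total."""
    counts = calls["tier"].value_counts().to_dict()
    counts.setdefault("esc_specific", 0)
    counts.setdefault("partial", 0)
    counts.setdefault("nonspecific", 0)
    counts["partial_or_better"] = counts["esc_specific"] + counts["partial"]
    return counts


def zscore_expression(
    expression: pd.DataFrame,
    gene_subset: list[str],
    reference: str,
) -> tuple[pd.DataFrame, GroupComparison]:
    """Jointly scale expression per gene across cell types to z-scores.

    ``expression`` is genes x cell types (one expression value per cell
    type; condition means upstream).  Each gene's values are scaled
    together across all columns (sample SD, n-1); genes with zero
    variance are excluded with a warning.  Returns the z table over the
    subset and pairwise Holm-adjusted comparisons of every cell type
    against ``reference``, with each cell type's z distribution over the
    subset as the group sample.
    """
    if not gene_subset:
        raise ValidationError("gene subset is empty")
    if reference not in expression.columns:
        raise ValidationError(f"reference column {reference!r} not in expression table")
    sub = expression.loc[[g for g in gene_subset if g in expression.index]]
    sd = sub.std(axis=1, ddof=1)
    degenerate = sub.index[(sd == 0) | sd.isna()]
    if len(degenerate):
        warnings.warn(
            f"{len(degenerate)} gene(s) with zero expression variance excluded"
        )
        sub = sub.drop(index=degenerate)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    samples = {ct: z[ct].to_numpy() for ct in z.columns}
    comparison = compare_groups(samples)
    # keep only contrasts involving the reference cell type, re-adjusted as a family
    from .expression import holm_adjust

    pw = comparison.pairwise
    mask = (pw["group_1"] == reference) | (pw["group_2"] == reference)
    pw = pw.loc[mask, ["group_1", "group_2", "t", "p_raw"]].reset_index(drop=True)
    pw["p_holm"] = holm_adjust(pw["p_raw"].to_numpy())
    return z, GroupComparison(comparison.groups, pw)
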