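"""FPKM-based expression classification and group methylation comparisons.

Genes are labelled from the ratio of condition-mean FPKM values:
``up`` when the fold change strictly exceeds 1.5, ``down`` when it falls
strictly below 1/1.5, ``silent`` when both conditions are below the
0.01-FPKM floor (silent takes precedence over any ratio), otherwise
``unchanged``.  Promoter methylation is then compared across the
expression classes with plain unpaired t tests and Holm step-down
adjustment over all pairwise contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionTable, ValidationError


def classify_expression(
    table: ExpressionTable,
    fold_cutoff: float = 1.5,
    silent_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Label every gene as up / down / silent / unchanged.

    Fold change is fpkm_b / fpkm_a.  Zero denominators: if both FPKM fall
    below ``silent_cutoff`` the gene is silent regardless of ratio;
    otherwise fpkm_a == 0 gives an infinite ratio (up) and fpkm_b == 0 a
    zero ratio (down).  Inequalities are strict, so a ratio exactly at
    the cutoff is unchanged.
    """
    if fold_cutoff <= 0 or silent_cutoff <= 0:
        raise ValidationError("fold_cutoff and silent_cutoff must be > 0")
    a = table.table["fpkm_a"].to_numpy(dtype=float)
    b = table.table["fpkm_b"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.divide(b, a)
    fold = np.where((a == 0) & (b == 0), np.nan, fold)

    silent = (a < silent_cutoff) & (b < silent_cutoff)
    up = ~silent & ((fold > fold_cutoff) | ((a == 0) & (b >= silent_cutoff)))
    down = ~silent & ~up & (fold < 1.0 / fold_cutoff)
    label = np.where(silent, "silent", np.where(up, "up", np.where(down, "down", "unchanged")))
    return pd.DataFrame(
        {
            "gene_id": table.gene_ids,
            "fpkm_a": a,
            "fpkm_b": b,
            "fold_change": fold,
            "label": label,
        }
    ).set_index("gene_id")


def classify_fold_changes(ratios, fold_cutoff: float = 1.5) -> pd.Series:
    """Label pre-computed fold-change ratios (up / down / unchanged).

    For worked examples where published expression ratios are given
    directly; the silent rule needs raw FPKM and does not apply here.
    """
    r = np.asarray(ratios, dtype=float)
    return pd.Series(
        np.where(r > fold_cutoff, "up",
                 np.where(r < 1.0 / fold_cutoff, "down", "unchanged"))
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class GroupComparison:
    """Per-group summaries plus pairwise t tests with Holm adjustment.

    ``groups`` has columns group, n, mean, sd; ``pairwise`` has columns
    group_1, group_2, t, p_raw, p_holm.
    """

    groups: pd.DataFrame
    pairwise: pd.DataFrame


def compare_groups(samples: dict[str, np.ndarray], min_n: int = 2) -> GroupComparison:
    """Mean +/- SD per group and all pairwise plain unpaired t tests.

    Groups with fewer than ``min_n`` members are excluded with a warning.
    The t test is Student's (pooled variance, not Welch); all pairwise
    raw p-values are Holm-adjusted as one family.
    """
    usable: dict[str, np.ndarray] = {}
    for name, vals in samples.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < min_n:
            warnings.warn(f"group {name!r} has fewer than {min_n} members; excluded")
            continue
        usable[name] = v
    if len(usable) < 2:
        raise ValidationError("need at least two groups with enough members")
    groups = pd.DataFrame(
        [
            {"group": name, "n": v.size, "mean": float(v.mean()),
             "sd": float(v.std(ddof=1))}
            for name, v in usable.items()
        ]
    )
    rows = []
    for g1, g2 in combinations(usable, 2):
        t, p = stats.ttest_ind(usable[g1], usable[g2], equal_var=True)
        rows.append({"group_1": g1, "group_2": g2, "t": float(t), "p_raw": float(p)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())
    return GroupComparison(groups, pairwise)


def compare_promoter_methylation(
    classes: pd.DataFrame,
    promoter_means: dict[str, pd.Series],
    labels: tuple[str, ...] = ("up", "down", "silent"),
) -> GroupComparison:
    """Compare promoter beta across expression classes and conditions.

    ``promoter_means`` maps condition name to a per-gene promoter-mean
    beta Series (from :func:`methylstate.profiles.tss_window_mean`).
    One group is formed per (label, condition) pair, e.g. up-regulated
    genes in each condition, mirroring the standard boxplot layout.
    """
    samples: dict[str, np.ndarray] = {}
    for label in labels:
        genes = classes.index[classes["label"] == label]
        for cond, pm in promoter_means.items():
            vals = pm.reindex(genes).dropna().to_numpy()
            samples[f"{label}/{cond}"] = vals
    return compare_groups(samples)
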