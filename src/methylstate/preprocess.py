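"""Probe-level QC and global beta-distribution summaries.

The 450K array interrogates ~482,421 CpGs; before analysis, probes with a
detection p-value above 0.05 in any sample and probes mapping to the Y
chromosome are removed.  The retained CpGs are then summarized by their
mean +/- SD beta and by the fractions in three canonical methylation bins:
hypomethylated (beta < 0.2), intermediate (0.2 <= beta <= 0.7) and
hypermethylated (beta > 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, ProbeAnnotation, SampleDesign, ValidationError

Y_CHROM_NAMES = frozenset({"chrY", "Y"})


@dataclass(frozen=True)
class FilterReport:
    """Counts of probes removed per QC reason.

    A probe failing both rules is counted once, under the detection-p
    reason (applied first).
    """

    n_input: int
    n_removed_detection_p: int
    n_removed_chry: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["input", "detection_p", "chrY", "retained"],
                "n_probes": [
                    self.n_input,
                    self.n_removed_detection_p,
                    self.n_removed_chry,
                    self.n_retained,
                ],
            }
        )


@dataclass(frozen=True)
class BetaDistributionSummary:
    """Global distribution of beta-values for one condition or sample."""

    n_cpgs: int
    mean: float
    sd: float
    fraction_hypo: float   # beta < 0.2
    fraction_mid: float    # 0.2 <= beta <= 0.7
    fraction_hyper: float  # beta > 0.7


def filter_probes(
    matrix: BetaMatrix,
    annotation: ProbeAnnotation,
    p_cutoff: float = 0.05,
    drop_chry: bool = True,
) -> tuple[BetaMatrix, FilterReport]:
    """Remove low-confidence and Y-chromosome probes.

    A probe is removed if its detection p-value exceeds ``p_cutoff`` in
    ANY sample (conservative all-sample rule), or if it maps to the Y
    chromosome.  Idempotent: the retained set passes the same filter.
    """
    if not (0.0 < p_cutoff < 1.0):
        raise ValidationError(f"p_cutoff must be in (0, 1); got {p_cutoff}")
    n_input = matrix.shape[0]

    if matrix.detection_p is not None:
        fail_p = (matrix.detection_p > p_cutoff).any(axis=1)
    else:
        fail_p = pd.Series(False, index=matrix.probes)

    chroms = annotation.table.loc[matrix.probes, "chrom"]
    on_y = chroms.isin(Y_CHROM_NAMES) if drop_chry else pd.Series(False, index=matrix.probes)

    keep = ~(fail_p | on_y)
    filtered = matrix.subset_probes(matrix.probes[keep])
    report = FilterReport(
        n_input=n_input,
        n_removed_detection_p=int(fail_p.sum()),
        n_removed_chry=int((on_y & ~fail_p).sum()),
        n_retained=int(keep.sum()),
    )
    return filtered, report


def bin_betas(betas: np.ndarray | pd.Series) -> tuple[int, int, int]:
    """Count betas in the three canonical bins.

    Boundaries follow the printed inequalities: hypo is strict (< 0.2),
    the middle bin is closed ([0.2, 0.7]), hyper is strict (> 0.7), so
    every beta falls in exactly one bin.
    """
    b = np.asarray(betas, dtype=float)
    n_hypo = int((b < 0.2).sum())
    n_hyper = int((b > 0.7).sum())
    n_mid = b.size - n_hypo - n_hyper
    return n_hypo, n_mid, n_hyper


def summarize_beta_distribution(
    matrix: BetaMatrix,
    design: SampleDesign | None = None,
    condition: str | None = None,
    sample: str | None = None,
) -> BetaDistributionSummary:
    """Summarize the beta distribution of one condition (or one sample).

    For a condition, each probe's beta is first averaged across that
    condition's samples; statistics and bin fractions are then taken over
    the per-probe means.
    """
    if matrix.shape[0] == 0:
        raise ValidationError("cannot summarize an empty beta matrix")
    if sample is not None:
        betas = matrix.beta[sample]
    elif condition is not None:
        if design is None:
            raise ValidationError("a SampleDesign is required to resolve a condition")
        betas = matrix.condition_mean(design, condition)
    else:
        # pool all samples via per-probe mean
        betas = matrix.beta.mean(axis=1)
    n = len(betas)
    n_hypo, n_mid, n_hyper = bin_betas(betas)
    return BetaDistributionSummary(
        n_cpgs=n,
        mean=float(betas.mean()),
        sd=float(betas.std(ddof=1)) if n > 1 else 0.0,
        fraction_hypo=n_hypo / n,
        fraction_mid=n_mid / n,
        fraction_hyper=n_hyper / n,
    )
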