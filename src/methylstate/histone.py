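"""Methylation levels inside differential histone-mark regions.

Differential H3K4me3 / H3K27ac peak regions (called upstream by a peak
caller, consumed here as BED intervals) are intersected with CpG probes;
beta distributions inside the regions are summarized per condition and
compared with an unpaired t test.  The complement construction yields
"mark-free" regions — the analysis space minus the union of both
conditions' peaks — to contrast marked against unmarked chromatin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, ProbeAnnotation, RegionSet, SampleDesign, ValidationError


def intersect_cpgs(regions: RegionSet, annotation: ProbeAnnotation) -> list[str]:
    """Probe ids whose position falls in any interval (half-open containment).

    Each probe is listed once, in annotation order, even when covered by
    several intervals.
    """
    merged = {chrom: _merge(ivs) for chrom, ivs in regions.by_chrom().items()}
    tab = annotation.table
    covered = np.zeros(len(tab), dtype=bool)
    pos_all = tab["pos"].to_numpy()
    chrom_all = tab["chrom"].to_numpy()
    for chrom, ivs in merged.items():
        mask = chrom_all == chrom
        if not mask.any() or not ivs:
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        pos = pos_all[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ivs) - 1)])
        covered[mask] = ok
    return list(tab.index[covered])


@dataclass(frozen=True)
class RegionMethylation:
    """Beta summary of the CpGs overlapping one region set."""

    name: str
    n_regions: int
    n_cpgs: int
    betas: dict[str, np.ndarray]       # condition -> per-CpG condition-mean betas
    means: dict[str, float]
    sds: dict[str, float]
    t_statistic: float | None          # None when < 2 CpGs
    p_value: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region_set": self.name, "condition": cond, "n_regions": self.n_regions,
             "n_cpgs": self.n_cpgs, "mean_beta": self.means[cond],
             "sd_beta": self.sds[cond], "t": self.t_statistic, "p": self.p_value}
            for cond in self.betas
        ]
        return pd.DataFrame(rows)


def region_methylation(
    regions: RegionSet,
    annotation: ProbeAnnotation,
    matrix: BetaMatrix,
    design: SampleDesign,
    conditions: tuple[str, str],
) -> RegionMethylation:
    """Per-condition beta distribution of CpGs inside a region set.

    Reports per-CpG condition-mean betas (one value per overlapping CpG)
    with mean +/- SD per condition and an unpaired t test between the two
    conditions.  Zero overlapping CpGs yields an explicit empty result
    rather than NaN statistics.
    """
    if len(regions) == 0:
        raise ValidationError("region set is empty")
    probe_ids = [p for p in intersect_cpgs(regions, annotation) if p in matrix.probes]
    betas = {c: matrix.condition_mean(design, c).loc[probe_ids].to_numpy()
             for c in conditions}
    if len(probe_ids) == 0:
        return RegionMethylation(regions.name, len(regions), 0, betas,
                                 {c: np.nan for c in conditions},
                                 {c: np.nan for c in conditions}, None, None)
    means = {c: float(v.mean()) for c, v in betas.items()}
    sds = {c: float(v.std(ddof=1)) if v.size > 1 else 0.0 for c, v in betas.items()}
    if len(probe_ids) > 1:
        t, p = stats.ttest_ind(betas[conditions[0]], betas[conditions[1]], equal_var=True)
        t, p = float(t), float(p)
    else:
        t = p = None
    return RegionMethylation(regions.name, len(regions), len(probe_ids),
                             betas, means, sds, t, p)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping intervals, sorted and merged."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def markfree_complement(
    peaks_a: RegionSet,
    peaks_b: RegionSet,
    analysis_space: RegionSet,
    name: str = "mark_free",
) -> RegionSet:
    """Analysis space minus the union of both conditions' peak regions.

    A base is mark-free only if no peak of either condition covers it in
    the given genomic universe (chromosome extents or gene windows).
    Output intervals are sorted and non-overlapping.
    """
    if len(analysis_space) == 0:
        raise ValidationError("analysis space is empty")
    peaks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rs in (peaks_a, peaks_b):
        for chrom, ivs in rs.by_chrom().items():
            peaks_by_chrom.setdefault(chrom, []).extend(ivs)
    out: list[tuple[str, int, int]] = []
    for chrom, space_ivs in analysis_space.by_chrom().items():
        peaks = _merge(peaks_by_chrom.get(chrom, []))
        for s, e in _merge(space_ivs):
            cursor = s
            for ps, pe in peaks:
                if pe <= cursor or ps >= e:
                    continue
                if ps > cursor:
                    out.append((chrom, cursor, ps))
                cursor = max(cursor, pe)
                if cursor >= e:
                    break
            if cursor < e:
                out.append((chrom, cursor, e))
    out.sort()
    return RegionSet(name=name, intervals=out)
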